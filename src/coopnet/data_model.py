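"""Core data containers for two-wave directed support networks.

The study system is a pair of adjacent villages observed at two points in
time.  Every adult resident is an actor; a directed binary tie ``x_ij = 1``
means actor *i* reports seeking one or more kinds of help from actor *j*.
Monadic covariates (gender, age, wealth, ...) and dyadic covariates
(kinship, friendship, co-residence, geographic distance) constrain who
helps whom.

Containers here are deliberately thin wrappers over :mod:`numpy` arrays and
:mod:`pandas` frames: actor identity lives in string ids, while all
computation uses 0-based positional indexing aligned to a fixed roster
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ActorRoster",
    "NetworkWave",
    "SupportLayerSet",
    "MonadicAttributeTable",
    "DyadicAttributeSet",
    "CompositionChangeSchedule",
    "AttributeSet",
    "SUPPORT_LAYERS",
    "combine_support_layers",
    "standardize_attributes",
    "abs_difference_dyad",
    "coverage_percent",
]

#: The six elicited support layers whose union defines the composite network.
SUPPORT_LAYERS = (
    "advice",
    "labour",
    "physical_help",
    "consumables",
    "money",
    "conversation",
)

#: Monadic columns required of every attribute table.
MONADIC_COLUMNS = (
    "woman",
    "age",
    "education",
    "wealth_log",
    "reputation",
    "caste",
    "married",
    "immigrant",
    "village",
)

#: Dyadic matrices required of every dyadic attribute set.
DYADIC_NAMES = ("kinship", "friendship", "same_household", "log_distance")


class DimensionError(ValueError):
    """Raised when rosters or array shapes disagree."""


class DegenerateVariableError(ValueError):
    """Raised when a variable to be standardized has zero variance."""


@dataclass
class ActorRoster:
    """Fixed, ordered set of actors with village membership and wave presence.

    Parameters
    ----------
    ids:
        Unique opaque string tokens, one per actor. Order defines positional
        indexing for every adjacency matrix sharing this roster.
    village:
        Categorical village label per actor (two levels in the study design).
    present:
        Boolean array of shape ``(n, 2)``; column *m* flags presence at wave
        *m*. Every actor must be present in at least one wave.
    """

    ids: list[str]
    village: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.village = np.asarray(self.village)
        self.present = np.asarray(self.present, dtype=bool)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("actor ids must be unique")
        if self.village.shape != (len(self.ids),):
            raise DimensionError("village labels must align with ids")
        if self.present.shape != (len(self.ids), 2):
            raise DimensionError("presence flags must be (n, 2)")
        if not self.present.any(axis=1).all():
            raise ValueError("every actor must be present in at least one wave")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, actor_id: str) -> int:
        return self.ids.index(actor_id)


@dataclass
class NetworkWave:
    """One observation of the directed 0/1 support network.

    ``adjacency[i, j] = 1`` iff actor *i* names *j* as a source of support at
    this wave. The diagonal is structurally zero.
    """

    label: str
    adjacency: np.ndarray
    roster: ActorRoster | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DimensionError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency values must be 0/1")
        if np.diagonal(a).any():
            raise ValueError("self-ties are not allowed")
        if self.roster is not None and a.shape[0] != self.roster.n:
            raise DimensionError("adjacency dimension must equal roster size")
        self.adjacency = a.astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def tie_count(self) -> int:
        return int(self.adjacency.sum())

    def copy(self, label: str | None = None) -> "NetworkWave":
        return NetworkWave(label or self.label, self.adjacency.copy(), self.roster)


@dataclass
class SupportLayerSet:
    """Six named 0/1 layers (advice, labour, ...) on a shared roster."""

    label: str
    layers: dict[str, np.ndarray]
    roster: ActorRoster | None = None

    def __post_init__(self) -> None:
        missing = set(SUPPORT_LAYERS) - set(self.layers)
        if missing:
            raise ValueError(f"missing support layers: {sorted(missing)}")
        shapes = {np.asarray(m).shape for m in self.layers.values()}
        if len(shapes) != 1:
            raise DimensionError("all layers must share one adjacency shape")
        # validate each layer through NetworkWave invariants
        self.layers = {
            name: NetworkWave(f"{self.label}:{name}", m, self.roster).adjacency
            for name, m in self.layers.items()
        }


def combine_support_layers(layers: SupportLayerSet) -> NetworkWave:
    """Element-wise logical OR of the six support layers.

    The composite tie ``x_ij = 1`` iff *i* turns to *j* for one **or more**
    kinds of help.
    """
    stack = np.stack([layers.layers[name] for name in SUPPORT_LAYERS])
    return NetworkWave(layers.label, stack.any(axis=0).astype(np.int8), layers.roster)


@dataclass
class MonadicAttributeTable:
    """Per-actor covariates keyed by actor id.

    Required columns: ``woman`` (1 = woman), ``age`` (years), ``education``
    (years), ``wealth_log`` (natural log of household wealth in rupees),
    ``reputation`` (count of intra-village nominations as generous /
    influential / of good character / strong), ``caste`` (categorical),
    ``married`` (0/1), ``immigrant`` (0/1, non-natal village resident),
    ``village`` (categorical).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MONADIC_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing monadic columns: {sorted(missing)}")
        if self.frame["woman"].isna().any():
            raise ValueError("gender may not be missing")
        ok_age = self.frame["age"].dropna()
        if (ok_age <= 0).any():
            raise ValueError("ages must be positive")
        rep = self.frame["reputation"].dropna()
        if (rep < 0).any():
            raise ValueError("reputation counts must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.frame)


@dataclass
class DyadicAttributeSet:
    """Dyadic covariate matrices: kinship, friendship, same_household
    (0/1, symmetric except friendship which may be directed) and
    ``log_distance`` = ln(metres + 1), symmetric and nonnegative."""

    matrices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(DYADIC_NAMES) - set(self.matrices)
        if missing:
            raise ValueError(f"missing dyadic matrices: {sorted(missing)}")
        shapes = {np.asarray(m).shape for m in self.matrices.values()}
        if len(shapes) != 1:
            raise DimensionError("dyadic matrices must share one shape")
        out = {}
        for name, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if np.diagonal(m).any():
                raise ValueError(f"{name}: diagonal must be zero")
            if name in ("kinship", "same_household") and not np.allclose(m, m.T):
                raise ValueError(f"{name}: must be symmetric")
            if name == "log_distance":
                if not np.allclose(m, m.T):
                    raise ValueError("log_distance must be symmetric")
                if (m < 0).any():
                    raise ValueError("log_distance must be nonnegative")
            out[name] = m
        self.matrices = out

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrices[name]


@dataclass
class CompositionChangeSchedule:
    """Entry/exit times per actor as fractions of the inter-wave interval.

    Actors present at both waves have ``entry = 0`` and ``exit = 1``;
    joiners have ``entry > 0``, leavers ``exit < 1``.
    """

    entry: np.ndarray
    exit: np.ndarray

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float)
        self.exit = np.asarray(self.exit, dtype=float)
        if self.entry.shape != self.exit.shape:
            raise DimensionError("entry/exit must align")
        if (self.entry < 0).any() or (self.exit > 1).any():
            raise ValueError("entry/exit must lie in [0, 1]")
        if (self.entry >= self.exit).any():
            raise ValueError("entry must precede exit for every actor")

    @classmethod
    def full_presence(cls, n: int) -> "CompositionChangeSchedule":
        return cls(np.zeros(n), np.ones(n))

    @property
    def n(self) -> int:
        return self.entry.shape[0]


def abs_difference_dyad(values: np.ndarray) -> np.ndarray:
    """Symmetric matrix of absolute pairwise differences ``|v_i - v_j|``.

    Used to encode heterophily with respect to quantitative attributes.
    """
    v = np.asarray(values, dtype=float)
    return np.abs(v[:, None] - v[None, :])


#: monadic variables that are z-scored, with their pre-transform.
_STANDARDIZED: dict[str, str | None] = {
    "age": None,
    "education": None,
    "wealth_log": None,  # already on the log scale
    "reputation": "sqrt",
}


@dataclass
class AttributeSet:
    """Monadic and dyadic covariates, raw plus standardized.

    Standardized monadic columns get a ``_z`` suffix (``age_z``, ...;
    ``reputation_z`` is the z-score of the square root of the nomination
    count). ``log_distance_z`` is the z-scored log-distance matrix. The
    ``scaling`` frame records the mean/SD used per variable so the transform
    is invertible.
    """

    monadic: pd.DataFrame
    dyadic: dict[str, np.ndarray]
    scaling: pd.DataFrame = field(default_factory=pd.DataFrame)

    # -- covariate access used by the effects registry -------------------
    def monadic_values(self, name: str) -> np.ndarray:
        """Numeric per-actor vector for covariate ``name``.

        Categorical columns (caste, village) are label-encoded; missing
        quantitative values have already been mean-imputed to 0 on the
        z-scale by :func:`standardize_attributes`.
        """
        col = self.monadic[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            return pd.Categorical(col).codes.astype(float)
        return col.to_numpy(dtype=float)

    def dyadic_values(self, name: str) -> np.ndarray:
        return self.dyadic[name]

    def has_monadic(self, name: str) -> bool:
        return name in self.monadic.columns

    def has_dyadic(self, name: str) -> bool:
        return name in self.dyadic

    @property
    def n(self) -> int:
        return len(self.monadic)

    def destandardize(self, name: str) -> np.ndarray:
        """Invert the z-scoring (and any pre-transform) of variable ``name``."""
        mean = self.scaling.loc[name, "mean"]
        sd = self.scaling.loc[name, "sd"]
        if name == "log_distance":
            return self.dyadic["log_distance_z"] * sd + mean
        raw = self.monadic[f"{name}_z"].to_numpy() * sd + mean
        if _STANDARDIZED.get(name) == "sqrt":
            raw = raw**2
        return raw


def _zscore(values: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    finite = values[np.isfinite(values)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise DegenerateVariableError(f"{name}: needs >= 2 distinct values")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=0))
    if sd == 0.0:
        raise DegenerateVariableError(f"{name}: zero variance")
    return (values - mean) / sd, mean, sd


def standardize_attributes(
    table: MonadicAttributeTable, dyads: DyadicAttributeSet
) -> AttributeSet:
    """Z-score the quantitative covariates over both villages pooled.

    Square-root transform is applied to reputation and the distance matrix
    is already ln(metres + 1); each variable is then centred on its global
    mean and divided by its global SD. Missing quantitative values are
    imputed with the global mean after standardization (z = 0) and flagged
    in a ``<name>_missing`` column.
    """
    frame = table.frame.copy()
    rows = []
    for name, pre in _STANDARDIZED.items():
        raw = frame[name].to_numpy(dtype=float)
        vals = np.sqrt(raw) if pre == "sqrt" else raw
        z, mean, sd = _zscore(vals, name)
        missing = ~np.isfinite(z)
        if missing.any():
            z = np.where(missing, 0.0, z)
            frame[f"{name}_missing"] = missing.astype(int)
        frame[f"{name}_z"] = z
        rows.append({"variable": name, "mean": mean, "sd": sd})

    dyadic = dict(dyads.matrices)
    dist = dyadic["log_distance"]
    off = ~np.eye(dist.shape[0], dtype=bool)
    mean = float(dist[off].mean())
    sd = float(dist[off].std(ddof=0))
    if sd == 0.0:
        raise DegenerateVariableError("log_distance: zero variance")
    dz = (dist - mean) / sd
    np.fill_diagonal(dz, 0.0)
    dyadic["log_distance_z"] = dz
    rows.append({"variable": "log_distance", "mean": mean, "sd": sd})

    # derived heterophily matrices used by the model ladder
    dyadic["abs_diff_age"] = abs_difference_dyad(frame["age_z"].to_numpy())
    dyadic["abs_diff_reputation"] = abs_difference_dyad(frame["reputation_z"].to_numpy())
    if frame["village"].dtype == object:
        vill = pd.Categorical(frame["village"]).codes.astype(float)
    else:
        vill = frame["village"].to_numpy(dtype=float)
    dyadic["abs_diff_village"] = abs_difference_dyad(vill)

    scaling = pd.DataFrame(rows).set_index("variable")
    return AttributeSet(monadic=frame, dyadic=dyadic, scaling=scaling)


def coverage_percent(n_interviewed: int, n_adults: int) -> int:
    """Census coverage as a whole-number percentage (half rounds up)."""
    return int(100.0 * n_interviewed / n_adults + 0.5)
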