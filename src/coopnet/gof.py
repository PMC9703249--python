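"""Simulation-based goodness-of-fit and gender-split ego-network comparison.

Fit of a model is judged by comparing auxiliary statistics of the observed
wave-2 network against the cloud of statistics from networks simulated
under the fitted model: the joint Mahalanobis distance (MHD) of the
observed vector from the simulated mean/covariance, with a Monte Carlo
p-value GOFp = share of simulated networks at least as distant as the
observed one (weak inequality: GOFp = 1 when the observed vector sits at
the simulated mean, and never 0). Small MHD and GOFp > 0.05 indicate an
adequate fit.

Auxiliary statistics: cumulative in-/out-degree distributions, the
distribution of directed geodesic distances (with a dedicated
"unreachable" bucket), the Holland-Leinhardt 16-class triad census, and
the gender split (women-mean minus men-mean) of eight ego-network
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .data_model import AttributeSet, NetworkWave

__all__ = [
    "AuxiliaryStatistic",
    "GofResult",
    "GofConfig",
    "EGONET_STATISTICS",
    "TRIAD_CLASSES",
    "egonet_statistics",
    "egonet_matrix",
    "auxiliary_suite",
    "mahalanobis_gof",
    "compare_egonets_by_gender",
]

#: Fig-style layout order of the ego-network statistics.
EGONET_STATISTICS = (
    "out_degree",
    "reciprocal_out_degree",
    "supportive_friends",
    "supportive_kin",
    "same_gender_patrons",
    "transitive_triads",
    "three_cycles",
    "reputation_gap",
)

#: Holland-Leinhardt triad isomorphism classes, canonical order.
TRIAD_CLASSES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)


@dataclass
class AuxiliaryStatistic:
    """Named statistic vector with support labels."""

    name: str
    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GofResult:
    mhd: float
    p_value: float
    n_ensemble: int
    statistic: str = ""
    n_dropped: int = 0


@dataclass
class GofConfig:
    indegree_max: int = 64
    outdegree_max: int = 32
    geodesic_max: int = 13
    statistics: tuple[str, ...] = (
        "indegree_distribution",
        "outdegree_distribution",
        "geodesic_distribution",
        "triad_census",
        "egonet_by_gender",
    )


def egonet_matrix(x: NetworkWave | np.ndarray, attrs: AttributeSet) -> np.ndarray:
    """All eight ego-network statistics for all actors, shape (8, n).

    ``reputation_gap`` is sum_j x_ij |z_i - z_j| on the z-score of the
    square root of the nomination count.
    """
    X = (x.adjacency if isinstance(x, NetworkWave) else np.asarray(x)).astype(float)
    n = X.shape[0]
    woman = attrs.monadic_values("woman")
    friend = attrs.dyadic_values("friendship")
    kin = attrs.dyadic_values("kinship")
    rep = attrs.monadic_values("reputation_z")
    XX = X @ X
    same_gender = (woman[:, None] == woman[None, :]).astype(float)
    rep_gap = np.abs(rep[:, None] - rep[None, :])
    S = np.zeros((len(EGONET_STATISTICS), n))
    S[0] = X.sum(axis=1)
    S[1] = (X * X.T).sum(axis=1)
    S[2] = (X * friend).sum(axis=1)
    S[3] = (X * kin).sum(axis=1)
    S[4] = (X * same_gender).sum(axis=1)
    S[5] = (X * XX).sum(axis=1)        # out-bound two-paths closed: i->h->j & i->j
    S[6] = (X * XX.T).sum(axis=1)      # in-bound two-paths closed: j->h->i & i->j
    S[7] = (X * rep_gap).sum(axis=1)
    return S


def egonet_statistics(x: NetworkWave, attrs: AttributeSet, i: int) -> dict[str, float]:
    """Ego-network statistics for one actor."""
    if not 0 <= i < x.n:
        raise ValueError(f"actor {i} outside roster")
    S = egonet_matrix(x, attrs)
    return {name: float(S[k, i]) for k, name in enumerate(EGONET_STATISTICS)}


def _cumulative_degree(deg: np.ndarray, max_support: int) -> np.ndarray:
    return np.array([(deg <= c).sum() for c in range(max_support + 1)], dtype=float)


def _geodesic_counts(X: np.ndarray, max_d: int) -> np.ndarray:
    """Counts of ordered pairs at each directed geodesic distance 1..max_d,
    an overflow bucket (> max_d) folded into the final 'unreachable+' bin."""
    n = X.shape[0]
    if X.sum() == 0:
        counts = np.zeros(max_d + 1)
        counts[-1] = n * (n - 1)
        return counts
    D = shortest_path(X.astype(float), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    d = D[off]
    counts = np.array([np.sum(d == k) for k in range(1, max_d + 1)], dtype=float)
    unreachable = np.sum(~np.isfinite(d)) + np.sum(np.isfinite(d) & (d > max_d))
    return np.concatenate([counts, [unreachable]])


def triad_census(x: NetworkWave | np.ndarray) -> np.ndarray:
    """Holland-Leinhardt 16-class triad census in canonical order."""
    X = x.adjacency if isinstance(x, NetworkWave) else np.asarray(x)
    G = nx.from_numpy_array(np.asarray(X), create_using=nx.DiGraph)
    census = nx.triadic_census(G)
    return np.array([census[c] for c in TRIAD_CLASSES], dtype=float)


def gender_split_egonet(
    x: NetworkWave | np.ndarray, attrs: AttributeSet
) -> np.ndarray:
    """Women-mean minus men-mean of each ego-network statistic."""
    woman = attrs.monadic_values("woman").astype(bool)
    if woman.all() or (~woman).all():
        raise ValueError("both gender classes must be nonempty")
    S = egonet_matrix(x, attrs)
    return S[:, woman].mean(axis=1) - S[:, ~woman].mean(axis=1)


def auxiliary_suite(
    x: NetworkWave | np.ndarray,
    attrs: AttributeSet | None = None,
    config: GofConfig | None = None,
) -> list[AuxiliaryStatistic]:
    """Compute the configured auxiliary statistics for one network."""
    config = config or GofConfig()
    X = x.adjacency if isinstance(x, NetworkWave) else np.asarray(x)
    out = []
    for name in config.statistics:
        if name == "indegree_distribution":
            vals = _cumulative_degree(X.sum(axis=0), config.indegree_max)
            labels = [f"<={c}" for c in range(config.indegree_max + 1)]
        elif name == "outdegree_distribution":
            vals = _cumulative_degree(X.sum(axis=1), config.outdegree_max)
            labels = [f"<={c}" for c in range(config.outdegree_max + 1)]
        elif name == "geodesic_distribution":
            vals = _geodesic_counts(X, config.geodesic_max)
            labels = [str(k) for k in range(1, config.geodesic_max + 1)] + ["inf"]
        elif name == "triad_census":
            vals = triad_census(X)
            labels = list(TRIAD_CLASSES)
        elif name == "egonet_by_gender":
            if attrs is None:
                raise ValueError("egonet_by_gender needs attributes")
            vals = gender_split_egonet(X, attrs)
            labels = [f"diff_{s}" for s in EGONET_STATISTICS]
        else:
            raise ValueError(f"unknown auxiliary statistic {name!r}")
        out.append(AuxiliaryStatistic(name, vals, labels))
    return out


def mahalanobis_gof(
    observed: AuxiliaryStatistic | np.ndarray,
    ensemble: list[AuxiliaryStatistic] | np.ndarray,
) -> GofResult:
    """Joint Mahalanobis distance of the observed vector from the simulated
    cloud, with Monte Carlo p.

    Dimensions constant across the whole ensemble are dropped (they carry
    no information and break the covariance); the covariance is
    pseudo-inverted with tolerance-based rank truncation.
    """
    name = observed.name if isinstance(observed, AuxiliaryStatistic) else ""
    obs = np.asarray(
        observed.values if isinstance(observed, AuxiliaryStatistic) else observed,
        dtype=float,
    )
    E = np.asarray(
        [m.values if isinstance(m, AuxiliaryStatistic) else m for m in ensemble],
        dtype=float,
    )
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("ensemble must hold >= 2 aligned vectors")
    if E.shape[1] != obs.shape[0]:
        raise ValueError("observed and ensemble vectors must align")
    keep = E.std(axis=0) > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        mhd_obs = 0.0 if np.allclose(obs, E[0]) else np.inf
        return GofResult(mhd_obs, 1.0 if mhd_obs == 0 else 0.0, len(E), name, n_dropped)
    Ek = E[:, keep]
    ok = obs[keep]
    mu = Ek.mean(axis=0)
    cov = np.cov(Ek.T) if Ek.shape[1] > 1 else np.array([[Ek.var(ddof=1)]])
    cov = np.atleast_2d(cov)
    prec = np.linalg.pinv(cov, rcond=1e-8)

    def mhd(v: np.ndarray) -> float:
        d = v - mu
        return float(np.sqrt(max(d @ prec @ d, 0.0)))

    mhd_obs = mhd(ok)
    mhd_ens = np.array([mhd(row) for row in Ek])
    p = float(np.mean(mhd_ens >= mhd_obs))
    return GofResult(mhd_obs, p, len(E), name, n_dropped)


def compare_egonets_by_gender(
    observed: NetworkWave,
    ensemble: list[NetworkWave] | list[np.ndarray],
    attrs: AttributeSet,
) -> pd.DataFrame:
    """Observed vs simulated gender differences in ego-net statistics.

    One row per statistic: observed difference (women minus men), plus the
    median, quartiles and whiskers (min/max) of the difference across the
    simulated networks.
    """
    obs_diff = gender_split_egonet(observed, attrs)
    sims = np.array([gender_split_egonet(w, attrs) for w in ensemble])
    rows = []
    for k, stat in enumerate(EGONET_STATISTICS):
        col = sims[:, k]
        rows.append(
            {
                "statistic": stat,
                "observed_diff": obs_diff[k],
                "median": float(np.median(col)),
                "q25": float(np.percentile(col, 25)),
                "q75": float(np.percentile(col, 75)),
                "lo": float(col.min()),
                "hi": float(col.max()),
            }
        )
    return pd.DataFrame(rows)
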