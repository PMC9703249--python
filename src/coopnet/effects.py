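"""SAOM effect registry: network statistics and change statistics.

Each *effect* k summarizes a feature of ego i's local network through a
per-actor statistic s_k,i(x). The evaluation function that drives tie
choice is the weighted sum over effects of the *change statistics*
``delta_k,ij(x, x_toggled) = s_k,i(x_toggled) - s_k,i(x)`` induced by
toggling the single tie x_ij. Change statistics are computed in closed form
(never by materializing the toggled network).

Structural effects and their statistics, for ego i on network x:

========================  ==================================================
out-degree                sum_j x_ij
reciprocity               sum_j x_ij x_ji
transitive triplets       sum_{j,h} x_ij x_ih x_hj   (i->j closing i->h->j)
three-cycles              sum_{j,h} x_ij x_jh x_hi   (generalized exchange)
in-degree popularity      sum_j x_ij * indeg(j)
out-degree activity       outdeg(i)^2
in-degree activity        indeg(i) * outdeg(i)
========================  ==================================================

Covariate effects: alter (sum_j x_ij v_j), ego (v_i * outdeg(i)),
same (sum_j x_ij 1[v_i = v_j]), absolute difference
(sum_j x_ij |v_i - v_j|), and dyadic (sum_j x_ij w_ij).

Interaction effects multiply an ego 0/1 flag (here: woman) into the parent
effect's change statistic, which equals flag_i * s_parent,i at the
statistic level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import AttributeSet, NetworkWave

__all__ = [
    "EffectSpec",
    "ModelSpec",
    "CompiledModel",
    "register_core_effects",
    "baseline_effects",
    "gender_interacted_effects",
    "social_constraint_effects",
    "statistic",
    "statistic_matrix",
    "statistic_totals",
    "change_statistics",
    "contribution_matrix",
    "interaction_change",
]

# numeric kind codes shared with the simulation kernel
K_OUTDEGREE = 0
K_RECIPROCITY = 1
K_TRANS_TRIP = 2
K_THREE_CYCLES = 3
K_IN_POP = 4
K_OUT_ACT = 5
K_IN_ACT = 6
K_ALTER = 7
K_EGO = 8
K_SAME = 9
K_ABS_DIFF = 10
K_DYADIC = 11
K_INTERACTION = 12

_STRUCTURAL = {
    "outdegree": K_OUTDEGREE,
    "reciprocity": K_RECIPROCITY,
    "transitive_triplets": K_TRANS_TRIP,
    "three_cycles": K_THREE_CYCLES,
    "indegree_popularity": K_IN_POP,
    "outdegree_activity": K_OUT_ACT,
    "indegree_activity": K_IN_ACT,
}

_COVARIATE_KINDS = {
    "alter": K_ALTER,
    "ego": K_EGO,
    "same": K_SAME,
    "abs_diff": K_ABS_DIFF,
    "dyadic": K_DYADIC,
}


class EffectConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSpec:
    """One registered effect.

    ``kind`` is a structural name (``outdegree`` ...), a covariate kind
    (``alter``/``ego``/``same``/``abs_diff``/``dyadic``) with ``covariate``
    naming the monadic or dyadic variable, or ``interaction`` with
    ``covariate`` the 0/1 ego flag and ``parent`` the interacted effect.
    """

    name: str
    kind: str
    covariate: str | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.kind in _STRUCTURAL:
            if self.covariate or self.parent:
                raise EffectConfigurationError(f"{self.name}: structural effects take no covariate")
        elif self.kind in _COVARIATE_KINDS:
            if not self.covariate:
                raise EffectConfigurationError(f"{self.name}: covariate required")
        elif self.kind == "interaction":
            if not self.covariate or not self.parent:
                raise EffectConfigurationError(
                    f"{self.name}: interactions need one ego flag and one parent effect"
                )
        else:
            raise EffectConfigurationError(f"{self.name}: unknown kind {self.kind!r}")


@dataclass
class ModelSpec:
    """Ordered effect list; order fixes parameter order everywhere."""

    effects: list[EffectSpec] = field(default_factory=list)

    def add(self, effect: EffectSpec) -> "ModelSpec":
        if any(e.name == effect.name for e in self.effects):
            raise EffectConfigurationError(f"duplicate effect {effect.name!r}")
        if effect.kind == "interaction":
            if effect.parent not in self.names:
                raise EffectConfigurationError(
                    f"{effect.name}: parent {effect.parent!r} not registered"
                )
        self.effects.append(effect)
        return self

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.effects]

    @property
    def n_effects(self) -> int:
        return len(self.effects)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise EffectConfigurationError(f"effect {name!r} not in model") from None

    def subset_indices(self, names: list[str]) -> np.ndarray:
        return np.array([self.index_of(n) for n in names], dtype=int)

    def compile(self, attrs: AttributeSet) -> "CompiledModel":
        return CompiledModel.build(self, attrs)


@dataclass
class CompiledModel:
    """Model lowered to flat integer tables for the numeric kernels.

    ``V`` stacks the referenced monadic covariate vectors (n_cov, n);
    ``W`` stacks the dyadic matrices (n_dyad, n, n).
    """

    spec: ModelSpec
    kinds: np.ndarray
    cov_idx: np.ndarray
    parent_idx: np.ndarray
    V: np.ndarray
    W: np.ndarray

    @classmethod
    def build(cls, spec: ModelSpec, attrs: AttributeSet) -> "CompiledModel":
        mon_names: list[str] = []
        dyad_names: list[str] = []
        kinds, cov_idx, parent_idx = [], [], []
        for e in spec.effects:
            if e.kind in _STRUCTURAL:
                kinds.append(_STRUCTURAL[e.kind])
                cov_idx.append(-1)
                parent_idx.append(-1)
            elif e.kind == "dyadic":
                if not attrs.has_dyadic(e.covariate):
                    raise EffectConfigurationError(f"unknown dyadic covariate {e.covariate!r}")
                if e.covariate not in dyad_names:
                    dyad_names.append(e.covariate)
                kinds.append(K_DYADIC)
                cov_idx.append(dyad_names.index(e.covariate))
                parent_idx.append(-1)
            elif e.kind in _COVARIATE_KINDS:
                if not attrs.has_monadic(e.covariate):
                    raise EffectConfigurationError(f"unknown monadic covariate {e.covariate!r}")
                if e.covariate not in mon_names:
                    mon_names.append(e.covariate)
                kinds.append(_COVARIATE_KINDS[e.kind])
                cov_idx.append(mon_names.index(e.covariate))
                parent_idx.append(-1)
            else:  # interaction
                if not attrs.has_monadic(e.covariate):
                    raise EffectConfigurationError(f"unknown monadic covariate {e.covariate!r}")
                if e.covariate not in mon_names:
                    mon_names.append(e.covariate)
                kinds.append(K_INTERACTION)
                cov_idx.append(mon_names.index(e.covariate))
                parent_idx.append(spec.index_of(e.parent))
        n = attrs.n
        V = (
            np.stack([attrs.monadic_values(m) for m in mon_names])
            if mon_names
            else np.zeros((0, n))
        )
        W = (
            np.stack([attrs.dyadic_values(d) for d in dyad_names])
            if dyad_names
            else np.zeros((0, n, n))
        )
        return cls(
            spec=spec,
            kinds=np.array(kinds, dtype=np.int64),
            cov_idx=np.array(cov_idx, dtype=np.int64),
            parent_idx=np.array(parent_idx, dtype=np.int64),
            V=np.ascontiguousarray(V, dtype=np.float64),
            W=np.ascontiguousarray(W, dtype=np.float64),
        )


# ---------------------------------------------------------------------------
# model ladders
# ---------------------------------------------------------------------------

def baseline_effects() -> list[EffectSpec]:
    """Baseline specification: structural closure/degree effects plus the
    dyadic constraints (kinship, friendship, homophily, co-residence,
    distance, village, reputation). 16 effects."""
    return [
        EffectSpec("outdegree", "outdegree"),
        EffectSpec("reciprocity", "reciprocity"),
        EffectSpec("transitive_triplets", "transitive_triplets"),
        EffectSpec("three_cycles", "three_cycles"),
        EffectSpec("indegree_popularity", "indegree_popularity"),
        EffectSpec("indegree_activity", "indegree_activity"),
        EffectSpec("outdegree_activity", "outdegree_activity"),
        EffectSpec("kinship", "dyadic", covariate="kinship"),
        EffectSpec("friendship", "dyadic", covariate="friendship"),
        EffectSpec("same_household", "dyadic", covariate="same_household"),
        EffectSpec("same_gender", "same", covariate="woman"),
        EffectSpec("same_caste", "same", covariate="caste"),
        EffectSpec("log_distance", "dyadic", covariate="log_distance_z"),
        EffectSpec("abs_diff_village", "dyadic", covariate="abs_diff_village"),
        EffectSpec("reputation_alter", "alter", covariate="reputation_z"),
        EffectSpec("abs_diff_reputation", "dyadic", covariate="abs_diff_reputation"),
    ]


def gender_interacted_effects() -> list[EffectSpec]:
    """Additions for the fully interacted model: the woman ego-activity
    effect plus woman x each remaining baseline effect (16 additions).

    The woman ego effect has change statistic ``woman_i`` — it *is* the
    interaction of gender with out-degree, so out-degree gets no separate
    interaction term (it would be perfectly collinear).
    """
    adds = [EffectSpec("woman_ego", "ego", covariate="woman")]
    for base in baseline_effects():
        if base.name == "outdegree":
            continue
        adds.append(
            EffectSpec(f"woman_x_{base.name}", "interaction", covariate="woman", parent=base.name)
        )
    return adds


def social_constraint_effects() -> list[EffectSpec]:
    """Additions for the social-constraints model: monadic factors that
    covary with gender and may confound it (8 additions)."""
    return [
        EffectSpec("age_ego", "ego", covariate="age_z"),
        EffectSpec("age_alter", "alter", covariate="age_z"),
        EffectSpec("abs_diff_age", "dyadic", covariate="abs_diff_age"),
        EffectSpec("wealth_ego", "ego", covariate="wealth_log_z"),
        EffectSpec("wealth_alter", "alter", covariate="wealth_log_z"),
        EffectSpec("education_ego", "ego", covariate="education_z"),
        EffectSpec("married_ego", "ego", covariate="married"),
        EffectSpec("immigrant_ego", "ego", covariate="immigrant"),
    ]


def register_core_effects(model: ModelSpec, ladder: str = "baseline") -> ModelSpec:
    """Register one of the nested study specifications onto ``model``.

    ``ladder`` is ``"baseline"``, ``"gender"`` (baseline + woman ego +
    woman x baseline interactions) or ``"constraints"`` (gender +
    sociological constraint covariates).
    """
    if ladder not in ("baseline", "gender", "constraints"):
        raise EffectConfigurationError(f"unknown ladder {ladder!r}")
    for e in baseline_effects():
        model.add(e)
    if ladder in ("gender", "constraints"):
        for e in gender_interacted_effects():
            model.add(e)
    if ladder == "constraints":
        for e in social_constraint_effects():
            model.add(e)
    return model


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def statistic_matrix(compiled: CompiledModel, x: NetworkWave | np.ndarray) -> np.ndarray:
    """All per-actor statistics: array of shape (n_effects, n)."""
    X = x.adjacency if isinstance(x, NetworkWave) else np.asarray(x)
    Xf = X.astype(np.float64)
    n = Xf.shape[0]
    outdeg = Xf.sum(axis=1)
    indeg = Xf.sum(axis=0)
    XX = Xf @ Xf
    S = np.zeros((len(compiled.kinds), n))
    for k, kind in enumerate(compiled.kinds):
        ci = compiled.cov_idx[k]
        if kind == K_OUTDEGREE:
            S[k] = outdeg
        elif kind == K_RECIPROCITY:
            S[k] = (Xf * Xf.T).sum(axis=1)
        elif kind == K_TRANS_TRIP:
            S[k] = (Xf * XX).sum(axis=1)
        elif kind == K_THREE_CYCLES:
            S[k] = (Xf * XX.T).sum(axis=1)
        elif kind == K_IN_POP:
            S[k] = Xf @ indeg
        elif kind == K_OUT_ACT:
            S[k] = outdeg**2
        elif kind == K_IN_ACT:
            S[k] = indeg * outdeg
        elif kind == K_ALTER:
            S[k] = Xf @ compiled.V[ci]
        elif kind == K_EGO:
            S[k] = compiled.V[ci] * outdeg
        elif kind == K_SAME:
            v = compiled.V[ci]
            S[k] = (Xf * (v[:, None] == v[None, :])).sum(axis=1)
        elif kind == K_ABS_DIFF:
            v = compiled.V[ci]
            S[k] = (Xf * np.abs(v[:, None] - v[None, :])).sum(axis=1)
        elif kind == K_DYADIC:
            S[k] = (Xf * compiled.W[ci]).sum(axis=1)
        else:  # interaction
            S[k] = compiled.V[ci] * S[compiled.parent_idx[k]]
    return S


def statistic(
    effect: EffectSpec, x: NetworkWave, attrs: AttributeSet, i: int
) -> float:
    """Statistic s_k,i(x) for one effect and one ego."""
    n = x.n
    if not 0 <= i < n:
        raise ValueError(f"actor {i} outside roster of size {n}")
    spec = ModelSpec()
    if effect.kind == "interaction":
        # parent must be resolvable; register a minimal pair
        parent = EffectSpec(effect.parent, effect.parent)
        spec.add(parent)
    spec.add(effect)
    S = statistic_matrix(spec.compile(attrs), x)
    return float(S[-1, i])


def statistic_totals(compiled: CompiledModel, x: NetworkWave | np.ndarray) -> np.ndarray:
    """Per-effect totals sum_i s_k,i(x) — the moment targets."""
    return statistic_matrix(compiled, x).sum(axis=1)


# ---------------------------------------------------------------------------
# change statistics (closed form)
# ---------------------------------------------------------------------------

def contribution_matrix(
    compiled: CompiledModel, x: NetworkWave | np.ndarray, i: int
) -> np.ndarray:
    """Change statistics for ego ``i`` toggling each alter, shape (n_eff, n).

    Column j holds delta_k,ij for toggling tie x_ij (signed: adding an
    absent tie gives s(x+ij) - s(x), deleting a present tie gives
    s(x-ij) - s(x)). Column i is zero — keeping the status quo changes
    nothing.
    """
    X = x.adjacency if isinstance(x, NetworkWave) else np.asarray(x)
    Xf = X.astype(np.float64)
    n = Xf.shape[0]
    row = Xf[i]
    col = Xf[:, i]
    outdeg_i = row.sum()
    indeg_i = col.sum()
    indeg = Xf.sum(axis=0)
    sign = 1.0 - 2.0 * row  # +1 where tie absent, -1 where present
    twopath = row @ Xf          # i -> h -> j counts
    j_to_alters = Xf @ row      # j -> (i's alters) counts
    cycles = Xf @ col           # j -> h -> i counts

    D = np.zeros((len(compiled.kinds), n))
    for k, kind in enumerate(compiled.kinds):
        ci = compiled.cov_idx[k]
        if kind == K_OUTDEGREE:
            c = np.ones(n)
        elif kind == K_RECIPROCITY:
            c = Xf[:, i].copy()
        elif kind == K_TRANS_TRIP:
            c = twopath + j_to_alters
        elif kind == K_THREE_CYCLES:
            c = cycles
        elif kind == K_IN_POP:
            c = indeg - row + 1.0
        elif kind == K_OUT_ACT:
            c = 2.0 * (outdeg_i - row) + 1.0
        elif kind == K_IN_ACT:
            c = np.full(n, indeg_i)
        elif kind == K_ALTER:
            c = compiled.V[ci].copy()
        elif kind == K_EGO:
            c = np.full(n, compiled.V[ci, i])
        elif kind == K_SAME:
            c = (compiled.V[ci] == compiled.V[ci, i]).astype(float)
        elif kind == K_ABS_DIFF:
            c = np.abs(compiled.V[ci] - compiled.V[ci, i])
        elif kind == K_DYADIC:
            c = compiled.W[ci, i].copy()
        else:  # interaction: flag_i times the (already signed) parent row
            D[k] = compiled.V[ci, i] * D[compiled.parent_idx[k]]
            D[k, i] = 0.0
            continue
        D[k] = sign * c
        D[k, i] = 0.0
    return D


def change_statistics(
    model: ModelSpec | CompiledModel,
    x: NetworkWave,
    attrs: AttributeSet | None,
    i: int,
    j: int,
) -> np.ndarray:
    """Closed-form change-statistic vector for ego ``i`` toggling tie to ``j``."""
    if i == j:
        raise ValueError("ego and alter must differ (i != j)")
    compiled = model if isinstance(model, CompiledModel) else model.compile(attrs)
    return contribution_matrix(compiled, x, i)[:, j]


def interaction_change(parent_delta: float, ego_flag: float) -> float:
    """Interaction change statistic: ego flag times the parent's delta."""
    return float(ego_flag) * float(parent_delta)
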