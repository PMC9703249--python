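"""Hypothesis scoring via linear combinations of parameter estimates.

Each cooperative-mechanism hypothesis (H1 general inclination, H2
reciprocity, H3 kin bias, H4 friend bias, H5a transitive closure, H5b
cyclic closure, H6 status difference, H7 gender homophily) is scored by
the total contribution to the evaluation function — the *attractiveness*
— of creating and maintaining one hypothetical tie x_ij in an artificial
status-quo network, computed separately for a female and a male ego who
are otherwise identical "typical" villagers.

The combination for a scenario cell is ``a' beta_hat`` where the weight
a_k of effect k is the artificial change statistic delta_k,ij implied by
adding the tie: 1 for out-degree, ``2 d + 1`` for out-degree activity at
ego out-degree d, ego in-degree for in-degree activity, ``q + 1`` for
in-degree popularity at alter in-degree q, the scenario's fixed focal
values (e.g. 1 for reciprocity, the median closed two-path count for
transitive closure), and for gender terms the ego's woman flag times the
parent weight. The standard error is ``sqrt(a' Sigma a)`` from the
estimate's covariance matrix; z = value/SE with a two-tailed normal p.

Default grid: ego out-degree 0-32 by alter in-degree 0-64 (33 x 65 = 2145
cells per gender), ego in-degree fixed at 6, alters' in-degree fixed at 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import EstimationResult

__all__ = [
    "ScenarioSpec",
    "LinearCombinationResult",
    "default_scenarios",
    "build_weight_vector",
    "evaluate_combination",
    "sweep_grid",
    "gender_term_names",
    "typical_dyad_distance_m",
]

#: degree-related base effects present in every combination
_BASE_PARENTED = ("outdegree_activity", "indegree_activity", "indegree_popularity")


@dataclass
class ScenarioSpec:
    """One hypothesis scenario.

    ``focal`` maps effect names to their fixed artificial change-statistic
    values (empty for H1). Grid ranges are inclusive.
    """

    hypothesis: str
    label: str
    focal: dict[str, float] = field(default_factory=dict)
    ego_indegree: int = 6
    alters_indegree: int = 6
    ego_outdegree_range: tuple[int, int] = (0, 32)
    alter_indegree_range: tuple[int, int] = (0, 64)

    def __post_init__(self) -> None:
        for lo, hi in (self.ego_outdegree_range, self.alter_indegree_range):
            if lo < 0 or hi < lo:
                raise ValueError("grid ranges must be nonnegative and nonempty")


@dataclass
class LinearCombinationResult:
    """Attractiveness of one scenario cell on the log-odds scale."""

    value: float
    se: float
    z: float
    p: float
    significant: bool  # two-tailed p < 0.001
    hypothesis: str
    gender: str
    out_degree: int
    in_degree: int


def default_scenarios(
    transitive_twopaths: float = 12.0, cyclic_twopaths: float = 5.0
) -> list[ScenarioSpec]:
    """The eight study scenarios (seven hypotheses; H5 split a/b).

    H1-H6 fix Same Gender = 0 (a cross-gender typical dyad); H7 isolates
    gender homophily by setting Same Gender = 1. H5a encodes the focal tie
    closing the median number of out-bound two-paths i->h->j (default 12,
    the transitive triad [i->h->j<-i]); H5b the median number of in-bound
    two-paths i<-h<-j (default 5, the cyclic triad [i<-h<-j<-i]). H6 is a
    one-SD gap in general reputation, for which the hypothesis predicts
    higher attractiveness for men.
    """
    return [
        ScenarioSpec("H1", "general inclination"),
        ScenarioSpec("H2", "reciprocity", {"reciprocity": 1.0}),
        ScenarioSpec("H3", "kin bias", {"kinship": 1.0}),
        ScenarioSpec("H4", "friend bias", {"friendship": 1.0}),
        ScenarioSpec("H5a", "transitive closure", {"transitive_triplets": transitive_twopaths}),
        ScenarioSpec("H5b", "cyclic closure", {"three_cycles": cyclic_twopaths}),
        ScenarioSpec("H6", "status difference", {"abs_diff_reputation": 1.0}),
        ScenarioSpec("H7", "gender homophily", {"same_gender": 1.0}),
    ]


def scenarios_from_yaml(path) -> list[ScenarioSpec]:
    """Load scenario definitions from a YAML file.

    Expected layout: a list of mappings with keys ``hypothesis``,
    ``label``, ``focal`` (effect name -> delta value) and optionally
    ``ego_indegree``, ``alters_indegree``, ``ego_outdegree_range``,
    ``alter_indegree_range``. Lets users edit hypothesis compositions
    without code changes.
    """
    import pathlib

    import yaml

    raw = yaml.safe_load(pathlib.Path(path).read_text())
    out = []
    for item in raw:
        for key in ("ego_outdegree_range", "alter_indegree_range"):
            if key in item:
                item[key] = tuple(item[key])
        out.append(ScenarioSpec(**item))
    return out


def build_weight_vector(
    effect_names: list[str],
    scenario: ScenarioSpec,
    ego_outdegree: int,
    alter_indegree: int,
    woman: bool,
) -> np.ndarray:
    """Per-effect weights (artificial change statistics) for one grid cell."""
    for name in scenario.focal:
        if name not in effect_names:
            raise KeyError(f"scenario references unregistered effect {name!r}")
    pos = {nm: k for k, nm in enumerate(effect_names)}
    a = np.zeros(len(effect_names))
    g = 1.0 if woman else 0.0

    def put(name: str, value: float) -> None:
        if name in pos:
            a[pos[name]] = value

    parented: dict[str, float] = {}
    put("outdegree", 1.0)
    put("woman_ego", g)
    parented["outdegree_activity"] = 2.0 * ego_outdegree + 1.0
    parented["indegree_activity"] = float(scenario.ego_indegree)
    parented["indegree_popularity"] = float(alter_indegree) + 1.0
    for name, value in scenario.focal.items():
        parented[name] = float(value)
    for name, value in parented.items():
        put(name, value)
        put(f"woman_x_{name}", g * value)
    return a


def gender_term_names(effect_names: list[str]) -> list[str]:
    """Effects whose weight depends on ego gender: the woman ego-activity
    effect and every woman x interaction present in the model."""
    return [nm for nm in effect_names if nm == "woman_ego" or nm.startswith("woman_x_")]


def evaluate_combination(
    estimate: EstimationResult,
    weights: np.ndarray,
    *,
    hypothesis: str = "",
    gender: str = "",
    out_degree: int = 0,
    in_degree: int = 0,
) -> LinearCombinationResult:
    """Value, SE, z and two-tailed p of one linear combination a' beta."""
    a = np.asarray(weights, dtype=float)
    if a.shape != estimate.beta.shape:
        raise ValueError("weight length must equal effect count")
    value = float(a @ estimate.beta)
    var = float(a @ estimate.covariance @ a)
    if var <= 0:
        raise FloatingPointError("a' Sigma a <= 0: degenerate combination")
    se = math.sqrt(var)
    z = value / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return LinearCombinationResult(
        value=value,
        se=se,
        z=z,
        p=p,
        significant=p < 0.001,
        hypothesis=hypothesis,
        gender=gender,
        out_degree=out_degree,
        in_degree=in_degree,
    )


def sweep_grid(estimate: EstimationResult, scenario: ScenarioSpec) -> pd.DataFrame:
    """All grid cells for both genders, long format.

    With the default ranges this yields 33 x 65 = 2145 rows per gender and
    4290 rows per hypothesis panel.
    """
    lo_d, hi_d = scenario.ego_outdegree_range
    lo_q, hi_q = scenario.alter_indegree_range
    names = estimate.effect_names
    rows = []
    for gender, woman in (("woman", True), ("man", False)):
        for d in range(lo_d, hi_d + 1):
            for q in range(lo_q, hi_q + 1):
                a = build_weight_vector(names, scenario, d, q, woman)
                r = evaluate_combination(
                    estimate,
                    a,
                    hypothesis=scenario.hypothesis,
                    gender=gender,
                    out_degree=d,
                    in_degree=q,
                )
                rows.append(
                    (
                        r.hypothesis,
                        gender,
                        d,
                        q,
                        r.value,
                        r.se,
                        r.z,
                        r.p,
                        r.significant,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "hypothesis",
            "gender",
            "out_degree",
            "in_degree",
            "value",
            "se",
            "z",
            "p",
            "significant",
        ],
    )


def typical_dyad_distance_m(mean_log_distance: float = 5.69) -> float:
    """Back-transform the typical dyad's log-distance to metres.

    The headline summary rounds the mean log-distance to one decimal
    before exponentiating and truncates (not rounds) the result to two
    decimals, e.g. exp(5.7) -> 298.86 m.
    """
    metres = math.exp(round(mean_log_distance, 1))
    return math.floor(metres * 100.0) / 100.0
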