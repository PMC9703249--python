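"""End-to-end study orchestration.

Runs the whole analysis ladder on a dataset (synthetic by default): fit
the three nested models (baseline -> fully gender-interacted -> social
constraints), Wald-test each nesting step, sweep the hypothesis grids
from the largest model, run the five goodness-of-fit tests per model and
the gender-split ego-network comparison, and write every table plus a
manifest tying artifacts to seeds and the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import ModelSpec
from .estimator import EstimationConfig, EstimationResult, estimate, wald_test
from .gof import GofConfig, auxiliary_suite, compare_egonets_by_gender, mahalanobis_gof
from .hypotheses import default_scenarios, sweep_grid
from .simulator import MAX_SEED, simulate_ensemble
from .synthetic import GeneratorConfig, generate_study, model_from_beta

__all__ = ["StudyConfig", "StudyReport", "run_study", "nested_ladder"]


def nested_ladder(
    model1: list[str] | None = None,
    model2: list[str] | None = None,
    model3: list[str] | None = None,
) -> dict[str, list[str]]:
    """Effect-name lists for the three nested specifications."""
    from .effects import baseline_effects, gender_interacted_effects, social_constraint_effects

    m1 = model1 if model1 is not None else [e.name for e in baseline_effects()]
    m2 = model2 if model2 is not None else m1 + [e.name for e in gender_interacted_effects()]
    m3 = model3 if model3 is not None else m2 + [e.name for e in social_constraint_effects()]
    return {"model1": m1, "model2": m2, "model3": m3}


@dataclass
class StudyConfig:
    """Study-wide settings; models must be strictly nested."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    models: dict[str, list[str]] = field(default_factory=nested_ladder)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    gof: GofConfig = field(default_factory=GofConfig)
    ensemble_size: int = 10_000
    grid_ego_outdegree: tuple[int, int] = (0, 32)
    grid_alter_indegree: tuple[int, int] = (0, 64)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        m1, m2, m3 = (self.models[k] for k in ("model1", "model2", "model3"))
        if not (set(m1) < set(m2) and set(m2) < set(m3)):
            diff = {
                "model2_minus_model1": sorted(set(m2) - set(m1)),
                "model1_not_in_model2": sorted(set(m1) - set(m2)),
                "model3_minus_model2": sorted(set(m3) - set(m2)),
                "model2_not_in_model3": sorted(set(m2) - set(m3)),
            }
            raise ValueError(f"model ladder is not strictly nested: {diff}")


@dataclass
class StudyReport:
    estimates: dict[str, EstimationResult]
    wald: dict[str, object]
    grids: dict[str, pd.DataFrame]
    gof: pd.DataFrame
    egonet_comparison: pd.DataFrame
    manifest: dict

    @property
    def n_hypotheses(self) -> int:
        return len({h.rstrip("ab") for h in self.grids})


def _model_from_names(names: list[str]) -> ModelSpec:
    from .synthetic import _effect_by_name

    spec = ModelSpec()
    for nm in names:
        spec.add(_effect_by_name(nm))
    return spec


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(
        {
            "generator": {k: str(v) for k, v in vars(config.generator).items()},
            "models": config.models,
            "estimation": vars(config.estimation),
            "ensemble_size": config.ensemble_size,
            "seed": config.seed,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study; see module docstring for the stages."""
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []

    def stage(name: str, **info) -> None:
        log.append({"stage": name, "elapsed_s": round(time.time() - t0, 2), **info})

    roster, table, dyads, attrs, wave1, wave2, schedule, _, _ = generate_study(
        config.generator
    )
    stage("generate", n=attrs.n, ties_w1=wave1.tie_count, ties_w2=wave2.tie_count)

    estimates: dict[str, EstimationResult] = {}
    for key in ("model1", "model2", "model3"):
        spec = _model_from_names(config.models[key])
        seed = int(rng.integers(0, MAX_SEED))
        estimates[key] = estimate(
            spec, wave1, wave2, attrs, schedule, config.estimation, seed=seed
        )
        stage("estimate", model=key, seed=seed, converged=estimates[key].converged)

    wald = {
        "model2_vs_model1": wald_test(
            estimates["model2"],
            [n for n in config.models["model2"] if n not in config.models["model1"]],
        ),
        "model3_vs_model2": wald_test(
            estimates["model3"],
            [n for n in config.models["model3"] if n not in config.models["model2"]],
        ),
    }
    stage("wald", **{k: v.p_value for k, v in wald.items()})

    grids: dict[str, pd.DataFrame] = {}
    for scenario in default_scenarios():
        scenario.ego_outdegree_range = config.grid_ego_outdegree
        scenario.alter_indegree_range = config.grid_alter_indegree
        grids[scenario.hypothesis] = sweep_grid(estimates["model3"], scenario)
    stage("hypotheses", panels=len(grids))

    gof_rows = []
    ego_comparison = None
    for key in ("model1", "model2", "model3"):
        spec = _model_from_names(config.models[key])
        compiled = spec.compile(attrs)
        seed = int(rng.integers(0, MAX_SEED))
        sims = list(
            simulate_ensemble(
                compiled,
                estimates[key].params,
                wave1,
                schedule=schedule,
                n_sims=config.ensemble_size,
                seed=seed,
            )
        )
        obs_aux = auxiliary_suite(wave2, attrs, config.gof)
        sim_aux = [auxiliary_suite(w, attrs, config.gof) for w in sims]
        for k, aux in enumerate(obs_aux):
            res = mahalanobis_gof(aux, [sa[k] for sa in sim_aux])
            gof_rows.append(
                {
                    "model": key,
                    "statistic": aux.name,
                    "mhd": res.mhd,
                    "gof_p": res.p_value,
                    "n_ensemble": res.n_ensemble,
                }
            )
        if key == "model3":
            ego_comparison = compare_egonets_by_gender(wave2, sims, attrs)
        stage("gof", model=key, seed=seed)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": log,
        "n_actors": attrs.n,
        "ensemble_size": config.ensemble_size,
    }
    report = StudyReport(
        estimates=estimates,
        wald=wald,
        grids=grids,
        gof=pd.DataFrame(gof_rows),
        egonet_comparison=ego_comparison,
        manifest=manifest,
    )
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for key, est in report.estimates.items():
        (outdir / f"estimate_{key}.json").write_text(est.to_json())
    wald_payload = {
        k: {"chi2": v.chi2, "df": v.df, "p": v.p_value, "tested": v.tested}
        for k, v in report.wald.items()
    }
    (outdir / "wald_tests.json").write_text(json.dumps(wald_payload, indent=2))
    for hyp, df in report.grids.items():
        df.to_csv(outdir / f"grid_{hyp}.csv", index=False)
    report.gof.to_csv(outdir / "gof.csv", index=False)
    report.egonet_comparison.to_csv(outdir / "egonet_comparison.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
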