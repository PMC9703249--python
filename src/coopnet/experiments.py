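"""Reusable validation experiments: recovery, calibration, stationarity.

These are the package's own quality checks — Monte Carlo experiments that
any fitted-model claim rests on: can the estimator recover known
parameters, are Wald tests calibrated under the null, is the
goodness-of-fit p-value uniform when the model is true, and does the
simulator's long-run behaviour match the exactly enumerated ministep
chain. The test suite and the acceptance script both drive these at the
study's scaled-down problem sizes.
"""

from __future__ import annotations

import itertools

import numpy as np

from .data_model import NetworkWave
from .effects import EffectSpec, ModelSpec, statistic_totals
from .estimator import EstimationConfig, estimate, wald_test
from .gof import GofConfig, auxiliary_suite, mahalanobis_gof
from .simulator import MAX_SEED, ParameterVector, ministep_probabilities, simulate_period
from .synthetic import GeneratorConfig, generate_study, model_from_beta, _tiny_attrs

__all__ = [
    "RECOVERY_BETA",
    "recovery_experiment",
    "wald_null_calibration",
    "gof_calibration",
    "exact_stationary_density",
    "simulated_stationary_density",
]

#: true parameters of the recovery experiment's data-generating process
RECOVERY_BETA = {"outdegree": -2.0, "reciprocity": 1.5, "transitive_triplets": 0.25}


def _fast_config(**overrides) -> EstimationConfig:
    base = dict(
        n_phase1=60,
        phase2_subphases=4,
        phase2_iterations=40,
        n_phase3=300,
        gain=0.3,
        strict=False,
        max_retries=1,
    )
    base.update(overrides)
    return EstimationConfig(**base)


def recovery_experiment(
    n_replicates: int = 20,
    n_per_village: int = 25,
    seed: int = 0,
    estimation: EstimationConfig | None = None,
) -> dict:
    """Simulate data at known parameters and re-estimate, repeatedly.

    Returns per-parameter mean estimates, Monte Carlo standard errors of
    those means, z-scores of the bias, and coverage of the +-2 SE
    intervals.
    """
    estimation = estimation or _fast_config()
    rng = np.random.default_rng(seed)
    names = list(RECOVERY_BETA)
    truth = np.array([RECOVERY_BETA[k] for k in names])
    B, SE = [], []
    for _ in range(n_replicates):
        cfg = GeneratorConfig(
            n_per_village=n_per_village,
            seed=int(rng.integers(0, MAX_SEED)),
            true_beta=dict(RECOVERY_BETA),
        )
        *_, attrs, w1, w2, sched, spec, _ = generate_study(cfg)
        res = estimate(spec, w1, w2, attrs, sched, estimation, seed=int(rng.integers(0, MAX_SEED)))
        B.append(res.beta)
        SE.append(res.se)
    B = np.asarray(B)
    SE = np.asarray(SE)
    mean = B.mean(axis=0)
    mc_se = B.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    cover = (np.abs((B - truth) / np.where(SE > 0, SE, np.inf)) < 2).mean(axis=0)
    return {
        "effects": names,
        "truth": truth,
        "mean": mean,
        "mc_se": mc_se,
        "bias_z": (mean - truth) / np.where(mc_se > 0, mc_se, np.inf),
        "coverage": cover,
        "estimates": B,
        "ses": SE,
    }


#: gender-neutral data-generating conditions for the Wald null experiment.
#: The network must be dense enough that reciprocity and the gender terms
#: are well identified at 30 actors, else boundary estimates dominate and
#: the experiment measures estimator breakdown instead of test calibration.
NULL_BETA = {"outdegree": -1.4, "reciprocity": 1.0}
NULL_RATE = 4.0


def _null_model() -> tuple[ModelSpec, np.ndarray]:
    """Gender-neutral data-generating model for the Wald null experiment."""
    return model_from_beta(dict(NULL_BETA))


def wald_null_calibration(
    n_replicates: int = 200,
    n_per_village: int = 15,
    seed: int = 0,
    alpha: float = 0.05,
    estimation: EstimationConfig | None = None,
) -> dict:
    """Rejection rate of the gender-interaction Wald test under the null.

    Data are simulated gender-neutrally; the fitted model adds the woman
    ego effect and the woman x reciprocity interaction, and the joint Wald
    test of those two coefficients should reject at ~alpha.
    """
    estimation = estimation or _fast_config(
        n_phase1=40, phase2_subphases=3, phase2_iterations=30, n_phase3=250
    )
    rng = np.random.default_rng(seed)
    tested = ["woman_ego", "woman_x_reciprocity"]
    fit_spec = ModelSpec()
    fit_spec.add(EffectSpec("outdegree", "outdegree"))
    fit_spec.add(EffectSpec("reciprocity", "reciprocity"))
    fit_spec.add(EffectSpec("woman_ego", "ego", covariate="woman"))
    fit_spec.add(
        EffectSpec("woman_x_reciprocity", "interaction", covariate="woman", parent="reciprocity")
    )
    null_beta, _ = _null_model()
    pvals = []
    for _ in range(n_replicates):
        cfg = GeneratorConfig(
            n_per_village=n_per_village,
            seed=int(rng.integers(0, MAX_SEED)),
            true_beta=dict(NULL_BETA),
            rate=NULL_RATE,
        )
        *_, attrs, w1, w2, sched, _, _ = generate_study(cfg)
        res = estimate(
            fit_spec, w1, w2, attrs, sched, estimation, seed=int(rng.integers(0, MAX_SEED))
        )
        pvals.append(wald_test(res, tested).p_value)
    pvals = np.asarray(pvals)
    return {
        "p_values": pvals,
        "rejection_rate": float((pvals < alpha).mean()),
        "alpha": alpha,
        "n_replicates": n_replicates,
    }


def gof_calibration(
    n_replicates: int = 100,
    n_ensemble: int = 300,
    n_per_village: int = 10,
    seed: int = 0,
    statistics: tuple[str, ...] = ("outdegree_distribution", "triad_census"),
) -> dict:
    """Distribution of GOFp when the fitted model is the true model.

    A model is fitted once to one synthetic dataset; then, repeatedly, a
    pseudo-observed network and an independent ensemble are both simulated
    under the fitted parameters and GOFp is computed. If the test is
    calibrated these p-values are approximately uniform. The ensemble
    must be large relative to the statistic dimension: the simulated
    mean/covariance are estimated in-sample for the ensemble members but
    out-of-sample for the observed vector, a bias of order dim/m.
    """
    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(
        n_per_village=n_per_village,
        seed=int(rng.integers(0, MAX_SEED)),
        true_beta={"outdegree": -1.6, "reciprocity": 1.0},
    )
    *_, attrs, w1, w2, sched, spec, _ = generate_study(cfg)
    res = estimate(
        spec,
        w1,
        w2,
        attrs,
        sched,
        _fast_config(n_phase1=40, phase2_subphases=3, phase2_iterations=30, n_phase3=150),
        seed=int(rng.integers(0, MAX_SEED)),
    )
    compiled = spec.compile(attrs)
    gof_cfg = GofConfig(
        statistics=statistics,
        outdegree_max=3 * n_per_village // 2,
        indegree_max=3 * n_per_village // 2,
    )

    def aux_vector(wave: NetworkWave) -> np.ndarray:
        parts = auxiliary_suite(wave, attrs, gof_cfg)
        return np.concatenate([p.values for p in parts])

    pvals = []
    for _ in range(n_replicates):
        sims = []
        for _ in range(n_ensemble + 1):
            w, _ = simulate_period(
                compiled, res.params, w1, schedule=sched, seed=int(rng.integers(0, MAX_SEED))
            )
            sims.append(aux_vector(w))
        observed, ensemble = sims[0], np.asarray(sims[1:])
        pvals.append(mahalanobis_gof(observed, ensemble).p_value)
    return {"p_values": np.asarray(pvals), "n_replicates": n_replicates}


def exact_stationary_density(beta_outdegree: float, n: int = 3) -> float:
    """Exact long-run tie probability of the out-degree-only ministep chain.

    Enumerates all 2^(n(n-1)) directed graphs, builds the one-ministep
    transition matrix from the model's own choice probabilities, and
    solves for the stationary distribution. Tractable for n <= 3-4.
    """
    attrs = _tiny_attrs(n)
    spec = ModelSpec()
    spec.add(EffectSpec("outdegree", "outdegree"))
    compiled = spec.compile(attrs)
    beta = np.array([beta_outdegree])
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = len(pairs)
    states = list(itertools.product([0, 1], repeat=m))
    idx = {s: k for k, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for s in states:
        adj = np.zeros((n, n), dtype=np.int8)
        for b, (i, j) in enumerate(pairs):
            adj[i, j] = s[b]
        wave = NetworkWave("s", adj)
        for i in range(n):
            p = ministep_probabilities(compiled, beta, wave, attrs, i)
            for j in range(n):
                if j == i:
                    T[idx[s], idx[s]] += p[j] / n
                else:
                    adj2 = adj.copy()
                    adj2[i, j] = 1 - adj2[i, j]
                    s2 = tuple(int(adj2[a, b]) for a, b in pairs)
                    T[idx[s], idx[s2]] += p[j] / n
    evals, evecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, k])
    pi = pi / pi.sum()
    return float(sum(pi[idx[s]] * sum(s) for s in states) / m)


def simulated_stationary_density(
    beta_outdegree: float, n: int = 3, n_epochs: int = 800, steps_per_epoch: int = 60, seed: int = 0
) -> float:
    """Long-run simulated tie probability under the out-degree-only model."""
    attrs = _tiny_attrs(n)
    spec = ModelSpec()
    spec.add(EffectSpec("outdegree", "outdegree"))
    compiled = spec.compile(attrs)
    pv = ParameterVector(np.array([beta_outdegree]), 1.0)
    rng = np.random.default_rng(seed)
    w = NetworkWave("e", np.zeros((n, n), dtype=np.int8))
    dens = []
    for epoch in range(n_epochs):
        w, _ = simulate_period(
            compiled, pv, w, seed=int(rng.integers(0, MAX_SEED)), fixed_steps=steps_per_epoch
        )
        if epoch >= n_epochs // 10:
            dens.append(w.adjacency.sum() / (n * (n - 1)))
    return float(np.mean(dens))
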