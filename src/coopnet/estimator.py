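"""Method-of-moments estimation for two-wave network dynamics.

The moment conditions equate, for every effect k, the expected simulated
end-of-period statistic total ``sum_i s_k,i(X_end)`` with its observed
value at wave 2, and the expected number of change opportunities taken
with the observed inter-wave Hamming distance (which identifies the rate
parameter). The system is solved by Robbins-Monro stochastic
approximation in three phases:

1. derivative matrix ``D = d E[S] / d theta`` estimated from the
   covariance between simulated statistics and the simulated path score
   (likelihood-ratio/score method);
2. Robbins-Monro sub-phases with decreasing gain (halved per sub-phase),
   iterate averaging within each sub-phase;
3. a large simulation batch at the solution for the statistic covariance,
   convergence t-ratios and the parameter covariance
   ``Sigma = D^-1 Cov(S) D^-T``.

The rate is estimated on the log scale so positivity is automatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
from scipy import stats

from .data_model import AttributeSet, CompositionChangeSchedule, NetworkWave
from .effects import CompiledModel, ModelSpec, statistic_totals
from .simulator import MAX_SEED, ParameterVector, simulate_period

__all__ = [
    "EstimationConfig",
    "EstimationResult",
    "WaldTestResult",
    "ConvergenceError",
    "target_statistics",
    "estimate",
    "wald_test",
]


class ConvergenceError(RuntimeError):
    """Raised when stochastic approximation fails to converge; carries the
    last iterate in ``.result``."""

    def __init__(self, message: str, result: "EstimationResult"):
        super().__init__(message)
        self.result = result


@dataclass
class EstimationConfig:
    """Stochastic-approximation settings.

    ``n_phase1``/``n_phase3`` are simulation counts for the derivative and
    covariance phases; phase 2 runs ``phase2_subphases`` sub-phases of
    ``phase2_iterations`` single-simulation updates each, with initial gain
    ``gain`` halved per sub-phase. ``t_threshold``/``t_max_threshold`` are
    the per-statistic and overall convergence-ratio limits. ``conditional``
    stops each simulated chain at the observed change count instead of
    using the Poisson opportunity process. ``diag_mix`` blends the
    estimated derivative matrix with its diagonal before inversion in
    phase 2 (0 = full matrix, 1 = diagonal only); partial diagonalization
    stabilizes the updates when the score-method estimate of a large
    derivative matrix is noisy. ``theta_box`` bounds every
    coefficient: a moment target at the boundary of its support (e.g. an
    observed triplet count of zero) has no finite solution, and the box
    turns such runaways into a flagged boundary estimate.
    """

    n_phase1: int = 60
    phase2_subphases: int = 4
    phase2_iterations: int = 40
    gain: float = 0.3
    n_phase3: int = 500
    max_step: float = 0.75
    theta_box: float = 8.0
    diag_mix: float = 0.5
    t_threshold: float = 0.1
    t_max_threshold: float = 0.25
    max_retries: int = 2
    conditional: bool = False
    strict: bool = True


@dataclass
class EstimationResult:
    """Point estimates, uncertainty and convergence diagnostics."""

    effect_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    covariance: np.ndarray
    rate: float
    rate_se: float
    tratios: np.ndarray
    tmax: float
    converged: bool
    n_iterations: int
    seed: int
    iteration_log: list = field(default_factory=list)

    @property
    def params(self) -> ParameterVector:
        return ParameterVector(self.beta, self.rate)

    @classmethod
    def from_json(cls, payload: str) -> "EstimationResult":
        d = json.loads(payload)
        return cls(
            effect_names=d["effects"],
            beta=np.array(d["beta"]),
            se=np.array(d["se"]),
            covariance=np.array(d["covariance"]),
            rate=d["rate"],
            rate_se=d["rate_se"],
            tratios=np.array(d["tratios"]),
            tmax=d["tmax"],
            converged=d["converged"],
            n_iterations=0,
            seed=d["seed"],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "effects": self.effect_names,
                "beta": self.beta.tolist(),
                "se": self.se.tolist(),
                "covariance": self.covariance.tolist(),
                "rate": self.rate,
                "rate_se": self.rate_se,
                "tratios": self.tratios.tolist(),
                "tmax": self.tmax,
                "converged": self.converged,
                "seed": self.seed,
            },
            indent=2,
        )


@dataclass
class WaldTestResult:
    """Multi-parameter Wald test of a coefficient subvector being zero."""

    chi2: float
    df: int
    p_value: float
    tested: list[str] = field(default_factory=list)


def target_statistics(
    model: ModelSpec | CompiledModel,
    x_t1: NetworkWave,
    x_t2: NetworkWave,
    attrs: AttributeSet | None = None,
) -> np.ndarray:
    """Observed moment targets: change count then per-effect totals at wave 2."""
    if x_t1.n != x_t2.n:
        raise ValueError("waves must share one roster")
    compiled = model if isinstance(model, CompiledModel) else model.compile(attrs)
    hamming = int((x_t1.adjacency != x_t2.adjacency).sum())
    return np.concatenate([[hamming], statistic_totals(compiled, x_t2)])


def _simulate_stats(
    compiled: CompiledModel,
    theta: np.ndarray,
    x_t1: NetworkWave,
    schedule: CompositionChangeSchedule | None,
    seed: int,
    conditional: bool,
    target_hamming: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One chain at theta = (log rate, beta); returns (S, score)."""
    params = ParameterVector(theta[1:], float(np.exp(theta[0])))
    wave, _, score, _ = simulate_period(
        compiled,
        params,
        x_t1,
        schedule=schedule,
        seed=seed,
        conditional=conditional,
        target_hamming=target_hamming,
        return_score=True,
    )
    hamming = int((wave.adjacency != x_t1.adjacency).sum())
    S = np.concatenate([[hamming], statistic_totals(compiled, wave)])
    return S, score


def _derivative(S: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Score-method derivative estimate D[a,b] = Cov(S_a, score_b)."""
    Sc = S - S.mean(axis=0)
    Qc = scores - scores.mean(axis=0)
    return Sc.T @ Qc / (len(S) - 1)


def _solve(D: np.ndarray, diff: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    p = D.shape[0]
    reg = D + ridge * np.eye(p) * (np.abs(np.diag(D)).mean() + 1.0)
    try:
        return np.linalg.solve(reg, diff)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(reg, diff, rcond=None)[0]


def estimate(
    model: ModelSpec | CompiledModel,
    x_t1: NetworkWave,
    x_t2: NetworkWave,
    attrs: AttributeSet | None = None,
    schedule: CompositionChangeSchedule | None = None,
    config: EstimationConfig | None = None,
    seed: int = 0,
) -> EstimationResult:
    """Fit the evaluation-function parameters and rate by method of moments."""
    config = config or EstimationConfig()
    compiled = model if isinstance(model, CompiledModel) else model.compile(attrs)
    names = compiled.spec.names
    if len(set(names)) != len(names):
        raise ValueError("duplicated effects make the model unidentifiable")
    S_obs = target_statistics(compiled, x_t1, x_t2)
    hamming_obs = int(S_obs[0])
    if hamming_obs == 0:
        raise ValueError("waves are identical; nothing to estimate")
    n = x_t1.n
    p = len(names) + 1

    # starting point: rate from the observed change count, density-matched
    # outdegree parameter, all else zero
    theta = np.zeros(p)
    theta[0] = theta0_rate = np.log(1.5 * hamming_obs / n)
    if "outdegree" in names:
        dens = x_t2.adjacency.mean() * n / (n - 1)
        dens = min(max(dens, 1.0 / (n * n)), 0.5)
        theta[1 + names.index("outdegree")] = np.log(dens / (1 - dens))

    rng = np.random.default_rng(seed)
    log: list[dict] = []

    def batch(theta_b: np.ndarray, n_sims: int) -> tuple[np.ndarray, np.ndarray]:
        S = np.empty((n_sims, p))
        Q = np.empty((n_sims, p))
        for r in range(n_sims):
            s = int(rng.integers(0, MAX_SEED))
            S[r], Q[r] = _simulate_stats(
                compiled, theta_b, x_t1, schedule, s, config.conditional, hamming_obs
            )
        return S, Q

    n_iter = 0
    theta_init = theta.copy()
    best: tuple | None = None
    for attempt in range(config.max_retries + 1):
        if attempt > 0:
            # restart from the moment-based initial point with a smaller
            # gain: rescues runs where an early mis-step left the iterate
            # in a region with uninformative derivatives
            theta = theta_init.copy()
            gain_now = config.gain / (2**attempt)
        else:
            gain_now = config.gain
        # phase 1: derivative matrix; sample size must grow with the
        # parameter count for a usable score-method estimate
        n1 = max(config.n_phase1, 4 * p)
        S1, Q1 = batch(theta, n1)
        D = _derivative(S1, Q1)
        # guard against near-singular score estimates
        d = np.abs(np.diag(D))
        floor = 0.05 * (d.mean() + 1e-9)
        for a in range(p):
            if d[a] < floor:
                D[a, a] = np.sign(D[a, a] or 1.0) * floor
        # partial diagonalization: robust updates for large noisy systems
        D = config.diag_mix * np.diag(np.diag(D)) + (1.0 - config.diag_mix) * D

        # phase 2: Robbins-Monro sub-phases with iterate averaging
        for sub in range(config.phase2_subphases):
            a_t = gain_now / (2**sub)
            acc = np.zeros(p)
            for _ in range(config.phase2_iterations):
                s = int(rng.integers(0, MAX_SEED))
                S_sim, _ = _simulate_stats(
                    compiled, theta, x_t1, schedule, s, config.conditional, hamming_obs
                )
                step = a_t * _solve(D, S_sim - S_obs)
                np.clip(step, -config.max_step, config.max_step, out=step)
                theta = theta - step
                theta[1:] = np.clip(theta[1:], -config.theta_box, config.theta_box)
                # keep the rate within a factor e^3 of its moment-based start
                theta[0] = np.clip(theta[0], theta0_rate - 3.0, theta0_rate + 3.0)
                acc += theta
                n_iter += 1
            theta = acc / config.phase2_iterations
            log.append({"phase": 2, "subphase": sub, "theta": theta.copy()})

        # phase 3: covariance and convergence check
        S3, Q3 = batch(theta, config.n_phase3)
        mean3 = S3.mean(axis=0)
        sd3 = S3.std(axis=0, ddof=1)
        sd3 = np.where(sd3 > 0, sd3, 1.0)
        tratios = (mean3 - S_obs) / sd3
        tmax = float(np.abs(tratios).max())
        D3 = _derivative(S3, Q3)
        covS = np.cov(S3.T)
        Dinv = np.linalg.pinv(D3, rcond=1e-10)
        Sigma = Dinv @ covS @ Dinv.T
        Sigma = 0.5 * (Sigma + Sigma.T)
        log.append({"phase": 3, "tratios": tratios.copy(), "tmax": tmax})

        converged = (
            np.abs(tratios).max() < config.t_max_threshold
            and np.median(np.abs(tratios)) < config.t_threshold
        )
        if best is None or tmax < best[0]:
            best = (tmax, theta.copy(), tratios.copy(), Sigma.copy())
        if converged:
            break
    # report the best attempt by overall convergence ratio
    tmax, theta, tratios, Sigma = best[0], best[1], best[2], best[3]
    converged = bool(
        tmax < config.t_max_threshold
        and np.median(np.abs(tratios)) < config.t_threshold
    )

    se_all = np.sqrt(np.clip(np.diag(Sigma), 0.0, None))
    result = EstimationResult(
        effect_names=list(names),
        beta=theta[1:].copy(),
        se=se_all[1:],
        covariance=Sigma[1:, 1:],
        rate=float(np.exp(theta[0])),
        rate_se=float(np.exp(theta[0]) * se_all[0]),  # delta method from log scale
        tratios=tratios,
        tmax=tmax,
        converged=bool(converged),
        n_iterations=n_iter,
        seed=seed,
        iteration_log=log,
    )
    if not converged and config.strict:
        raise ConvergenceError(
            f"no convergence after {config.max_retries + 1} attempts "
            f"(max |t| = {tmax:.3f})",
            result,
        )
    return result


def wald_test(
    full: EstimationResult, restricted_effect_names: list[str]
) -> WaldTestResult:
    """Wald chi-square test that the named coefficients are jointly zero.

    One-tailed: p is the upper tail of the chi-square distribution with
    df = number of tested parameters.
    """
    idx = [full.effect_names.index(nm) for nm in restricted_effect_names]
    if not idx:
        raise ValueError("no effects to test")
    bA = full.beta[idx]
    SAA = full.covariance[np.ix_(idx, idx)]
    try:
        sol = np.linalg.solve(SAA, bA)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance sub-matrix; re-run phase 3 with more "
            "simulations or use a pseudo-inverse"
        ) from exc
    chi2 = float(bA @ sol)
    df = len(idx)
    return WaldTestResult(
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        tested=list(restricted_effect_names),
    )
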