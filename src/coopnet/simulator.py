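"""Continuous-time forward simulation of network evolution.

Between two observation waves the network changes through a long sequence
of *ministeps*: a randomly chosen present actor i may toggle one outgoing
tie (or keep the status quo), with choice probabilities given by a
multinomial logit over the evaluation-function gains. Option ``j == i``
denotes "no change" and has gain 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .data_model import AttributeSet, CompositionChangeSchedule, NetworkWave
from .effects import CompiledModel, ModelSpec, contribution_matrix

__all__ = [
    "ParameterVector",
    "MinistepRecord",
    "evaluation_gain",
    "ministep_probabilities",
    "simulate_period",
    "simulate_ensemble",
    "replay_ministeps",
]

MAX_SEED = 2**31 - 1


@dataclass
class ParameterVector:
    """Ordered effect weights beta plus the period rate parameter."""

    beta: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.isfinite(self.beta).all():
            raise ValueError("beta must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class MinistepRecord:
    """One change opportunity: acting ego, chosen option (alter index, or
    the ego's own index for 'no change'), event time, and the gain of every
    option at the moment of choice."""

    step: int
    actor: int
    chosen: int
    time: float
    gains: np.ndarray

    @property
    def toggled(self) -> bool:
        return self.chosen != self.actor


def _compiled(model: ModelSpec | CompiledModel, attrs: AttributeSet | None) -> CompiledModel:
    if isinstance(model, CompiledModel):
        return model
    return model.compile(attrs)


def evaluation_gain(beta: np.ndarray, delta: np.ndarray) -> float:
    """Evaluation-function gain of one option: sum_k beta_k * delta_k."""
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if beta.shape != delta.shape:
        raise ValueError("beta and change-statistic vector must align")
    return float(beta @ delta)


def ministep_probabilities(
    model: ModelSpec | CompiledModel,
    beta: np.ndarray,
    x: NetworkWave,
    attrs: AttributeSet | None,
    i: int,
    active: np.ndarray | None = None,
) -> np.ndarray:
    """Multinomial-logit choice probabilities for ego ``i``.

    Returns a length-n vector: entry j is the probability of toggling the
    tie to j; entry i is the probability of keeping the status quo.
    Inactive alters (``active[j] == False``) get probability 0.
    """
    compiled = _compiled(model, attrs)
    D = contribution_matrix(compiled, x, i)
    gains = np.asarray(beta, dtype=float) @ D
    gains[i] = 0.0
    if active is not None:
        gains = np.where(np.asarray(active, dtype=bool), gains, -np.inf)
        gains[i] = 0.0
    g = np.exp(gains - np.max(gains))
    return g / g.sum()


def _kernel_args(compiled: CompiledModel):
    return (
        compiled.kinds,
        compiled.cov_idx,
        compiled.parent_idx,
        compiled.V,
        compiled.W,
    )


def simulate_period(
    model: ModelSpec | CompiledModel,
    params: ParameterVector,
    x_start: NetworkWave,
    attrs: AttributeSet | None = None,
    schedule: CompositionChangeSchedule | None = None,
    seed: int = 0,
    *,
    conditional: bool = False,
    target_hamming: int = 0,
    fixed_steps: int | None = None,
    record: bool = False,
    return_score: bool = False,
):
    """Simulate one between-wave period of ministeps.

    The expected number of change opportunities is ``rate * n`` (Poisson
    distributed), unless ``fixed_steps`` pins the count or ``conditional``
    stops the chain when the Hamming distance to ``x_start`` reaches
    ``target_hamming``. Reproducible given ``seed``.

    Returns ``(wave_end, records)``; ``records`` is empty unless
    ``record=True``. With ``return_score=True`` returns
    ``(wave_end, records, score, n_opportunities)`` where ``score`` is the
    simulated path's score vector (log-rate first, then each effect) used
    by the method-of-moments derivative estimator.
    """
    compiled = _compiled(model, attrs)
    n = x_start.n
    if compiled.V.shape[0] and compiled.V.shape[1] != n:
        raise ValueError("attribute dimension does not match network")
    if schedule is None:
        schedule = CompositionChangeSchedule.full_presence(n)
    X = x_start.adjacency.copy()
    score, m_eff, _hamming, rec_actor, rec_alter, rec_time, rec_gains = _kernel.simulate_chain(
        X,
        x_start.adjacency,
        *_kernel_args(compiled),
        np.asarray(params.beta, dtype=float),
        float(params.rate),
        schedule.entry,
        schedule.exit,
        int(seed) % MAX_SEED,
        conditional,
        int(target_hamming),
        -1 if fixed_steps is None else int(fixed_steps),
        record,
    )
    wave = NetworkWave(f"{x_start.label}+sim", X, x_start.roster)
    records: list[MinistepRecord] = []
    if record:
        for s in range(len(rec_actor)):
            if rec_actor[s] >= 0:
                records.append(
                    MinistepRecord(
                        step=s,
                        actor=int(rec_actor[s]),
                        chosen=int(rec_alter[s]),
                        time=float(rec_time[s]),
                        gains=rec_gains[s].copy(),
                    )
                )
    if return_score:
        return wave, records, score, m_eff
    return wave, records


def ministeps_to_csv(records: list[MinistepRecord], path) -> None:
    """Write a ministep log as CSV (step, time, actor, alter, toggled)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "time", "actor", "alter", "toggled"])
        for r in records:
            w.writerow([r.step, f"{r.time:.6f}", r.actor,
                        r.chosen if r.toggled else "", int(r.toggled)])


def replay_ministeps(
    x_start: NetworkWave, records: list[MinistepRecord]
) -> NetworkWave:
    """Re-apply a recorded ministep chain; validates chain adjacency."""
    X = x_start.adjacency.copy()
    for rec in records:
        if rec.toggled:
            X[rec.actor, rec.chosen] = 1 - X[rec.actor, rec.chosen]
    return NetworkWave(f"{x_start.label}+replay", X, x_start.roster)


def simulate_ensemble(
    model: ModelSpec | CompiledModel,
    params: ParameterVector,
    x_start: NetworkWave,
    attrs: AttributeSet | None = None,
    schedule: CompositionChangeSchedule | None = None,
    n_sims: int = 1,
    seed: int = 0,
    **kwargs,
):
    """Yield ``n_sims`` independent end-of-period networks (streamed)."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    compiled = _compiled(model, attrs)
    rng = np.random.default_rng(seed)
    for _ in range(n_sims):
        sub = int(rng.integers(0, MAX_SEED))
        wave, _ = simulate_period(
            compiled, params, x_start, schedule=schedule, seed=sub, **kwargs
        )
        yield wave
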