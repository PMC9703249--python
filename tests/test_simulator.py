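import numpy as np
import pytest

from coopnet.data_model import CompositionChangeSchedule, NetworkWave
from coopnet.effects import EffectSpec, ModelSpec, register_core_effects
from coopnet.simulator import (
    ParameterVector,
    evaluation_gain,
    ministep_probabilities,
    replay_ministeps,
    simulate_ensemble,
    simulate_period,
)
from conftest import random_wave


@pytest.fixture(scope="module")
def model3(attrs10):
    spec = register_core_effects(ModelSpec(), "baseline")
    return spec, spec.compile(attrs10)


class TestEvaluationGain:
    def test_reciprocity_example(self):
        """A reciprocity weight of 1.7 contributes 1.7 when the toggled tie
        closes a mutual dyad."""
        beta = np.array([0.0, 1.7])
        delta = np.array([1.0, 1.0])
        assert evaluation_gain(np.array([0.0, 1.7]), np.array([0.0, 1.0])) == 1.7

    def test_zero_weights_zero_gain(self):
        assert evaluation_gain(np.zeros(5), np.arange(5.0)) == 0.0

    def test_matches_dot_product(self):
        rng = np.random.default_rng(0)
        b, d = rng.normal(size=7), rng.normal(size=7)
        assert evaluation_gain(b, d) == pytest.approx(float(np.dot(b, d)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluation_gain(np.zeros(3), np.zeros(4))


class TestMinistepProbabilities:
    def test_zero_beta_gives_uniform(self, model3, attrs10):
        spec, compiled = model3
        wave = random_wave(10, 0.2, np.random.default_rng(1))
        p = ministep_probabilities(compiled, np.zeros(spec.n_effects), wave, attrs10, 0)
        assert np.allclose(p, 0.1)

    def test_probabilities_normalize(self, model3, attrs10):
        spec, compiled = model3
        rng = np.random.default_rng(2)
        beta = rng.normal(scale=0.5, size=spec.n_effects)
        for i in range(10):
            p = ministep_probabilities(compiled, beta, random_wave(10, 0.3, rng), attrs10, i)
            assert abs(p.sum() - 1.0) < 1e-12

    def test_three_actor_hand_enumeration(self, fixtures):
        """Softmax over the 3 options (two toggles + status quo) matches a
        hand-computed enumeration."""
        attrs3 = fixtures["all_triads"]["attrs"]
        spec = ModelSpec()
        spec.add(EffectSpec("outdegree", "outdegree"))
        spec.add(EffectSpec("reciprocity", "reciprocity"))
        compiled = spec.compile(attrs3)
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[1, 0] = 1  # actor 1 points at 0; toggling 0->1 reciprocates
        beta = np.array([-1.0, 2.0])
        p = ministep_probabilities(compiled, beta, NetworkWave("w", adj), attrs3, 0)
        g = np.array([0.0, -1.0 + 2.0, -1.0])  # stay, add 0->1 (recip), add 0->2
        expect = np.exp(g) / np.exp(g).sum()
        assert p[0] == pytest.approx(expect[0])
        assert p[1] == pytest.approx(expect[1])
        assert p[2] == pytest.approx(expect[2])

    def test_empirical_frequencies_match(self, fixtures):
        """Simulated one-step choices follow the enumerated multinomial
        logit within 3 Monte Carlo SEs (10^4 draws here; the full-scale
        10^5-draw check runs in the acceptance suite)."""
        attrs3 = fixtures["all_triads"]["attrs"]
        spec = ModelSpec()
        spec.add(EffectSpec("outdegree", "outdegree"))
        spec.add(EffectSpec("reciprocity", "reciprocity"))
        compiled = spec.compile(attrs3)
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[1, 0] = 1
        wave = NetworkWave("w", adj)
        beta = np.array([-1.0, 2.0])
        p = ministep_probabilities(compiled, beta, wave, attrs3, 0)
        pv = ParameterVector(beta, 1.0)
        counts = np.zeros(3)
        n_draws = 10_000
        k = 0
        seed = 0
        while k < n_draws:
            _, recs = simulate_period(
                compiled, pv, wave, seed=seed, fixed_steps=1, record=True
            )
            seed += 1
            if recs and recs[0].actor == 0:
                counts[recs[0].chosen] += 1
                k += 1
        freq = counts / n_draws
        mc_se = np.sqrt(p * (1 - p) / n_draws)
        assert np.all(np.abs(freq - p) < 3 * mc_se + 1e-9)


class TestSimulatePeriod:
    def test_zero_steps_identity(self, model3, attrs10):
        spec, compiled = model3
        wave = random_wave(10, 0.3, np.random.default_rng(3))
        out, _ = simulate_period(
            compiled, ParameterVector(np.zeros(spec.n_effects), 1.0), wave, seed=1, fixed_steps=0
        )
        assert (out.adjacency == wave.adjacency).all()

    def test_seed_determinism(self, model3, attrs10):
        spec, compiled = model3
        wave = random_wave(10, 0.3, np.random.default_rng(4))
        pv = ParameterVector(np.full(spec.n_effects, 0.1), 3.0)
        a, _ = simulate_period(compiled, pv, wave, seed=42)
        b, _ = simulate_period(compiled, pv, wave, seed=42)
        assert (a.adjacency == b.adjacency).all()

    def test_replay_reproduces_end_state(self, model3, attrs10, tmp_path):
        spec, compiled = model3
        wave = random_wave(10, 0.2, np.random.default_rng(5))
        pv = ParameterVector(np.full(spec.n_effects, 0.05), 4.0)
        out, recs = simulate_period(compiled, pv, wave, seed=9, record=True)
        replayed = replay_ministeps(wave, recs)
        assert (replayed.adjacency == out.adjacency).all()
        # the log serializes to CSV with one row per opportunity
        from coopnet.simulator import ministeps_to_csv

        ministeps_to_csv(recs, tmp_path / "log.csv")
        assert len((tmp_path / "log.csv").read_text().splitlines()) == len(recs) + 1

    def test_chain_steps_differ_by_at_most_one_tie(self, model3, attrs10):
        spec, compiled = model3
        wave = random_wave(10, 0.2, np.random.default_rng(6))
        pv = ParameterVector(np.zeros(spec.n_effects), 3.0)
        _, recs = simulate_period(compiled, pv, wave, seed=10, record=True)
        X = wave.adjacency.copy()
        for rec in recs:
            Y = X.copy()
            if rec.toggled:
                Y[rec.actor, rec.chosen] = 1 - Y[rec.actor, rec.chosen]
            assert np.abs(Y.astype(int) - X.astype(int)).sum() <= 1
            X = Y

    def test_leaver_makes_no_ministeps_after_exit(self, model3, attrs10):
        spec, compiled = model3
        wave = random_wave(10, 0.2, np.random.default_rng(7))
        sched = CompositionChangeSchedule(
            np.zeros(10), np.array([0.5] + [1.0] * 9)
        )
        pv = ParameterVector(np.zeros(spec.n_effects), 5.0)
        for seed in range(10):
            _, recs = simulate_period(
                compiled, pv, wave, schedule=sched, seed=seed, record=True
            )
            for rec in recs:
                if rec.actor == 0:
                    assert rec.time <= 0.5

    def test_negative_outdegree_weight_depletes_dense_network(self, attrs10):
        spec = ModelSpec()
        spec.add(EffectSpec("outdegree", "outdegree"))
        compiled = spec.compile(attrs10)
        dense = random_wave(10, 0.8, np.random.default_rng(8))
        pv = ParameterVector(np.array([-3.0]), 10.0)
        counts = [
            w.tie_count
            for w in simulate_ensemble(compiled, pv, dense, n_sims=20, seed=11)
        ]
        assert np.mean(counts) < dense.tie_count

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            ParameterVector(np.zeros(2), 0.0)


class TestEnsemble:
    def test_single_simulation_reduces_to_period(self, model3, attrs10):
        spec, compiled = model3
        wave = random_wave(10, 0.2, np.random.default_rng(9))
        pv = ParameterVector(np.zeros(spec.n_effects), 2.0)
        (only,) = simulate_ensemble(compiled, pv, wave, n_sims=1, seed=5)
        assert only.n == 10

    def test_same_seed_identical_ensemble(self, model3, attrs10):
        spec, compiled = model3
        wave = random_wave(10, 0.2, np.random.default_rng(10))
        pv = ParameterVector(np.zeros(spec.n_effects), 2.0)
        e1 = [w.adjacency for w in simulate_ensemble(compiled, pv, wave, n_sims=5, seed=3)]
        e2 = [w.adjacency for w in simulate_ensemble(compiled, pv, wave, n_sims=5, seed=3)]
        for a, b in zip(e1, e2):
            assert (a == b).all()

    def test_mean_tie_count_stabilizes(self, model3, attrs10):
        """Variance of the ensemble-mean tie count shrinks roughly like 1/n."""
        spec, compiled = model3
        wave = random_wave(10, 0.2, np.random.default_rng(12))
        pv = ParameterVector(np.zeros(spec.n_effects), 2.0)
        means_small, means_big = [], []
        for rep in range(12):
            cs = [w.tie_count for w in simulate_ensemble(compiled, pv, wave, n_sims=4, seed=100 + rep)]
            cb = [w.tie_count for w in simulate_ensemble(compiled, pv, wave, n_sims=32, seed=500 + rep)]
            means_small.append(np.mean(cs))
            means_big.append(np.mean(cb))
        assert np.var(means_big) < np.var(means_small)

    def test_invalid_count_rejected(self, model3, attrs10):
        spec, compiled = model3
        wave = random_wave(10, 0.2, np.random.default_rng(13))
        with pytest.raises(ValueError):
            list(simulate_ensemble(compiled, ParameterVector(np.zeros(spec.n_effects), 1.0), wave, n_sims=0))


class TestStationaryLaw:
    def test_long_run_matches_exact_enumeration(self):
        """Long-run simulated density under the out-degree-only model
        matches the stationary distribution of the exactly enumerated
        3-actor ministep chain (note: this differs from the naive logistic
        e^b/(1+e^b), which is not the stationary law of the
        multinomial-logit ministep process)."""
        from coopnet.experiments import exact_stationary_density, simulated_stationary_density

        exact = exact_stationary_density(-1.0, n=3)
        sim = simulated_stationary_density(-1.0, n=3, n_epochs=1500, steps_per_epoch=60, seed=4)
        assert exact == pytest.approx(0.2267, abs=2e-3)  # frozen from enumeration
        assert sim == pytest.approx(exact, abs=0.02)
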