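import numpy as np
import pytest

from coopnet.data_model import NetworkWave
from coopnet.effects import ModelSpec, register_core_effects, change_statistics
from coopnet.estimator import EstimationResult
from coopnet.hypotheses import (
    ScenarioSpec,
    build_weight_vector,
    default_scenarios,
    evaluate_combination,
    gender_term_names,
    sweep_grid,
    typical_dyad_distance_m,
)


@pytest.fixture(scope="module")
def model3_names():
    return register_core_effects(ModelSpec(), "constraints").names


@pytest.fixture(scope="module")
def mock_estimate(model3_names):
    """Deterministic stand-in estimate (synthetic: fixed coefficients and a
    well-conditioned covariance) for exercising the scoring algebra."""
    rng = np.random.default_rng(99)
    p = len(model3_names)
    beta = rng.normal(scale=0.4, size=p)
    A = rng.normal(size=(p, p)) / np.sqrt(p)
    cov = A @ A.T + 0.1 * np.eye(p)
    return EstimationResult(
        effect_names=list(model3_names),
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        covariance=cov,
        rate=3.0,
        rate_se=0.2,
        tratios=np.zeros(p + 1),
        tmax=0.05,
        converged=True,
        n_iterations=100,
        seed=0,
    )


def _scenario(hyp="H2"):
    return next(s for s in default_scenarios() if s.hypothesis == hyp)


class TestWeightVectors:
    def test_man_reciprocity_weights_restricted_to_expected_effects(self, model3_names):
        a = build_weight_vector(model3_names, _scenario("H2"), 4, 7, woman=False)
        nonzero = {model3_names[k] for k in np.nonzero(a)[0]}
        assert nonzero == {
            "outdegree",
            "reciprocity",
            "outdegree_activity",
            "indegree_activity",
            "indegree_popularity",
        }

    def test_woman_adds_gender_terms(self, model3_names):
        a = build_weight_vector(model3_names, _scenario("H2"), 4, 7, woman=True)
        nonzero = {model3_names[k] for k in np.nonzero(a)[0]}
        assert "woman_ego" in nonzero
        assert "woman_x_reciprocity" in nonzero
        assert "woman_x_outdegree_activity" in nonzero

    def test_outdegree_activity_weight_at_zero_outdegree(self, model3_names):
        """Adding the first tie changes the squared out-degree by 1."""
        a = build_weight_vector(model3_names, _scenario("H1"), 0, 0, woman=False)
        k = model3_names.index("outdegree_activity")
        assert a[k] == 1.0

    def test_degree_weights_track_grid_point(self, model3_names):
        a = build_weight_vector(model3_names, _scenario("H1"), 10, 25, woman=False)
        assert a[model3_names.index("outdegree_activity")] == 21.0
        assert a[model3_names.index("indegree_popularity")] == 26.0
        assert a[model3_names.index("indegree_activity")] == 6.0
        assert a[model3_names.index("outdegree")] == 1.0

    def test_unregistered_focal_effect_rejected(self, model3_names):
        bad = ScenarioSpec("HX", "bogus", {"no_such_effect": 1.0})
        with pytest.raises(KeyError):
            build_weight_vector(model3_names, bad, 0, 0, woman=False)

    def test_weights_match_change_statistics_on_constructed_network(self, attrs10):
        """Constructive oracle: on a toy network realizing the H2 scenario
        (reciprocated target, no other structure), the artificial weights
        equal true change statistics for the focal tie."""
        spec = ModelSpec()
        for e in register_core_effects(ModelSpec(), "gender").effects:
            spec.add(e)
        names = spec.names
        n = 10
        adj = np.zeros((n, n), dtype=np.int8)
        ego, alter = 0, 1
        adj[alter, ego] = 1          # makes the focal tie reciprocating
        adj[2, ego] = adj[3, ego] = 1  # ego in-degree contributors
        wave = NetworkWave("w", adj)
        delta = change_statistics(spec, wave, attrs10, ego, alter)
        scen = ScenarioSpec("H2", "reciprocity", {"reciprocity": 1.0}, ego_indegree=3)
        woman = bool(attrs10.monadic_values("woman")[ego])
        a = build_weight_vector(names, scen, ego_outdegree=0, alter_indegree=0, woman=woman)
        for k, nm in enumerate(names):
            if nm in (
                "outdegree",
                "reciprocity",
                "outdegree_activity",
                "indegree_activity",
                "indegree_popularity",
                "woman_ego",
                "woman_x_reciprocity",
                "woman_x_outdegree_activity",
                "woman_x_indegree_activity",
                "woman_x_indegree_popularity",
            ):
                assert a[k] == pytest.approx(delta[k]), nm

    def test_h5_variants_swap_closure_effect(self, model3_names):
        a5a = build_weight_vector(model3_names, _scenario("H5a"), 3, 3, woman=False)
        a5b = build_weight_vector(model3_names, _scenario("H5b"), 3, 3, woman=False)
        tt = model3_names.index("transitive_triplets")
        cyc = model3_names.index("three_cycles")
        assert a5a[tt] == 12.0 and a5a[cyc] == 0.0
        assert a5b[cyc] == 5.0 and a5b[tt] == 0.0

    def test_same_gender_isolated_to_h7(self, model3_names):
        sg = model3_names.index("same_gender")
        for s in default_scenarios():
            a = build_weight_vector(model3_names, s, 2, 2, woman=True)
            if s.hypothesis == "H7":
                assert a[sg] == 1.0
            else:
                assert a[sg] == 0.0


class TestCombinations:
    def test_unit_vector_returns_coefficient(self, mock_estimate):
        p = len(mock_estimate.beta)
        a = np.zeros(p)
        a[3] = 1.0
        est = mock_estimate
        r = evaluate_combination(est, a)
        assert r.value == pytest.approx(est.beta[3])
        assert r.se == pytest.approx(np.sqrt(est.covariance[3, 3]))
        assert r.z == pytest.approx(r.value / r.se)

    def test_zero_vector_is_degenerate(self, mock_estimate):
        with pytest.raises(FloatingPointError):
            evaluate_combination(mock_estimate, np.zeros(len(mock_estimate.beta)))

    def test_se_matches_monte_carlo_draws(self, mock_estimate):
        rng = np.random.default_rng(5)
        a = rng.normal(size=len(mock_estimate.beta))
        r = evaluate_combination(mock_estimate, a)
        draws = rng.multivariate_normal(mock_estimate.beta, mock_estimate.covariance, 100_000)
        mc = (draws @ a).std()
        assert r.se == pytest.approx(mc, rel=0.02)

    def test_length_mismatch_rejected(self, mock_estimate):
        with pytest.raises(ValueError):
            evaluate_combination(mock_estimate, np.zeros(3))


class TestGridSweep:
    def test_default_grid_cardinality(self, mock_estimate):
        df = sweep_grid(mock_estimate, _scenario("H2"))
        assert len(df) == 4290
        assert (df.groupby("gender").size() == 2145).all()

    def test_single_cell_ranges(self, mock_estimate):
        s = ScenarioSpec("H1", "x", ego_outdegree_range=(0, 0), alter_indegree_range=(0, 0))
        df = sweep_grid(mock_estimate, s)
        assert len(df) == 2

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("H1", "x", ego_outdegree_range=(3, 2))

    def test_gender_difference_is_sum_of_gender_terms(self, mock_estimate):
        """Algebraic cancellation: at any grid point the woman-minus-man
        difference equals exactly the summed contributions of the gender
        terms (all constitutive terms cancel)."""
        names = mock_estimate.effect_names
        gset = gender_term_names(names)
        for s in default_scenarios():
            for (d, q) in [(0, 0), (7, 13), (32, 64)]:
                aw = build_weight_vector(names, s, d, q, woman=True)
                am = build_weight_vector(names, s, d, q, woman=False)
                vw = evaluate_combination(mock_estimate, aw).value
                vm = evaluate_combination(mock_estimate, am).value
                gender_sum = sum(
                    mock_estimate.beta[names.index(g)] * aw[names.index(g)] for g in gset
                )
                assert vw - vm == pytest.approx(gender_sum, abs=1e-12)

    def test_monotone_response_in_positive_direction(self, mock_estimate):
        """With a positive in-degree-popularity weight, attractiveness never
        decreases as the alter's in-degree grows."""
        est = mock_estimate
        est.beta[est.effect_names.index("indegree_popularity")] = abs(
            est.beta[est.effect_names.index("indegree_popularity")]
        )
        names = est.effect_names
        s = _scenario("H1")
        vals = []
        for q in range(0, 30):
            a = build_weight_vector(names, s, 5, q, woman=False)
            # zero every weight except the monotone one plus constants
            vals.append(
                est.beta[names.index("indegree_popularity")] * a[names.index("indegree_popularity")]
            )
        assert np.all(np.diff(vals) >= 0)

    def test_significance_flag_matches_threshold(self, mock_estimate):
        df = sweep_grid(mock_estimate, _scenario("H3"))
        assert ((df["p"] < 0.001) == df["significant"]).all()


def test_scenarios_round_trip_through_yaml(tmp_path):
    import yaml

    from coopnet.hypotheses import scenarios_from_yaml

    payload = [
        {"hypothesis": "H2", "label": "reciprocity", "focal": {"reciprocity": 1.0}},
        {
            "hypothesis": "H5a",
            "label": "transitive closure",
            "focal": {"transitive_triplets": 12.0},
            "ego_outdegree_range": [0, 4],
            "alter_indegree_range": [0, 4],
        },
    ]
    path = tmp_path / "scenarios.yaml"
    path.write_text(yaml.safe_dump(payload))
    scens = scenarios_from_yaml(path)
    assert scens[0].focal == {"reciprocity": 1.0}
    assert scens[1].ego_outdegree_range == (0, 4)


def test_typical_dyad_distance_back_transform():
    assert typical_dyad_distance_m(5.69) == 298.86
    assert typical_dyad_distance_m(5.7) == 298.86
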