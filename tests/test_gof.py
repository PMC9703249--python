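import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coopnet.data_model import NetworkWave
from coopnet.gof import (
    AuxiliaryStatistic,
    EGONET_STATISTICS,
    GofConfig,
    TRIAD_CLASSES,
    auxiliary_suite,
    compare_egonets_by_gender,
    egonet_matrix,
    egonet_statistics,
    gender_split_egonet,
    mahalanobis_gof,
    triad_census,
)
from conftest import random_wave


class TestEgonetStatistics:
    def test_isolate_has_all_zero(self, attrs10):
        wave = NetworkWave("w", np.zeros((10, 10), dtype=np.int8))
        stats = egonet_statistics(wave, attrs10, 0)
        assert all(v == 0 for v in stats.values())

    def test_reputation_gap_single_tie(self, attrs10):
        adj = np.zeros((10, 10), dtype=np.int8)
        adj[0, 1] = 1
        rep = attrs10.monadic_values("reputation_z")
        stats = egonet_statistics(NetworkWave("w", adj), attrs10, 0)
        assert stats["reputation_gap"] == pytest.approx(abs(rep[0] - rep[1]))

    def test_matches_brute_force_loops(self, attrs10):
        rng = np.random.default_rng(1)
        X = random_wave(10, 0.35, rng).adjacency
        woman = attrs10.monadic_values("woman")
        friend = attrs10.dyadic_values("friendship")
        kin = attrs10.dyadic_values("kinship")
        rep = attrs10.monadic_values("reputation_z")
        S = egonet_matrix(X, attrs10)
        for i in range(10):
            outdeg = sum(X[i, j] for j in range(10))
            recip = sum(X[i, j] * X[j, i] for j in range(10))
            fr = sum(X[i, j] * friend[i, j] for j in range(10))
            kn = sum(X[i, j] * kin[i, j] for j in range(10))
            sg = sum(X[i, j] * (woman[i] == woman[j]) for j in range(10) if j != i)
            tt = sum(
                X[i, j] * X[i, h] * X[h, j] for j in range(10) for h in range(10)
            )
            cyc = sum(
                X[i, j] * X[j, h] * X[h, i] for j in range(10) for h in range(10)
            )
            gap = sum(X[i, j] * abs(rep[i] - rep[j]) for j in range(10))
            expect = [outdeg, recip, fr, kn, sg, tt, cyc, gap]
            assert np.allclose(S[:, i], expect)

    def test_absent_actor_rejected(self, attrs10):
        wave = NetworkWave("w", np.zeros((10, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            egonet_statistics(wave, attrs10, 10)


class TestAuxiliarySuite:
    def test_empty_network_degenerate_buckets(self, attrs10):
        suite = auxiliary_suite(np.zeros((10, 10), dtype=np.int8), attrs10)
        by_name = {s.name: s for s in suite}
        geo = by_name["geodesic_distribution"].values
        assert geo[-1] == 90  # all ordered pairs unreachable
        assert geo[:-1].sum() == 0
        tc = by_name["triad_census"].values
        assert tc[0] == math.comb(10, 3)
        assert tc[1:].sum() == 0

    def test_transitive_triangle_census(self, fixtures):
        wave = fixtures["transitive_triad"]["wave"]
        tc = triad_census(wave)
        assert tc[TRIAD_CLASSES.index("030T")] == 1
        assert tc.sum() == 1

    def test_census_sums_to_n_choose_3(self):
        rng = np.random.default_rng(2)
        for n in (5, 9, 12):
            tc = triad_census(random_wave(n, 0.3, rng))
            assert tc.sum() == math.comb(n, 3)

    def test_geodesics_match_bfs_oracle(self, attrs10):
        """Distance counts equal per-source BFS via networkx."""
        rng = np.random.default_rng(3)
        X = random_wave(12, 0.15, rng).adjacency
        cfg = GofConfig(geodesic_max=13, statistics=("geodesic_distribution",))
        (geo,) = auxiliary_suite(X, None, cfg)
        G = nx.from_numpy_array(X, create_using=nx.DiGraph)
        lengths = dict(nx.all_pairs_shortest_path_length(G))
        counts = np.zeros(14)
        reachable = 0
        for i in range(12):
            for j in range(12):
                if i == j:
                    continue
                d = lengths.get(i, {}).get(j)
                if d is None or d > 13:
                    counts[-1] += 1
                else:
                    counts[d - 1] += 1
        assert np.array_equal(geo.values, counts)

    def test_cumulative_degree_distribution_monotone(self, attrs10):
        rng = np.random.default_rng(4)
        suite = auxiliary_suite(random_wave(10, 0.4, rng), attrs10)
        for s in suite:
            if s.name.endswith("degree_distribution"):
                assert np.all(np.diff(s.values) >= 0)
                assert s.values[-1] == 10  # every actor counted at the cap


class TestMahalanobis:
    def test_observed_at_mean_gives_zero_distance_p_one(self):
        rng = np.random.default_rng(5)
        E = rng.normal(size=(50, 4))
        res = mahalanobis_gof(E.mean(axis=0), E)
        assert res.mhd == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == 1.0

    def test_identity_covariance_reduces_to_euclidean(self):
        """With an uncorrelated unit-variance cloud, MHD approaches the
        Euclidean norm of the centred observation."""
        rng = np.random.default_rng(6)
        E = rng.normal(size=(20000, 3))
        obs = E.mean(axis=0) + np.array([1.0, 2.0, 2.0])
        res = mahalanobis_gof(obs, E)
        assert res.mhd == pytest.approx(3.0, rel=0.05)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        E = rng.normal(size=(60, 5))
        obs = rng.normal(size=5)
        r1 = mahalanobis_gof(obs, E)
        scale = np.array([2.0, 0.5, 3.0, 1.0, 10.0])
        shift = np.array([1.0, -2.0, 0.0, 4.0, 5.0])
        r2 = mahalanobis_gof(obs * scale + shift, E * scale + shift)
        assert r1.p_value == r2.p_value
        assert r1.mhd == pytest.approx(r2.mhd, rel=1e-6)

    def test_constant_dimensions_dropped(self):
        rng = np.random.default_rng(8)
        E = np.column_stack([rng.normal(size=40), np.full(40, 7.0)])
        obs = np.array([0.0, 7.0])
        res = mahalanobis_gof(obs, E)
        assert res.n_dropped == 1
        assert np.isfinite(res.mhd)

    def test_small_ensemble_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_gof(np.zeros(3), np.zeros((1, 3)))


class TestEgonetComparison:
    def test_gender_neutral_symmetric_setup_centres_near_zero(self, small_study):
        """Ensemble drawn by permuting rows/columns of a fixed network with
        genders balanced: differences scatter around zero."""
        attrs = small_study["attrs"]
        rng = np.random.default_rng(9)
        n = attrs.n
        base = random_wave(n, 0.1, rng)
        sims = []
        for _ in range(40):
            perm = rng.permutation(n)
            sims.append(NetworkWave("p", base.adjacency[np.ix_(perm, perm)]))
        df = compare_egonets_by_gender(base, sims, attrs)
        assert (df["q25"] <= df["median"]).all() and (df["median"] <= df["q75"]).all()
        assert np.abs(df.loc[df["statistic"] == "out_degree", "median"].iloc[0]) < 1.0

    def test_single_member_ensemble_is_its_own_median(self, small_study):
        attrs = small_study["attrs"]
        w = small_study["wave2"]
        df = compare_egonets_by_gender(w, [w], attrs)
        assert np.allclose(df["median"], df["observed_diff"])

    def test_matches_independent_groupby_recompute(self, small_study):
        attrs = small_study["attrs"]
        rng = np.random.default_rng(10)
        sims = [random_wave(attrs.n, 0.1, rng) for _ in range(5)]
        df = compare_egonets_by_gender(small_study["wave2"], sims, attrs)
        woman = attrs.monadic_values("woman").astype(bool)
        # independent recompute via pandas group-by means
        for k, stat in enumerate(EGONET_STATISTICS):
            vals = []
            for w in sims:
                per_actor = egonet_matrix(w, attrs)[k]
                s = pd.DataFrame({"woman": woman, "v": per_actor}).groupby("woman")["v"].mean()
                vals.append(s[True] - s[False])
            assert df.loc[df["statistic"] == stat, "median"].iloc[0] == pytest.approx(
                float(np.median(vals))
            )

    def test_single_gender_rejected(self, attrs10):
        attrs = attrs10
        woman = attrs.monadic.copy()
        woman["woman"] = 1
        from coopnet.data_model import AttributeSet

        mono = AttributeSet(woman, attrs.dyadic, attrs.scaling)
        with pytest.raises(ValueError, match="gender"):
            gender_split_egonet(np.zeros((10, 10), dtype=np.int8), mono)
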