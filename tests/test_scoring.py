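"""Scoring: uncentered correlation, matching, netmats, group stats, baselines."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm, t as t_dist

from pfmodes.scoring import (
    UndefinedScoreError,
    dual_regression,
    fisher_group_zstats,
    match_modes,
    netmat_rmse,
    partial_correlations,
    score_decomposition,
    test_retest,
    uncentered_correlation,
)


class TestUncenteredCorrelation:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1.0, 2.0, -1.0], [1.0, 2.0, -1.0], 1.0),
            ([1.0, 0.0], [0.0, 1.0], 0.0),
            ([1.0, 0.0], [1.0, 1.0], 1.0 / np.sqrt(2.0)),
        ],
    )
    def test_hand_cases(self, x, y, expected):
        assert uncentered_correlation(x, y) == pytest.approx(expected)

    def test_means_not_removed(self):
        # Offsetting one vector changes the score — unlike Pearson r.
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert uncentered_correlation(x, x + 10.0) != pytest.approx(1.0)

    def test_zero_vector_is_undefined_not_zero(self):
        with pytest.raises(UndefinedScoreError):
            uncentered_correlation([0.0, 0.0], [1.0, 2.0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 50))
    def test_bounded_and_symmetric(self, seed, n):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, n))
        r = uncentered_correlation(x, y)
        assert -1.0 <= r <= 1.0
        assert r == pytest.approx(uncentered_correlation(y, x))
        assert uncentered_correlation(-x, y) == pytest.approx(-r)


class TestMatchModes:
    def test_identity(self, rng):
        maps = rng.standard_normal((50, 4))
        tc = rng.standard_normal((4, 30))
        m = match_modes(maps, maps, tc, tc)
        assert m.permutation == {i: i for i in range(4)}
        assert all(v == 1 for v in m.sign_flips.values())

    def test_swap_and_negate_recovered(self, rng):
        maps = rng.standard_normal((50, 3))
        tc = rng.standard_normal((3, 30))
        est_maps = maps[:, [1, 0, 2]].copy()
        est_tc = tc[[1, 0, 2]].copy()
        est_maps[:, 1] *= -1  # negate what was mode 0
        est_tc[1] *= -1
        m = match_modes(est_maps, maps, est_tc, tc)
        assert m.permutation == {0: 1, 1: 0, 2: 2}
        assert m.sign_flips == {0: 1, 1: -1, 2: 1}

    @pytest.mark.parametrize("M", [2, 4, 6])
    def test_equals_brute_force(self, M, rng):
        # Hungarian total equals exhaustive search over all M! permutations
        # with per-pair optimal signs.
        for _ in range(34):
            score = rng.uniform(-2, 2, size=(M, M))
            maps_e = rng.standard_normal((30, M))
            maps_r = rng.standard_normal((30, M))
            m = match_modes(maps_e, maps_r)
            total = sum(
                abs(uncentered_correlation(maps_e[:, i], maps_r[:, j]))
                for i, j in m.permutation.items()
            )
            brute = max(
                sum(
                    abs(uncentered_correlation(maps_e[:, i], maps_r[:, perm[i]]))
                    for i in range(M)
                )
                for perm in itertools.permutations(range(M))
            )
            assert total == pytest.approx(brute, abs=1e-10)

    def test_unequal_mode_counts(self, rng):
        est = rng.standard_normal((40, 5))
        ref = rng.standard_normal((40, 3))
        m = match_modes(est, ref)
        assert len(m.permutation) == 3
        assert len(m.unmatched_est) == 2
        assert m.unmatched_ref == []

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            match_modes(np.empty((10, 0)), np.empty((10, 0)))


def _toy_decomposition(rng, V=200, M=3, S=3, T=40):
    subjects = [f"s{i}" for i in range(S)]
    maps = {s: rng.standard_normal((V, M)) for s in subjects}
    tcs = {(s, "r1"): rng.standard_normal((M, T)) for s in subjects}
    return maps, tcs


class TestScoreDecomposition:
    def test_perfect_recovery(self, rng):
        maps, tcs = _toy_decomposition(rng)
        match = match_modes(maps["s0"], maps["s0"], tcs[("s0", "r1")], tcs[("s0", "r1")])
        rep = score_decomposition(maps, tcs, maps, tcs, match)
        for v in rep.spatial_accuracy.values():
            assert v == pytest.approx(1.0)
        for v in rep.temporal_accuracy.values():
            assert v == pytest.approx(1.0)
        assert rep.spatial_netmat_rmse == pytest.approx(0.0, abs=1e-12)

    def test_additive_noise_attenuation(self, rng):
        # Noisy copies of the truth score at the analytic attenuation factor
        # sqrt(P_sig / (P_sig + P_noise)).
        V, M, S = 5000, 2, 4
        sigma = 0.8
        truth_maps = {f"s{i}": rng.standard_normal((V, M)) for i in range(S)}
        est_maps = {
            s: m + sigma * rng.standard_normal((V, M)) for s, m in truth_maps.items()
        }
        tcs = {(f"s{i}", "r1"): rng.standard_normal((M, 50)) for i in range(S)}
        match = match_modes(
            np.mean(list(est_maps.values()), axis=0),
            np.mean(list(truth_maps.values()), axis=0),
        )
        rep = score_decomposition(est_maps, tcs, truth_maps, tcs, match)
        expected = np.sqrt(1.0 / (1.0 + sigma**2))
        for v in rep.spatial_accuracy.values():
            assert v == pytest.approx(expected, abs=0.02)

    def test_subject_permutation_invariance(self, rng):
        maps, tcs = _toy_decomposition(rng)
        est_maps = {s: m + 0.1 * rng.standard_normal(m.shape) for s, m in maps.items()}
        match = match_modes(est_maps["s0"], maps["s0"])
        rep1 = score_decomposition(est_maps, tcs, maps, tcs, match)
        # relabel subjects consistently in both est and truth
        relabel = {"s0": "z2", "s1": "z0", "s2": "z1"}
        maps_p = {relabel[s]: m for s, m in maps.items()}
        est_p = {relabel[s]: m for s, m in est_maps.items()}
        tcs_p = {(relabel[s], r): v for (s, r), v in tcs.items()}
        rep2 = score_decomposition(est_p, tcs_p, maps_p, tcs_p, match)
        assert rep1.spatial_accuracy == pytest.approx(rep2.spatial_accuracy)


class TestNetmatRmse:
    def test_single_offdiagonal_case(self, rng):
        # Build 2-mode maps with controlled correlations: est 0.5, truth ~0.3.
        V = 20_000
        z = rng.standard_normal((V, 3))
        def corr_pair(r):
            a = z[:, 0]
            b = r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1]
            return np.column_stack([a, b])
        est = {"s0": corr_pair(0.5)}
        truth = {"s0": corr_pair(0.3)}
        tcs = {("s0", "r1"): rng.standard_normal((2, 30))}
        match = match_modes(est["s0"], truth["s0"])
        sp, _ = netmat_rmse(est, tcs, truth, tcs, match)
        emp_est = np.corrcoef(est["s0"].T)[0, 1]
        emp_truth = np.corrcoef(truth["s0"].T)[0, 1]
        assert sp == pytest.approx(abs(emp_est - emp_truth), abs=1e-10)

    def test_joint_sign_flip_invariance(self, rng):
        maps, tcs = _toy_decomposition(rng)
        est_maps = {s: m.copy() for s, m in maps.items()}
        est_tcs = {k: v.copy() for k, v in tcs.items()}
        for s in est_maps:
            est_maps[s][:, 1] *= -1
        for k in est_tcs:
            est_tcs[k][1] *= -1
        match = match_modes(
            est_maps["s0"], maps["s0"], est_tcs[("s0", "r1")], tcs[("s0", "r1")]
        )
        sp, tp = netmat_rmse(est_maps, est_tcs, maps, tcs, match)
        assert sp == pytest.approx(0.0, abs=1e-10)
        assert tp == pytest.approx(0.0, abs=1e-10)


class TestTestRetest:
    def test_identical_states_score_one(self, rng):
        maps = rng.standard_normal((100, 4))
        rt = test_retest(maps, maps)
        for v in rt["scores"].values():
            assert v == pytest.approx(1.0)
        assert rt["eliminated_pairs"] == []

    def test_independent_noise_scores_below_permutation_null(self, rng):
        V, M = 500, 4
        a = rng.standard_normal((V, M))
        b = rng.standard_normal((V, M))
        observed = np.abs(list(test_retest(a, b)["scores"].values())).mean()
        null = []
        for _ in range(100):
            perm = rng.permutation(V)
            null.append(
                np.abs(list(test_retest(a, b[perm])["scores"].values())).mean()
            )
        assert observed <= np.quantile(null, 0.95)

    def test_weak_modes_flagged_as_eliminated(self, rng):
        maps = rng.standard_normal((200, 3))
        maps[:, 2] *= 1e-4  # effectively eliminated mode
        rt = test_retest(maps, maps)
        flagged = rt["eliminated_pairs"]
        assert len(flagged) == 1
        assert rt["strengths"][flagged[0]] < 0.05


class TestFisherZ:
    def test_zero_correlations_give_zero_z(self):
        mats = np.zeros((4, 3, 3))
        for i in range(3):
            mats[:, i, i] = 1.0
        z = fisher_group_zstats(mats)
        assert np.allclose(z, 0.0)

    def test_closed_form_four_subjects(self):
        fz = np.array([0.1, 0.2, 0.3, 0.2])
        r = np.tanh(fz)
        mats = np.zeros((4, 2, 2))
        for i in range(4):
            mats[i] = [[1.0, r[i]], [r[i], 1.0]]
        z = fisher_group_zstats(mats)
        mean, sd = fz.mean(), fz.std(ddof=1)
        t = mean / (sd / 2.0)
        assert t == pytest.approx(4.89897948557)
        z_oracle = norm.isf(t_dist.sf(t, df=3))
        assert z[0, 1] == pytest.approx(z_oracle, abs=1e-10)
        assert z[1, 0] == pytest.approx(z_oracle, abs=1e-10)

    def test_antisymmetric_under_negation(self, rng):
        r = rng.uniform(-0.8, 0.8, size=(5, 3, 3))
        mats = (r + r.transpose(0, 2, 1)) / 2
        for i in range(3):
            mats[:, i, i] = 1.0
        z = fisher_group_zstats(mats)
        z_neg = fisher_group_zstats(-mats + np.where(np.eye(3), 2.0, 0.0)[None])
        assert np.allclose(z_neg, -z, atol=1e-10)

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            fisher_group_zstats(np.zeros((2, 2, 2)))


class TestPartialCorrelations:
    def test_independent_modes_equal_full(self, rng):
        x = rng.standard_normal((2, 100_000))
        partial = partial_correlations(x, subset=[0, 1])
        full = np.corrcoef(x)
        assert np.allclose(partial, full, atol=0.02)

    def test_chain_partial_vanishes(self, rng):
        n = 200_000
        x = rng.standard_normal(n)
        y = x + 0.5 * rng.standard_normal(n)
        z = y + 0.5 * rng.standard_normal(n)
        series = np.vstack([x, y, z])
        full = np.corrcoef(series)
        partial = partial_correlations(series)
        assert abs(full[0, 2]) > 0.3
        assert abs(partial[0, 2]) < 0.05
        assert np.allclose(np.diag(partial), 1.0)

    def test_subset_conditions_on_remaining_modes(self, rng):
        n = 100_000
        x = rng.standard_normal(n)
        y = x + 0.5 * rng.standard_normal(n)
        z = y + 0.5 * rng.standard_normal(n)
        series = np.vstack([x, y, z])
        block = partial_correlations(series, subset=[0, 2])
        assert abs(block[0, 1]) < 0.05  # still conditioned on y


class TestDualRegression:
    def test_exact_recovery_noiseless(self, rng):
        V, M, T = 100, 4, 60
        G = rng.standard_normal((V, M))
        A = rng.standard_normal((M, T))
        tc, maps = dual_regression(G, G @ A)
        assert np.allclose(tc, A, atol=1e-8)
        assert np.allclose(maps, G, atol=1e-8)

    def test_orthonormal_maps_give_projections(self, rng):
        V, M, T = 50, 3, 30
        G, _ = np.linalg.qr(rng.standard_normal((V, M)))
        D = rng.standard_normal((V, T))
        tc, _ = dual_regression(G, D)
        assert np.allclose(tc, G.T @ D, atol=1e-10)

    def test_subject_map_error_shrinks_with_t(self, rng):
        V, M = 150, 3
        G = rng.standard_normal((V, M))
        errs = []
        for T in (50, 500):
            A = rng.standard_normal((M, T))
            D = G @ A + 2.0 * rng.standard_normal((V, T))
            _, maps = dual_regression(G, D)
            errs.append(np.linalg.norm(maps - G) / np.linalg.norm(G))
        assert errs[1] < errs[0]

    def test_rank_deficient_maps_named(self, rng):
        G = rng.standard_normal((30, 3))
        G[:, 2] = G[:, 0]
        with pytest.raises(ValueError, match="rank deficient"):
            dual_regression(G, rng.standard_normal((30, 10)))
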