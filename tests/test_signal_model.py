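import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import hashdemux as hd
from hashdemux.errors import DegenerateFitError, ValidationError
from hashdemux.signal_model import EMPIRICAL_FLOORS


def oracle_em(x, tol=1e-8, max_iter=1000):
    """Independent brute-force EM: direct responsibility/update iteration.

    Median-split hard initialization, per-component scipy pdf evaluation,
    relative log-likelihood stopping rule |dll| / max(1, |ll|) < tol.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    lower, upper = x[x <= med], x[x > med]
    mu = [lower.mean(), upper.mean()]
    sigma = [max(lower.std(), 1e-6 * x.std()), max(upper.std(), 1e-6 * x.std())]
    w = [len(lower) / len(x), len(upper) / len(x)]
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = np.stack(
            [w[k] * stats.norm.pdf(x, mu[k], sigma[k]) for k in range(2)], axis=1
        )
        total = dens.sum(axis=1)
        ll = float(np.log(total).sum())
        resp = dens / total[:, None]
        for k in range(2):
            nk = resp[:, k].sum()
            w[k] = nk / len(x)
            mu[k] = float((resp[:, k] * x).sum() / nk)
            sigma[k] = float(np.sqrt((resp[:, k] * (x - mu[k]) ** 2).sum() / nk))
        if abs(ll - ll_prev) / max(1.0, abs(ll)) < tol:
            converged = True
            break
        ll_prev = ll
    order = np.argsort(mu)
    mu = [mu[k] for k in order]
    sigma = [sigma[k] for k in order]
    w = [w[k] for k in order]
    return mu[0], sigma[0], w[0], mu[1], sigma[1], w[1], converged


class TestReshape:
    def test_thinning_positions_for_eight_hashtags(self):
        # 10 sorted negatives, theta=4 -> 1-based positions 1, 5, 9 survive
        cfg = hd.ReshapeConfig(n_hashtags=8, empirical_cutoff=1.5)
        neg = np.linspace(0.0, 1.0, 10)
        pos = np.array([2.0, 2.5, 3.0])
        out = hd.reshape_low_signals(np.concatenate([neg, pos]), cfg)
        assert out.size == 6
        np.testing.assert_allclose(sorted(out[:3]), neg[[0, 4, 8]])
        np.testing.assert_allclose(sorted(out[3:]), pos)

    def test_disabled_for_few_hashtags(self):
        cfg = hd.ReshapeConfig(n_hashtags=2, empirical_cutoff=1.5)
        x = np.array([0.1, 0.2, 5.0])
        np.testing.assert_array_equal(hd.reshape_low_signals(x, cfg), x)

    def test_no_negatives_is_identity(self):
        cfg = hd.ReshapeConfig(n_hashtags=9, empirical_cutoff=1.5)
        x = np.array([2.0, 3.0, 4.0, 5.0])
        np.testing.assert_array_equal(hd.reshape_low_signals(x, cfg), x)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValidationError):
            hd.reshape_low_signals(np.array([]), hd.ReshapeConfig(n_hashtags=8))

    @given(
        n_hashtags=st.integers(1, 12),
        data=st.lists(st.floats(-3, 8), min_size=1, max_size=200),
    )
    def test_positives_always_kept_and_size_shrinks(self, n_hashtags, data):
        cfg = hd.ReshapeConfig(n_hashtags=n_hashtags, empirical_cutoff=1.5)
        x = np.array(data)
        out = hd.reshape_low_signals(x, cfg)
        assert out.size <= x.size
        if not cfg.enabled:
            np.testing.assert_array_equal(out, x)
        else:
            assert np.sort(out[out >= 1.5]).tolist() == np.sort(x[x >= 1.5]).tolist()


class TestEM:
    def test_matches_brute_force_oracle_across_seeds(self):
        """Production EM equals a direct responsibility/update EM to 1e-6."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(100, 501))
            k = rng.binomial(n, 0.7)
            x = np.concatenate(
                [rng.normal(0.2, 0.2, size=k), rng.normal(2.8, 0.4, size=n - k)]
            )
            got = hd.fit_two_gaussians(x)
            want = oracle_em(x)
            np.testing.assert_allclose(got[:6], want[:6], atol=1e-6, rtol=0)
            assert got[6] == want[6]

    def test_parameter_recovery_on_well_separated_mixture(self):
        rng = np.random.default_rng(42)
        x = np.concatenate(
            [rng.normal(0.3, 0.15, size=4000), rng.normal(2.5, 0.3, size=1000)]
        )
        mu1, s1, w1, mu2, s2, w2, conv = hd.fit_two_gaussians(x)
        assert conv
        assert abs(mu1 - 0.3) < 0.05 and abs(mu2 - 2.5) < 0.05
        assert abs(w1 - 0.8) < 0.05

    def test_constant_vector_degenerates(self):
        with pytest.raises(DegenerateFitError):
            hd.fit_two_gaussians(np.full(50, 1.3))

    def test_cross_check_against_sklearn(self):
        """Independent library fit agrees on a clean mixture (loose tolerance)."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(7)
        x = np.concatenate(
            [rng.normal(0.0, 0.2, size=1500), rng.normal(3.0, 0.4, size=500)]
        )
        mu1, s1, w1, mu2, s2, w2, _ = hd.fit_two_gaussians(x)
        gm = GaussianMixture(2, random_state=0, tol=1e-8, max_iter=1000).fit(
            x.reshape(-1, 1)
        )
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(
            [mu1, mu2], gm.means_.ravel()[order], atol=0.02
        )
        np.testing.assert_allclose(
            [s1, s2], np.sqrt(gm.covariances_.ravel()[order]), atol=0.02
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            hd.fit_two_gaussians(np.arange(10.0))


class TestCutoffFormula:
    def test_hand_evaluated_case(self):
        assert hd.compute_cutoff(1.0, 0.25, 3.0, 4.0, rank=2) == pytest.approx(1.4)

    @given(
        mu1=st.floats(-5, 5),
        gap=st.floats(0.1, 10),
        s1=st.floats(0.01, 10),
        s2=st.floats(0.01, 10),
        rank=st.integers(1, 8),
    )
    def test_equal_sds_give_midpoint_and_strict_interior(self, mu1, gap, s1, s2, rank):
        mu2 = mu1 + gap
        c = hd.compute_cutoff(mu1, s1, mu2, s2, rank=rank)
        assert mu1 < c < mu2
        mid = hd.compute_cutoff(mu1, s1, mu2, s1, rank=rank)
        assert mid == pytest.approx((mu1 + mu2) / 2, rel=1e-9)

    def test_large_rank_tends_to_midpoint(self):
        c = hd.compute_cutoff(0.0, 0.01, 2.0, 9.0, rank=10**6)
        assert c == pytest.approx(1.0, abs=1e-3)

    def test_unordered_means_rejected(self):
        with pytest.raises(ValidationError):
            hd.compute_cutoff(3.0, 1.0, 1.0, 1.0)


class TestValidateCutoff:
    def test_above_floor_unchanged(self):
        x = np.random.default_rng(0).normal(2, 1, 100)
        assert hd.validate_cutoff(2.0, x, 0.0, 4.0, floor=1.5) == (2.0, False)

    def test_adjusts_to_known_density_valley(self):
        # equal-weight, equal-SD modes at 0.5 and 3.5: the mixture density has
        # its unique minimum exactly at the midpoint 2.0
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [rng.normal(0.5, 0.5, 3000), rng.normal(3.5, 0.5, 3000)]
        )
        adjusted, flag = hd.validate_cutoff(0.9, x, 0.5, 3.5, floor=1.5)
        assert flag
        assert abs(adjusted - 2.0) < 0.35

    def test_sparse_window_falls_back_to_floor(self):
        x = np.array([0.0] * 30 + [5.0] * 30)
        assert hd.validate_cutoff(0.2, x, 0.5, 4.5, floor=1.5) == (1.5, True)

    def test_uniform_signal_stays_inside_window(self):
        x = np.random.default_rng(2).uniform(0.0, 3.0, 500)
        adjusted, flag = hd.validate_cutoff(0.1, x, 0.0, 3.0, floor=1.5)
        assert flag
        assert 0.0 <= adjusted <= 3.0


class TestCallCutoffs:
    def test_cutoffs_separate_generator_modes(self, sim_default):
        cfg, cm, truth, geno = sim_default
        norm = hd.log_normalize(cm)
        cutoffs = hd.call_cutoffs(norm)
        for h in norm.hashtag_names:
            fit = cutoffs[h]
            # cutoff must fall between the background and positive count modes
            assert cfg.background_meanlog < fit.cutoff < cfg.positive_meanlog

    def test_determinism(self, sim_default):
        _, cm, _, _ = sim_default
        norm = hd.clr_normalize(cm)
        assert hd.call_cutoffs(norm, seed=3) == hd.call_cutoffs(norm, seed=3)

    def test_reshaping_engages_only_above_four_hashtags(self, sim_default):
        _, cm, _, _ = sim_default
        norm = hd.clr_normalize(cm)
        cutoffs = hd.call_cutoffs(norm)
        assert all(cutoffs[h].n_points_fit < cm.n_cells for h in norm.hashtag_names)

        cfg2 = hd.SimulationConfig(n_samples=2, cells_per_sample=(300, 300), seed=1)
        cm2, _, _ = hd.simulate_experiment(cfg2)
        norm2 = hd.clr_normalize(cm2)
        cutoffs2 = hd.call_cutoffs(norm2)
        assert all(cutoffs2[h].n_points_fit == cm2.n_cells for h in norm2.hashtag_names)

    def test_degenerate_hashtag_gets_floor_cutoff(self):
        # one constant hashtag column cannot support a two-component fit
        rng = np.random.default_rng(0)
        counts = np.column_stack(
            [np.full(100, 7), rng.integers(1, 400, size=100)]
        )
        cm = hd.CountMatrix(counts, [f"c{i}" for i in range(100)], ["H1", "H2"])
        norm = hd.log_normalize(cm)
        cutoffs = hd.call_cutoffs(norm)
        assert cutoffs["H1"].degenerate
        assert cutoffs["H1"].cutoff == EMPIRICAL_FLOORS["log"]
        assert cutoffs["H1"].cutoff_adjusted
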