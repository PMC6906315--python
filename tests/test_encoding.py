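import numpy as np
import pytest

from enscode.encoding import (ALIGNED_OFFSETS_DEG, STIMULUS_ORIENTATIONS_DEG,
                              align_and_average, baseline_correct,
                              basis_responses, cross_condition_iem, ctf_slope,
                              design_matrix, estimate_weights,
                              ideal_basis_profile, invert_to_ctf, run_iem)
from enscode.synthdata import (draw_weights, generate_stimuli, simulate_epochs)
from .conftest import decode_cfg


def brute_force_slope(profile):
    """Independent regression oracle on the sign-folded offset axis."""
    x = -np.abs(ALIGNED_OFFSETS_DEG)
    return np.polyfit(x, profile, 1)[0]


class TestBasis:
    @pytest.mark.parametrize("delta,expected", [(0.0, 1.0), (90.0, 0.0),
                                                (-90.0, 0.0), (22.5, 0.5745)])
    def test_channel_response_at_offsets(self, delta, expected):
        center = STIMULUS_ORIENTATIONS_DEG[3]
        resp = basis_responses(center + delta)
        assert resp[3] == pytest.approx(expected, abs=5e-5)

    def test_design_is_full_rank_on_the_orientation_grid(self):
        C = design_matrix(STIMULUS_ORIENTATIONS_DEG)
        assert np.linalg.matrix_rank(C) == 8

    def test_responses_are_nonnegative_and_peak_at_center(self):
        from enscode.circular import orientation_diff

        thetas = np.linspace(-90, 89, 181)
        resp = basis_responses(thetas)
        assert (resp >= 0).all()
        nearest = np.abs(
            orientation_diff(thetas[:, None], STIMULUS_ORIENTATIONS_DEG[None, :])
        ).argmin(1)
        assert np.allclose(resp.max(axis=1),
                           resp[np.arange(len(thetas)), nearest], atol=1e-12)


class TestWeightEstimation:
    def test_exact_recovery_on_consistent_system(self):
        rng = np.random.default_rng(0)
        W_true = rng.standard_normal((14, 8))
        C1 = design_matrix(np.tile(STIMULUS_ORIENTATIONS_DEG, 3))
        B1 = W_true @ C1
        assert np.allclose(estimate_weights(B1, C1), W_true, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        C1 = design_matrix(np.tile(STIMULUS_ORIENTATIONS_DEG[:4], 4))
        B1 = np.zeros((10, C1.shape[1]))
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            estimate_weights(B1, C1)

    def test_unbiased_under_zero_mean_noise(self):
        rng = np.random.default_rng(1)
        W_true = rng.standard_normal((10, 8))
        C1 = design_matrix(np.tile(STIMULUS_ORIENTATIONS_DEG, 4))
        n_rep, sigma = 100, 1.0
        est = np.mean([
            estimate_weights(W_true @ C1 + sigma * rng.standard_normal((10, C1.shape[1])), C1)
            for _ in range(n_rep)
        ], axis=0)
        # LS sampling SD per entry follows σ²(C₁C₁ᵀ)⁻¹ — the cos⁷ design has
        # small trailing eigenvalues, so tolerate 4 SDs of the worst entry
        gram_inv = np.linalg.inv(C1 @ C1.T)
        tol = 4.0 * sigma * np.sqrt(np.diag(gram_inv).max() / n_rep)
        assert np.abs(est - W_true).max() < tol


class TestInversion:
    def test_roundtrip_recovers_channel_responses(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((12, 8))
        C_true = design_matrix(STIMULUS_ORIENTATIONS_DEG)
        C_hat = invert_to_ctf(W, W @ C_true)
        assert np.allclose(C_hat, C_true, atol=1e-10)
        assert C_hat.shape == (8, 8)

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(np.linalg.LinAlgError):
            invert_to_ctf(rng.standard_normal((6, 8)), rng.standard_normal((6, 4)))


class TestCtfPostprocessing:
    def test_baseline_correction_is_idempotent_and_zero_sum(self):
        rng = np.random.default_rng(4)
        C = rng.standard_normal((8, 5))
        once = baseline_correct(C)
        assert np.allclose(once.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(baseline_correct(once), once)
        assert np.allclose(baseline_correct(np.ones((8, 3))), 0.0)

    def test_alignment_of_basis_profiles_returns_basis(self):
        # per-orientation CTFs that are each the basis response to their own
        # orientation must align to the canonical profile
        C = design_matrix(STIMULUS_ORIENTATIONS_DEG)  # column j: profile of bin j
        avg = align_and_average(C, np.arange(8))
        assert np.allclose(avg, ideal_basis_profile(), atol=1e-12)

    def test_single_profile_contributes_one_eighth(self):
        C = np.zeros((8, 8))
        C[:, 0] = ideal_basis_profile()  # bin 0 already centered? align anyway
        avg = align_and_average(C, np.arange(8))
        assert np.allclose(np.sort(avg)[-1], ideal_basis_profile().max() / 8)


class TestSlope:
    def test_flat_profile_has_zero_slope(self):
        assert ctf_slope(np.full(8, 0.7)) == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_regression_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.standard_normal(8)
            assert ctf_slope(p) == pytest.approx(brute_force_slope(p), abs=1e-10)

    def test_mirror_symmetry_and_shift_invariance(self):
        p = ideal_basis_profile()
        trough = p.max() + p.min() - p  # center-trough mirror
        assert ctf_slope(trough) == pytest.approx(-ctf_slope(p), abs=1e-12)
        assert ctf_slope(p + 5.0) == pytest.approx(ctf_slope(p), abs=1e-12)
        assert ctf_slope(3.0 * p) == pytest.approx(3.0 * ctf_slope(p), abs=1e-12)


class TestRunIem:
    def test_noiseless_closed_loop_reaches_ideal_slope(self, small_noiseless):
        series = run_iem(small_noiseless, n_iterations=2, seed=3)
        ideal = ctf_slope(ideal_basis_profile())
        post = small_noiseless.times >= 0
        assert np.allclose(series.slopes[post], ideal, atol=1e-9)
        assert np.allclose(series.slopes[~post], 0.0, atol=1e-12)

    def test_shuffled_labels_give_null_sensitivity(self, small_noisy):
        rng = np.random.default_rng(0)
        ep = small_noisy
        slopes = []
        for rep in range(50):
            shuffled = ep.trial_table.copy()
            shuffled["orientation_bin"] = rng.permutation(
                shuffled["orientation_bin"].to_numpy())
            from enscode.synthdata import EpochSet
            ep2 = EpochSet(data=ep.data, times=ep.times,
                           sampling_rate=ep.sampling_rate,
                           electrode_labels=ep.electrode_labels,
                           trial_table=shuffled)
            slopes.append(run_iem(ep2, n_iterations=1, seed=rep).slopes.mean())
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 2 * se + 1e-4

    def test_deterministic_under_seed(self, small_noisy):
        a = run_iem(small_noisy, n_iterations=3, seed=11)
        b = run_iem(small_noisy, n_iterations=3, seed=11)
        assert np.array_equal(a.slopes, b.slopes)


class TestCrossCondition:
    def _pair(self, lam, seed=0):
        cfg = decode_cfg(noise_sd=0.2, ensemble_weight=lam,
                         epoch_window=(0.0, 0.05))
        W = draw_weights(cfg, 42)
        so = simulate_epochs(generate_stimuli(48, "SO", 1, seed=seed, balanced=True),
                             cfg, rng=np.random.default_rng([3, seed]), weights=W)
        vo = simulate_epochs(generate_stimuli(48, "VO", 1, seed=seed + 1, balanced=True),
                             cfg, rng=np.random.default_rng([4, seed]), weights=W)
        return so, vo

    def test_full_ensemble_weight_matches_within_condition(self):
        so, vo = self._pair(lam=1.0)
        cross = cross_condition_iem(so, vo, n_iterations=3, seed=5).slopes.mean()
        within = run_iem(so, n_iterations=3, seed=5).slopes.mean()
        assert cross == pytest.approx(within, abs=0.15 * abs(within))

    def test_item_mixture_flattens_the_reconstruction(self):
        so, vo0 = self._pair(lam=0.0)
        _, vo1 = self._pair(lam=1.0)
        s0 = cross_condition_iem(so, vo0, n_iterations=3, seed=5).slopes.mean()
        s1 = cross_condition_iem(so, vo1, n_iterations=3, seed=5).slopes.mean()
        assert 0.0 < s0 < s1

    def test_electrode_mismatch_rejected(self):
        so, vo = self._pair(lam=0.5)
        vo.electrode_labels = [f"X{i}" for i in range(len(vo.electrode_labels))]
        with pytest.raises(ValueError, match="electrodes"):
            cross_condition_iem(so, vo)
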