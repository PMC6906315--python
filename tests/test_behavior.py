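import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enscode.behavior import (estimation_bias, estimation_precision,
                              fit_weibull_mle, median_split,
                              oldnew_tuning_curve, orientation_similarity,
                              weibull_cdf)
from enscode.synthdata import (PROBE_OFFSETS_VO_DEG, generate_stimuli,
                               simulate_estimation_behavior)


def make_oldnew_table(true_params, n_per_level=50, seed=0):
    """Binomial responses from a known Weibull observer on the VO probe design."""
    rng = np.random.default_rng(seed)
    rows = []
    for off in PROBE_OFFSETS_VO_DEG:
        theta = np.deg2rad(abs(off) if off != -90.0 else 90.0)
        p = weibull_cdf(orientation_similarity(theta), *true_params)
        k = rng.binomial(n_per_level, p)
        rows += [(off, "old")] * k + [(off, "new")] * (n_per_level - k)
    return pd.DataFrame(rows, columns=["probe_offset_deg", "response"])


class TestSimilarityAndCdf:
    @pytest.mark.parametrize("theta,expected", [(0.0, 1.0), (np.pi / 2, 0.0),
                                                (-np.pi / 2, 0.0), (np.pi / 4, 0.5)])
    def test_similarity_values(self, theta, expected):
        assert orientation_similarity(theta) == pytest.approx(expected)

    def test_similarity_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            orientation_similarity(2.0)

    def test_cdf_boundary_and_threshold_semantics(self):
        a, b, g, d = 0.4, 3.0, 0.9, 0.1
        assert weibull_cdf(0.0, a, b, g, d) == pytest.approx(d)
        at_alpha = weibull_cdf(a, a, b, g, d)
        assert (at_alpha - d) / (g - d) == pytest.approx(1 - np.exp(-1))
        # steep slope limit: below threshold the curve sits at delta
        assert weibull_cdf(0.3, a, 1e8, g, d) == pytest.approx(d)
        with pytest.raises(ValueError):
            weibull_cdf(0.5, -0.1, b, g, d)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.05, 0.95), st.floats(0.2, 8.0))
    def test_cdf_monotone_when_gamma_above_delta(self, alpha, beta):
        sims = np.linspace(0, 1, 41)
        vals = weibull_cdf(sims, alpha, beta, 0.9, 0.1)
        assert (np.diff(vals) >= -1e-12).all()
        assert (vals >= 0.1 - 1e-9).all() and (vals <= 0.9 + 1e-9).all()


class TestWeibullFit:
    def test_parameter_recovery(self):
        true = (0.4, 3.0, 0.9, 0.1)
        fits = [fit_weibull_mle(make_oldnew_table(true, seed=rep), seed=rep)
                for rep in range(8)]
        est = np.mean([[f.alpha, f.beta, f.gamma, f.delta] for f in fits], axis=0)
        assert est[0] == pytest.approx(true[0], abs=0.05)
        assert est[1] == pytest.approx(true[1], abs=0.5)
        assert est[2] == pytest.approx(true[2], abs=0.05)
        assert est[3] == pytest.approx(true[3], abs=0.05)

    def test_true_parameters_beat_perturbed_on_likelihood(self):
        from enscode.behavior import weibull_nll, _level_counts

        true = (0.4, 3.0, 0.9, 0.1)
        worse = 0
        for rep in range(10):
            tab = make_oldnew_table(true, n_per_level=200, seed=100 + rep)
            sim, n, k = _level_counts(tab)
            if weibull_nll(np.array(true), sim, n, k) <= \
               weibull_nll(np.array([0.55, 2.0, 0.8, 0.2]), sim, n, k):
                worse += 1
        assert worse >= 9

    def test_all_old_responses_flagged_as_boundary(self):
        tab = pd.DataFrame({
            "probe_offset_deg": np.repeat([0.0, 20.0, 40.0, 80.0], 10),
            "response": "old",
        })
        fit = fit_weibull_mle(tab, seed=0)
        assert fit.boundary_flag
        assert fit.gamma > 0.9 and fit.delta > 0.9

    def test_fit_deterministic_given_seed(self):
        tab = make_oldnew_table((0.5, 2.0, 0.85, 0.15), seed=7)
        a = fit_weibull_mle(tab, seed=3)
        b = fit_weibull_mle(tab, seed=3)
        assert (a.alpha, a.beta, a.gamma, a.delta, a.nll) == \
               (b.alpha, b.beta, b.gamma, b.delta, b.nll)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull_mle(pd.DataFrame(columns=["probe_offset_deg", "response"]))


class TestTuningCurve:
    def test_proportions_and_missing_bins(self):
        tab = pd.DataFrame({
            "probe_offset_deg": [0.0] * 10 + [20.0] * 4,
            "response": ["old"] * 10 + ["new"] * 4,
        })
        curve = oldnew_tuning_curve(tab).set_index("probe_offset_deg")
        assert curve.loc[0.0, "proportion_old"] == 1.0
        assert curve.loc[20.0, "proportion_old"] == 0.0
        assert 40.0 not in curve.index  # empty bin reported as missing

    def test_mean_vs_item_offsets_comparison_is_computable(self):
        tab = make_oldnew_table((0.4, 3.0, 0.9, 0.1), seed=1)
        curve = oldnew_tuning_curve(tab).set_index("probe_offset_deg")
        at_mean = curve.loc[0.0, "proportion_old"]
        at_items = curve.loc[[10.0, -10.0, 30.0, -30.0], "proportion_old"].mean()
        assert np.isfinite(at_mean) and np.isfinite(at_items)


class TestEstimation:
    def test_sign_convention_toward_mean(self):
        tab = pd.DataFrame({
            "target_offset_deg": [22.5] * 4 + [-22.5] * 4,
            "response_error_deg": [-5.0] * 4 + [5.0] * 4,
        })
        per_target, tend = estimation_bias(tab)
        assert np.allclose(per_target["bias_toward_mean_deg"], 5.0)
        assert tend.value == pytest.approx(5.0)

    def test_zero_mean_errors_give_zero_bias(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({
            "target_offset_deg": np.tile([-22.5, -7.5, 7.5, 22.5], 2500),
            "response_error_deg": rng.normal(0, 5, 10000),
        })
        _, tend = estimation_bias(tab)
        assert tend.value == pytest.approx(0.0, abs=0.3)

    def test_recovers_generating_bias(self):
        stim = generate_stimuli(10_000, "VO", 2, seed=2)
        tab = simulate_estimation_behavior(stim, w=0.4, kappa=8.0, seed=3)
        _, tend = estimation_bias(tab)
        assert tend.value == pytest.approx(0.4 * 15.0, abs=0.5)

    def test_precision_matches_von_mises_closed_form(self):
        rng = np.random.default_rng(4)
        kappa = 8.0
        errs = np.rad2deg(rng.vonmises(0.0, kappa, 10_000)) / 2.0
        tab = pd.DataFrame({"target_offset_deg": 7.5, "response_error_deg": errs})
        from scipy.special import i0, i1
        r = i1(kappa) / i0(kappa)
        expected_sd = np.rad2deg(np.sqrt(-2 * np.log(r))) / 2.0
        assert estimation_precision(tab) == pytest.approx(1.0 / expected_sd, rel=0.05)

    def test_more_noise_means_less_precision(self):
        stim = generate_stimuli(4000, "VO", 2, seed=5)
        tight = simulate_estimation_behavior(stim, w=0.0, kappa=16.0, seed=6)
        loose = simulate_estimation_behavior(stim, w=0.0, kappa=4.0, seed=6)
        ratio = estimation_precision(tight) / estimation_precision(loose)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_identical_errors_flag_infinite_precision(self):
        tab = pd.DataFrame({"target_offset_deg": [7.5] * 5,
                            "response_error_deg": [3.0] * 5})
        assert estimation_precision(tab) == np.inf


class TestMedianSplit:
    def test_bimodal_split_matches_modes(self):
        tab = pd.DataFrame({
            "target_offset_deg": [22.5] * 20,
            "response_error_deg": [0.0] * 10 + [-20.0] * 10,  # toward-mean: 0 and +20
        })
        out = median_split(tab)
        toward = -np.sign(tab.target_offset_deg) * tab.response_error_deg
        assert (out.loc[toward == 20.0, "split_label"] == "mean").all()
        assert (out.loc[toward == 0.0, "split_label"] == "target").all()

    def test_partition_is_exhaustive_and_order_invariant(self):
        stim = generate_stimuli(200, "VO", 2, seed=7)
        tab = simulate_estimation_behavior(stim, w=0.3, kappa=4.0, seed=8)
        out = median_split(tab)
        assert set(out.split_label) == {"mean", "target"}
        shuffled = tab.sample(frac=1.0, random_state=1)
        out2 = median_split(shuffled).sort_index()
        pd.testing.assert_series_equal(out2.split_label, out.split_label)

    def test_symmetric_sample_splits_evenly(self):
        tab = pd.DataFrame({
            "target_offset_deg": [7.5] * 21,
            "response_error_deg": np.linspace(-10, 10, 21),
        })
        out = median_split(tab)
        counts = out.split_label.value_counts()
        assert abs(counts.get("mean", 0) - counts.get("target", 0)) <= 1

    def test_degenerate_and_tiny_tables_rejected(self):
        with pytest.raises(ValueError):
            median_split(pd.DataFrame({"target_offset_deg": [7.5] * 6,
                                       "response_error_deg": [2.0] * 6}))
        with pytest.raises(ValueError):
            median_split(pd.DataFrame({"target_offset_deg": [7.5] * 3,
                                       "response_error_deg": [1.0, 2.0, 3.0]}))
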