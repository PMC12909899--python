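import numpy as np
import pandas as pd
import pytest

from foragebold.neural import (NeuralPlantSpec, ROITimecourse, VoxelDataset,
                               synthesize_roi_bold)
from foragebold.roi import (GroupEffect, TimecourseBetas, epoch_grid,
                            group_contrasts, holm_adjust, loo_peak_estimate,
                            pointwise_glm, ppi_fit, preprocess_roi,
                            upsample_and_epoch)


class TestPreprocess:
    def test_normalisation_identity(self):
        tc = ROITimecourse("r", 1.0, np.random.default_rng(0).standard_normal(100))
        z = preprocess_roi(tc)
        assert abs(z.samples.mean()) < 1e-12
        assert abs(z.samples.std() - 1.0) < 1e-12

    def test_affine_invariance(self):
        x = np.random.default_rng(1).standard_normal(50)
        a = preprocess_roi(ROITimecourse("r", 1.0, x))
        b = preprocess_roi(ROITimecourse("r", 1.0, 3.2 * x - 7.0))
        assert np.allclose(a.samples, b.samples)

    def test_voxel_average_of_identical_voxels_matches_single(self):
        x = np.random.default_rng(2).standard_normal(40)
        vd = VoxelDataset("r", 1.0, np.column_stack([x, x]))
        a = preprocess_roi(vd)
        b = preprocess_roi(ROITimecourse("r", 1.0, x))
        assert np.allclose(a.samples, b.samples)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            preprocess_roi(ROITimecourse("r", 1.0, np.ones(10)))


class TestEpoching:
    def test_linear_signal_reproduced_exactly(self, one_subject_events):
        """Cubic splines reproduce polynomials, so epochs of a ramp are exact."""
        tr = 1.775
        dur = float(one_subject_events["onset_s"].max() + 30)
        n = int(np.ceil(dur / tr))
        tc = ROITimecourse("r", tr, 0.01 * tr * np.arange(n))
        ep = upsample_and_epoch(tc, one_subject_events)
        grid = epoch_grid(tr)
        expected = 0.01 * (one_subject_events["onset_s"].to_numpy()[ep.trial_rows, None]
                           + grid[None, :])
        assert np.allclose(ep.data, expected, atol=1e-9)

    def test_epoch_window_spans_minus2_to_8(self):
        grid = epoch_grid(1.775)
        assert grid[0] == pytest.approx(-2.0)
        assert grid[-1] <= 8.0 < grid[-1] + 0.1
        assert np.allclose(np.diff(grid), 1.775 / 20)

    def test_trials_near_session_edges_dropped(self, one_subject_events):
        ev = one_subject_events.copy()
        ev.loc[0, "onset_s"] = 0.5  # pre-window leaves the session
        tc = ROITimecourse("r", 1.775, np.random.default_rng(0)
                           .standard_normal(2000))
        ep = upsample_and_epoch(tc, ev)
        assert 0 not in ep.trial_rows

    def test_hrf_response_peaks_near_kernel_peak(self, one_subject_events):
        plant = NeuralPlantSpec(amplitudes={"r": {"all": 1.0}}, noise_sd=1e-9,
                                ar1=0.0)
        tcs = synthesize_roi_bold(one_subject_events, plant,
                                  np.random.default_rng(0))
        ep = upsample_and_epoch(tcs["r"], one_subject_events)
        mean_epoch = ep.data.mean(axis=0)
        t_peak = ep.grid[np.argmax(mean_epoch)]
        assert 3.5 <= t_peak <= 7.5  # convolution + overlap can shift slightly


class TestPointwiseGLM:
    def test_noise_only_betas_hover_near_zero(self, one_subject_events):
        tr = 1.775
        n = int(np.ceil((one_subject_events["onset_s"].max() + 30) / tr))
        tc = preprocess_roi(ROITimecourse(
            "r", tr, np.random.default_rng(3).standard_normal(n)))
        ep = upsample_and_epoch(tc, one_subject_events)
        tb = pointwise_glm(ep, one_subject_events, "4.1a")
        series = tb.series("policy_switch")
        assert np.abs(series.mean()) < 0.2

    def test_planted_effect_peaks_post_onset(self, one_subject_events):
        plant = NeuralPlantSpec(amplitudes={"r": {"congruent_pursue": 3.0}},
                                noise_sd=0.01, ar1=0.0)
        tcs = synthesize_roi_bold(one_subject_events, plant,
                                  np.random.default_rng(1))
        ep = upsample_and_epoch(preprocess_roi(tcs["r"]), one_subject_events)
        tb = pointwise_glm(ep, one_subject_events, "4.2a")
        series = tb.series("congruent_pursue")
        t_peak = ep.grid[np.argmax(series)]
        assert 3.0 <= t_peak <= 7.5
        assert series.max() > 0

    def test_contrast_coding_of_opposed_plants(self, one_subject_events):
        """+a at congruent pursues, -a at congruent rejects reads out as +a."""
        plant = NeuralPlantSpec(amplitudes={"r": {"congruent_pursue": 2.0,
                                                  "congruent_reject": -2.0}},
                                noise_sd=1e-6, ar1=0.0)
        tcs = synthesize_roi_bold(one_subject_events, plant,
                                  np.random.default_rng(2))
        ep = upsample_and_epoch(tcs["r"], one_subject_events)
        tb = pointwise_glm(ep, one_subject_events, "4.5")
        # amplitudes are expressed in noise-SD units (here 1e-6)
        assert tb.series("congruent_change").max() > 1.0e-6

    def test_unknown_glm_rejected(self, one_subject_events):
        tc = ROITimecourse("r", 1.775, np.random.default_rng(0)
                           .standard_normal(2000))
        ep = upsample_and_epoch(preprocess_roi(tc), one_subject_events)
        with pytest.raises(KeyError):
            pointwise_glm(ep, one_subject_events, "nope")


def _fake_betas(B, grid, regressor="x"):
    return [TimecourseBetas(f"s{i}", "roi", ["constant", regressor, "trial"],
                            grid, np.vstack([np.zeros_like(row), row,
                                             np.zeros_like(row)]))
            for i, row in enumerate(B)]


class TestLooPeak:
    def test_common_peak_reads_each_subject_at_that_time(self):
        grid = np.linspace(-2, 8, 101)
        base = np.exp(-0.5 * ((grid - 5.0) / 1.0) ** 2)
        rng = np.random.default_rng(0)
        B = np.stack([(1.0 + 0.1 * rng.standard_normal()) * base
                      for _ in range(10)])
        eff = loo_peak_estimate(_fake_betas(B, grid), "x")
        k = np.argmin(np.abs(grid - 5.0))
        assert np.allclose(eff.loo_betas, B[:, k])
        assert np.allclose(eff.peak_times, 5.0, atol=0.11)
        assert eff.p < 0.01

    def test_all_zero_betas_give_null_result(self):
        grid = np.linspace(-2, 8, 51)
        B = np.zeros((5, 51))
        eff = loo_peak_estimate(_fake_betas(B, grid), "x")
        assert eff.tstat == 0.0 and eff.p == 1.0

    def test_needs_three_subjects(self):
        grid = np.linspace(-2, 8, 11)
        with pytest.raises(ValueError):
            loo_peak_estimate(_fake_betas(np.zeros((2, 11)), grid), "x")

    def test_signflip_pvalue_calibrated_on_smooth_null(self):
        """Smoke calibration: ~5% rejection for smooth null curves."""
        from scipy.ndimage import gaussian_filter1d
        rng = np.random.default_rng(4)
        grid = np.linspace(-2, 8, 101)
        rej = 0
        n_rep = 120
        for _ in range(n_rep):
            B = gaussian_filter1d(rng.standard_normal((12, 101)), 8, axis=1)
            eff = loo_peak_estimate(_fake_betas(B, grid), "x", n_flips=299)
            rej += eff.p < 0.05
        assert rej / n_rep < 0.12  # inflated naive t-test sits near 0.25 here


class TestGroupContrasts:
    def test_identical_effects_are_null(self):
        e = GroupEffect("x", "a", np.ones(6), np.full(6, 5.0), 1.0, 0.5)
        f = GroupEffect("x", "b", np.ones(6), np.full(6, 5.0), 1.0, 0.5)
        out = group_contrasts({"a": e, "b": f}, [("a", "b")])
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_mismatched_subjects_rejected(self):
        e = GroupEffect("x", "a", np.ones(6), np.full(6, 5.0), 1.0, 0.5)
        f = GroupEffect("x", "b", np.ones(5), np.full(5, 5.0), 1.0, 0.5)
        with pytest.raises(ValueError, match="mismatched"):
            group_contrasts({"a": e, "b": f}, [("a", "b")])

    def test_holm_stepdown_arithmetic(self):
        adj = holm_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.04, 0.04])


class TestPPI:
    def test_env_independent_coupling_loads_on_main_effect(self, one_subject_events):
        rng = np.random.default_rng(5)
        n = 1500
        tr = 1.775
        s = rng.standard_normal(n)
        y = 0.6 * s + 0.1 * rng.standard_normal(n)
        fit = ppi_fit(ROITimecourse("t", tr, y), ROITimecourse("s", tr, s),
                      one_subject_events)
        assert fit["seed"]["p"] < 1e-6
        assert abs(fit["ppi"]["coef"]) < 0.05

    def test_independent_noise_gives_null_everything(self, one_subject_events):
        rng = np.random.default_rng(6)
        n = 1500
        fit = ppi_fit(ROITimecourse("t", 1.775, rng.standard_normal(n)),
                      ROITimecourse("s", 1.775, rng.standard_normal(n)),
                      one_subject_events)
        assert abs(fit["seed"]["coef"]) < 0.1
        assert abs(fit["ppi"]["coef"]) < 0.1

    def test_length_mismatch_rejected(self, one_subject_events):
        with pytest.raises(ValueError, match="length"):
            ppi_fit(ROITimecourse("t", 1.0, np.zeros(10) + np.arange(10)),
                    ROITimecourse("s", 1.0, np.arange(11)),
                    one_subject_events)
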