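"""Regime segmentation: recovery, equivariance, oracle, replicate summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinamech.curves import FDCurve
from retinamech.segmentation import (
    RegimeModel,
    SegmentationError,
    SegmentationOptions,
    segment_regimes,
    summarize_replicates,
)
from retinamech.synthetic import generate_fd_curve, make_rate_preset

from conftest import exhaustive_regime_sse


class TestNoiselessRecovery:
    @pytest.mark.parametrize("rate", [2.0, 0.1, 0.5])
    def test_generator_parameters_recovered(self, rate):
        preset = make_rate_preset(rate)
        fit = segment_regimes(generate_fd_curve(preset, 1000, 0.0, seed=1))
        assert fit.k1 == pytest.approx(preset.k1, rel=1e-3)
        assert fit.k3 == pytest.approx(preset.k3, rel=1e-3)
        assert fit.F_y1 == pytest.approx(preset.F_y1, rel=1e-3)
        assert fit.F_y2 == pytest.approx(preset.F_y2, rel=1e-3)
        assert fit.plateau_forces[0] == pytest.approx(preset.F_y1, rel=1e-3)
        assert fit.plateau_forces[1] == pytest.approx(preset.F_y2, rel=1e-3)
        assert not fit.no_yield_detected and not fit.partial

    def test_breakpoints_land_on_generator_corners(self):
        preset = make_rate_preset(2.0)
        curve = generate_fd_curve(preset, 1000, 0.0, seed=1)
        fit = segment_regimes(curve)
        dx = curve.displacement[1] - curve.displacement[0]
        # the three yield/plateau corners are identifiable to ~a sample
        for fitted, truth in zip(fit.breakpoints[1:], preset.breakpoints[1:]):
            assert abs(fitted - truth) < 2 * dx

    def test_invariants_of_fit(self):
        fit = segment_regimes(generate_fd_curve(make_rate_preset(0.1), 1000, 0.0, seed=2))
        assert np.all(np.diff(fit.breakpoints) > 0)
        assert fit.k1 > 0 and fit.k3 > fit.k1
        assert fit.F_y2 > fit.F_y1
        assert abs(fit.F_y1 - fit.plateau_forces[0]) <= 0.1 * fit.plateau_forces[0]


class TestNoisyRecovery:
    def test_median_relative_slope_error_under_noise(self):
        # 0.02 mN force noise, 1000 samples: median k1 error < 5% over 50 seeds
        preset = make_rate_preset(2.0)
        errs = []
        for seed in range(1, 51):
            fit = segment_regimes(generate_fd_curve(preset, 1000, 0.02e-3, seed=seed))
            errs.append(abs(fit.k1 - preset.k1) / preset.k1)
        assert np.median(errs) < 0.05

    def test_small_replicate_set_mean_within_experimental_sd(self):
        preset = make_rate_preset(0.1)
        fits = [segment_regimes(generate_fd_curve(preset, 1000, 0.02e-3, seed=s))
                for s in range(1, 6)]
        summary = summarize_replicates(fits)
        assert abs(summary.stats["k1"][0] - 33.5) < 4.7  # quoted replicate SD


class TestEquivariance:
    @given(c=st.floats(0.25, 8.0))
    @settings(max_examples=8, deadline=None)
    def test_force_rescaling_scales_forces_and_fixes_breakpoints(self, c):
        curve = generate_fd_curve(make_rate_preset(2.0), 600, 0.02e-3, seed=9)
        scaled = FDCurve(curve.displacement, c * curve.force, rate=curve.rate)
        a, b = segment_regimes(curve), segment_regimes(scaled)
        assert b.breakpoint_indices == a.breakpoint_indices
        assert b.k1 == pytest.approx(c * a.k1, rel=1e-9)
        assert b.k3 == pytest.approx(c * a.k3, rel=1e-9)
        assert b.F_y1 == pytest.approx(c * a.F_y1, rel=1e-12)
        assert b.F_y2 == pytest.approx(c * a.F_y2, rel=1e-12)


class TestExhaustiveOracle:
    @pytest.mark.parametrize("noise_sd,seed", [(0.0, 1), (5e-6, 1), (5e-6, 2)])
    def test_search_matches_brute_force_global_minimum(self, short_record_params,
                                                       noise_sd, seed):
        curve = generate_fd_curve(short_record_params, 80, noise_sd, seed=seed)
        fit = RegimeModel(curve, SegmentationOptions(min_seg_points=5)).fit()
        oracle_sse, oracle_idx = exhaustive_regime_sse(
            curve.displacement, curve.force, 4, 5
        )
        assert fit.sse == pytest.approx(oracle_sse, rel=1e-12)
        assert fit.breakpoint_indices == oracle_idx


class TestDegenerateAndPartial:
    def test_straight_line_flagged_no_yield(self):
        d = np.linspace(0, 1e-3, 200)
        fit = segment_regimes(FDCurve(d, 20.0 * d, rate=2e-6))
        assert fit.no_yield_detected

    def test_partial_curve_reduced_model(self):
        # record stopped inside the first plateau: toe + regime 1 + plateau 2
        preset = make_rate_preset(2.0)
        full = generate_fd_curve(preset, 1000, 0.0, seed=1)
        stop = np.searchsorted(full.displacement, 150e-6)
        partial = FDCurve(full.displacement[:stop], full.force[:stop], rate=full.rate)
        fit = RegimeModel(partial, SegmentationOptions(n_breakpoints=2)).fit()
        assert fit.partial
        assert fit.k1 == pytest.approx(preset.k1, rel=1e-3)
        assert fit.F_y1 == pytest.approx(preset.F_y1, rel=1e-3)
        assert fit.k3 is None and fit.F_y2 is None

    def test_too_few_samples_raises(self):
        curve = generate_fd_curve(make_rate_preset(2.0), 50, 0.0, seed=1)
        with pytest.raises(SegmentationError):
            RegimeModel(curve, SegmentationOptions(min_seg_points=15)).fit()

    def test_options_validation(self):
        with pytest.raises(ValueError):
            SegmentationOptions(n_breakpoints=5)
        with pytest.raises(ValueError):
            SegmentationOptions(smooth_window=4)


class TestReplicateSummary:
    def test_hand_computed_mean_and_sd(self):
        fits = [segment_regimes(generate_fd_curve(make_rate_preset(2.0), 400, 0.0, seed=1))]
        base = fits[0]
        from dataclasses import replace
        trio = [replace(base, k1=20.0), replace(base, k1=21.0), replace(base, k1=22.0)]
        s = summarize_replicates(trio)
        assert s.stats["k1"] == (pytest.approx(21.0), pytest.approx(1.0))
        assert s.n == 3

    def test_identical_fits_have_zero_sd(self):
        fit = segment_regimes(generate_fd_curve(make_rate_preset(2.0), 400, 0.0, seed=1))
        s = summarize_replicates([fit, fit, fit])
        assert s.stats["k1"][1] == 0.0

    def test_empty_and_mixed_rate_inputs_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates([])
        a = segment_regimes(generate_fd_curve(make_rate_preset(2.0), 400, 0.0, seed=1))
        b = segment_regimes(generate_fd_curve(make_rate_preset(0.1), 400, 0.0, seed=1))
        with pytest.raises(ValueError):
            summarize_replicates([a, b])

    def test_json_serialisation(self, tmp_path):
        fit = segment_regimes(generate_fd_curve(make_rate_preset(2.0), 400, 0.0, seed=1))
        fit.to_json(tmp_path / "fit.json")
        summarize_replicates([fit]).to_json(tmp_path / "sum.json")
        import json
        d = json.loads((tmp_path / "fit.json").read_text())
        assert d["k1_N_per_m"] == pytest.approx(21.5, rel=1e-3)
        assert json.loads((tmp_path / "sum.json").read_text())["n"] == 1
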