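"""Synthetic generators: presets, piecewise curve shape, seeding, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinamech.synthetic import (
    DEFAULT_MASSES_KG,
    G_STANDARD,
    RegimeParams,
    generate_calibration_table,
    generate_fd_curve,
    hooke_extension,
    make_rate_preset,
)


class TestRatePresets:
    @pytest.mark.parametrize(
        "rate,k1,fy1",
        [(2.0, 21.5, 1.5e-3), (0.1, 33.5, 2.2e-3)],
    )
    def test_published_anchor_values(self, rate, k1, fy1):
        p = make_rate_preset(rate)
        assert p.k1 == k1
        assert p.F_y1 == fy1
        assert not p.extrapolated
        assert "k1" not in p.invented

    @pytest.mark.parametrize("rate", [0.1, 0.5, 2.0])
    def test_toe_and_plateau_geometry(self, rate):
        p = make_rate_preset(rate)
        assert p.toe_end == pytest.approx(1.0e-5)   # linearity begins at 0.01 mm
        assert p.plateau2_len == pytest.approx(200e-6)
        assert p.d_max == pytest.approx(1.0e-3)

    def test_intermediate_rate_is_interpolated_and_flagged(self):
        p = make_rate_preset(0.5)
        # linear interpolation between the 0.1 and 2.0 um/s anchors
        frac = (0.5 - 0.1) / (2.0 - 0.1)
        assert p.k1 == pytest.approx(33.5 + frac * (21.5 - 33.5))
        assert p.F_y1 == pytest.approx(2.2e-3 + frac * (1.5e-3 - 2.2e-3))
        assert {"k1", "F_y1"} <= set(p.invented)
        assert not p.extrapolated

    def test_out_of_range_rate_flagged_extrapolated(self):
        assert make_rate_preset(3.0).extrapolated

    @pytest.mark.parametrize("rate", [0.0, -1.0])
    def test_nonpositive_rate_rejected(self, rate):
        with pytest.raises(ValueError):
            make_rate_preset(rate)

    @given(rate=st.floats(0.1, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_preset_invariants_hold_across_rates(self, rate):
        p = make_rate_preset(rate)
        assert p.k3 > p.k1 > 0
        assert p.F_y2 > p.F_y1 > 0
        assert p.breakpoints[3] < p.d_max
        assert np.all(np.diff(p.breakpoints) > 0)


class TestMeanCurve:
    def test_zero_at_origin(self):
        p = make_rate_preset(2.0)
        assert p.mean_force(0.0) == 0.0

    def test_regime1_linear_extension_of_toe(self):
        # one toe-length plus 0.02 mm into regime 1, evaluated by hand
        p = make_rate_preset(2.0)
        expected = 2.0 / 3.0 * 21.5 * 1e-5 + 21.5 * 0.02e-3
        assert p.mean_force(1e-5 + 0.02e-3) == pytest.approx(expected, rel=1e-12)

    def test_regime2_plateau_at_first_yield_force(self):
        p = make_rate_preset(2.0)
        _, d1, d2, _ = p.breakpoints
        inside = np.linspace(d1 + 1e-6, d2 - 1e-6, 7)
        assert np.allclose(p.mean_force(inside), 1.5e-3)

    def test_monotone_and_continuous_at_breakpoints(self):
        for rate in (0.1, 0.5, 2.0):
            p = make_rate_preset(rate)
            d = np.linspace(0, p.d_max, 5000)
            assert np.all(np.diff(p.mean_force(d)) >= -1e-15)
            eps = 1e-12
            for b in p.breakpoints:
                lo, hi = p.mean_force(b - eps), p.mean_force(b + eps)
                # continuous: the two-sided gap is at most slope * 2 eps
                assert abs(hi - lo) <= 2 * eps * p.k3 + 1e-15


class TestGenerateFDCurve:
    def test_seed_reproducibility_bit_identical(self):
        p = make_rate_preset(2.0)
        a = generate_fd_curve(p, 200, 0.05e-3, seed=42)
        b = generate_fd_curve(p, 200, 0.05e-3, seed=42)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.displacement, b.displacement)
        c = generate_fd_curve(p, 200, 0.05e-3, seed=43)
        assert not np.array_equal(a.force, c.force)

    def test_noiseless_curve_equals_mean_curve(self):
        p = make_rate_preset(0.1)
        c = generate_fd_curve(p, 500, 0.0, seed=0)
        assert np.allclose(c.force, p.mean_force(c.displacement))
        assert c.force[0] == 0.0

    def test_noisy_mean_converges_to_mean_curve(self):
        # 1000 draws at three displacements; sample mean within 3 standard errors
        p = make_rate_preset(2.0)
        sd = 0.05e-3
        probes = [100, 400, 800]
        draws = np.stack([
            generate_fd_curve(p, 1000, sd, seed=s).force[probes] for s in range(1000)
        ])
        truth = p.mean_force(generate_fd_curve(p, 1000, 0.0, seed=0).displacement[probes])
        se = sd / np.sqrt(1000)
        assert np.all(np.abs(draws.mean(axis=0) - truth) < 3 * se)

    def test_input_validation(self):
        p = make_rate_preset(2.0)
        with pytest.raises(ValueError):
            generate_fd_curve(p, 10, 0.0, seed=1)
        with pytest.raises(ValueError):
            generate_fd_curve(p, 100, -1.0, seed=1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RegimeParams(rate=2e-6, toe_end=1e-5, k1=21.5, F_y1=1.5e-3,
                         plateau2_len=2e-4, k3=10.0, F_y2=3.75e-3, d_max=1e-3)
        with pytest.raises(ValueError):
            RegimeParams(rate=2e-6, toe_end=1e-5, k1=21.5, F_y1=1.5e-3,
                         plateau2_len=2e-4, k3=43.0, F_y2=1.0e-3, d_max=1e-3)


class TestCalibrationTable:
    def test_hand_computed_extension(self):
        # 1000 mg on a 54.96 N/m spring: x = 1e-3 * 9.81 / 54.96 = 178.5 um
        t = generate_calibration_table(54.96, masses=[1e-3], noise_sd=0.0, seed=0)
        assert t.extensions[0] == pytest.approx(178.5e-6, rel=1e-3)

    def test_zero_mass_extension_is_zero(self):
        assert hooke_extension(0.0, 54.96) == 0.0

    def test_default_mass_grid_spans_brass_wire_range(self):
        t = generate_calibration_table(54.96, noise_sd=0.0, seed=0)
        assert t.masses.min() == pytest.approx(150e-6 * 1e3 * 1e-3)  # 150 mg in kg
        assert t.masses.max() == pytest.approx(2.2e-3)
        assert t.n == DEFAULT_MASSES_KG.size == 10

    def test_noise_is_seeded_and_zero_mean_model(self):
        a = generate_calibration_table(54.96, noise_sd=2e-6, seed=5)
        b = generate_calibration_table(54.96, noise_sd=2e-6, seed=5)
        assert np.array_equal(a.extensions, b.extensions)
        clean = generate_calibration_table(54.96, noise_sd=0.0, seed=5)
        assert clean.extensions == pytest.approx(clean.masses * G_STANDARD / 54.96)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_calibration_table(-1.0, seed=0)
        with pytest.raises(ValueError):
            generate_calibration_table(54.96, masses=[0.0, 1e-3], seed=0)
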