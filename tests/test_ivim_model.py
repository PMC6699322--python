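import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivimhsi.ivim_model import (
    IVIMCube,
    TissueParams,
    adc_two_point,
    biexp_signal,
    compute_param_maps,
    fit_adc,
    fit_ivim,
    fit_slope,
)

CENTRAL = TissueParams(D=0.76, Dstar=9.38, PF=0.215)
PERIPHERAL = TissueParams(D=0.93, Dstar=9.02, PF=0.253)
CYST = TissueParams(D=1.59, Dstar=4.62, PF=0.411)


class TestBiexpSignal:
    def test_unity_at_b_zero(self):
        assert biexp_signal(CENTRAL, 0.0) == pytest.approx(1.0)

    def test_reduces_to_monoexponential_when_pf_zero(self):
        tp = TissueParams(D=1.0, Dstar=10.0, PF=0.0)
        assert biexp_signal(tp, 1000.0) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_cyst_value_matches_scalar_arithmetic(self):
        # independent scalar evaluation of the two-compartment decay
        expected = (1 - 0.411) * math.exp(-1000 * 1.59e-3) + 0.411 * math.exp(-1000 * 4.62e-3)
        assert biexp_signal(CYST, 1000.0) == pytest.approx(expected, rel=1e-14)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            biexp_signal(CENTRAL, -5.0)


class TestAdcTwoPoint:
    def test_ratio_e_over_1000(self):
        assert adc_two_point(math.e, 1.0, 0.0, 1000.0) == pytest.approx(1.0)

    def test_equal_signals_give_zero(self):
        assert adc_two_point(5.0, 5.0, 0.0, 700.0) == 0.0

    def test_matches_log_arithmetic(self):
        assert adc_two_point(1.0, 0.124, 0.0, 1000.0) == pytest.approx(
            math.log(1 / 0.124) / 1000 / 1e-3
        )

    @pytest.mark.parametrize("args", [(1.0, 1.0, 500.0, 500.0), (0.0, 1.0, 0.0, 500.0)])
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            adc_two_point(*args)


class TestFitAdc:
    def test_exact_on_noiseless_monoexponential(self, bvals):
        sig = 7.0 * np.exp(-bvals * 1.23e-3)
        assert fit_adc(sig, bvals) == pytest.approx(1.23, abs=1e-9)

    def test_constant_signal_gives_zero(self, bvals):
        assert fit_adc(np.full_like(bvals, 3.3), bvals) == pytest.approx(0.0, abs=1e-12)

    def test_perfusion_inflates_adc_above_d(self, bvals):
        sig = np.asarray(biexp_signal(CYST, bvals))
        assert fit_adc(sig, bvals) > CYST.D

    def test_error_names_offending_bvalue(self, bvals):
        sig = np.asarray(biexp_signal(CYST, bvals))
        sig[7] = 0.0
        with pytest.raises(ValueError, match="400"):
            fit_adc(sig, bvals)

    def test_two_point_series_equals_two_point_formula(self):
        b = np.array([0.0, 1000.0])
        sig = np.array([1.0, 0.31])
        assert fit_adc(sig, b) == pytest.approx(adc_two_point(sig[0], sig[1], b[0], b[1]))


class TestFitSlope:
    def test_constant_signal_gives_zero(self, bvals):
        assert fit_slope(np.full_like(bvals, 2.0), bvals) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_input(self, bvals):
        sig = 1.0 - 0.5 * (bvals / 1000.0)
        assert fit_slope(sig, bvals) == pytest.approx(-0.5, abs=1e-12)

    def test_matches_polyfit_oracle(self, bvals):
        sig = np.asarray(biexp_signal(CENTRAL, bvals))
        expected = np.polyfit(bvals / 1000.0, sig / sig[0], 1)[0]
        assert fit_slope(sig, bvals) == pytest.approx(expected, rel=1e-10)


class TestFitIvim:
    @pytest.mark.parametrize("tp", [CENTRAL, PERIPHERAL, CYST], ids=["central", "peripheral", "cyst"])
    def test_noiseless_roundtrip_within_1_percent(self, bvals, tp):
        sig = 100.0 * np.asarray(biexp_signal(tp, bvals))
        fit = fit_ivim(sig, bvals)
        assert fit.converged
        assert fit.D == pytest.approx(tp.D, rel=0.01)
        assert fit.Dstar == pytest.approx(tp.Dstar, rel=0.01)
        assert fit.PF == pytest.approx(tp.PF, rel=0.01)

    def test_pf_zero_signal_yields_tiny_pf(self, bvals):
        sig = np.exp(-bvals * 1.1e-3)
        assert fit_ivim(sig, bvals).PF <= 0.01

    def test_zero_signal_rejected(self, bvals):
        sig = np.asarray(biexp_signal(CENTRAL, bvals))
        sig[-1] = 0.0
        with pytest.raises(ValueError):
            fit_ivim(sig, bvals)

    def test_full_residual_never_worse_than_segmented(self, bvals, rng):
        sig = 100 * np.asarray(biexp_signal(PERIPHERAL, bvals)) + rng.normal(0, 1.0, bvals.size)
        sig = np.abs(sig) + 1e-6
        seg = fit_ivim(sig, bvals, method="segmented")
        full = fit_ivim(sig, bvals, method="full")
        assert full.residual_norm <= seg.residual_norm + 1e-12

    def test_d_not_above_adc_on_biexponential_input(self, bvals):
        for tp in (CENTRAL, PERIPHERAL, CYST):
            sig = np.asarray(biexp_signal(tp, bvals))
            fit = fit_ivim(sig, bvals)
            assert fit.D <= fit.ADC + 1e-9

    def test_too_few_points_above_split_rejected(self):
        b = np.array([0.0, 50.0, 100.0, 300.0])
        sig = np.exp(-b * 1e-3)
        with pytest.raises(ValueError, match="b_split"):
            fit_ivim(sig, b, b_split=250.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        b = np.asarray([0, 15, 30, 45, 60, 100, 250, 400, 550, 700, 850, 1000], dtype=float)
        sig = np.asarray(biexp_signal(PERIPHERAL, b))
        f1 = fit_ivim(sig, b)
        f2 = fit_ivim(scale * sig, b)
        assert f2.ADC == pytest.approx(f1.ADC, rel=1e-8)
        assert f2.slope == pytest.approx(f1.slope, rel=1e-8)
        assert f2.D == pytest.approx(f1.D, rel=1e-6)
        assert f2.PF == pytest.approx(f1.PF, rel=1e-6)


class TestComputeParamMaps:
    def _uniform_cube(self, bvals, tp, shape=(4, 4, 1)):
        sig = tp.S0 * np.asarray(biexp_signal(tp, bvals))
        data = np.broadcast_to(sig, shape + (bvals.size,)).copy()
        return IVIMCube(data=data, bvals=bvals)

    def test_noiseless_single_tissue_recovery(self, bvals):
        tp = TissueParams(D=1.14, Dstar=5.98, PF=0.311, S0=100.0)
        cube = self._uniform_cube(bvals, tp)
        maps = compute_param_maps(cube, np.ones(cube.spatial_shape, bool))
        assert maps.valid.all()
        np.testing.assert_allclose(maps.D, tp.D, rtol=0.01)
        np.testing.assert_allclose(maps.PF, tp.PF, rtol=0.01)

    def test_single_pixel_mask(self, bvals):
        cube = self._uniform_cube(bvals, CENTRAL)
        mask = np.zeros(cube.spatial_shape, bool)
        mask[2, 1, 0] = True
        maps = compute_param_maps(cube, mask)
        assert maps.valid.sum() == 1
        assert np.isnan(maps.D[0, 0, 0])

    def test_empty_mask_rejected(self, bvals):
        cube = self._uniform_cube(bvals, CENTRAL)
        with pytest.raises(ValueError, match="empty mask"):
            compute_param_maps(cube, np.zeros(cube.spatial_shape, bool))

    def test_nonpositive_pixels_flagged_not_fatal(self, bvals):
        cube = self._uniform_cube(bvals, CENTRAL)
        cube.data[0, 0, 0, :] = 0.0
        maps = compute_param_maps(cube, np.ones(cube.spatial_shape, bool))
        assert not maps.valid[0, 0, 0]
        assert np.isnan(maps.D[0, 0, 0])
        assert maps.valid.sum() == maps.valid.size - 1
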