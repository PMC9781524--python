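"""Oxygen-metabolism biomarker equations and range thresholding."""

import math

import numpy as np
import pytest

from oxyradiomics.constants import DEFAULT_RANGES, PhysiologicalRange, QBOLDConstants
from oxyradiomics.maps import QuantMap, Quantity
from oxyradiomics.qbold import (apply_physiological_range, compute_capipo2,
                                compute_cmro2, compute_mitopo2, compute_oef,
                                oef_as_percent)

SPACING = (1.0, 1.0, 1.0)
C = QBOLDConstants()


def qmap(value, quantity, shape=(2, 2, 2)):
    return QuantMap(np.full(shape, float(value)), SPACING, quantity)


class TestOEF:
    def test_zero_numerator_gives_zero(self):
        oef = compute_oef(qmap(15.0, Quantity.R2STAR), qmap(15.0, Quantity.R2),
                          qmap(0.03, Quantity.CBV))
        assert np.all(oef.values == 0.0)
        assert oef.valid.all()

    def test_printed_constant_scalar_value(self):
        # independent literal evaluation of the published formula
        expected = 8.0 / ((4.0 / 3.0) * math.pi * 2.67502e8 * 0.264e-6
                          * (0.42 * 0.85) * 3.0 * 0.03)
        oef = compute_oef(qmap(20.0, Quantity.R2STAR), qmap(12.0, Quantity.R2),
                          qmap(0.03, Quantity.CBV))
        assert oef.values == pytest.approx(expected, rel=1e-12)

    def test_doubling_cbv_halves_oef(self):
        a = compute_oef(qmap(20.0, Quantity.R2STAR), qmap(12.0, Quantity.R2),
                        qmap(0.03, Quantity.CBV))
        b = compute_oef(qmap(20.0, Quantity.R2STAR), qmap(12.0, Quantity.R2),
                        qmap(0.06, Quantity.CBV))
        assert np.allclose(a.values, 2.0 * b.values)

    def test_negative_difference_invalidated(self):
        oef = compute_oef(qmap(10.0, Quantity.R2STAR), qmap(12.0, Quantity.R2),
                          qmap(0.03, Quantity.CBV))
        assert not oef.valid.any()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            compute_oef(qmap(20.0, Quantity.R2STAR, shape=(3, 3, 3)),
                        qmap(12.0, Quantity.R2), qmap(0.03, Quantity.CBV))


class TestCMRO2:
    def test_zero_cbf_gives_zero(self):
        cmro2 = compute_cmro2(qmap(0.4, Quantity.OEF), qmap(0.0, Quantity.CBF))
        assert np.all(cmro2.values == 0.0)

    def test_fick_scalar_value(self):
        cmro2 = compute_cmro2(qmap(0.4, Quantity.OEF), qmap(50.0, Quantity.CBF))
        assert cmro2.values == pytest.approx(8.68 * 50.0 * 0.4)  # 173.6

    def test_direct_form_equals_ca_cbf_oef(self):
        """The published CMRO2 equation is algebraically Ca·CBF·OEF."""
        rng = np.random.default_rng(5)
        r2s = QuantMap(rng.uniform(15, 30, (3, 3, 3)), SPACING, Quantity.R2STAR)
        r2 = QuantMap(rng.uniform(8, 14, (3, 3, 3)), SPACING, Quantity.R2)
        cbv = QuantMap(rng.uniform(0.01, 0.08, (3, 3, 3)), SPACING, Quantity.CBV)
        cbf = QuantMap(rng.uniform(20, 80, (3, 3, 3)), SPACING, Quantity.CBF)
        oef = compute_oef(r2s, r2, cbv)
        via_oef = compute_cmro2(oef, cbf)
        direct = (C.ca * cbf.values / (C.susceptibility_factor * cbv.values)
                  * (r2s.values - r2.values))
        assert np.allclose(via_oef.values, direct, rtol=1e-14)


class TestTensions:
    def test_full_extraction_reaches_p50(self):
        capi = compute_capipo2(qmap(1.0, Quantity.OEF))
        assert capi.values == pytest.approx(27.0)

    def test_half_extraction_scalar_value(self):
        capi = compute_capipo2(qmap(0.5, Quantity.OEF))
        assert capi.values == pytest.approx(27.0 * 3.0 ** (1.0 / 2.7), rel=1e-12)
        assert capi.values == pytest.approx(40.56, abs=0.01)

    def test_strictly_decreasing_in_oef(self):
        oefs = np.linspace(0.05, 1.0, 50)
        vals = [float(compute_capipo2(qmap(o, Quantity.OEF)).values[0, 0, 0])
                for o in oefs]
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_oef_invalidated(self):
        capi = compute_capipo2(qmap(0.0, Quantity.OEF))
        assert not capi.valid.any()

    def test_mitopo2_equals_capipo2_at_zero_cmro2(self):
        mito = compute_mitopo2(qmap(40.0, Quantity.CAPIPO2),
                               qmap(0.0, Quantity.CMRO2))
        assert mito.values == pytest.approx(40.0)

    def test_mitopo2_scalar_value(self):
        mito = compute_mitopo2(qmap(40.55, Quantity.CAPIPO2),
                               qmap(100.0, Quantity.CMRO2))
        assert mito.values == pytest.approx(40.55 - 100.0 / 4.4, abs=1e-9)
        assert mito.values == pytest.approx(17.82, abs=0.01)

    def test_mitopo2_linear_in_cmro2(self):
        base = compute_mitopo2(qmap(50.0, Quantity.CAPIPO2),
                               qmap(100.0, Quantity.CMRO2))
        shifted = compute_mitopo2(qmap(50.0, Quantity.CAPIPO2),
                                  qmap(144.0, Quantity.CMRO2))
        assert (base.values - shifted.values) == pytest.approx(44.0 / 4.4)


class TestPhysiologicalRange:
    def test_all_inside_unchanged(self):
        m = qmap(50.0, Quantity.CMRO2)
        out, removed = apply_physiological_range(m, DEFAULT_RANGES[Quantity.CMRO2])
        assert removed == 0
        assert np.array_equal(out.values, m.values)
        assert out.valid.all()

    def test_oef_percent_thresholding(self):
        vals = np.array([-5.0, 50.0, 120.0]).reshape(3, 1, 1)
        m = QuantMap(vals, SPACING, Quantity.OEF, units="percent")
        out, removed = apply_physiological_range(m, DEFAULT_RANGES[Quantity.OEF])
        assert removed == 2
        assert list(out.valid[:, 0, 0]) == [False, True, False]
        # surviving value untouched
        assert out.values[1, 0, 0] == 50.0

    def test_closed_interval_retains_boundary(self):
        m = qmap(1000.0, Quantity.CMRO2)
        out, removed = apply_physiological_range(m, DEFAULT_RANGES[Quantity.CMRO2])
        assert removed == 0 and out.valid.all()

    def test_quantity_mismatch_rejected(self):
        with pytest.raises(ValueError, match="range for"):
            apply_physiological_range(qmap(1.0, Quantity.CBF),
                                      DEFAULT_RANGES[Quantity.CMRO2])


def test_oef_percent_conversion():
    pct = oef_as_percent(qmap(0.42, Quantity.OEF))
    assert pct.values == pytest.approx(42.0)
    assert pct.units == "percent"


def test_default_ranges_yield_67_bins():
    for prange in DEFAULT_RANGES.values():
        assert prange.n_bins == 67
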