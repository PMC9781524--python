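"""Discretization, shape and first-order features, full extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import voi_from_labels
from oxyradiomics.constants import DEFAULT_RANGES
from oxyradiomics.maps import QuantMap, Quantity
from oxyradiomics.radiomics import (DiscretizationSpec, FeatureCatalog,
                                    default_spec_for, discretize, extract_all,
                                    extract_map, firstorder_features,
                                    shape_features)
from oxyradiomics.radiomics.catalog import FAMILY_COUNTS, TOTAL_FEATURES

SPACING = (1.0, 1.0, 1.0)
CMRO2_SPEC = DiscretizationSpec(0.0, 1000.0, 15.0)


class TestDiscretize:
    def test_cmro2_spec_has_67_bins(self):
        assert CMRO2_SPEC.n_bins == 67

    def test_edge_rule(self):
        vals = np.array([14.999, 15.0, 1000.0, 0.0]).reshape(4, 1, 1)
        m = QuantMap(vals, SPACING, Quantity.CMRO2)
        voi = discretize(m, np.ones((4, 1, 1), bool), CMRO2_SPEC)
        assert list(voi.voi_labels) == [1, 2, 67, 1]

    def test_constant_map_single_bin(self):
        m = QuantMap(np.full((3, 3, 3), 500.0), SPACING, Quantity.CMRO2)
        voi = discretize(m, np.ones((3, 3, 3), bool), CMRO2_SPEC)
        assert len(np.unique(voi.voi_labels)) == 1

    def test_invalid_voxels_excluded(self):
        m = QuantMap(np.full((2, 2, 2), 100.0), SPACING, Quantity.CMRO2)
        m.valid[0, 0, 0] = False
        voi = discretize(m, np.ones((2, 2, 2), bool), CMRO2_SPEC)
        assert voi.n_voxels == 7

    def test_empty_voi_rejected(self):
        m = QuantMap(np.full((2, 2, 2), 100.0), SPACING, Quantity.CMRO2)
        with pytest.raises(ValueError, match="empty"):
            discretize(m, np.zeros((2, 2, 2), bool), CMRO2_SPEC)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1000.0,
                     allow_nan=False, allow_infinity=False))
    def test_labels_always_in_range(self, value):
        m = QuantMap(np.full((1, 1, 1), value), SPACING, Quantity.CMRO2)
        voi = discretize(m, np.ones((1, 1, 1), bool), CMRO2_SPEC)
        assert 1 <= voi.voi_labels[0] <= 67


class TestShape:
    def test_cube_voxel_volume(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        feats = shape_features(mask, SPACING)
        assert feats["Voxel Volume"] == pytest.approx(1000.0)

    def test_cube_max_3d_diameter(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        feats = shape_features(mask, SPACING)
        assert feats["Maximum 3D Diameter"] == pytest.approx(np.sqrt(3) * 9.0)

    def test_cube_2d_diameters(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        feats = shape_features(mask, SPACING)
        for key in ("Maximum 2D Diameter Slice", "Maximum 2D Diameter Row",
                    "Maximum 2D Diameter Column"):
            assert feats[key] == pytest.approx(np.sqrt(2) * 9.0)

    def test_sphere_sphericity_near_one(self):
        n = 41
        g = np.indices((n, n, n)).astype(float) - (n - 1) / 2
        mask = np.sqrt((g ** 2).sum(axis=0)) <= 15.0
        feats = shape_features(mask, SPACING)
        assert feats["Sphericity"] == pytest.approx(1.0, abs=0.05)
        analytic_v = 4.0 / 3.0 * np.pi * 15.0 ** 3
        assert feats["Mesh Volume"] == pytest.approx(analytic_v, rel=0.05)

    def test_axis_permutation_invariance(self):
        from scipy import ndimage
        rng = np.random.default_rng(3)
        field = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2.5)
        mask = field > np.percentile(field, 75)
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
        a = shape_features(mask, SPACING)
        b = shape_features(np.transpose(mask, (2, 0, 1)), SPACING)
        # PCA and point-set features are exactly symmetric; mesh quantities
        # only up to the (orientation-dependent) triangulation of the
        # iso-surface
        for key in ("Voxel Volume", "Major Axis Length", "Elongation",
                    "Flatness", "Maximum 3D Diameter"):
            assert a[key] == pytest.approx(b[key], rel=1e-9)
        for key in ("Mesh Volume", "Surface Area"):
            assert a[key] == pytest.approx(b[key], rel=1e-2)

    def test_single_voxel_fallbacks(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        feats = shape_features(mask, SPACING)
        assert feats["Elongation"] == 1.0 and feats["Flatness"] == 1.0
        assert feats["Maximum 3D Diameter"] == 0.0
        assert feats["Voxel Volume"] == 1.0


class TestFirstOrder:
    def test_constant_voi_degenerate_values(self):
        voi = voi_from_labels(np.full((3, 3, 3), 5, dtype=int), n_bins=67)
        feats = firstorder_features(voi)
        assert feats["Variance"] == 0.0
        assert feats["Entropy"] == 0.0
        assert feats["Uniformity"] == 1.0
        assert feats["Skewness"] == 0.0
        assert feats["Kurtosis"] == 3.0

    def test_hand_arithmetic_small_voi(self):
        voi = voi_from_labels(np.array([1, 2, 3, 4]).reshape(4, 1, 1), n_bins=4)
        feats = firstorder_features(voi)
        assert feats["Mean"] == pytest.approx(2.5)
        assert feats["Energy"] == pytest.approx(30.0)
        assert feats["Root Mean Squared"] == pytest.approx(np.sqrt(7.5))
        assert feats["Range"] == 3.0
        assert feats["Median"] == 2.5

    def test_total_energy_identity(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 9, size=(4, 4, 4))
        voi = voi_from_labels(labels, spacing=(2.0, 1.5, 1.0))
        feats = firstorder_features(voi)
        assert feats["Total Energy"] == pytest.approx(3.0 * feats["Energy"])

    def test_voxel_order_invariance(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(1, 7, size=(3, 3, 3))
        voi_a = voi_from_labels(labels)
        voi_b = voi_from_labels(np.transpose(labels, (1, 2, 0)))
        fa, fb = firstorder_features(voi_a), firstorder_features(voi_b)
        for key in fa:
            assert fa[key] == pytest.approx(fb[key], rel=1e-12)


class TestExtractAll:
    def _small_case(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((12, 12, 12), bool)
        mask[2:10, 2:10, 2:10] = True
        vals = np.where(mask, rng.uniform(50, 400, (12, 12, 12)), 0.0)
        return QuantMap(vals, SPACING, Quantity.CMRO2), mask

    def test_full_inventory_107_finite(self):
        m, mask = self._small_case()
        vec = extract_map(m, mask)
        assert len(vec) == TOTAL_FEATURES == 107
        assert vec.is_finite()

    def test_family_counts(self):
        assert FAMILY_COUNTS == {"shape": 14, "firstorder": 18, "glcm": 24,
                                 "gldm": 14, "glrlm": 16, "glszm": 16,
                                 "ngtdm": 5}

    def test_four_maps_concatenate_to_428(self):
        m, mask = self._small_case()
        maps = {name: m for name in ("OEF", "CMRO2", "capiPO2", "mitoPO2")}
        specs = {name: default_spec_for(Quantity.CMRO2) for name in maps}
        vecs = extract_all(maps, mask, specs=specs)
        assert sum(len(v) for v in vecs.values()) == 4 * 107

    def test_repeat_extraction_identical(self):
        m, mask = self._small_case()
        a = extract_map(m, mask).to_series()
        b = extract_map(m, mask).to_series()
        assert (a == b).all()

    def test_empty_voi_error_names_case_and_map(self):
        m, mask = self._small_case()
        with pytest.raises(ValueError, match="case_X.*CMRO2|CMRO2.*case_X"):
            extract_map(m, np.zeros_like(mask), case_id="case_X")

    def test_catalog_column_names_ordered(self):
        cat = FeatureCatalog()
        cols = cat.column_names()
        assert len(cols) == 107
        assert cols[0] == "shape/Elongation"
        assert cols[-1] == "ngtdm/Strength"
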