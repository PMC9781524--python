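"""Synthetic cohort generator: geometry, determinism, forward model."""

import numpy as np
import pytest
from scipy import ndimage

from oxyradiomics.maps import Quantity
from oxyradiomics.relaxometry import fit_relaxation_rate
from oxyradiomics.synthetic import (BM_LIKE, GB_LIKE, SyntheticCohortConfig,
                                    generate_cohort, generate_quant_maps,
                                    generate_tumor_mask, synthesize_echo_train)

GRID = (48, 48, 48)
SPACING = (1.0, 1.0, 1.0)


class TestTumorMask:
    def test_sphere_voxel_count_matches_analytic_volume(self):
        # collapsed radius range -> exact sphere of radius 10 mm
        mask = generate_tumor_mask(GRID, SPACING, (10.0, 10.0), seed=3)
        expected = 4.0 / 3.0 * np.pi * 10.0 ** 3
        assert abs(mask.sum() - expected) / expected < 0.05

    def test_collapsed_range_same_count_different_centers(self):
        masks = [generate_tumor_mask(GRID, SPACING, (9.0, 9.0), seed=s)
                 for s in range(6)]
        counts = {int(m.sum()) for m in masks}
        assert len(counts) == 1          # exact sphere: seed-independent size
        centers = {tuple(np.argwhere(m).mean(axis=0).round(6)) for m in masks}
        assert len(centers) > 1          # placement still randomizes

    def test_seeded_reproducibility(self):
        m1 = generate_tumor_mask(GRID, SPACING, (8.0, 14.0), seed=5)
        m2 = generate_tumor_mask(GRID, SPACING, (8.0, 14.0), seed=5)
        assert np.array_equal(m1, m2)

    def test_single_connected_component_inside_grid(self):
        mask = generate_tumor_mask(GRID, SPACING, (8.0, 14.0), seed=9)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
        assert n == 1
        assert mask.sum() >= 200
        assert not mask[0].any() and not mask[-1].any()

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            generate_tumor_mask((10, 10, 10), SPACING, (8.0, 14.0), seed=0)


class TestQuantMaps:
    def test_fixed_seed_bit_identical(self):
        cfg = SyntheticCohortConfig()
        mask = generate_tumor_mask(GRID, SPACING, (8.0, 12.0), seed=0)
        a = generate_quant_maps(mask, GB_LIKE, cfg, seed=7)
        b = generate_quant_maps(mask, GB_LIKE, cfg, seed=7)
        for key in a:
            assert np.array_equal(a[key].values, b[key].values)

    def test_physiological_plausibility(self):
        cfg = SyntheticCohortConfig()
        mask = generate_tumor_mask(GRID, SPACING, (8.0, 12.0), seed=1)
        maps = generate_quant_maps(mask, BM_LIKE, cfg, seed=2)
        r2s, r2 = maps["R2STAR"].values[mask], maps["R2"].values[mask]
        cbv, cbf = maps["CBV"].values[mask], maps["CBF"].values[mask]
        assert np.all(r2s > r2) and np.all(r2 > 0)
        assert np.all((cbv > 0) & (cbv < 0.2))
        assert np.all(cbf > 0)

    def test_empty_mask_rejected(self):
        cfg = SyntheticCohortConfig()
        with pytest.raises(ValueError, match="empty"):
            generate_quant_maps(np.zeros(GRID, bool), GB_LIKE, cfg, seed=0)

    def test_mean_matching_across_replicate_cohorts(self):
        """Per-case mean CMRO2 and mitoPO2 carry no class signal: the
        two-sample t-test is non-significant in >= 90% of replicates."""
        from scipy import stats
        from oxyradiomics import qbold
        non_sig_cmro2 = non_sig_mito = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = SyntheticCohortConfig(n_class_a=50, n_class_b=50, seed=100 + rep)
            means_c = {GB_LIKE: [], BM_LIKE: []}
            means_m = {GB_LIKE: [], BM_LIKE: []}
            for case in generate_cohort(cfg):
                oxy = qbold.compute_oxygen_maps(
                    case.maps["R2STAR"], case.maps["R2"],
                    case.maps["CBV"], case.maps["CBF"])
                means_c[case.class_label].append(
                    oxy.cmro2.valid_values(case.mask).mean())
                means_m[case.class_label].append(
                    oxy.mitopo2.valid_values(case.mask).mean())
            _, p_c = stats.ttest_ind(means_c[GB_LIKE], means_c[BM_LIKE])
            _, p_m = stats.ttest_ind(means_m[GB_LIKE], means_m[BM_LIKE])
            non_sig_cmro2 += p_c > 0.05
            non_sig_mito += p_m > 0.05
        assert non_sig_cmro2 >= 0.9 * n_rep
        assert non_sig_mito >= 0.9 * n_rep

    def test_texture_separates_classes_with_large_effect(self):
        """A first-order-free texture statistic (GLCM Contrast of CMRO2)
        differs between classes with |Cohen's d| > 1 at default settings."""
        from oxyradiomics import qbold
        from oxyradiomics.radiomics import default_spec_for, discretize
        from oxyradiomics.radiomics.texture import glcm_features
        cfg = SyntheticCohortConfig(n_class_a=15, n_class_b=15, seed=42)
        vals = {GB_LIKE: [], BM_LIKE: []}
        for case in generate_cohort(cfg):
            oxy = qbold.compute_oxygen_maps(
                case.maps["R2STAR"], case.maps["R2"],
                case.maps["CBV"], case.maps["CBF"])
            voi = discretize(oxy.cmro2, case.mask,
                             default_spec_for(Quantity.CMRO2))
            vals[case.class_label].append(glcm_features(voi)["Contrast"])
        a, b = np.asarray(vals[GB_LIKE]), np.asarray(vals[BM_LIKE])
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        d = (a.mean() - b.mean()) / pooled
        assert abs(d) > 1.0


class TestEchoTrain:
    def test_noiseless_magnitudes_exact(self):
        from oxyradiomics.maps import QuantMap
        r = QuantMap(np.full((2, 2, 2), 20.0), SPACING, Quantity.R2STAR)
        train = synthesize_echo_train(r, 1000.0, np.array([5e-3, 10e-3, 20e-3]),
                                      noise_sd=0.0, seed=0)
        expected = 1000.0 * np.exp(-20.0 * np.array([5e-3, 10e-3, 20e-3]))
        for k in range(3):
            assert train.magnitudes[k] == pytest.approx(expected[k])

    def test_zero_rate_constant_signal(self):
        from oxyradiomics.maps import QuantMap
        r = QuantMap(np.zeros((2, 2, 2)), SPACING, Quantity.R2)
        train = synthesize_echo_train(r, 500.0, np.array([0.01, 0.02, 0.03]),
                                      noise_sd=0.0, seed=0)
        assert np.all(train.magnitudes == 500.0)

    def test_roundtrip_with_relaxometry_is_exact(self):
        from oxyradiomics.maps import QuantMap
        rng = np.random.default_rng(0)
        truth = rng.uniform(10, 40, size=(4, 4, 4))
        r = QuantMap(truth, SPACING, Quantity.R2STAR)
        train = synthesize_echo_train(r, 1000.0,
                                      np.array([5, 15, 25, 35, 45]) * 1e-3,
                                      noise_sd=0.0, seed=0)
        fitted = fit_relaxation_rate(train, spacing=SPACING)
        assert np.max(np.abs(fitted.values - truth) / truth) < 1e-9

    def test_non_ascending_echoes_rejected(self):
        from oxyradiomics.maps import QuantMap
        r = QuantMap(np.ones((2, 2, 2)), SPACING, Quantity.R2)
        with pytest.raises(ValueError, match="increasing"):
            synthesize_echo_train(r, 1.0, np.array([0.01, 0.01, 0.02]),
                                  noise_sd=0.0, seed=0)


def test_cohort_is_seed_deterministic_and_labelled():
    cfg = SyntheticCohortConfig(n_class_a=3, n_class_b=2, seed=4)
    cases_a = list(generate_cohort(cfg))
    cases_b = list(generate_cohort(cfg))
    assert [c.class_label for c in cases_a] == [GB_LIKE] * 3 + [BM_LIKE] * 2
    for ca, cb in zip(cases_a, cases_b):
        assert np.array_equal(ca.mask, cb.mask)
        assert np.array_equal(ca.maps["CBF"].values, cb.maps["CBF"].values)


def test_cohort_roundtrip_via_nifti(tmp_path):
    from oxyradiomics.maps import Quantity, load_map, load_mask
    from oxyradiomics.synthetic import write_cohort
    cfg = SyntheticCohortConfig(n_class_a=1, n_class_b=1, seed=8)
    manifest = write_cohort(cfg, tmp_path)
    assert len(manifest) == 2
    case = next(generate_cohort(cfg))
    mask, _ = load_mask(tmp_path / "case_000" / "mask.nii.gz")
    cbf = load_map(tmp_path / "case_000" / "cbf.nii.gz", Quantity.CBF)
    assert np.array_equal(mask, case.mask)
    assert np.allclose(cbf.values, case.maps["CBF"].values)
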