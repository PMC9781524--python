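"""Synthetic tumor cohort generator.

Emulates a two-class cohort (96 glioblastoma-like vs 37 metastasis-like
cases) of quantitative input maps (R2*, R2, CBV, CBF) on a common voxel
grid, with a key property of the clinical problem built in: the two classes
have per-case in-mask *means* drawn from the same distributions (so mean or
median comparisons carry no class signal), while their *intratumoral spatial
texture* differs.  Classes are distinguished only through the spatial
correlation length of the fields that drive CMRO2 (the R2*−R2 difference and
CBF); the texture amplitude (contrast) is shared, which keeps the marginal
voxel-value distribution — and hence the per-case mean of any nonlinear
derived map — class-independent by construction.

Texture model: Gaussian random fields obtained by smoothing white noise with
a class-specific Gaussian kernel, standardized over the tumor mask and
rescaled to a per-case target mean and SD.  All randomness flows through one
seeded :class:`numpy.random.Generator` per case; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .maps import QuantMap, Quantity, save_map, save_mask, save_echo_train

GB_LIKE = "GB"
BM_LIKE = "BM"


@dataclass
class EchoTrain:
    """Multi-echo magnitude volumes with their echo times (seconds)."""

    echo_times: np.ndarray
    magnitudes: np.ndarray          # (n_echo, nx, ny, nz), non-negative
    sequence_kind: str = "gradient-echo"

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=np.float64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.echo_times.ndim != 1 or self.echo_times.size < 3:
            raise ValueError("need at least 3 echo times")
        if not np.all(np.diff(self.echo_times) > 0):
            raise ValueError("echo_times must be strictly increasing")
        if self.magnitudes.shape[0] != self.echo_times.size:
            raise ValueError("one magnitude volume per echo required")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.sequence_kind not in ("gradient-echo", "spin-echo"):
            raise ValueError("sequence_kind must be gradient-echo or spin-echo")


@dataclass
class SyntheticCohortConfig:
    """Study conditions of the synthetic cohort.

    Class sizes default to the clinical cohort (96 glioblastoma, 37 brain
    metastasis).  Classes share every per-case mean distribution and texture
    contrast; they differ only in ``texture_correlation_length``.
    """

    n_class_a: int = 96                     # GB-like cases
    n_class_b: int = 37                     # BM-like cases
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range: tuple[float, float] = (8.0, 14.0)     # mm
    #: spatial correlation length (mm) of the CMRO2-driving fields per class
    texture_correlation_length: dict[str, float] = field(
        default_factory=lambda: {GB_LIKE: 1.5, BM_LIKE: 3.5})
    #: relative in-mask SD of the CMRO2-driving fields per class (shared by
    #: default so marginal value distributions are class-identical)
    texture_contrast: dict[str, float] = field(
        default_factory=lambda: {GB_LIKE: 0.35, BM_LIKE: 0.35})
    #: per-case mean targets (mean, between-case SD) for each generated input
    global_mean_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "R2": (12.0, 1.0),          # 1/s
            "DELTA_R2": (4.5, 0.7),     # R2* - R2, 1/s
            "CBV": (0.04, 0.004),       # fraction
            "CBF": (40.0, 5.0),         # mL/100g/min
        })
    #: additive white measurement noise SD per output quantity
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "R2STAR": 0.3, "R2": 0.15, "CBV": 0.001, "CBF": 1.0})
    #: correlation length / contrast of the shared (class-independent) fields
    background_correlation_length: float = 2.5   # mm, R2 base and CBV
    background_contrast: float = 0.15
    mask_perturbation: float = 0.05              # radial irregularity scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class_a < 1 or self.n_class_b < 1:
            raise ValueError("class sizes must be >= 1")
        if any(v <= 0 for v in self.texture_correlation_length.values()):
            raise ValueError("correlation lengths must be > 0")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise ValueError("tumor_radius_range must satisfy 0 < lo <= hi")
        for n, sp in zip(self.grid_shape, self.voxel_spacing):
            # same integer margin the mask generator uses
            if n - 2 * int(np.ceil(1.25 * hi / sp)) < 1:
                raise ValueError(
                    f"grid extent {n * sp} mm too small for max tumor radius {hi} mm")


@dataclass
class CohortCase:
    """One synthetic case: mask plus the four quantitative input maps."""

    case_id: str
    class_label: str
    seed: int
    mask: np.ndarray
    maps: dict[str, QuantMap]      # keys: R2STAR, R2, CBV, CBF


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_tumor_mask(grid_shape: tuple[int, int, int],
                        spacing: tuple[float, float, float],
                        radius_range: tuple[float, float],
                        seed: int | np.random.Generator,
                        perturbation: float = 0.05) -> np.ndarray:
    """Generate a single connected, randomly perturbed ellipsoidal mask.

    The ellipsoid has semi-axes drawn uniformly from ``radius_range`` (mm), a
    random rotation, and a smooth radial perturbation whose amplitude scales
    with the width of ``radius_range`` (a collapsed range gives an exact
    sphere, so the voxel count is independent of the seed).  The center is
    placed on a voxel center so that the mask lies entirely inside the grid.
    """
    rng = _as_rng(seed)
    lo, hi = radius_range
    margin_mm = 1.25 * hi
    margins = [int(np.ceil(margin_mm / sp)) for sp in spacing]
    for n, m in zip(grid_shape, margins):
        if n - 2 * m < 1:
            raise ValueError("grid too small for requested tumor radius range: "
                             f"axis of {n} voxels needs > {2 * m}")

    semi_axes = rng.uniform(lo, hi, size=3)
    # random rotation via QR of a Gaussian matrix; a sphere (collapsed
    # radius range) is rotation-invariant, so use the identity there to keep
    # boundary lattice points free of float-rotation noise
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.ptp(semi_axes) == 0:
        q = np.eye(3)
    center = np.array([rng.integers(m, n - m) for n, m in zip(grid_shape, margins)],
                      dtype=float)

    coords = np.stack(np.meshgrid(*[np.arange(n, dtype=float) * sp
                                    for n, sp in zip(grid_shape, spacing)],
                                  indexing="ij"))
    delta = coords - (center * np.asarray(spacing))[:, None, None, None]
    local = np.einsum("ij,jxyz->ixyz", q.T, delta)
    rho = np.sqrt(np.sum((local / semi_axes[:, None, None, None]) ** 2, axis=0))

    amp = perturbation * (hi - lo) / max(lo, 1e-9)
    if amp > 0:
        noise = rng.normal(size=grid_shape)
        smooth = ndimage.gaussian_filter(noise, sigma=3.0)
        sd = smooth.std()
        eps = np.clip(smooth / sd * amp, -3 * amp, 3 * amp) if sd > 0 else 0.0
    else:
        eps = 0.0
    mask = rho <= 1.0 + eps

    # enforce a clean interior and a single connected component
    mask[0, :, :] = mask[-1, :, :] = False
    mask[:, 0, :] = mask[:, -1, :] = False
    mask[:, :, 0] = mask[:, :, -1] = False
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n_comp == 0:
        raise ValueError("degenerate mask: no voxels inside the ellipsoid")
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if mask.sum() < 200:
        raise ValueError(f"mask too small ({int(mask.sum())} voxels < 200); "
                         "increase tumor_radius_range or grid resolution")
    return mask


def _textured_field(grid_shape: tuple[int, int, int],
                    spacing: tuple[float, float, float],
                    corr_length_mm: float,
                    mean: float, sd: float,
                    mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field rescaled to in-mask mean/SD (mean, sd)."""
    noise = rng.normal(size=grid_shape)
    sigma_vox = [corr_length_mm / sp for sp in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    inside = smooth[mask]
    mu, s = inside.mean(), inside.std()
    if s == 0 or sd == 0:
        return np.full(grid_shape, mean, dtype=np.float64)
    return mean + (smooth - mu) / s * sd


def generate_quant_maps(mask: np.ndarray,
                        class_label: str,
                        config: SyntheticCohortConfig,
                        seed: int | np.random.Generator) -> dict[str, QuantMap]:
    """Generate {R2STAR, R2, CBV, CBF} maps for one case.

    Per-case in-mask target means are drawn from the same distributions for
    both classes; only the correlation length of the R2*−R2 and CBF fields is
    class-specific.  CBV and the R2 baseline use shared texture parameters.
    """
    if not np.any(mask):
        raise ValueError("empty tumor mask")
    if class_label not in (GB_LIKE, BM_LIKE):
        raise ValueError(f"class_label must be {GB_LIKE!r} or {BM_LIKE!r}")
    rng = _as_rng(seed)
    shape, spacing = mask.shape, config.voxel_spacing
    corr = config.texture_correlation_length[class_label]
    contrast = config.texture_contrast[class_label]
    tgt = config.global_mean_targets

    def case_mean(key: str) -> float:
        m, s = tgt[key]
        return float(rng.normal(m, s))

    mean_r2 = max(case_mean("R2"), 2.0)
    mean_dr2 = max(case_mean("DELTA_R2"), 0.5)
    mean_cbv = float(np.clip(case_mean("CBV"), 0.01, 0.15))
    mean_cbf = max(case_mean("CBF"), 5.0)

    bg_corr = config.background_correlation_length
    bg_con = config.background_contrast
    r2 = _textured_field(shape, spacing, bg_corr, mean_r2, bg_con * mean_r2, mask, rng)
    dr2 = _textured_field(shape, spacing, corr, mean_dr2, contrast * mean_dr2, mask, rng)
    cbv = _textured_field(shape, spacing, bg_corr, mean_cbv, bg_con * mean_cbv, mask, rng)
    cbf = _textured_field(shape, spacing, corr, mean_cbf, contrast * mean_cbf, mask, rng)

    nsd = config.noise_sd
    r2 = r2 + rng.normal(0, nsd.get("R2", 0.0), shape)
    dr2_noise = rng.normal(0, nsd.get("R2STAR", 0.0), shape)
    cbv = cbv + rng.normal(0, nsd.get("CBV", 0.0), shape)
    cbf = cbf + rng.normal(0, nsd.get("CBF", 0.0), shape)

    r2 = np.clip(r2, 1.0, None)
    dr2 = np.clip(dr2 + dr2_noise, 0.2, None)   # keeps R2* > R2
    r2s = r2 + dr2
    cbv = np.clip(cbv, 0.005, 0.19)
    cbf = np.clip(cbf, 1.0, None)

    return {
        "R2STAR": QuantMap(r2s, spacing, Quantity.R2STAR),
        "R2": QuantMap(r2, spacing, Quantity.R2),
        "CBV": QuantMap(cbv, spacing, Quantity.CBV),
        "CBF": QuantMap(cbf, spacing, Quantity.CBF),
    }


def synthesize_echo_train(r2_map: QuantMap,
                          s0_map: QuantMap | float,
                          echo_times: np.ndarray,
                          noise_sd: float,
                          seed: int | np.random.Generator,
                          sequence_kind: str = "gradient-echo") -> EchoTrain:
    """Forward mono-exponential decay: S(TE) = S0·exp(−R·TE) + noise, ≥ 0."""
    echo_times = np.asarray(echo_times, dtype=np.float64)
    if echo_times.size < 3:
        raise ValueError("need at least 3 echoes")
    if not np.all(np.diff(echo_times) > 0):
        raise ValueError("echo_times must be strictly increasing")
    rng = _as_rng(seed)
    s0 = s0_map.values if isinstance(s0_map, QuantMap) else np.full(
        r2_map.shape, float(s0_map))
    rate = r2_map.values
    mags = s0[None] * np.exp(-rate[None] * echo_times[:, None, None, None])
    if noise_sd > 0:
        mags = mags + rng.normal(0, noise_sd, mags.shape)
    return EchoTrain(echo_times=echo_times, magnitudes=np.clip(mags, 0, None),
                     sequence_kind=sequence_kind)


def generate_cohort(config: SyntheticCohortConfig) -> Iterator[CohortCase]:
    """Yield the full seeded cohort (class A cases first, then class B).

    Each case gets an independent child seed derived from ``config.seed`` via
    :class:`numpy.random.SeedSequence`, so the cohort is bit-reproducible and
    individual cases can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_class_a + config.n_class_b
    children = ss.spawn(n_total)
    labels = [GB_LIKE] * config.n_class_a + [BM_LIKE] * config.n_class_b
    for i, (label, child) in enumerate(zip(labels, children)):
        case_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(child)
        mask = generate_tumor_mask(config.grid_shape, config.voxel_spacing,
                                   config.tumor_radius_range, rng,
                                   perturbation=config.mask_perturbation)
        maps = generate_quant_maps(mask, label, config, rng)
        yield CohortCase(case_id=f"case_{i:03d}", class_label=label,
                         seed=case_seed, mask=mask, maps=maps)


def write_cohort(config: SyntheticCohortConfig, out_dir: str | Path,
                 echo_trains: bool = False) -> pd.DataFrame:
    """Write one directory per case (NIfTI volumes) plus a cohort manifest CSV.

    With ``echo_trains=True`` a 4D gradient-echo and spin-echo stack with a
    JSON echo-time sidecar is written per case instead of ready-made rate
    maps being the only record.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    file_names = {"R2STAR": "r2s.nii.gz", "R2": "r2.nii.gz",
                  "CBV": "cbv.nii.gz", "CBF": "cbf.nii.gz"}
    ge_tes = np.array([5, 10, 15, 20, 25, 30, 35, 40]) * 1e-3
    se_tes = np.array([20, 40, 60, 80, 100, 120]) * 1e-3
    for case in generate_cohort(config):
        case_dir = out_dir / case.case_id
        case_dir.mkdir(exist_ok=True)
        save_mask(case.mask, config.voxel_spacing, case_dir / "mask.nii.gz")
        for key, fname in file_names.items():
            save_map(case.maps[key], case_dir / fname)
        if echo_trains:
            rng = np.random.default_rng(case.seed)
            ge = synthesize_echo_train(case.maps["R2STAR"], 1000.0, ge_tes,
                                       noise_sd=2.0, seed=rng)
            se = synthesize_echo_train(case.maps["R2"], 1000.0, se_tes,
                                       noise_sd=2.0, seed=rng,
                                       sequence_kind="spin-echo")
            save_echo_train(ge.magnitudes, ge.echo_times, config.voxel_spacing,
                            case_dir / "ge_echoes.nii.gz")
            save_echo_train(se.magnitudes, se.echo_times, config.voxel_spacing,
                            case_dir / "se_echoes.nii.gz")
        rows.append({"case_id": case.case_id, "class": case.class_label,
                     "seed": case.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
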