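"""qBOLD oxygen-metabolism biomarker mapping.

From co-registered R2*, R2 (1/s), CBV (fraction) and CBF (mL/100 g/min)
maps, four voxelwise biomarkers are derived:

* ``OEF``     — oxygen extraction fraction (dimensionless fraction):
  ``OEF = (R2* − R2) / ((4/3)·π·γ·Δχ·Hct·B0 · CBV)``
* ``CMRO2``   — cerebral metabolic rate of oxygen (µmol/100 g/min), via the
  Fick relation ``CMRO2 = Ca · CBF · OEF``
* ``capiPO2`` — capillary oxygen tension (mmHg) from the inverted Hill
  model: ``capiPO2 = P50 · (2/OEF − 1)^(1/h)`` (reaches P50 at OEF = 1)
* ``mitoPO2`` — mitochondrial oxygen tension (mmHg):
  ``mitoPO2 = capiPO2 − CMRO2 / L``

Physiological-range thresholding *removes* (invalidates) out-of-range
voxels — closed interval, surviving values untouched — rather than clipping
them, because out-of-range values signal imaging artefacts, not saturation.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_RANGES, PhysiologicalRange, QBOLDConstants
from .maps import OxygenMapSet, QuantMap, Quantity, require_same_grid


def compute_oef(r2star: QuantMap, r2: QuantMap, cbv: QuantMap,
                constants: QBOLDConstants = QBOLDConstants()) -> QuantMap:
    """Oxygen extraction fraction map (as a fraction, not percent).

    Voxels with CBV <= 0 or R2* < R2 are marked invalid (the model has no
    physical solution there); validity also requires all three inputs valid.
    """
    require_same_grid(r2star, r2, cbv)
    valid = r2star.valid & r2.valid & cbv.valid
    valid &= (cbv.values > 0) & (r2star.values >= r2.values)
    denom = constants.susceptibility_factor * cbv.values
    oef = np.zeros(r2star.shape)
    np.divide(r2star.values - r2.values, denom, out=oef, where=valid)
    return QuantMap(values=oef, spacing=r2star.spacing, quantity=Quantity.OEF,
                    valid=valid)


def compute_cmro2(oef: QuantMap, cbf: QuantMap,
                  constants: QBOLDConstants = QBOLDConstants()) -> QuantMap:
    """CMRO2 = Ca · CBF · OEF, in µmol/100 g/min (Fick relation)."""
    require_same_grid(oef, cbf)
    valid = oef.valid & cbf.valid & (cbf.values >= 0)
    values = constants.ca * cbf.values * oef.values
    values = np.where(valid, values, 0.0)
    return QuantMap(values=values, spacing=oef.spacing, quantity=Quantity.CMRO2,
                    valid=valid)


def compute_capipo2(oef: QuantMap,
                    constants: QBOLDConstants = QBOLDConstants()) -> QuantMap:
    """Capillary oxygen tension P50·(2/OEF − 1)^(1/h), in mmHg.

    Strictly decreasing in OEF on (0, 1]; equals P50 at OEF = 1.  Voxels
    with OEF <= 0 are invalid (no oxygen extraction, tension undefined).
    """
    valid = oef.valid & (oef.values > 0)
    base = np.ones(oef.shape)
    np.divide(2.0, oef.values, out=base, where=valid)
    base = np.where(valid, base - 1.0, 1.0)
    # OEF slightly above 1 would make the base negative; treat as invalid
    valid &= base >= 0
    values = np.where(valid, np.power(base, 1.0 / constants.hill_h,
                                      where=base >= 0,
                                      out=np.zeros_like(base)), 0.0)
    values = constants.p50 * values
    return QuantMap(values=np.where(valid, values, 0.0), spacing=oef.spacing,
                    quantity=Quantity.CAPIPO2, valid=valid)


def compute_mitopo2(capipo2: QuantMap, cmro2: QuantMap,
                    constants: QBOLDConstants = QBOLDConstants()) -> QuantMap:
    """Mitochondrial oxygen tension capiPO2 − CMRO2/L, in mmHg.

    May be negative before physiological-range masking.
    """
    require_same_grid(capipo2, cmro2)
    valid = capipo2.valid & cmro2.valid
    values = capipo2.values - cmro2.values / constants.conductivity_l
    return QuantMap(values=np.where(valid, values, 0.0), spacing=capipo2.spacing,
                    quantity=Quantity.MITOPO2, valid=valid)


def apply_physiological_range(qmap: QuantMap, prange: PhysiologicalRange
                              ) -> tuple[QuantMap, int]:
    """Invalidate voxels outside [lower, upper] (closed interval).

    Returns the thresholded map and the number of removed (previously valid)
    voxels.  Surviving values are never altered.
    """
    if prange.quantity != qmap.quantity:
        raise ValueError(f"range for {prange.quantity.value} applied to "
                         f"{qmap.quantity.value} map")
    inside = (qmap.values >= prange.lower) & (qmap.values <= prange.upper)
    new_valid = qmap.valid & inside
    removed = int(qmap.valid.sum() - new_valid.sum())
    return qmap.with_values(qmap.values, valid=new_valid), removed


def oef_as_percent(oef: QuantMap) -> QuantMap:
    """Express an OEF fraction map in percent (for the 0–100 feature range)."""
    if oef.quantity != Quantity.OEF:
        raise ValueError("input must be an OEF map")
    return QuantMap(values=oef.values * 100.0, spacing=oef.spacing,
                    quantity=Quantity.OEF, units="percent",
                    valid=oef.valid.copy())


def compute_oxygen_maps(r2star: QuantMap, r2: QuantMap, cbv: QuantMap,
                        cbf: QuantMap,
                        constants: QBOLDConstants = QBOLDConstants(),
                        ranges: dict | None = None,
                        apply_ranges: bool = True) -> OxygenMapSet:
    """Full biomarker set from the four inputs, with OEF in percent and
    (optionally) physiological-range thresholding applied.
    """
    oef = compute_oef(r2star, r2, cbv, constants)
    cmro2 = compute_cmro2(oef, cbf, constants)
    capipo2 = compute_capipo2(oef, constants)
    mitopo2 = compute_mitopo2(capipo2, cmro2, constants)
    oef_pct = oef_as_percent(oef)
    if apply_ranges:
        ranges = DEFAULT_RANGES if ranges is None else ranges
        oef_pct, _ = apply_physiological_range(oef_pct, ranges[Quantity.OEF])
        cmro2, _ = apply_physiological_range(cmro2, ranges[Quantity.CMRO2])
        capipo2, _ = apply_physiological_range(capipo2, ranges[Quantity.CAPIPO2])
        mitopo2, _ = apply_physiological_range(mitopo2, ranges[Quantity.MITOPO2])
    return OxygenMapSet(oef=oef_pct, cmro2=cmro2, capipo2=capipo2,
                        mitopo2=mitopo2)
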