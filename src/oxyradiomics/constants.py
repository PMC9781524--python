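"""Physical constants of the qBOLD oxygen-metabolism model and the
physiological value ranges used for thresholding and discretization.

The defaults are the published values of the static-dephasing qBOLD model at
3 T: gyromagnetic ratio, susceptibility difference between fully oxygenated
and fully deoxygenated hemoglobin, microvascular hematocrit (systemic 0.42
scaled by 0.85 for small vessels), arterial oxygen content, hemoglobin
half-saturation tension P50, Hill coefficient, and the tissue oxygen
conductivity of the Gjedde/Vafaee capillary model.

Unit conventions (documented in docs/methods.md): arterial oxygen content
``ca`` is in µmol O2 per mL blood so that CMRO2 = Ca·CBF·OEF lands in
µmol/100 g/min when CBF is in mL/100 g/min; conductivity ``conductivity_l``
is in µmol/100 g/min/mmHg so that CMRO2/L is a tension in mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .maps import Quantity


@dataclass(frozen=True)
class QBOLDConstants:
    """Constants of the qBOLD biomarker equations (all strictly positive)."""

    gamma: float = 2.67502e8        # nuclear gyromagnetic ratio [rad/s/T]
    delta_chi: float = 0.264e-6     # Hb susceptibility difference [dimensionless]
    hct: float = 0.42 * 0.85        # microvascular hematocrit fraction
    b0: float = 3.0                 # main static field [T]
    ca: float = 8.68                # arterial O2 content [umol/mL]
    p50: float = 27.0               # Hb half-saturation tension [mmHg]
    hill_h: float = 2.7             # Hill coefficient of O2 binding
    conductivity_l: float = 4.4     # tissue O2 conductivity [umol/100g/min/mmHg]

    def __post_init__(self) -> None:
        for name in ("gamma", "delta_chi", "hct", "b0", "ca", "p50", "hill_h",
                     "conductivity_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.hct >= 1:
            raise ValueError("hct must be < 1")

    @property
    def susceptibility_factor(self) -> float:
        """(4/3)·π·γ·Δχ·Hct·B0 — the OEF denominator per unit CBV [1/s]."""
        return (4.0 / 3.0) * math.pi * self.gamma * self.delta_chi * self.hct * self.b0


@dataclass(frozen=True)
class PhysiologicalRange:
    """Closed value interval [lower, upper] with the discretization bin width.

    Values outside the interval are non-physiological (imaging artefacts) and
    are removed, not clipped.  ``n_bins`` is ``ceil((upper-lower)/bin_width)``;
    for all four published ranges this equals 67.
    """

    quantity: Quantity
    lower: float
    upper: float
    bin_width: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")

    @property
    def n_bins(self) -> int:
        return int(math.ceil((self.upper - self.lower) / self.bin_width - 1e-12))


#: Published per-quantity ranges and bin widths.  OEF is expressed in percent
#: (0–100, width 1.5); CMRO2 in µmol/100 g/min (0–1000, width 15); the two
#: oxygen tensions in mmHg (0–200, width 3).  Each yields 67 bins.
DEFAULT_RANGES: dict[Quantity, PhysiologicalRange] = {
    Quantity.OEF: PhysiologicalRange(Quantity.OEF, 0.0, 100.0, 1.5),
    Quantity.CMRO2: PhysiologicalRange(Quantity.CMRO2, 0.0, 1000.0, 15.0),
    Quantity.CAPIPO2: PhysiologicalRange(Quantity.CAPIPO2, 0.0, 200.0, 3.0),
    Quantity.MITOPO2: PhysiologicalRange(Quantity.MITOPO2, 0.0, 200.0, 3.0),
}
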