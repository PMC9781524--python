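"""3D oxygen-metabolomic radiomics: discretization and the 107-feature
inventory (14 shape + 18 first-order + 75 texture) over a tumor VOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..constants import DEFAULT_RANGES
from ..maps import OxygenMapSet, QuantMap, Quantity
from .catalog import (FAMILIES, FAMILY_COUNTS, FEATURE_NAMES, FIRSTORDER,
                      GLCM, GLDM, GLRLM, GLSZM, NGTDM, SHAPE, TOTAL_FEATURES,
                      FeatureCatalog)
from .discretize import DiscretizationSpec, DiscretizedVOI, discretize
from .firstorder import firstorder_features
from .shape import shape_features
from .texture import (gldm_features, glcm_features, glrlm_features,
                      glszm_features, ngtdm_features)

__all__ = [
    "DiscretizationSpec", "DiscretizedVOI", "FeatureCatalog", "FeatureVector",
    "discretize", "shape_features", "firstorder_features", "glcm_features",
    "gldm_features", "glrlm_features", "glszm_features", "ngtdm_features",
    "extract_map", "extract_all", "default_spec_for",
]


@dataclass
class FeatureVector:
    """Ordered (family, feature) -> value mapping for one map's VOI."""

    values: dict[tuple[str, str], float]
    quantity: str = ""
    case_id: str = ""

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self, prefix: str = "") -> pd.Series:
        pre = f"{prefix}/" if prefix else ""
        return pd.Series({f"{pre}{fam}/{name}": v
                          for (fam, name), v in self.values.items()})

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(list(self.values.values()))))


def default_spec_for(quantity: Quantity) -> DiscretizationSpec:
    """Published range/bin-width discretization for a biomarker quantity."""
    return DiscretizationSpec.from_range(DEFAULT_RANGES[quantity])


def extract_map(qmap: QuantMap, mask: np.ndarray,
                spec: DiscretizationSpec | None = None,
                catalog: FeatureCatalog = FeatureCatalog(),
                case_id: str = "") -> FeatureVector:
    """Extract the full ordered feature inventory for one map's tumor VOI.

    Raises ``ValueError`` (naming case and map) if the VOI is empty after
    masking.  The returned vector has exactly one entry per catalog feature
    (107 for the full catalog) and is finite everywhere.
    """
    if spec is None:
        spec = default_spec_for(qmap.quantity)
    try:
        voi = discretize(qmap, mask, spec)
    except ValueError as exc:
        raise ValueError(f"case {case_id or '?'} map {qmap.quantity.value}: {exc}"
                         ) from exc
    per_family: dict[str, dict[str, float]] = {}
    for fam in catalog.families:
        if fam == SHAPE:
            per_family[fam] = shape_features(voi.voi_mask, qmap.spacing)
        elif fam == FIRSTORDER:
            per_family[fam] = firstorder_features(voi)
        elif fam == GLCM:
            per_family[fam] = glcm_features(voi)
        elif fam == GLDM:
            per_family[fam] = gldm_features(voi)
        elif fam == GLRLM:
            per_family[fam] = glrlm_features(voi)
        elif fam == GLSZM:
            per_family[fam] = glszm_features(voi)
        elif fam == NGTDM:
            per_family[fam] = ngtdm_features(voi)
        else:
            raise ValueError(f"unknown feature family {fam!r}")
    values = {(fam, name): float(per_family[fam][name])
              for fam, name in catalog.keys()}
    return FeatureVector(values=values, quantity=qmap.quantity.value,
                         case_id=case_id)


def extract_all(maps: OxygenMapSet | dict[str, QuantMap], mask: np.ndarray,
                specs: dict[str, DiscretizationSpec] | None = None,
                catalog: FeatureCatalog = FeatureCatalog(),
                case_id: str = "") -> dict[str, FeatureVector]:
    """Extract per-map feature vectors for several biomarker maps.

    Returns one :class:`FeatureVector` per map, keyed by map name; for the
    multi-map ("OxyMet") representation concatenate the vectors in key
    order.
    """
    map_dict = maps.as_dict() if isinstance(maps, OxygenMapSet) else maps
    if not map_dict:
        raise ValueError("at least one map required")
    out: dict[str, FeatureVector] = {}
    for name, qmap in map_dict.items():
        spec = (specs or {}).get(name)
        out[name] = extract_map(qmap, mask, spec=spec, catalog=catalog,
                                case_id=case_id)
    return out
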