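"""Canonical 107-feature inventory: family names, feature names, order.

Families and counts: 14 shape, 18 first-order, and 75 texture features split
over five gray-level matrix families (24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM,
5 NGTDM).  Names follow the widely used IBSI-aligned naming of the reference
radiomics literature; feature vectors are always emitted in this order.
"""

from __future__ import annotations

from dataclasses import dataclass

SHAPE = "shape"
FIRSTORDER = "firstorder"
GLCM = "glcm"
GLDM = "gldm"
GLRLM = "glrlm"
GLSZM = "glszm"
NGTDM = "ngtdm"

FAMILIES = (SHAPE, FIRSTORDER, GLCM, GLDM, GLRLM, GLSZM, NGTDM)

FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    SHAPE: (
        "Elongation",
        "Flatness",
        "Least Axis Length",
        "Major Axis Length",
        "Maximum 2D Diameter Column",
        "Maximum 2D Diameter Row",
        "Maximum 2D Diameter Slice",
        "Maximum 3D Diameter",
        "Mesh Volume",
        "Minor Axis Length",
        "Sphericity",
        "Surface Area",
        "Surface Volume Ratio",
        "Voxel Volume",
    ),
    FIRSTORDER: (
        "10th Percentile",
        "90th Percentile",
        "Energy",
        "Entropy",
        "Interquartile Range",
        "Kurtosis",
        "Maximum",
        "Mean Absolute Deviation",
        "Mean",
        "Median",
        "Minimum",
        "Range",
        "Robust Mean Absolute Deviation",
        "Root Mean Squared",
        "Skewness",
        "Total Energy",
        "Uniformity",
        "Variance",
    ),
    GLCM: (
        "Autocorrelation",
        "Cluster Prominence",
        "Cluster Shade",
        "Cluster Tendency",
        "Contrast",
        "Correlation",
        "Difference Average",
        "Difference Entropy",
        "Difference Variance",
        "Id",
        "Idm",
        "Idmn",
        "Idn",
        "Imc1",
        "Imc2",
        "Inverse Variance",
        "Joint Average",
        "Joint Energy",
        "Joint Entropy",
        "MCC",
        "Maximum Probability",
        "Sum Average",
        "Sum Entropy",
        "Sum Squares",
    ),
    GLDM: (
        "Dependence Entropy",
        "Dependence Non-Uniformity",
        "Dependence Non-Uniformity Normalized",
        "Dependence Variance",
        "Gray Level Non-Uniformity",
        "Gray Level Variance",
        "High Gray Level Emphasis",
        "Large Dependence Emphasis",
        "Large Dependence High Gray Level Emphasis",
        "Large Dependence Low Gray Level Emphasis",
        "Low Gray Level Emphasis",
        "Small Dependence Emphasis",
        "Small Dependence High Gray Level Emphasis",
        "Small Dependence Low Gray Level Emphasis",
    ),
    GLRLM: (
        "Gray Level Non-Uniformity",
        "Gray Level Non-Uniformity Normalized",
        "Gray Level Variance",
        "High Gray Level Run Emphasis",
        "Long Run Emphasis",
        "Long Run High Gray Level Emphasis",
        "Long Run Low Gray Level Emphasis",
        "Low Gray Level Run Emphasis",
        "Run Entropy",
        "Run Length Non-Uniformity",
        "Run Length Non-Uniformity Normalized",
        "Run Percentage",
        "Run Variance",
        "Short Run Emphasis",
        "Short Run High Gray Level Emphasis",
        "Short Run Low Gray Level Emphasis",
    ),
    GLSZM: (
        "Gray Level Non-Uniformity",
        "Gray Level Non-Uniformity Normalized",
        "Gray Level Variance",
        "High Gray Level Zone Emphasis",
        "Large Area Emphasis",
        "Large Area High Gray Level Emphasis",
        "Large Area Low Gray Level Emphasis",
        "Low Gray Level Zone Emphasis",
        "Size Zone Non-Uniformity",
        "Size Zone Non-Uniformity Normalized",
        "Small Area Emphasis",
        "Small Area High Gray Level Emphasis",
        "Small Area Low Gray Level Emphasis",
        "Zone Entropy",
        "Zone Percentage",
        "Zone Variance",
    ),
    NGTDM: (
        "Busyness",
        "Coarseness",
        "Complexity",
        "Contrast",
        "Strength",
    ),
}

FAMILY_COUNTS = {fam: len(names) for fam, names in FEATURE_NAMES.items()}
TOTAL_FEATURES = sum(FAMILY_COUNTS.values())       # 107
TEXTURE_FEATURES = sum(FAMILY_COUNTS[f] for f in (GLCM, GLDM, GLRLM, GLSZM, NGTDM))


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered (family, name) pairs defining feature-vector layout."""

    families: tuple[str, ...] = FAMILIES

    def keys(self) -> list[tuple[str, str]]:
        return [(fam, name) for fam in self.families
                for name in FEATURE_NAMES[fam]]

    def column_names(self) -> list[str]:
        """Flat column labels of the form 'family/Feature Name'."""
        return [f"{fam}/{name}" for fam, name in self.keys()]

    def __len__(self) -> int:
        return sum(FAMILY_COUNTS[f] for f in self.families)


def validate_counts() -> None:
    expected = {SHAPE: 14, FIRSTORDER: 18, GLCM: 24, GLDM: 14,
                GLRLM: 16, GLSZM: 16, NGTDM: 5}
    assert FAMILY_COUNTS == expected, FAMILY_COUNTS
    assert TOTAL_FEATURES == 107
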