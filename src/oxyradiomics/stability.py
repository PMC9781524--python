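"""Feature reproducibility across repeated segmentations: ICC filtering.

Each radiomic feature is measured once per segmentation (rater) for every
case; the intraclass correlation coefficient quantifies absolute agreement.
The default form is ICC(2,1) — two-way random effects, absolute agreement,
single measurement — computed from the standard ANOVA mean-squares
decomposition:

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

with n cases, k raters, MS_R the between-case, MS_C the between-rater and
MS_E the residual mean square.  Features with ICC >= 0.8 are retained.

A curated 74-feature list (family counts 3/18/19/9/10/11/4) is bundled so
the stability-filtered pipeline runs without a second-segmentation
experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .radiomics.catalog import FAMILIES, FEATURE_NAMES, FeatureCatalog


def icc(measurements: np.ndarray, form: str = "icc2_1") -> float:
    """Intraclass correlation of a (cases x raters) measurement table.

    Parameters
    ----------
    measurements
        2D array, one row per case, one column per rater; no missing cells.
    form
        ``"icc2_1"`` (two-way random, absolute agreement, single measurement;
        default) or ``"icc3_1"`` (two-way mixed, consistency).

    Returns
    -------
    float
        ICC value in [-1, 1].  Degenerate case: a table with zero total
        variance (all columns identical and constant rows allowed) returns
        1.0, since the raters agree exactly.
    """
    x = np.asarray(measurements, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2D table with >= 2 cases and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("measurements contain non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    if ss_total <= 1e-30 or np.allclose(x, x[:, [0]]):
        return 1.0

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    if form == "icc2_1":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    elif form == "icc3_1":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        return 1.0
    return float((ms_r - ms_e) / denom)


@dataclass
class StabilityReport:
    """Per-feature ICC values and the resulting selection."""

    icc_values: dict[tuple[str, str], float]
    threshold: float = 0.8

    @property
    def selected(self) -> list[tuple[str, str]]:
        return [key for key, v in self.icc_values.items() if v >= self.threshold]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"family": fam, "feature": name, "icc": v,
                 "selected": v >= self.threshold}
                for (fam, name), v in self.icc_values.items()]
        return pd.DataFrame(rows)


def stability_report(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     threshold: float = 0.8,
                     form: str = "icc2_1") -> StabilityReport:
    """ICC per feature from two feature tables of the same cases.

    Tables are wide (case x feature) with identical index and columns named
    ``family/Feature Name``.
    """
    if list(table_a.columns) != list(table_b.columns):
        raise ValueError("feature tables must share identical columns")
    if len(table_a) != len(table_b):
        raise ValueError("feature tables must cover the same cases")
    values: dict[tuple[str, str], float] = {}
    for col in table_a.columns:
        fam, name = col.split("/", 1)
        pair = np.column_stack([table_a[col].to_numpy(),
                                table_b[col].to_numpy()])
        values[(fam, name)] = icc(pair, form=form)
    return StabilityReport(icc_values=values, threshold=threshold)


def load_curated_list() -> list[tuple[str, str]]:
    """The bundled curated 74-feature list, in catalog order."""
    payload = json.loads(resources.files("oxyradiomics.data")
                         .joinpath("curated_features.json").read_text())
    selected = payload["selected"]
    out: list[tuple[str, str]] = []
    for fam in FAMILIES:
        for name in selected.get(fam, []):
            if name not in FEATURE_NAMES[fam]:
                raise ValueError(f"unknown feature {fam}/{name} in curated list")
            out.append((fam, name))
    # preserve catalog order within each family
    ordered = [(fam, name) for fam in FAMILIES for name in FEATURE_NAMES[fam]
               if (fam, name) in set(out)]
    return ordered


def select_features(report: StabilityReport | None = None,
                    curated: bool = False,
                    catalog: FeatureCatalog = FeatureCatalog()
                    ) -> list[tuple[str, str]]:
    """Ordered list of retained features.

    Either from a computed :class:`StabilityReport` (features with
    ICC >= threshold, in catalog order) or, with ``curated=True``, the
    bundled curated list.
    """
    if curated:
        return load_curated_list()
    if report is None:
        raise ValueError("provide a StabilityReport or set curated=True")
    cat_keys = catalog.keys()
    missing = [k for k in cat_keys if k not in report.icc_values]
    if missing:
        raise ValueError(f"stability report does not cover the catalog: "
                         f"missing {missing[:3]}...")
    sel = set(report.selected)
    return [k for k in cat_keys if k in sel]
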