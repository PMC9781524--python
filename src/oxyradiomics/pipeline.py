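"""End-to-end workflow: simulate → map → extract → select → balance/split
→ train → evaluate.

The pipeline reproduces the study design on a synthetic cohort: qBOLD
biomarker maps are derived per case, the tumor VOI is discretized on the
fixed physiological ranges, the 107-feature inventory is extracted for the
chosen biomarker map(s), the curated 74-feature stability selection is
applied, classes are balanced with SMOTE, the cohort is split 70/15/15 with
z-scoring by training statistics, and the 1D-CNN is trained and evaluated
on the held-out test set.

Every stage derives its seed from the single global seed, so a rerun with
the same configuration is bit-identical for the deterministic stages
(including CNN training, which is pure NumPy).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import balancing, cnn, evaluation, qbold
from .balancing import LABEL_COL, PROVENANCE_COL
from .constants import QBOLDConstants
from .radiomics import FeatureCatalog, extract_map
from .stability import load_curated_list
from .synthetic import GB_LIKE, SyntheticCohortConfig, generate_cohort

logger = logging.getLogger("oxyradiomics")

MAP_CHOICES = ("OEF", "CMRO2", "capiPO2", "mitoPO2", "OxyMet")


@dataclass
class PipelineConfig:
    """Complete description of one pipeline run."""

    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    constants: QBOLDConstants = field(default_factory=QBOLDConstants)
    map_selection: str = "CMRO2"          # one biomarker or "OxyMet"
    stability_mode: str = "curated"       # "curated" | "computed" | "none"
    balancing_mode: str = "train-only"    # "train-only" | "paper-faithful"
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    smote_k_neighbors: int = 5
    max_epochs: int = 300
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.map_selection not in MAP_CHOICES:
            raise ValueError(f"map_selection must be one of {MAP_CHOICES}")
        if self.balancing_mode not in ("train-only", "paper-faithful"):
            raise ValueError("balancing_mode must be train-only or paper-faithful")
        if self.stability_mode not in ("curated", "computed", "none"):
            raise ValueError("stability_mode must be curated, computed or none")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True)
                              .encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    report: evaluation.EvalReport
    feature_table: pd.DataFrame
    split: balancing.SplitAssignment
    history: pd.DataFrame
    model: cnn.CNN1D
    mean_map_values: pd.DataFrame       # per-case in-mask means of the maps


def _selected_columns(map_names: list[str], mode: str) -> list[str] | None:
    if mode == "none":
        keys = FeatureCatalog().keys()
    elif mode == "curated":
        keys = load_curated_list()
    else:
        return None                     # computed later from two segmentations
    return [f"{m}/{fam}/{name}" for m in map_names for fam, name in keys]


def build_feature_table(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cohort and extract the per-case feature matrix.

    Returns (feature table with a ``class`` column, per-case mean-map table
    used for the mean/median class comparison).
    """
    map_names = (["OEF", "CMRO2", "capiPO2", "mitoPO2"]
                 if config.map_selection == "OxyMet" else [config.map_selection])
    rows, mean_rows = {}, []
    t0 = time.time()
    for case in generate_cohort(config.cohort):
        oxy = qbold.compute_oxygen_maps(case.maps["R2STAR"], case.maps["R2"],
                                        case.maps["CBV"], case.maps["CBF"],
                                        constants=config.constants)
        all_maps = oxy.as_dict()
        series = []
        for name in map_names:
            vec = extract_map(all_maps[name], case.mask, case_id=case.case_id)
            series.append(vec.to_series(prefix=name))
        row = pd.concat(series)
        row[LABEL_COL] = case.class_label
        rows[case.case_id] = row
        mean_rows.append({
            "case_id": case.case_id, LABEL_COL: case.class_label,
            **{f"mean_{n}": float(np.mean(m.valid_values(case.mask)))
               for n, m in all_maps.items()},
            **{f"median_{n}": float(np.median(m.valid_values(case.mask)))
               for n, m in all_maps.items()},
        })
    table = pd.DataFrame(rows).T
    table[LABEL_COL] = table[LABEL_COL].astype(str)
    feats = [c for c in table.columns if c != LABEL_COL]
    table[feats] = table[feats].astype(np.float64)
    logger.info("feature extraction: %d cases x %d features in %.1f s",
                len(table), len(feats), time.time() - t0)
    return table, pd.DataFrame(mean_rows).set_index("case_id")


def _apply_selection(table: pd.DataFrame, config: PipelineConfig,
                     map_names: list[str]) -> pd.DataFrame:
    cols = _selected_columns(map_names, config.stability_mode)
    if cols is None:
        raise ValueError("computed stability mode requires two segmentations; "
                         "use oxyradiomics.stability.stability_report directly")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"selected features missing from table: {missing[:3]}")
    return table[cols + [LABEL_COL]]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the complete workflow and return the held-out evaluation."""
    t_start = time.time()
    ss = np.random.SeedSequence(config.seed)
    seed_smote, seed_split, seed_train = (int(s.generate_state(1)[0] % (2 ** 31))
                                          for s in ss.spawn(3))
    logger.info("pipeline seed=%d (smote=%d split=%d train=%d) hash=%s",
                config.seed, seed_smote, seed_split, seed_train,
                config.config_hash())

    map_names = (["OEF", "CMRO2", "capiPO2", "mitoPO2"]
                 if config.map_selection == "OxyMet" else [config.map_selection])
    full_table, mean_table = build_feature_table(config)
    table = _apply_selection(full_table, config, map_names)

    if config.balancing_mode == "paper-faithful":
        table = balancing.balance_cohort(table, k_neighbors=config.smote_k_neighbors,
                                         seed=seed_smote)
        split = balancing.partition(table, config.fractions, seed=seed_split)
        parts = {p: table.loc[split.ids(p)] for p in ("train", "validation", "test")}
    else:
        split = balancing.partition(table, config.fractions, seed=seed_split)
        parts = {p: table.loc[split.ids(p)] for p in ("train", "validation", "test")}
        parts["train"] = balancing.balance_cohort(
            parts["train"], k_neighbors=config.smote_k_neighbors, seed=seed_smote)

    feats = balancing.feature_columns(table)
    stats = balancing.fit_zscore(parts["train"])
    norm = {p: balancing.apply_zscore(stats, t) for p, t in parts.items()}
    kept = list(stats.mean.index)

    def xy(part: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return (part[kept].to_numpy(dtype=np.float64),
                (part[LABEL_COL] == GB_LIKE).to_numpy(dtype=np.float64))

    x_train, y_train = xy(norm["train"])
    x_val, y_val = xy(norm["validation"])
    x_test, y_test = xy(norm["test"])

    spec = cnn.CNNSpec(input_length=len(kept))
    tcfg = cnn.TrainingConfig(max_epochs=config.max_epochs, seed=seed_train)
    model, history = cnn.train(x_train, y_train, spec, tcfg,
                               val_features=x_val, val_labels=y_val)
    scores = model.predict_proba(x_test)
    labels = norm["test"][LABEL_COL].to_numpy()
    report = evaluation.evaluate_predictions(labels, scores, positive_class=GB_LIKE)
    logger.info("pipeline done in %.1f s: AUROC=%.3f accuracy=%.3f",
                time.time() - t_start, report.auroc, report.accuracy)

    if config.out_dir is not None:
        _persist(config, full_table, split, history, model, report, tcfg)
    return PipelineResult(report=report, feature_table=full_table, split=split,
                          history=history, model=model, mean_map_values=mean_table)


def _persist(config: PipelineConfig, table: pd.DataFrame,
             split: balancing.SplitAssignment, history: pd.DataFrame,
             model: cnn.CNN1D, report: evaluation.EvalReport,
             tcfg: cnn.TrainingConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    table.to_csv(out / f"features_{h}.csv")
    (out / f"split_{h}.json").write_text(json.dumps(
        {"fractions": split.fractions, "seed": split.seed,
         "assignment": split.assignment}, indent=2))
    history.to_csv(out / f"history_{h}.csv", index=False)
    model.save(out / f"model_{h}.npz", training_config=tcfg)
    evaluation.render_report({config.map_selection: report},
                             csv_path=out / f"report_{h}.csv")
    (out / f"manifest_{h}.json").write_text(json.dumps(
        {"config_hash": h, "seed": config.seed,
         "map_selection": config.map_selection,
         "balancing_mode": config.balancing_mode,
         "metrics": {k: (None if not np.isfinite(v) else v)
                     for k, v in report.metrics().items()}}, indent=2))


def make_fixtures(seed: int = 0) -> dict[str, np.ndarray]:
    """Small (≤ 8³) deterministic label volumes for oracle verification.

    Returns integer gray-level volumes (0 = outside VOI) whose texture
    matrices are small enough to enumerate by hand or brute force.
    """
    rng = np.random.default_rng(seed)
    constant = np.full((4, 4, 4), 3, dtype=np.int64)
    checker = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1
    two_blob = np.zeros((6, 6, 6), dtype=np.int64)
    two_blob[1:3, 1:3, 1:3] = 2
    two_blob[4:6, 4:6, 4:6] = 2
    random_small = rng.integers(1, 5, size=(4, 4, 4))
    line = np.zeros((1, 1, 8), dtype=np.int64) + 5
    return {"constant_cube": constant, "checkerboard": checker.astype(np.int64),
            "two_blobs": two_blob, "random_small": random_small,
            "single_line": line}
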