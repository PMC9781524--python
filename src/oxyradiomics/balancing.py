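"""Class balancing (SMOTE), stratified partitioning, and z-scoring.

SMOTE synthesizes minority-class feature vectors by linear interpolation
between a minority point and one of its k nearest minority neighbors:
``x_new = x + u·(x_nn − x)`` with ``u ~ Uniform(0, 1)``.  Every synthetic
row records its two parent case ids, so colinearity (and the convex-hull
property) is verifiable after the fact.

Two balancing modes are provided.  The methodologically safe default
applies SMOTE to the *training* partition only (no synthetic information
reaches validation/test).  The alternative "paper-faithful" mode balances
the full cohort before splitting — with 96 majority and 37 minority cases
this yields 59 synthetic rows and 192 cases entering the 70/15/15 split.

Partition sizes use largest-remainder rounding per class (train receives
ties); z-scoring uses training-set statistics (sample SD) for all
partitions, dropping zero-variance columns with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

LABEL_COL = "class"
PROVENANCE_COL = "provenance"
PARENTS_COL = "smote_parents"
_META_COLS = (LABEL_COL, PROVENANCE_COL, PARENTS_COL, "partition")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a cohort table (everything except metadata)."""
    return [c for c in table.columns if c not in _META_COLS]


def smote(minority: pd.DataFrame, n_synthetic: int, k_neighbors: int = 5,
          seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate ``n_synthetic`` interpolated minority vectors.

    Parameters
    ----------
    minority
        Feature-only frame (cases x features) indexed by case id.
    n_synthetic
        Number of synthetic rows to produce.
    k_neighbors
        Neighborhood size; must be < number of minority cases.
    seed
        RNG seed or generator.

    Returns
    -------
    DataFrame of synthetic rows indexed ``smote_000...``, with a
    ``smote_parents`` column listing the two parent ids.
    """
    if minority.isnull().to_numpy().any():
        raise ValueError("minority vectors contain missing values")
    n_min = len(minority)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n_min:
        raise ValueError(f"k_neighbors ({k_neighbors}) must be < minority "
                         f"count ({n_min})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = minority.to_numpy(dtype=np.float64)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    # first neighbor is the point itself
    neigh_idx = nn.kneighbors(x, return_distance=False)[:, 1:]

    base = rng.integers(0, n_min, size=n_synthetic)
    pick = rng.integers(0, k_neighbors, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    nn_of_base = neigh_idx[base, pick]
    new_x = x[base] + u[:, None] * (x[nn_of_base] - x[base])

    ids = [f"smote_{i:03d}" for i in range(n_synthetic)]
    out = pd.DataFrame(new_x, columns=minority.columns, index=ids)
    parents = [f"{minority.index[b]}|{minority.index[n]}"
               for b, n in zip(base, nn_of_base)]
    out[PARENTS_COL] = parents
    return out


def balance_cohort(table: pd.DataFrame, k_neighbors: int = 5,
                   seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Oversample the minority class up to the majority count.

    ``table`` must carry a ``class`` column; synthetic rows get
    ``provenance == "smote"``, originals ``"original"``.
    """
    counts = table[LABEL_COL].value_counts()
    if len(counts) != 2:
        raise ValueError("cohort must contain exactly two classes")
    minority_label = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    feats = feature_columns(table)
    out = table.copy()
    if PROVENANCE_COL not in out:
        out[PROVENANCE_COL] = "original"
    if n_needed == 0:
        return out
    minority = table.loc[table[LABEL_COL] == minority_label, feats]
    synth = smote(minority, n_needed, k_neighbors=k_neighbors, seed=seed)
    synth[LABEL_COL] = minority_label
    synth[PROVENANCE_COL] = "smote"
    return pd.concat([out, synth], axis=0)


@dataclass
class SplitAssignment:
    """case id -> partition, with the fractions and seed that produced it."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def ids(self, partition: str) -> list[str]:
        return [cid for cid, p in self.assignment.items() if p == partition]


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer partition sizes by largest remainder; first entry gets ties."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = [r - b for r, b in zip(raw, base)]
    short = n - sum(base)
    # stable order: ties resolved toward earlier partitions (train first)
    order = sorted(range(len(fractions)), key=lambda i: (-rem[i], i))
    for i in order[:short]:
        base[i] += 1
    return base


def _stratified_sizes(class_counts: list[int], fractions: tuple[float, ...]
                      ) -> list[list[int]]:
    """Per-class partition sizes consistent with the *global* largest-
    remainder sizes (controlled rounding).

    Global sizes come first from largest remainder on the full cohort; each
    class then gets the floor of its ideal share, and the remaining slots
    are distributed by descending fractional remainder wherever both the
    class and the partition still have a deficit.
    """
    n_total = sum(class_counts)
    targets = _largest_remainder(n_total, fractions)
    base = [[int(np.floor(c * f)) for f in fractions] for c in class_counts]
    row_deficit = [c - sum(row) for c, row in zip(class_counts, base)]
    col_deficit = [t - sum(base[r][p] for r in range(len(base)))
                   for p, t in enumerate(targets)]
    candidates = sorted(
        ((c * f - np.floor(c * f), r, p)
         for r, c in enumerate(class_counts)
         for p, f in enumerate(fractions)),
        key=lambda t: (-t[0], t[1], t[2]))
    for _, r, p in candidates:
        if row_deficit[r] > 0 and col_deficit[p] > 0:
            base[r][p] += 1
            row_deficit[r] -= 1
            col_deficit[p] -= 1
    for r in range(len(base)):          # defensive: resolve any leftover
        while row_deficit[r] > 0:
            p = int(np.argmax(col_deficit))
            base[r][p] += 1
            row_deficit[r] -= 1
            col_deficit[p] -= 1
    return base


def partition(table: pd.DataFrame,
              fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
              seed: int = 0, stratified: bool = True) -> SplitAssignment:
    """Deterministic stratified train/validation/test assignment.

    Global partition sizes follow largest-remainder rounding of the full
    cohort (192 cases at 70/15/15 gives 134/29/29); stratification then
    preserves class proportions within ±1 case per partition.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    names = ("train", "validation", "test")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    if stratified:
        groups = [grp for _, grp in table.groupby(LABEL_COL, sort=True)]
    else:
        groups = [table]
    sizes_per_group = _stratified_sizes([len(g) for g in groups], fractions)
    totals = [sum(s[p] for s in sizes_per_group) for p in range(len(fractions))]
    if any(f > 0 and t < 1 for f, t in zip(fractions, totals)):
        raise ValueError("a requested partition would receive < 1 case")
    for group, sizes in zip(groups, sizes_per_group):
        ids = np.asarray(group.index, dtype=object)
        rng.shuffle(ids)
        start = 0
        for name, size in zip(names, sizes):
            for cid in ids[start:start + size]:
                assignment[str(cid)] = name
            start += size
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


@dataclass
class ZScoreStats:
    """Training-set mean/SD per feature column (sample SD, ddof=1)."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)


def fit_zscore(train: pd.DataFrame) -> ZScoreStats:
    feats = feature_columns(train)
    mean = train[feats].mean()
    sd = train[feats].std(ddof=1)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): "
                      f"{dropped[:5]}", stacklevel=2)
    kept = [f for f in feats if f not in dropped]
    return ZScoreStats(mean=mean[kept], sd=sd[kept], dropped=dropped)


def apply_zscore(stats: ZScoreStats, table: pd.DataFrame) -> pd.DataFrame:
    """Transform any partition with *training* statistics."""
    out = table.copy()
    kept = list(stats.mean.index)
    out = out.drop(columns=stats.dropped, errors="ignore")
    out[kept] = (out[kept] - stats.mean) / stats.sd
    return out


def zscore(train: pd.DataFrame, *others: pd.DataFrame
           ) -> tuple[pd.DataFrame, ...]:
    """Z-score the training table and co-transform the other partitions."""
    stats = fit_zscore(train)
    return tuple(apply_zscore(stats, t) for t in (train, *others))
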