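"""Starting-cell-number control, inclusion criteria, and cohort statistics.

Every patternoid carries its grid position, starting cell number c0,
c0 class (a +/-10% tolerance band around a configured target), and QC
flags observed at day 0 / day 1 / day 3.  Only defect-free records
with an assigned class enter the analysis; for multi-batch comparisons
the c0-class distributions are matched by deterministic subsampling.
QC flags are data (from the synthetic ground truth or user
annotation), not image computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortError",
    "QC_FLAGS_BY_STAGE",
    "ALL_QC_FLAGS",
    "PatternoidRecord",
    "GrowthResult",
    "classify_c0",
    "apply_inclusion_criteria",
    "pool_matched_c0",
    "growth_rate",
    "compare_groups",
]


class CohortError(ValueError):
    """Invalid cohort configuration or data."""


QC_FLAGS_BY_STAGE = {
    "d0": ("agglomeration_d0", "excess_cells_d0"),
    "d1": ("invasive_at_drug_add_d1",),
    "d3": ("staining_failure_d3", "conjoined_d3", "planar_growth_d3", "collapsed_d3"),
}
ALL_QC_FLAGS = tuple(f for flags in QC_FLAGS_BY_STAGE.values() for f in flags)


@dataclass
class PatternoidRecord:
    """Identity and bookkeeping for one patternoid."""

    id: str
    row: int
    col: int
    c0: int
    c0_class: int | None = None
    qc_flags: set = field(default_factory=set)
    included: bool = False
    final_count: int | None = None
    metrics: object | None = None

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise CohortError("c0 must be >= 0")
        if self.final_count is not None and self.final_count < 0:
            raise CohortError("final_count must be >= 0")
        unknown = set(self.qc_flags) - set(ALL_QC_FLAGS)
        if unknown:
            raise CohortError(f"unknown QC flags: {sorted(unknown)}")
        if self.included and (self.qc_flags or self.c0_class is None):
            raise CohortError("included records must be defect-free with an assigned c0 class")


@dataclass(frozen=True)
class GrowthResult:
    """Exponential growth rate r from c(t) = c0 * exp(r t)."""

    r: float
    c0: int
    c_t: int
    t: float


def classify_c0(count: int, targets, tol: float = 0.10) -> int | None:
    """Assign a count to the unique target class with ``t*(1-tol) <= count <= t*(1+tol)``.

    Boundaries are inclusive after exact multiplication (no rounding):
    with targets {10, 20, 30}, 22 belongs to class 20 and 23 to none.
    Overlapping tolerance bands are a configuration error.
    """
    targets = sorted(int(t) for t in targets)
    if any(t <= 0 for t in targets):
        raise CohortError("targets must be positive")
    for a, b in zip(targets, targets[1:]):
        if a * (1 + tol) >= b * (1 - tol):
            raise CohortError(f"c0 classes {a} and {b} overlap at tolerance {tol}")
    if count < 0:
        raise CohortError("count must be >= 0")
    for t in targets:
        if t * (1 - tol) <= count <= t * (1 + tol):
            return t
    return None


def apply_inclusion_criteria(records: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Drop records carrying any QC flag relevant to the given stage.

    ``records`` is a DataFrame with 0/1 flag columns named as in
    :data:`ALL_QC_FLAGS`; a ``drop_reason_<stage>`` column documents
    each drop in the returned (filtered) copy's attrs.
    """
    if stage not in QC_FLAGS_BY_STAGE:
        raise CohortError(f"unknown stage {stage!r}; expected one of {sorted(QC_FLAGS_BY_STAGE)}")
    flag_cols = [f for f in QC_FLAGS_BY_STAGE[stage] if f in records.columns]
    unknown = [c for c in records.columns if c.endswith(("_d0", "_d1", "_d3")) and c not in ALL_QC_FLAGS]
    if unknown:
        raise CohortError(f"unknown QC flag columns: {unknown}")
    if not flag_cols:
        return records.copy()
    bad = records[flag_cols].astype(bool).any(axis=1)
    reasons = {
        str(records.loc[i, "id"]) if "id" in records.columns else str(i): [
            f for f in flag_cols if bool(records.loc[i, f])
        ]
        for i in records.index[bad]
    }
    kept = records.loc[~bad].copy()
    kept.attrs[f"dropped_{stage}"] = reasons
    return kept


def pool_matched_c0(batches, targets, seed=0):
    """Subsample batches to identical per-class counts (hence proportions).

    The common per-class count is the largest achievable: the minimum
    across batches of that class's count.  Subsampling is random
    without replacement under the seed, preserving within-class order.
    Returns ``(pooled_batches, report)`` where the report lists
    per-batch, per-class counts before and after.
    """
    batches = [b.copy() for b in batches]
    if len(batches) < 2:
        raise CohortError("pooling requires >= 2 batches")
    targets = sorted(int(t) for t in targets)
    rng = np.random.default_rng(seed)
    counts_before = []
    for b in batches:
        if "c0_class" not in b.columns:
            raise CohortError("each batch needs a c0_class column")
        counts_before.append({t: int((b["c0_class"] == t).sum()) for t in targets})
    common = {}
    for t in targets:
        n = min(c[t] for c in counts_before)
        if n == 0:
            lacking = [i for i, c in enumerate(counts_before) if c[t] == 0]
            raise CohortError(f"c0 class {t} is empty in batch(es) {lacking}; pooling infeasible")
        common[t] = n
    pooled = []
    for b in batches:
        keep_idx = []
        for t in targets:
            idx = list(b.index[b["c0_class"] == t])
            chosen = sorted(rng.choice(len(idx), size=common[t], replace=False))
            keep_idx.extend(idx[i] for i in chosen)
        pooled.append(b.loc[sorted(keep_idx, key=list(b.index).index)])
    report = {
        "targets": targets,
        "per_class_kept": common,
        "before": counts_before,
        "after": [{t: int((b["c0_class"] == t).sum()) for t in targets} for b in pooled],
    }
    return pooled, report


def growth_rate(c0: int, c_t: int, t_hours: float) -> GrowthResult:
    """r = ln(c_t / c0) / t from the exponential growth model c(t) = c0 e^{rt}."""
    if c0 <= 0 or c_t <= 0:
        raise CohortError("growth rate requires positive cell counts")
    if t_hours <= 0:
        raise CohortError("t_hours must be > 0")
    r = math.log(c_t / c0) / t_hours
    return GrowthResult(r=r, c0=int(c0), c_t=int(c_t), t=float(t_hours))


def compare_groups(values_a, values_b, alpha: float = 0.05):
    """Unpaired two-tailed Student's t-test assuming equal variances.

    Returns ``(t, p, significant)``.  Degenerate case: zero pooled
    variance with equal means yields ``(0, 1, False)`` by convention;
    zero variance with unequal means is an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CohortError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise CohortError("values must be finite")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        raise CohortError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), bool(p < alpha)
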