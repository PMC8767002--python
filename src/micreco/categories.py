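"""Abundance-range classification of OTUs into six categories.

Within one sample group, every OTU observed in at least one sample gets
exactly one label, from its minimum and maximum per-sample relative abundance
across the group's samples (zeros in samples where it is absent count as
abundance 0):

===== ==========================================================
RT    rare everywhere: max <= rare cutoff (0.1%)
AT    abundant everywhere: min >= abundant cutoff (1%)
MT    moderate everywhere: strictly between the cutoffs in all samples
CRT   conditionally rare: rare somewhere, never reaching abundant
CAT   conditionally abundant: abundant somewhere, never rare
CRAT  conditionally rare or abundant: spans rare to abundant
===== ==========================================================

The six predicates partition the (min, max) plane, boundaries included
exactly as the <=/>= conventions above state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RelAbundanceTable

__all__ = ["CATEGORY_LABELS", "CategoryThresholds", "classify_label",
           "classify_taxa", "category_summary"]

CATEGORY_LABELS = ("RT", "AT", "MT", "CRT", "CAT", "CRAT")


@dataclass(frozen=True)
class CategoryThresholds:
    """Relative-abundance cutoffs separating rare / moderate / abundant."""

    rare_cutoff: float = 0.001
    abundant_cutoff: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.rare_cutoff < self.abundant_cutoff < 1.0:
            raise ValueError(
                "thresholds must satisfy 0 < rare_cutoff < abundant_cutoff < 1"
            )


def classify_label(a_min: float, a_max: float,
                   thresholds: CategoryThresholds = CategoryThresholds()) -> str:
    """Label a single OTU from its min/max per-sample relative abundance."""
    r, a = thresholds.rare_cutoff, thresholds.abundant_cutoff
    if a_min > a_max:
        raise ValueError("a_min cannot exceed a_max")
    if a_max <= r:
        return "RT"
    if a_min >= a:
        return "AT"
    if a_max >= a:
        return "CRAT" if a_min <= r else "CAT"
    # a_max strictly between the cutoffs
    return "CRT" if a_min <= r else "MT"


def classify_taxa(rel: RelAbundanceTable | pd.DataFrame,
                  thresholds: CategoryThresholds = CategoryThresholds()) -> pd.Series:
    """Classify every observed OTU of one group's relative-abundance table.

    Only OTUs with nonzero abundance in at least one sample are classified;
    group-absent OTUs do not appear in the result.
    """
    props = rel.proportions if isinstance(rel, RelAbundanceTable) else rel
    arr = props.to_numpy(dtype=float)
    observed = arr.max(axis=0) > 0
    a_min = arr.min(axis=0)[observed]
    a_max = arr.max(axis=0)[observed]
    labels = [classify_label(lo, hi, thresholds) for lo, hi in zip(a_min, a_max)]
    return pd.Series(labels, index=props.columns[observed], name="category")


def category_summary(assignments: dict[str, pd.Series]) -> pd.DataFrame:
    """Per-group category counts and percentages (long format).

    Percentages are 100 x count / total observed OTUs in the group, rounded
    to 2 decimals.
    """
    rows = []
    for group, labels in assignments.items():
        total = len(labels)
        counts = labels.value_counts()
        for cat in CATEGORY_LABELS:
            n = int(counts.get(cat, 0))
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    "count": n,
                    "percent": round(100.0 * n / total, 2) if total else np.nan,
                    "total_observed": total,
                }
            )
    return pd.DataFrame(rows)


def category_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide report: rows = category, columns = group, cells ``percent (count)``."""
    pivot = summary.pivot(index="category", columns="group", values=["percent", "count"])
    groups = sorted(summary["group"].unique())
    out = pd.DataFrame(index=list(CATEGORY_LABELS), columns=groups, dtype=object)
    for g in groups:
        for cat in CATEGORY_LABELS:
            out.loc[cat, g] = (
                f"{pivot[('percent', g)][cat]:.2f} ({int(pivot[('count', g)][cat])})"
            )
    return out
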