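"""Class assignment, cross-timepoint inventory, and functional summaries.

Each tested protein receives exactly one label per timepoint:

* **class1** — detected only in the oocyte extract (absent from vehicle- and
  primed-control sperm) and found on sperm after extract co-incubation, with
  p below the loosened Class-1 threshold (default 0.2).  Interpreted as an
  ooplasmic factor that binds sperm.
* **class2** — present in primed-control sperm and significantly increased
  after co-incubation (p below the Class-2/3 threshold, default 0.1).
* **class3** — present in primed-control sperm (in the extract too or not)
  and significantly decreased after co-incubation; interpreted as a
  sperm-borne degradation substrate or mitophagy determinant.
* **unclassified** — everything else.

The per-timepoint assignments are merged into a single candidate inventory
with overlap accounting (a protein may appear at both timepoints, possibly
with different classes), and functional-category frequencies are summarized
per timepoint and class from a user-provided accession -> category map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .difftest import SignificanceThresholds
from .ingest import Condition, DetectionMatrix, SampleSheet, Timepoint

__all__ = [
    "ClassifyError",
    "ClassAssignmentTable",
    "Inventory",
    "detection_pattern",
    "assign_class",
    "classify_proteins",
    "build_inventory",
    "category_frequencies",
]

CLASS_LABELS = ("class1", "class2", "class3", "unclassified")
PATTERN_COLUMNS = ["in_vehicle_control", "in_primed_control", "in_extract", "in_treated"]
UNCATEGORIZED = "uncategorized"


class ClassifyError(ValueError):
    """Raised on inconsistent classification inputs."""


def detection_pattern(dm: DetectionMatrix, sheet: SampleSheet,
                      timepoint: Timepoint, presence_min: int = 1) -> pd.DataFrame:
    """Per-protein presence booleans for the four conditions at a timepoint.

    A protein is "in" a condition when it is detected in at least
    ``presence_min`` of that condition's replicate samples (default 1: seen
    in any replicate).  Vehicle-control and extract samples recorded as
    timepoint-agnostic in the sheet count toward every timepoint.
    """
    columns = {}
    for cond, col in [
        (Condition.VEHICLE_CONTROL, "in_vehicle_control"),
        (Condition.PRIMED_CONTROL, "in_primed_control"),
        (Condition.EXTRACT, "in_extract"),
        (Condition.TREATED, "in_treated"),
    ]:
        samples = sheet.samples_for(cond, timepoint)
        if not samples:
            raise ClassifyError(
                f"no {cond.value} samples at timepoint {timepoint.value}")
        if not (1 <= presence_min <= len(samples)):
            raise ClassifyError(
                f"presence_min {presence_min} out of range 1..{len(samples)} "
                f"for {cond.value}")
        missing = [s for s in samples if s not in dm.detected.columns]
        if missing:
            raise ClassifyError(f"sample(s) missing from detection matrix: {missing}")
        columns[col] = dm.detected[samples].sum(axis=1) >= presence_min
    out = pd.DataFrame(columns)
    out.index = dm.detected.index
    return out


def assign_class(pattern: Mapping[str, bool], p_value: float, direction: str,
                 th: SignificanceThresholds) -> tuple[str, float]:
    """Label one protein from its detection pattern and test outcome.

    Returns ``(klass, admitted_alpha)``; ``admitted_alpha`` is the threshold
    that admitted the protein (nan when unclassified).  The class clauses are
    evaluated in order class1, class2, class3, so a protein receives at most
    one label.  Class-1 admission is impossible whenever the protein was
    detected in either sperm control, regardless of p.
    """
    extract_only = (not pattern["in_vehicle_control"]
                    and not pattern["in_primed_control"]
                    and pattern["in_extract"] and pattern["in_treated"])
    if extract_only and p_value < th.class1_alpha:
        return "class1", th.class1_alpha
    if pattern["in_primed_control"] and direction == "increase" \
            and p_value < th.class23_alpha:
        return "class2", th.class23_alpha
    if pattern["in_primed_control"] and direction == "decrease" \
            and p_value < th.class23_alpha:
        return "class3", th.class23_alpha
    return "unclassified", math.nan


@dataclass(frozen=True)
class ClassAssignmentTable:
    """Per-protein class labels at one timepoint, plus the thresholds used."""

    frame: pd.DataFrame  # protein_id, timepoint, klass, p_value, direction, admitted_alpha
    timepoint: Timepoint
    thresholds: SignificanceThresholds

    def classified(self) -> pd.DataFrame:
        return self.frame[self.frame["klass"] != "unclassified"]


def classify_proteins(patterns: pd.DataFrame, results: pd.DataFrame,
                      th: SignificanceThresholds,
                      timepoint: Timepoint) -> ClassAssignmentTable:
    """Assign a class to every tested protein at a timepoint.

    ``patterns`` is the output of :func:`detection_pattern`; ``results`` the
    output of :func:`mitoscreen.difftest.run_differential`.  Only proteins
    appearing in ``results`` (i.e. detected somewhere in the compared
    conditions) are labeled.
    """
    missing = [p for p in results["protein_id"] if p not in patterns.index]
    if missing:
        raise ClassifyError(
            f"protein(s) in results but not in patterns: {missing[:5]}")
    rows = []
    for rec in results.itertuples(index=False):
        pat = patterns.loc[rec.protein_id]
        klass, alpha = assign_class(pat, rec.p_value, rec.direction, th)
        rows.append((rec.protein_id, timepoint.value, klass, rec.p_value,
                     rec.direction, alpha))
    frame = pd.DataFrame(
        rows, columns=["protein_id", "timepoint", "klass", "p_value",
                       "direction", "admitted_alpha"])
    return ClassAssignmentTable(frame=frame, timepoint=timepoint, thresholds=th)


@dataclass(frozen=True)
class Inventory:
    """Merged cross-timepoint candidate list with overlap accounting."""

    entries: pd.DataFrame  # protein_id, class_4h, class_24h, p_4h, p_24h,
    #                        in_4h, in_24h, overlap, category
    totals: dict

    def members(self, timepoint: str) -> set[str]:
        col = "in_4h" if timepoint == "4h" else "in_24h"
        return set(self.entries.loc[self.entries[col], "protein_id"])


def build_inventory(a4: ClassAssignmentTable, a24: ClassAssignmentTable,
                    annotations: Mapping[str, str] | None = None) -> Inventory:
    """Merge the 4 h and 24 h class assignments into the final inventory.

    A protein enters a timepoint's inventory when its class there is not
    ``unclassified``; the merged entries carry both timepoints' classes, the
    overlap flag, and an optional functional category.  Both assignments
    must have been computed with identical thresholds.
    """
    if a4.thresholds != a24.thresholds:
        raise ClassifyError(
            f"threshold mismatch between timepoints: {a4.thresholds} vs "
            f"{a24.thresholds}")
    annotations = dict(annotations or {})

    def per_tp(table: ClassAssignmentTable) -> pd.DataFrame:
        f = table.classified()
        return f.set_index("protein_id")[["klass", "p_value"]]

    f4, f24 = per_tp(a4), per_tp(a24)
    set4, set24 = set(f4.index), set(f24.index)
    ordered = list(f4.index) + [p for p in f24.index if p not in set4]
    rows = []
    for protein in ordered:
        in4, in24 = protein in set4, protein in set24
        rows.append(
            (protein,
             f4.at[protein, "klass"] if in4 else "",
             f24.at[protein, "klass"] if in24 else "",
             f4.at[protein, "p_value"] if in4 else math.nan,
             f24.at[protein, "p_value"] if in24 else math.nan,
             in4, in24, in4 and in24,
             annotations.get(protein, UNCATEGORIZED)))
    entries = pd.DataFrame(
        rows, columns=["protein_id", "class_4h", "class_24h", "p_4h", "p_24h",
                       "in_4h", "in_24h", "overlap", "category"])
    entries = entries.astype({"in_4h": bool, "in_24h": bool, "overlap": bool})
    per_class = {
        (tp, klass): int((frame["klass"] == klass).sum())
        for tp, frame in (("4h", f4), ("24h", f24))
        for klass in ("class1", "class2", "class3")
    }
    totals = {
        "n_4h": len(set4),
        "n_24h": len(set24),
        "n_overlap": len(set4 & set24),
        "n_union": len(set4 | set24),
        "per_class": per_class,
    }
    assert totals["n_union"] == totals["n_4h"] + totals["n_24h"] - totals["n_overlap"]
    return Inventory(entries=entries, totals=totals)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def category_frequencies(inv: Inventory,
                         annotations: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Functional-category counts and percentages per (timepoint, class).

    Percentages are of that class's proteins at that timepoint, rounded half
    up to integer percent (pie-chart style); unannotated proteins fall into
    ``uncategorized``.  Empty classes simply produce no rows.
    """
    annotations = dict(annotations or {})
    rows = []
    for tp, class_col, in_col in (("4h", "class_4h", "in_4h"),
                                  ("24h", "class_24h", "in_24h")):
        sub = inv.entries[inv.entries[in_col]]
        for klass in ("class1", "class2", "class3"):
            members = sub[sub[class_col] == klass]
            n = len(members)
            if n == 0:
                continue
            cats = [annotations.get(p, c) for p, c in
                    zip(members["protein_id"], members["category"])]
            counts = pd.Series(cats).value_counts()
            for category, count in sorted(counts.items()):
                rows.append((tp, klass, category, int(count),
                             _round_half_up(100.0 * count / n)))
    return pd.DataFrame(
        rows, columns=["timepoint", "klass", "category", "count", "percent"])
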