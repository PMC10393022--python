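"""Per-protein paired t-tests: primed-control vs cell-free-treated sperm.

Each treated sample is paired with the primed-control sample of the same
biological replicate; the test is a one-sample Student t on the per-replicate
differences of normalized abundance (treated minus control), two-sided, with
n - 1 degrees of freedom.  Direction (increase/decrease) is read from the
sign of the mean difference separately from the two-sided p.

Proteins never detected in either condition are omitted; a protein detected
in only one condition enters with zeros on the other side, which is what lets
extract-derived (Class 1) proteins — all-zero in controls — be tested at all.
Degenerate difference vectors (zero standard deviation) are flagged rather
than erroring: all-zero differences give p = 1, constant nonzero differences
give p = 0 with the sign's direction.

No multiple-testing correction enters class assignment; a Benjamini-Hochberg
adjusted column can be added to the output for exploration only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import SampleSheet, Timepoint
from .normalize import NormalizedMatrix

__all__ = [
    "DifftestError",
    "PairedTestResult",
    "SignificanceThresholds",
    "paired_t",
    "run_differential",
    "add_bh_column",
]

RESULT_COLUMNS = [
    "protein_id", "timepoint", "n_pairs", "mean_control", "mean_treated",
    "t_stat", "df", "p_value", "direction", "degenerate",
]


class DifftestError(ValueError):
    """Raised on invalid test input (length mismatch, too few pairs, ...)."""


@dataclass(frozen=True)
class SignificanceThresholds:
    """Raw-p admission thresholds: 0.1 for Class 2/3, loosened to 0.2 for Class 1."""

    class23_alpha: float = 0.1
    class1_alpha: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.class23_alpha <= self.class1_alpha < 1):
            raise DifftestError(
                "thresholds must satisfy 0 < class23_alpha <= class1_alpha < 1; "
                f"got {self.class23_alpha}, {self.class1_alpha}")


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one protein's paired comparison at one timepoint."""

    protein_id: str
    timepoint: str
    n_pairs: int
    diffs: tuple[float, ...]
    mean_control: float
    mean_treated: float
    t_stat: float  # nan when degenerate with zero mean, +/-inf with nonzero mean
    p_value: float
    direction: Literal["increase", "decrease", "none"]
    degenerate: bool


def paired_t(control: Sequence[float], treated: Sequence[float],
             *, protein_id: str = "", timepoint: str = "") -> PairedTestResult:
    """Paired Student t-test of ``treated`` against ``control`` (paired by index).

    t = mean(d) / (sd(d)/sqrt(n)) with sample sd (n-1 denominator) on
    d_i = treated_i - control_i; p is the two-sided tail probability of
    Student's t with n-1 degrees of freedom.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treated, dtype=float)
    if c.shape != t.shape or c.ndim != 1:
        raise DifftestError(
            f"control and treated must be 1-d of equal length; got shapes "
            f"{c.shape} and {t.shape}")
    n = c.size
    if n < 2:
        raise DifftestError(f"need at least 2 pairs, got {n}")
    diffs = t - c
    mean_d = float(diffs.mean())
    sd_d = float(diffs.std(ddof=1))
    direction: Literal["increase", "decrease", "none"]
    if mean_d > 0:
        direction = "increase"
    elif mean_d < 0:
        direction = "decrease"
    else:
        direction = "none"
    if sd_d == 0.0:
        if mean_d == 0.0:
            t_stat, p = math.nan, 1.0
        else:
            t_stat, p = math.copysign(math.inf, mean_d), 0.0
        degenerate = True
    else:
        t_stat = mean_d / (sd_d / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 1))
        degenerate = False
    return PairedTestResult(
        protein_id=protein_id,
        timepoint=timepoint,
        n_pairs=n,
        diffs=tuple(diffs.tolist()),
        mean_control=float(c.mean()),
        mean_treated=float(t.mean()),
        t_stat=t_stat,
        p_value=p,
        direction=direction,
        degenerate=degenerate,
    )


def run_differential(nm: NormalizedMatrix, sheet: SampleSheet,
                     timepoint: Timepoint) -> pd.DataFrame:
    """Paired t-tests for every protein present at a timepoint.

    A protein is tested when it has a positive normalized value in at least
    one primed-control or treated sample of the timepoint (zeros produced by
    detection censoring count as absent); non-detected cells enter the test
    as 0.  Returns one row per tested protein with columns
    ``RESULT_COLUMNS``, in the matrix's row order.
    """
    pairs = sheet.pairs_at(timepoint)
    if not pairs:
        raise DifftestError(f"no primed_control/treated pairs at {timepoint.value}")
    if len(pairs) < 2:
        raise DifftestError(
            f"need >= 2 pairs at {timepoint.value}, got {len(pairs)}")
    control_ids = [c for c, _ in pairs]
    treated_ids = [t for _, t in pairs]
    missing = [s for s in control_ids + treated_ids if s not in nm.values.columns]
    if missing:
        raise DifftestError(f"sample(s) missing from matrix: {missing}")
    control = nm.values[control_ids].to_numpy()
    treated = nm.values[treated_ids].to_numpy()
    present = (control > 0).any(axis=1) | (treated > 0).any(axis=1)
    rows = []
    for i, protein in enumerate(nm.values.index):
        if not present[i]:
            continue
        res = paired_t(control[i], treated[i], protein_id=str(protein),
                       timepoint=timepoint.value)
        rows.append((res.protein_id, res.timepoint, res.n_pairs,
                     res.mean_control, res.mean_treated, res.t_stat,
                     res.n_pairs - 1, res.p_value, res.direction,
                     res.degenerate))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def add_bh_column(results: pd.DataFrame) -> pd.DataFrame:
    """Append a Benjamini-Hochberg adjusted p column (exploratory only).

    The adjusted values never participate in class assignment.
    """
    from statsmodels.stats.multitest import multipletests

    out = results.copy()
    if len(out):
        out["p_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_bh"] = pd.Series(dtype=float)
    return out
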