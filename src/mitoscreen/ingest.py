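"""Reading and validation of spectral-count tables and sample metadata.

The screen starts from the protein-level export of a database search: one row
per protein accession, one column of MS/MS spectral counts per sample.  This
module loads that table, loads the sample sheet describing the paired
co-incubation design (vehicle control sperm, primed control sperm, oocyte
extract, cell-free-treated sperm; biological replicates; 4 h / 24 h
co-incubation timepoints), and applies the per-sample protein detection rule:
a protein counts as present in a sample only when at least ``min_spectra``
spectra were matched to it there (default 4).

A protein absent from a sample is encoded as count 0, not missing: spectral
counting has no distinct missing code, and the downstream presence/absence
logic treats non-observation as absence.  Protein identity is the accession
string verbatim.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Timepoint",
    "SpectralCountMatrix",
    "SampleSheet",
    "DetectionMatrix",
    "IngestError",
    "read_spectral_counts",
    "read_value_table",
    "write_spectral_counts",
    "read_sample_sheet",
    "apply_detection_filter",
]


class IngestError(ValueError):
    """Raised when an input table violates the ingest contract."""


class Condition(str, enum.Enum):
    """Sample condition in the cell-free co-incubation design."""

    VEHICLE_CONTROL = "vehicle_control"
    PRIMED_CONTROL = "primed_control"
    EXTRACT = "extract"
    TREATED = "treated"


class Timepoint(str, enum.Enum):
    """Co-incubation timepoint of a sample (controls may be timepoint-agnostic)."""

    H4 = "4h"
    H24 = "24h"
    NOT_APPLICABLE = "not_applicable"


_CONDITION_ALIASES = {c.value: c for c in Condition}
_TIMEPOINT_ALIASES = {
    "4h": Timepoint.H4,
    "4hr": Timepoint.H4,
    "4 h": Timepoint.H4,
    "24h": Timepoint.H24,
    "24hr": Timepoint.H24,
    "24 h": Timepoint.H24,
    "na": Timepoint.NOT_APPLICABLE,
    "n/a": Timepoint.NOT_APPLICABLE,
    "none": Timepoint.NOT_APPLICABLE,
    "": Timepoint.NOT_APPLICABLE,
    "not_applicable": Timepoint.NOT_APPLICABLE,
}


@dataclass(frozen=True)
class SpectralCountMatrix:
    """Non-negative integer protein x sample spectral-count table.

    ``counts`` is indexed by protein accession (rows) and sample id (columns);
    0 means the protein was not observed in that sample.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise IngestError(f"duplicate protein accession(s): {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise IngestError(f"duplicate sample id(s): {dupes}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            bad = _first_offender(counts, lambda v: not _is_number(v))
            raise IngestError(f"non-numeric count at {bad}")
        if arr.size:
            if np.any(~np.isfinite(arr.astype(float))):
                bad = _first_offender(counts, lambda v: not np.isfinite(float(v)))
                raise IngestError(f"non-finite count at {bad}")
            if np.any(arr < 0):
                bad = _first_offender(counts, lambda v: float(v) < 0)
                raise IngestError(f"negative count at {bad}")
            if np.any(arr.astype(float) != np.floor(arr.astype(float))):
                bad = _first_offender(counts, lambda v: float(v) != int(float(v)))
                raise IngestError(f"non-integral count at {bad}")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def _is_number(value: object) -> bool:
    try:
        float(value)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def _first_offender(frame: pd.DataFrame, predicate) -> str:
    for protein in frame.index:
        for sample in frame.columns:
            if predicate(frame.at[protein, sample]):
                return f"row {protein!r}, column {sample!r}"
    return "<unknown cell>"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    condition: Condition
    timepoint: Timepoint
    replicate: int
    pair_id: str


@dataclass(frozen=True)
class SampleSheet:
    """Condition / timepoint / replicate / pairing metadata for the design.

    Every ``treated`` sample must share its ``pair_id`` (and timepoint) with
    exactly one ``primed_control`` sample of the same biological replicate;
    that pairing defines the paired t-test.
    """

    samples: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IngestError(f"duplicate sample_id(s): {dupes}")
        for cond in Condition:
            for tp in Timepoint:
                reps = [s.replicate for s in self.samples
                        if s.condition is cond and s.timepoint is tp]
                if len(set(reps)) != len(reps):
                    raise IngestError(
                        f"duplicate replicate index within {cond.value}/{tp.value}")
        for s in self.samples:
            if s.condition is Condition.TREATED:
                mates = [c for c in self.samples
                         if c.condition is Condition.PRIMED_CONTROL
                         and c.pair_id == s.pair_id and c.timepoint == s.timepoint]
                if len(mates) != 1:
                    raise IngestError(
                        f"treated sample {s.sample_id!r} has {len(mates)} "
                        f"primed_control partner(s) for pair_id {s.pair_id!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_for(self, condition: Condition,
                    timepoint: Timepoint | None = None) -> list[str]:
        """Sample ids of a condition, optionally restricted to a timepoint.

        When a timepoint is given, timepoint-agnostic samples (recorded as
        ``not_applicable``) are included as well: the study's vehicle-control
        and extract samples may be shared across trials.
        """
        out = []
        for s in self.samples:
            if s.condition is not condition:
                continue
            if timepoint is None or s.timepoint is timepoint \
                    or s.timepoint is Timepoint.NOT_APPLICABLE:
                out.append(s.sample_id)
        return out

    def pairs_at(self, timepoint: Timepoint) -> list[tuple[str, str]]:
        """(primed_control, treated) sample-id pairs at a timepoint, ordered by pair_id."""
        controls = {s.pair_id: s.sample_id for s in self.samples
                    if s.condition is Condition.PRIMED_CONTROL
                    and s.timepoint is timepoint}
        pairs = []
        for s in self.samples:
            if s.condition is Condition.TREATED and s.timepoint is timepoint:
                if s.pair_id in controls:
                    pairs.append((s.pair_id, controls[s.pair_id], s.sample_id))
        pairs.sort()
        return [(c, t) for _, c, t in pairs]

    def timepoints(self) -> list[Timepoint]:
        """Timepoints with at least one primed_control/treated pair."""
        return [tp for tp in (Timepoint.H4, Timepoint.H24) if self.pairs_at(tp)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition.value for s in self.samples],
                "timepoint": [s.timepoint.value for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "pair_id": [s.pair_id for s in self.samples],
            }
        )


@dataclass(frozen=True)
class DetectionMatrix:
    """Detection calls plus censored counts under the min-spectra rule.

    ``detected[p, s]`` is true iff the raw count reached ``min_spectra``;
    ``censored_counts`` carries the raw count where detected and 0 elsewhere.
    """

    detected: pd.DataFrame
    censored_counts: pd.DataFrame
    min_spectra: int

    @property
    def protein_ids(self) -> list[str]:
        return list(self.censored_counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.censored_counts.columns)


def _read_delimited(path: Path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    return pd.read_csv(path, sep=sep, index_col=0)


def read_spectral_counts(path: str | Path, *, sep: str | None = None,
                         sheet: str | int = 0) -> SpectralCountMatrix:
    """Read a protein x sample spectral-count table.

    Parameters
    ----------
    path
        Delimited text file (CSV/TSV, delimiter sniffed unless ``sep`` is
        given) or an ``.xlsx`` workbook.  First column = protein accession,
        remaining columns = per-sample counts; row/column order is preserved.
    sep
        Force a delimiter instead of sniffing.
    sheet
        Worksheet name or index for ``.xlsx`` input.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        frame = pd.read_excel(path, sheet_name=sheet, index_col=0)
    else:
        frame = _read_delimited(path, sep)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return SpectralCountMatrix(frame)


def read_value_table(path: str | Path, *, sep: str | None = None,
                     sheet: str | int = 0) -> pd.DataFrame:
    """Read an already-normalized protein x sample table of real values.

    Same layout contract as :func:`read_spectral_counts` but values may be
    non-integral; used by the from-normalized pipeline entry mode.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        frame = pd.read_excel(path, sheet_name=sheet, index_col=0)
    else:
        frame = _read_delimited(path, sep)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise IngestError(f"duplicate protein accession(s): {dupes}")
    values = frame.astype(float)
    if (values.to_numpy() < 0).any():
        bad = _first_offender(values, lambda v: float(v) < 0)
        raise IngestError(f"negative value at {bad}")
    return values


def write_spectral_counts(m: SpectralCountMatrix, path: str | Path,
                          *, sep: str = "\t") -> None:
    """Write a count matrix in the same layout :func:`read_spectral_counts` reads."""
    m.counts.to_csv(path, sep=sep, index_label="accession")


def read_sample_sheet(path: str | Path, *, sep: str | None = None) -> SampleSheet:
    """Read the sample sheet (columns sample_id, condition, timepoint, replicate, pair_id).

    Condition and timepoint labels are mapped case-insensitively onto the
    :class:`Condition` / :class:`Timepoint` enums.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                        dtype=str, keep_default_na=False)
    required = {"sample_id", "condition", "timepoint", "replicate", "pair_id"}
    missing = required - set(frame.columns)
    if missing:
        raise IngestError(f"sample sheet missing column(s): {sorted(missing)}")
    return sample_sheet_from_frame(frame)


def sample_sheet_from_frame(frame: pd.DataFrame) -> SampleSheet:
    records = []
    for _, row in frame.iterrows():
        cond_key = str(row["condition"]).strip().lower()
        if cond_key not in _CONDITION_ALIASES:
            raise IngestError(f"unknown condition label: {row['condition']!r}")
        tp_key = str(row["timepoint"]).strip().lower()
        if tp_key not in _TIMEPOINT_ALIASES:
            raise IngestError(f"unknown timepoint label: {row['timepoint']!r}")
        try:
            replicate = int(row["replicate"])
        except (TypeError, ValueError):
            raise IngestError(f"non-integer replicate: {row['replicate']!r}") from None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                condition=_CONDITION_ALIASES[cond_key],
                timepoint=_TIMEPOINT_ALIASES[tp_key],
                replicate=replicate,
                pair_id=str(row["pair_id"]),
            )
        )
    return SampleSheet(tuple(records))


def write_sample_sheet(sheet: SampleSheet, path: str | Path, *, sep: str = "\t") -> None:
    sheet.to_frame().to_csv(path, sep=sep, index=False)


def apply_detection_filter(
    m: SpectralCountMatrix | DetectionMatrix, min_spectra: int = 4
) -> DetectionMatrix:
    """Apply the per-sample detection rule: present iff count >= ``min_spectra``.

    Sub-threshold counts are censored to 0; the input matrix is left
    unmodified.  Filtering an already-censored matrix with the same threshold
    is a no-op (idempotence).
    """
    if min_spectra < 1:
        raise IngestError(f"min_spectra must be >= 1, got {min_spectra}")
    counts = m.censored_counts if isinstance(m, DetectionMatrix) else m.counts
    detected = counts >= min_spectra
    censored = counts.where(detected, 0)
    return DetectionMatrix(detected=detected, censored_counts=censored,
                           min_spectra=min_spectra)
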