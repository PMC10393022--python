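"""Two-stage reference normalization of spectral counts.

Sperm-containing samples are first scaled so that their summed content of the
outer-dense-fiber reference proteins (ODF1/2/3, structural proteins of the
sperm flagellum and hence proxies for sperm load) is equal across samples;
all samples of a batch are then scaled to a common mean to damp residual
batch variance.  The two stages are applied in that order.

Each stage is expressed as a set of positive per-sample multipliers
(:class:`ScaleFactors`); a :class:`NormalizedMatrix` records every applied
stage in order, so a normalization can be audited or replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .ingest import DetectionMatrix, SpectralCountMatrix

__all__ = [
    "NormalizationError",
    "ReferenceSet",
    "DEFAULT_REFERENCE",
    "ScaleFactors",
    "NormalizedMatrix",
    "odf_scale_factors",
    "mean_scale_factors",
    "apply_scaling",
]


class NormalizationError(ValueError):
    """Raised when scale factors cannot be computed or applied."""


@dataclass(frozen=True)
class ReferenceSet:
    """Reference-protein accessions used as sperm-load anchors."""

    accessions: tuple[str, ...]
    label: str = "ODF"

    def __post_init__(self) -> None:
        if not self.accessions:
            raise NormalizationError("reference set must be non-empty")


#: Outer dense fiber proteins of the sperm flagellum, the default anchors.
DEFAULT_REFERENCE = ReferenceSet(accessions=("ODF1", "ODF2", "ODF3"))


@dataclass(frozen=True)
class ScaleFactors:
    """Per-sample positive multipliers for one normalization stage."""

    factors: dict[str, float]
    stage: Literal["odf", "mean"]
    reference_value: float

    def __post_init__(self) -> None:
        for sample, f in self.factors.items():
            if not np.isfinite(f) or f <= 0:
                raise NormalizationError(
                    f"scale factor for sample {sample!r} is {f!r}; must be "
                    "positive and finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.factors),
                "stage": self.stage,
                "factor": list(self.factors.values()),
                "reference_value": self.reference_value,
            }
        )


@dataclass(frozen=True)
class NormalizedMatrix:
    """Protein x sample real-valued table plus the scaling provenance."""

    values: pd.DataFrame
    provenance: tuple[ScaleFactors, ...] = ()

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


MatrixLike = SpectralCountMatrix | DetectionMatrix | NormalizedMatrix | pd.DataFrame


def _values(m: MatrixLike) -> pd.DataFrame:
    if isinstance(m, SpectralCountMatrix):
        return m.counts.astype(float)
    if isinstance(m, DetectionMatrix):
        return m.censored_counts.astype(float)
    if isinstance(m, NormalizedMatrix):
        return m.values
    return m.astype(float)


def odf_scale_factors(m: MatrixLike, ref: ReferenceSet,
                      target_samples: Iterable[str]) -> ScaleFactors:
    """Factors equalizing the summed reference-protein content across samples.

    For each target sample ``s``, ``factor[s] = reference_value /
    odf_total[s]`` where ``odf_total[s]`` is the sum of the reference
    accessions' values in ``s`` and ``reference_value`` is the arithmetic
    mean of those totals over the target samples.  Samples outside the target
    set get factor 1 (the reference proteins are sperm flagellar proteins, so
    only sperm-containing samples are meaningfully anchored to them).
    """
    values = _values(m)
    targets = list(target_samples)
    missing = [a for a in ref.accessions if a not in values.index]
    if missing:
        raise NormalizationError(f"reference accession(s) absent from matrix: {missing}")
    unknown = [s for s in targets if s not in values.columns]
    if unknown:
        raise NormalizationError(f"target sample(s) absent from matrix: {unknown}")
    totals = values.loc[list(ref.accessions), targets].sum(axis=0)
    zeros = totals.index[totals <= 0].tolist()
    if zeros:
        raise NormalizationError(
            f"zero summed reference counts in sample(s): {zeros}")
    reference_value = float(totals.mean())
    factors = {s: 1.0 for s in values.columns}
    for s in targets:
        factors[s] = reference_value / float(totals[s])
    return ScaleFactors(factors=factors, stage="odf", reference_value=reference_value)


def mean_scale_factors(m: MatrixLike, target_samples: Iterable[str],
                       shared_only: bool = True) -> ScaleFactors:
    """Factors equalizing per-sample mean abundance across a batch.

    ``factor[s] = grand_mean / sample_mean[s]``, with means taken either over
    all proteins (``shared_only=False``) or over proteins observed (> 0) in
    every target sample (``shared_only=True``, the default: presence/absence
    differences then cannot dominate the scaling).  ``grand_mean`` is the
    arithmetic mean of the sample means over the target samples.
    """
    values = _values(m)
    targets = list(target_samples)
    unknown = [s for s in targets if s not in values.columns]
    if unknown:
        raise NormalizationError(f"target sample(s) absent from matrix: {unknown}")
    sub = values[targets]
    if shared_only:
        shared = (sub > 0).all(axis=1)
        if not shared.any():
            raise NormalizationError(
                "no protein is observed in every target sample; cannot take "
                "shared-only means")
        sub = sub.loc[shared]
    means = sub.mean(axis=0)
    zeros = means.index[means <= 0].tolist()
    if zeros:
        raise NormalizationError(f"zero sample mean in sample(s): {zeros}")
    grand_mean = float(means.mean())
    factors = {s: 1.0 for s in values.columns}
    for s in targets:
        factors[s] = grand_mean / float(means[s])
    return ScaleFactors(factors=factors, stage="mean", reference_value=grand_mean)


def apply_scaling(m: MatrixLike, f: ScaleFactors) -> NormalizedMatrix:
    """Multiply each sample column by its factor; append to the provenance.

    Samples without a factor default to 1.  The input is not modified.
    """
    values = _values(m)
    multipliers = np.array([f.factors.get(s, 1.0) for s in values.columns])
    if np.any(~np.isfinite(multipliers)) or np.any(multipliers <= 0):
        raise NormalizationError("all scale factors must be positive and finite")
    scaled = values * multipliers
    provenance = m.provenance if isinstance(m, NormalizedMatrix) else ()
    return NormalizedMatrix(values=scaled, provenance=provenance + (f,))
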