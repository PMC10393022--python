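"""Synthetic spectral-count experiments with planted classification truth.

The generator reproduces the study design — vehicle-control sperm,
primed-control sperm, oocyte extract, and cell-free-treated sperm, in
biological triplicate at 4 h and 24 h co-incubation — and plants proteins of
known type so every pipeline stage can be exercised without any download:

* ``null`` proteins sit at baseline in all sperm samples (and in the extract
  with probability 0.5);
* ``reference`` proteins emulate the ODF1/2/3 sperm-load anchors: high fixed
  abundance in every sperm-containing sample, absent from the extract;
* ``class1`` proteins are extract-derived sperm binders: exactly zero in the
  vehicle and primed controls (a hard constraint, not a stochastic one),
  baseline in the extract and in treated sperm;
* ``class2`` proteins increase ``effect_fold``-fold on treated sperm;
* ``class3`` proteins decrease ``effect_fold``-fold on treated sperm (and
  appear in the extract with probability 0.5, exercising the
  both-gametes branch of the Class-3 rule).

Counts are overdispersed with the negative-binomial law (mean mu, variance
mu + mu^2/dispersion), realised as a gamma-Poisson mixture whose gamma
biological effect is shared between the primed-control and treated aliquots
of the same biological replicate.  That sharing is what biological
replication means in a paired design — both aliquots derive from one semen
collection — and it is what the paired t-test exploits; the marginal law of
every count is exactly the negative binomial above.  Per-sample loading
variation enters as an independent log-normal multiplier.  Counts below the
detection floor are left as drawn: censoring is the ingest stage's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassAssignmentTable
from .ingest import (Condition, SampleRecord, SampleSheet, SpectralCountMatrix,
                     Timepoint, write_sample_sheet, write_spectral_counts)

__all__ = [
    "SimulationError",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "write_fixture",
    "truth_confusion",
    "recovery_rates",
]

TRUTH_LABELS = ("null", "reference", "class1", "class2", "class3")


class SimulationError(ValueError):
    """Raised on an invalid synthetic-experiment configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and noise parameters of a synthetic experiment.

    Defaults mirror the study conditions: triplicate pairs at two
    co-incubation timepoints, a 4-spectra detection floor, three high-
    abundance reference anchors, moderately overdispersed counts, and a
    null-dominated proteome (roughly one protein in ten carrying a planted
    effect, with decreases outnumbering increases about 4:1 as in the
    screen's inventories).  Mean normalization assumes most proteins are
    unchanged, so the planted-effect fraction is deliberately kept small;
    the default 4:1 class3:class2 ratio at fold 4 additionally keeps total
    planted abundance condition-independent, emulating the equal peptide
    load injected per MS run.
    """

    n_null: int = 1000
    n_class1: int = 12
    n_class2: int = 25
    n_class3: int = 100
    n_reference: int = 3
    n_pairs: int = 3
    timepoints: tuple[str, ...] = ("4h", "24h")
    baseline_mean: float = 50.0
    effect_fold: float = 4.0
    dispersion: float = 10.0
    sample_scale_jitter: float = 0.1
    reference_scale: float = 20.0
    extract_presence_prob: float = 0.5
    min_spectra: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_null", "n_class1", "n_class2", "n_class3", "n_reference"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.n_pairs < 2:
            raise SimulationError("n_pairs must be >= 2")
        if self.effect_fold <= 1:
            raise SimulationError("effect_fold must be > 1")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise SimulationError("baseline_mean must be > 0")
        if self.sample_scale_jitter < 0:
            raise SimulationError("sample_scale_jitter must be >= 0")
        if not (0 <= self.extract_presence_prob <= 1):
            raise SimulationError("extract_presence_prob must be in [0, 1]")
        if self.min_spectra < 1:
            raise SimulationError("min_spectra must be >= 1")
        bad = [t for t in self.timepoints if t not in ("4h", "24h")]
        if bad or not self.timepoints:
            raise SimulationError(
                f"timepoints must be a non-empty subset of ('4h', '24h'); got "
                f"{self.timepoints}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted label per protein: null, reference, class1, class2 or class3."""

    labels: dict[str, str]

    def of_label(self, label: str) -> list[str]:
        return [p for p, l in self.labels.items() if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"protein_id": list(self.labels),
                             "label": list(self.labels.values())})


def _protein_ids(cfg: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    ids: list[str] = []
    labels: dict[str, str] = {}

    def add(prefix: str, n: int, label: str, width: int = 3) -> None:
        for i in range(1, n + 1):
            pid = f"{prefix}{i:0{width}d}" if width else f"{prefix}{i}"
            ids.append(pid)
            labels[pid] = label

    add("ODF", cfg.n_reference, "reference", width=0)
    add("C1_", cfg.n_class1, "class1")
    add("C2_", cfg.n_class2, "class2")
    add("C3_", cfg.n_class3, "class3")
    add("NUL", cfg.n_null, "null", width=4)
    return ids, labels


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[SpectralCountMatrix, SampleSheet, SyntheticTruth]:
    """Draw one complete synthetic experiment.

    Returns the raw count matrix (all timepoints side by side), the matching
    sample sheet, and the planted truth.  Identical configs (including seed)
    give bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    ids, labels = _protein_ids(cfg)
    n_proteins = len(ids)
    label_arr = np.array([labels[p] for p in ids])

    # per-protein extract presence for null/class3 (drawn once per protein)
    extract_present = rng.random(n_proteins) < cfg.extract_presence_prob
    mult = {}
    for cond in Condition:
        mult[cond] = np.ones(n_proteins)
    is_ref = label_arr == "reference"
    is_c1 = label_arr == "class1"
    is_c2 = label_arr == "class2"
    is_c3 = label_arr == "class3"
    is_null = label_arr == "null"
    for cond in (Condition.VEHICLE_CONTROL, Condition.PRIMED_CONTROL,
                 Condition.TREATED):
        mult[cond][is_ref] = cfg.reference_scale
    mult[Condition.VEHICLE_CONTROL][is_c1] = 0.0
    mult[Condition.PRIMED_CONTROL][is_c1] = 0.0
    mult[Condition.TREATED][is_c2] = cfg.effect_fold
    mult[Condition.TREATED][is_c3] = 1.0 / cfg.effect_fold
    ex = np.ones(n_proteins)
    ex[is_ref] = 0.0
    ex[is_null] = extract_present[is_null].astype(float)
    ex[is_c3] = extract_present[is_c3].astype(float)
    mult[Condition.EXTRACT] = ex

    records: list[SampleRecord] = []
    columns: dict[str, np.ndarray] = {}
    short = {Condition.VEHICLE_CONTROL: "vc", Condition.PRIMED_CONTROL: "pc",
             Condition.TREATED: "tr", Condition.EXTRACT: "ex"}
    for tp_value in cfg.timepoints:
        tp = Timepoint(tp_value)
        # pair-shared biological effect for primed/treated aliquots
        pair_effect = rng.gamma(cfg.dispersion, 1.0 / cfg.dispersion,
                                size=(n_proteins, cfg.n_pairs))
        for cond in (Condition.VEHICLE_CONTROL, Condition.PRIMED_CONTROL,
                     Condition.TREATED, Condition.EXTRACT):
            for rep in range(1, cfg.n_pairs + 1):
                sample_id = f"{short[cond]}_{tp_value}_r{rep}"
                pair_id = (f"{tp_value}_p{rep}"
                           if cond in (Condition.PRIMED_CONTROL, Condition.TREATED)
                           else "")
                records.append(SampleRecord(sample_id=sample_id, condition=cond,
                                            timepoint=tp, replicate=rep,
                                            pair_id=pair_id))
                load = float(np.exp(rng.normal(0.0, cfg.sample_scale_jitter))) \
                    if cfg.sample_scale_jitter > 0 else 1.0
                if cond in (Condition.PRIMED_CONTROL, Condition.TREATED):
                    effect = pair_effect[:, rep - 1]
                else:
                    effect = rng.gamma(cfg.dispersion, 1.0 / cfg.dispersion,
                                       size=n_proteins)
                mu = cfg.baseline_mean * mult[cond] * effect * load
                columns[sample_id] = rng.poisson(mu)

    counts = pd.DataFrame(columns, index=pd.Index(ids, name="accession"),
                          dtype=np.int64)
    return (SpectralCountMatrix(counts), SampleSheet(tuple(records)),
            SyntheticTruth(labels))


def write_fixture(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a ready-to-run fixture directory: counts, sample sheet, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, sheet, truth = generate_dataset(cfg)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_spectral_counts(matrix, paths["counts"])
    write_sample_sheet(sheet, paths["samples"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def truth_confusion(assignments: ClassAssignmentTable,
                    truth: SyntheticTruth) -> pd.DataFrame:
    """Confusion matrix of (planted label x assigned class) counts.

    Rows are planted labels, columns assigned classes; planted proteins the
    pipeline never tested (e.g. fully censored) count as ``unclassified``.
    """
    frame = assignments.frame
    unknown = [p for p in frame["protein_id"] if p not in truth.labels]
    if unknown:
        raise SimulationError(
            f"assigned protein(s) missing from the planted truth: {unknown[:5]}")
    assigned = dict(zip(frame["protein_id"], frame["klass"]))
    table = pd.DataFrame(0, index=list(TRUTH_LABELS),
                         columns=["unclassified", "class1", "class2", "class3"])
    for protein, planted in truth.labels.items():
        table.at[planted, assigned.get(protein, "unclassified")] += 1
    return table


def recovery_rates(confusion: pd.DataFrame) -> dict[str, float]:
    """Recovery and false-positive summaries derived from a confusion matrix.

    ``recovery_class2``/``recovery_class3`` are the fractions of planted
    effect proteins assigned their own class; ``null_fp_rate`` is the
    fraction of planted nulls assigned any class.
    """
    out: dict[str, float] = {}
    for klass in ("class1", "class2", "class3"):
        planted = confusion.loc[klass].sum()
        out[f"recovery_{klass}"] = (
            float(confusion.at[klass, klass] / planted) if planted else float("nan"))
    n_null = confusion.loc["null"].sum()
    fp = confusion.loc["null", ["class1", "class2", "class3"]].sum()
    out["null_fp_rate"] = float(fp / n_null) if n_null else float("nan")
    return out
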