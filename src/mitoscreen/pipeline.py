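"""End-to-end orchestration: ingest -> normalize -> test -> classify -> report.

A run is configured by a :class:`PipelineConfig` (YAML-loadable), executes
deterministically, and emits every intermediate table as TSV into the output
directory: per-timepoint normalized matrices, scale factors, paired-test
results, class assignments, the merged inventory, the category table, and a
JSON run report whose counts are recomputable from the emitted tables.

Two entry modes exist.  ``from-raw`` recomputes everything from raw spectral
counts.  ``from-normalized`` ingests a table of already-normalized values
(e.g. the study's deposited workbook sheets) and runs only testing and
classification, for when the original normalization arithmetic is to be
taken as given; :func:`compare_runs` quantifies how class memberships differ
between two runs.

All tables are computed before anything is written, so a failing stage
leaves no partial output; stage errors are re-raised with the stage name and
offending entity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .classify import (ClassAssignmentTable, Inventory, build_inventory,
                       category_frequencies, classify_proteins,
                       detection_pattern)
from .difftest import SignificanceThresholds, run_differential
from .ingest import (Condition, DetectionMatrix, SampleSheet, Timepoint,
                     apply_detection_filter, read_sample_sheet,
                     read_spectral_counts, read_value_table)
from .normalize import (DEFAULT_REFERENCE, NormalizedMatrix, ReferenceSet,
                        apply_scaling, mean_scale_factors, odf_scale_factors)

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "compare_runs",
    "read_annotations",
]

logger = logging.getLogger("mitoscreen")

FLOAT_FORMAT = "%.10g"  # fixed table formatting => reruns are byte-identical


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and original error."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs: paths, thresholds, normalization options."""

    counts: str
    sample_sheet: str
    output_dir: str
    annotations: str | None = None
    mode: str = "from-raw"  # or "from-normalized"
    min_spectra: int = 4
    presence_min: int = 1
    class23_alpha: float = 0.1
    class1_alpha: float = 0.2
    reference_accessions: tuple[str, ...] = DEFAULT_REFERENCE.accessions
    shared_only: bool = True
    normalize_extract: bool = False  # include extract samples in the mean stage
    odf_include_vehicle: bool = True  # vehicle controls enter the ODF reference mean
    export_xlsx: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("from-raw", "from-normalized"):
            raise PipelineError(f"unknown mode: {self.mode!r}")
        SignificanceThresholds(self.class23_alpha, self.class1_alpha)

    @property
    def thresholds(self) -> SignificanceThresholds:
        return SignificanceThresholds(self.class23_alpha, self.class1_alpha)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "reference_accessions" in raw:
            raw["reference_accessions"] = tuple(raw["reference_accessions"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["reference_accessions"] = list(self.reference_accessions)
        return d


@dataclass
class RunReport:
    """Per-stage counts and configuration echo for one pipeline run."""

    config: dict[str, Any]
    fingerprint: str
    n_proteins_in: int
    n_proteins_detected: int
    per_timepoint: dict[str, dict[str, Any]]
    inventory_totals: dict[str, Any]
    outputs: dict[str, str]
    log_path: str

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["inventory_totals"] = _jsonable_totals(self.inventory_totals)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _jsonable_totals(totals: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(totals)
    if "per_class" in out:
        out["per_class"] = {f"{tp}:{klass}": v
                            for (tp, klass), v in out["per_class"].items()}
    return out


def read_annotations(path: str | Path, *, sep: str | None = None) -> dict[str, str]:
    """Read an accession -> functional-category map (two delimited columns)."""
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                        dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise PipelineError("annotation map needs >= 2 columns (accession, category)")
    acc, cat = frame.columns[0], frame.columns[1]
    return dict(zip(frame[acc], frame[cat]))


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def _sperm_samples(sheet: SampleSheet, tp: Timepoint,
                   include_vehicle: bool) -> list[str]:
    conds = [Condition.PRIMED_CONTROL, Condition.TREATED]
    if include_vehicle:
        conds.insert(0, Condition.VEHICLE_CONTROL)
    out: list[str] = []
    for cond in conds:
        out.extend(sheet.samples_for(cond, tp))
    return out


def _batch_samples(sheet: SampleSheet, tp: Timepoint,
                   include_extract: bool) -> list[str]:
    out = _sperm_samples(sheet, tp, include_vehicle=True)
    if include_extract:
        out.extend(sheet.samples_for(Condition.EXTRACT, tp))
    return out


def normalize_timepoint(dm: DetectionMatrix | NormalizedMatrix,
                        sheet: SampleSheet, tp: Timepoint,
                        reference: ReferenceSet,
                        shared_only: bool = True,
                        normalize_extract: bool = False,
                        odf_include_vehicle: bool = True) -> NormalizedMatrix:
    """Apply the two normalization stages to one timepoint batch.

    ODF scaling first, over the sperm-containing samples of the batch; mean
    scaling second, over the whole batch (optionally excluding the extract
    samples).  Columns outside the batch are dropped from the result.
    """
    batch = _batch_samples(sheet, tp, include_extract=True)
    odf_targets = _sperm_samples(sheet, tp, include_vehicle=odf_include_vehicle)
    mean_targets = _batch_samples(sheet, tp, include_extract=normalize_extract)
    f_odf = odf_scale_factors(dm, reference, odf_targets)
    nm = apply_scaling(dm, f_odf)
    f_mean = mean_scale_factors(nm, mean_targets, shared_only=shared_only)
    nm = apply_scaling(nm, f_mean)
    return NormalizedMatrix(values=nm.values[batch], provenance=nm.provenance)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute a full run and write all outputs under ``cfg.output_dir``."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir, log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, outdir: Path, log_path: Path) -> RunReport:
    thresholds = cfg.thresholds
    annotations: dict[str, str] = {}
    with _stage("ingest"):
        sheet = read_sample_sheet(cfg.sample_sheet)
        if cfg.mode == "from-raw":
            matrix = read_spectral_counts(cfg.counts)
            dm = apply_detection_filter(matrix, cfg.min_spectra)
            n_in = len(matrix.protein_ids)
        else:
            values = read_value_table(cfg.counts)
            dm = DetectionMatrix(detected=values > 0, censored_counts=values,
                                 min_spectra=1)
            n_in = len(values.index)
        if cfg.annotations:
            annotations = read_annotations(cfg.annotations)
    n_detected = int((dm.detected.any(axis=1)).sum())
    logger.info("ingest: %d proteins in, %d detected somewhere (min_spectra=%s)",
                n_in, n_detected, dm.min_spectra)

    timepoints = sheet.timepoints()
    if not timepoints:
        raise PipelineError("stage 'ingest': sample sheet defines no "
                            "primed_control/treated pairs at any timepoint")

    tables: dict[str, pd.DataFrame] = {}
    assignments: dict[Timepoint, ClassAssignmentTable] = {}
    per_timepoint: dict[str, dict[str, Any]] = {}
    for tp in timepoints:
        key = tp.value
        with _stage(f"normalize[{key}]"):
            if cfg.mode == "from-raw":
                nm = normalize_timepoint(
                    dm, sheet, tp,
                    reference=ReferenceSet(cfg.reference_accessions),
                    shared_only=cfg.shared_only,
                    normalize_extract=cfg.normalize_extract,
                    odf_include_vehicle=cfg.odf_include_vehicle)
            else:
                batch = _batch_samples(sheet, tp, include_extract=True)
                batch = [s for s in batch if s in dm.censored_counts.columns]
                nm = NormalizedMatrix(values=dm.censored_counts[batch].astype(float))
        with _stage(f"difftest[{key}]"):
            results = run_differential(nm, sheet, tp)
        with _stage(f"classify[{key}]"):
            patterns = detection_pattern(dm, sheet, tp, cfg.presence_min)
            assignments[tp] = classify_proteins(patterns, results, thresholds, tp)
        factor_frames = [f.to_frame() for f in nm.provenance]
        tables[f"normalized_{key}.tsv"] = nm.values.rename_axis("accession").reset_index()
        if factor_frames:
            tables[f"factors_{key}.tsv"] = pd.concat(factor_frames, ignore_index=True)
        tables[f"results_{key}.tsv"] = results
        tables[f"assignments_{key}.tsv"] = assignments[tp].frame
        counts = assignments[tp].frame["klass"].value_counts()
        per_timepoint[key] = {
            "n_tested": int(len(results)),
            "n_class1": int(counts.get("class1", 0)),
            "n_class2": int(counts.get("class2", 0)),
            "n_class3": int(counts.get("class3", 0)),
            "n_unclassified": int(counts.get("unclassified", 0)),
            "n_classified": int(len(assignments[tp].classified())),
        }
        logger.info("timepoint %s: tested %d, classified %d", key,
                    per_timepoint[key]["n_tested"],
                    per_timepoint[key]["n_classified"])

    with _stage("inventory"):
        a4 = assignments.get(Timepoint.H4) or _empty_assignments(Timepoint.H4, thresholds)
        a24 = assignments.get(Timepoint.H24) or _empty_assignments(Timepoint.H24, thresholds)
        inventory = build_inventory(a4, a24, annotations)
        categories = category_frequencies(inventory, annotations)
    tables["inventory.tsv"] = inventory.entries
    tables["categories.tsv"] = categories
    logger.info("inventory: %s", inventory.totals)

    with _stage("write"):
        outputs: dict[str, str] = {}
        for name, frame in tables.items():
            path = outdir / name
            frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
            outputs[name] = name
        if cfg.export_xlsx:
            xlsx = outdir / "inventory.xlsx"
            with pd.ExcelWriter(xlsx) as writer:
                for tp_val, col in (("4h", "in_4h"), ("24h", "in_24h")):
                    sub = inventory.entries[inventory.entries[col]]
                    sub.to_excel(writer, sheet_name=f"{tp_val} inventory", index=False)
            outputs["inventory.xlsx"] = "inventory.xlsx"

    # report cross-check: totals must equal the emitted inventory rows
    for tp_val, col in (("4h", "in_4h"), ("24h", "in_24h")):
        emitted = int(inventory.entries[col].sum())
        if tp_val in per_timepoint and per_timepoint[tp_val]["n_classified"] != emitted:
            raise PipelineError(
                f"stage 'report': inventory rows for {tp_val} ({emitted}) do not "
                f"match classified count ({per_timepoint[tp_val]['n_classified']})")

    config_dict = cfg.to_dict()
    fingerprint = hashlib.sha256(
        json.dumps({"version": _version, **{k: v for k, v in config_dict.items()
                                            if k != "output_dir"}},
                   sort_keys=True).encode()).hexdigest()[:16]
    report = RunReport(
        config=config_dict,
        fingerprint=fingerprint,
        n_proteins_in=n_in,
        n_proteins_detected=n_detected,
        per_timepoint=per_timepoint,
        inventory_totals=inventory.totals,
        outputs=outputs,
        log_path=log_path.name,
    )
    report.to_json(outdir / "report.json")
    return report


def _empty_assignments(tp: Timepoint,
                       th: SignificanceThresholds) -> ClassAssignmentTable:
    frame = pd.DataFrame(columns=["protein_id", "timepoint", "klass", "p_value",
                                  "direction", "admitted_alpha"])
    return ClassAssignmentTable(frame=frame, timepoint=tp, thresholds=th)


def compare_runs(dir_a: str | Path, dir_b: str | Path) -> dict[str, Any]:
    """Diff the class memberships of two pipeline output directories.

    Returns, per timepoint and class, the accessions present in one run's
    inventory but not the other's, plus count deltas; an empty diff means
    the runs classified identically.
    """
    diff: dict[str, Any] = {"changed": []}
    entries = {}
    for label, d in (("a", Path(dir_a)), ("b", Path(dir_b))):
        path = d / "inventory.tsv"
        if not path.exists():
            raise PipelineError(f"no inventory.tsv under {d}")
        entries[label] = pd.read_csv(path, sep="\t", dtype={"protein_id": str},
                                     keep_default_na=False)
    for tp_val, col in (("4h", "class_4h"), ("24h", "class_24h")):
        a = dict(zip(entries["a"]["protein_id"], entries["a"][col]))
        b = dict(zip(entries["b"]["protein_id"], entries["b"][col]))
        a = {p: k for p, k in a.items() if k and k != "unclassified"}
        b = {p: k for p, k in b.items() if k and k != "unclassified"}
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        moved = sorted(p for p in set(a) & set(b) if a[p] != b[p])
        diff[tp_val] = {
            "only_a": only_a,
            "only_b": only_b,
            "reclassified": moved,
            "count_delta": len(b) - len(a),
        }
        diff["changed"].extend(only_a + only_b + moved)
    diff["changed"] = sorted(set(diff["changed"]))
    diff["identical"] = not diff["changed"]
    return diff
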