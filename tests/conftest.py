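import pandas as pd
import pytest
from hypothesis import settings

import mitoscreen as ms

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def tiny_counts(tmp_path):
    """Literal 2-protein x 3-sample count table on disk."""
    path = tmp_path / "counts.csv"
    path.write_text(
        "accession,s1,s2,s3\n"
        "P1,5,0,7\n"
        "P2,4,4,4\n"
    )
    return path


def make_sheet_frame(timepoints=("4h", "24h"), n_pairs=3,
                     extra_conditions=("vehicle_control", "extract")):
    rows = []
    for tp in timepoints:
        for rep in range(1, n_pairs + 1):
            rows.append((f"pc_{tp}_r{rep}", "primed_control", tp, rep, f"{tp}_p{rep}"))
            rows.append((f"tr_{tp}_r{rep}", "treated", tp, rep, f"{tp}_p{rep}"))
        for cond in extra_conditions:
            short = "vc" if cond == "vehicle_control" else "ex"
            for rep in range(1, n_pairs + 1):
                rows.append((f"{short}_{tp}_r{rep}", cond, tp, rep, ""))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "timepoint",
                                       "replicate", "pair_id"])


@pytest.fixture
def sheet_frame():
    return make_sheet_frame()


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic experiment at the study-condition defaults."""
    cfg = ms.SyntheticConfig(seed=7)
    matrix, sheet, truth = ms.generate_dataset(cfg)
    return cfg, matrix, sheet, truth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_dataset):
    """A full from-raw pipeline run on the default synthetic experiment."""
    cfg_s, *_ = default_dataset
    base = tmp_path_factory.mktemp("default_run")
    paths = ms.write_fixture(cfg_s, base / "fix")
    cfg = ms.PipelineConfig(counts=str(paths["counts"]),
                            sample_sheet=str(paths["samples"]),
                            output_dir=str(base / "out"))
    report = ms.run_pipeline(cfg)
    return cfg, paths, report


def read_truth(path) -> ms.SyntheticTruth:
    # keep_default_na=False: the planted label "null" must stay a string
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ms.SyntheticTruth(dict(zip(frame["protein_id"], frame["label"])))


def read_assignments(path, timepoint, thresholds=None) -> ms.ClassAssignmentTable:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return ms.ClassAssignmentTable(
        frame=frame, timepoint=ms.Timepoint(timepoint),
        thresholds=thresholds or ms.SignificanceThresholds())
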