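"""Detection patterns, class rules, inventory merging, category summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mitoscreen as ms
from mitoscreen.classify import ClassifyError, UNCATEGORIZED
from mitoscreen.ingest import Timepoint, sample_sheet_from_frame

from conftest import make_sheet_frame

TH = ms.SignificanceThresholds()


def sheet_4h():
    return sample_sheet_from_frame(make_sheet_frame(timepoints=("4h",)))


def detection(detected_rows, proteins):
    samples = [f"{c}_4h_r{i}" for c in ("pc", "tr", "vc", "ex") for i in (1, 2, 3)]
    detected = pd.DataFrame(detected_rows, index=proteins, columns=samples,
                            dtype=bool)
    counts = detected.astype(int) * 10
    return ms.DetectionMatrix(detected=detected, censored_counts=counts,
                              min_spectra=4)


class TestDetectionPattern:
    def test_extract_only_pattern(self):
        # seen in extract and treated only: the hallmark of an ooplasmic binder
        dm = detection([[0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1]], ["MVPLIKE"])
        pat = ms.detection_pattern(dm, sheet_4h(), Timepoint.H4)
        row = pat.loc["MVPLIKE"]
        assert not row["in_vehicle_control"] and not row["in_primed_control"]
        assert row["in_extract"] and row["in_treated"]

    def test_ubiquitous_protein_is_not_extract_only(self):
        dm = detection([[1] * 12], ["P"])
        row = ms.detection_pattern(dm, sheet_4h(), Timepoint.H4).loc["P"]
        assert row.all()

    def test_presence_min_threshold_semantics(self):
        dm = detection([[0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0]], ["P"])  # 2/3 treated
        strict = ms.detection_pattern(dm, sheet_4h(), Timepoint.H4, presence_min=3)
        loose = ms.detection_pattern(dm, sheet_4h(), Timepoint.H4, presence_min=1)
        assert not strict.loc["P", "in_treated"]
        assert loose.loc["P", "in_treated"]

    def test_presence_min_out_of_range(self):
        dm = detection([[1] * 12], ["P"])
        with pytest.raises(ClassifyError):
            ms.detection_pattern(dm, sheet_4h(), Timepoint.H4, presence_min=4)


EXTRACT_ONLY = {"in_vehicle_control": False, "in_primed_control": False,
                "in_extract": True, "in_treated": True}
IN_SPERM = {"in_vehicle_control": True, "in_primed_control": True,
            "in_extract": False, "in_treated": True}


class TestAssignClass:
    def test_extract_only_admitted_at_loosened_alpha(self):
        klass, alpha = ms.assign_class(EXTRACT_ONLY, 0.15, "increase", TH)
        assert (klass, alpha) == ("class1", 0.2)

    def test_significant_increase_on_sperm_is_class2(self):
        klass, alpha = ms.assign_class(IN_SPERM, 0.015, "increase", TH)
        assert (klass, alpha) == ("class2", 0.1)

    def test_significant_decrease_on_sperm_is_class3(self):
        klass, alpha = ms.assign_class(IN_SPERM, 0.035, "decrease", TH)
        assert (klass, alpha) == ("class3", 0.1)

    def test_both_gametes_decrease_is_class3(self):
        pattern = dict(IN_SPERM, in_extract=True)
        klass, _ = ms.assign_class(pattern, 0.05, "decrease", TH)
        assert klass == "class3"

    def test_insignificant_decrease_unclassified(self):
        klass, alpha = ms.assign_class(IN_SPERM, 0.5, "decrease", TH)
        assert klass == "unclassified"
        assert math.isnan(alpha)

    def test_class1_blocked_by_any_sperm_control_detection(self):
        seen_in_primed = dict(EXTRACT_ONLY, in_primed_control=True)
        klass, _ = ms.assign_class(seen_in_primed, 1e-9, "increase", TH)
        assert klass != "class1"

    def test_extract_only_above_loosened_alpha_unclassified(self):
        klass, _ = ms.assign_class(EXTRACT_ONLY, 0.25, "increase", TH)
        assert klass == "unclassified"

    @given(vc=st.booleans(), pc=st.booleans(), ex=st.booleans(), tr=st.booleans(),
           p=st.floats(0, 1), direction=st.sampled_from(["increase", "decrease", "none"]))
    def test_exactly_one_label_and_alpha_monotonicity(self, vc, pc, ex, tr, p,
                                                      direction):
        pattern = {"in_vehicle_control": vc, "in_primed_control": pc,
                   "in_extract": ex, "in_treated": tr}
        klass, _ = ms.assign_class(pattern, p, direction, TH)
        assert klass in ("class1", "class2", "class3", "unclassified")
        if klass == "class1":
            assert not pc and not vc
        # enlarging the class-2/3 threshold never removes a class2/3 label
        looser = ms.SignificanceThresholds(class23_alpha=0.2, class1_alpha=0.2)
        klass_loose, _ = ms.assign_class(pattern, p, direction, looser)
        if klass in ("class2", "class3"):
            assert klass_loose == klass


def assignments(timepoint, labelled, th=TH):
    rows = [(pid, timepoint, klass, 0.05, "decrease", 0.1)
            for pid, klass in labelled]
    frame = pd.DataFrame(rows, columns=["protein_id", "timepoint", "klass",
                                        "p_value", "direction", "admitted_alpha"])
    return ms.ClassAssignmentTable(frame=frame, timepoint=Timepoint(timepoint),
                                   thresholds=th)


class TestBuildInventory:
    def test_inclusion_exclusion_on_printed_sizes(self):
        # 144 and 63 with 22 shared -> union 185
        a4 = assignments("4h", [(f"P{i}", "class3") for i in range(144)])
        a24 = assignments("24h", [(f"P{i}", "class3") for i in range(122, 185)])
        inv = ms.build_inventory(a4, a24)
        assert inv.totals == dict(inv.totals, n_4h=144, n_24h=63,
                                  n_overlap=22, n_union=185)

    def test_disjoint_sets(self):
        inv = ms.build_inventory(
            assignments("4h", [("A", "class2"), ("B", "class3")]),
            assignments("24h", [("C", "class1"), ("D", "class3"), ("E", "class2")]))
        assert inv.totals["n_union"] == 5
        assert inv.totals["n_overlap"] == 0

    def test_identical_sets(self):
        members = [("A", "class2"), ("B", "class3")]
        inv = ms.build_inventory(assignments("4h", members),
                                 assignments("24h", members))
        assert inv.totals["n_union"] == inv.totals["n_overlap"] == 2
        assert inv.entries["overlap"].all()

    def test_unclassified_proteins_excluded(self):
        inv = ms.build_inventory(
            assignments("4h", [("A", "class2"), ("B", "unclassified")]),
            assignments("24h", []))
        assert inv.members("4h") == {"A"}

    def test_protein_may_change_class_between_timepoints(self):
        inv = ms.build_inventory(assignments("4h", [("A", "class2")]),
                                 assignments("24h", [("A", "class3")]))
        entry = inv.entries.set_index("protein_id").loc["A"]
        assert entry["class_4h"] == "class2" and entry["class_24h"] == "class3"
        assert entry["overlap"]

    def test_threshold_mismatch_rejected(self):
        other = ms.SignificanceThresholds(0.05, 0.2)
        with pytest.raises(ClassifyError, match="threshold"):
            ms.build_inventory(assignments("4h", []),
                               assignments("24h", [], th=other))


class TestCategoryFrequencies:
    def test_percentages_round_half_up(self):
        # 15 of 108 class-3 proteins annotated as tail proteins -> 14%
        members = [(f"P{i}", "class3") for i in range(108)]
        annot = {f"P{i}": "tail" for i in range(15)}
        inv = ms.build_inventory(assignments("4h", members),
                                 assignments("24h", []), annotations=annot)
        table = ms.category_frequencies(inv, annot)
        tail = table[(table["timepoint"] == "4h") & (table["category"] == "tail")]
        assert tail["count"].item() == 15
        assert tail["percent"].item() == 14

    def test_empty_class_produces_no_rows_and_no_error(self):
        inv = ms.build_inventory(assignments("4h", []), assignments("24h", []))
        assert len(ms.category_frequencies(inv)) == 0

    def test_single_category_is_100_percent(self):
        members = [("A", "class2"), ("B", "class2")]
        annot = {"A": "proteasome", "B": "proteasome"}
        inv = ms.build_inventory(assignments("4h", members),
                                 assignments("24h", []), annotations=annot)
        table = ms.category_frequencies(inv, annot)
        assert table["percent"].tolist() == [100]

    def test_unannotated_fall_into_uncategorized(self):
        inv = ms.build_inventory(assignments("4h", [("A", "class2")]),
                                 assignments("24h", []))
        table = ms.category_frequencies(inv)
        assert table["category"].tolist() == [UNCATEGORIZED]

    def test_counts_sum_to_class_size_and_percents_to_100ish(self):
        members = [(f"P{i}", "class3") for i in range(7)]
        annot = {"P0": "tail", "P1": "tail", "P2": "mito"}
        inv = ms.build_inventory(assignments("4h", members),
                                 assignments("24h", []), annotations=annot)
        table = ms.category_frequencies(inv, annot)
        sub = table[(table["timepoint"] == "4h") & (table["klass"] == "class3")]
        assert sub["count"].sum() == 7
        assert abs(sub["percent"].sum() - 100) <= len(sub)  # rounding slack
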