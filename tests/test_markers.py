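"""Marker curation and mutual cross-link consistency validation."""

import pytest

from clasp import (CrossLink, LocalizationMarker, augment_candidates,
                   auto_select_candidates, consistency_percentage,
                   normalize_location, read_annotations, validate_candidates)
from clasp.errors import InputError
from clasp.markers import DEFAULT_MITO_VOCAB


def _lm(acc, comp, length=100):
    return LocalizationMarker(acc, [(1, length, comp)], source="manual")


class TestConsistencyPercentage:
    def test_printed_count_arithmetic(self):
        # 4502 marker-marker links with 12 contradictions -> 99.7%
        assert round(consistency_percentage(4502, 12), 1) == 99.7
        assert round(consistency_percentage(7209, 21), 1) == 99.7

    def test_no_links_is_fully_consistent(self):
        assert consistency_percentage(0, 0) == 100.0

    def test_invalid_counts(self):
        with pytest.raises(InputError):
            consistency_percentage(10, 11)


class TestNormalizeLocation:
    def test_single_term(self):
        assert normalize_location("SUBCELLULAR LOCATION: Mitochondrion matrix.",
                                  DEFAULT_MITO_VOCAB) == ["matrix"]

    def test_multiple_terms(self):
        text = "Mitochondrion inner membrane; Mitochondrion outer membrane"
        assert set(normalize_location(text, DEFAULT_MITO_VOCAB)) == {"IMM", "OMM"}

    def test_longest_phrase_wins(self):
        # "inner membrane" must not also count as a bare membrane hit
        assert normalize_location("Mitochondrion intermembrane space",
                                  DEFAULT_MITO_VOCAB) == ["IMS"]

    def test_empty(self):
        assert normalize_location(None, DEFAULT_MITO_VOCAB) == []


AUTO_FIXTURE = """Entry\tLength\tSubcellular location [CC]\tTransmembrane\tTopological domain
M1\t100\tSUBCELLULAR LOCATION: Mitochondrion matrix.\t\t
M2\t80\tSUBCELLULAR LOCATION: Mitochondrion intermembrane space.\t\t
M3\t90\tSUBCELLULAR LOCATION: Mitochondrion inner membrane; Mitochondrion outer membrane.\t\t
M4\t120\tSUBCELLULAR LOCATION: Mitochondrion inner membrane.\tTRANSMEM 40..60; /note="Helical"\tTOPO_DOM 61..120; /note="Matrix side"
M5\t70\tSUBCELLULAR LOCATION: Mitochondrion matrix. Note=May relocate.\t\t
M6\t60\t\t\t
"""


class TestAutoSelect:
    def test_fixture_matches_hand_derived_expectation(self, tmp_path, mito):
        path = tmp_path / "sp.tsv"
        path.write_text(AUTO_FIXTURE)
        candidates, excluded = auto_select_candidates(read_annotations(path), mito)
        by_acc = {c.accession: c for c in candidates}
        # M1/M2: unequivocal soluble -> full-length marker
        assert by_acc["M1"].regions == ((1, 100, "matrix"),)
        assert by_acc["M2"].regions == ((1, 80, "IMS"),)
        # M4: membrane protein oriented by its matrix-side C-terminal domain
        assert by_acc["M4"].regions == ((1, 39, "IMS"), (61, 120, "matrix"))
        # M3 equivocal, M5 Note=-qualified, M6 unannotated
        assert set(by_acc) == {"M1", "M2", "M4"}
        assert "equivocal" in excluded["M3"]
        assert "Note=" in excluded["M5"]
        assert "no location" in excluded["M6"]


class TestValidateCandidates:
    def test_no_lm_links_all_retained(self, mito):
        cands = [_lm("A", "matrix"), _lm("B", "IMS")]
        report, validated = validate_candidates(cands, [], mito)
        assert report.consistent_fraction == 100.0
        assert [lm.accession for lm in validated] == ["A", "B"]

    def test_contradiction_removes_both_endpoints(self, mito):
        cands = [_lm("A", "matrix"), _lm("B", "IMS"), _lm("C", "matrix")]
        links = [CrossLink.create("A", 10, "B", 20),    # matrix-IMS: contradiction
                 CrossLink.create("A", 11, "C", 30)]    # matrix-matrix: fine... but A removed
        report, validated = validate_candidates(cands, links, mito)
        assert report.n_lm_links == 2
        assert len(report.contradictions) == 1
        assert report.removed_candidates == ["A", "B"]
        assert [lm.accession for lm in validated] == ["C"]
        assert round(report.consistent_fraction, 1) == 50.0

    def test_membrane_lm_residue_in_tm_segment_skipped(self, mito):
        membrane_lm = LocalizationMarker("M", [(1, 39, "IMS"), (61, 120, "matrix")])
        links = [CrossLink.create("M", 50, "S", 5)]   # residue 50 is in the TM gap
        report, _ = validate_candidates([membrane_lm, _lm("S", "matrix", 50)], links, mito)
        assert report.n_lm_links == 0
        assert report.n_skipped == 1

    def test_idempotent(self, mito, small_dataset):
        org, links, _ = small_dataset
        report1, v1 = validate_candidates(org.markers(), links, mito)
        report2, v2 = validate_candidates(v1, links, mito)
        assert v2 == v1
        assert not report2.removed_candidates

    def test_removal_never_creates_new_contradictions(self, mito):
        """The contradiction set shrinks monotonically under removal."""
        cands = [_lm("A", "matrix"), _lm("B", "IMS"), _lm("C", "IMS")]
        links = [CrossLink.create("A", 1, "B", 2), CrossLink.create("B", 3, "C", 4)]
        report, validated = validate_candidates(cands, links, mito)
        keys = {xl.key for xl, _, _ in report.contradictions}
        report2, _ = validate_candidates(validated, links, mito)
        assert {xl.key for xl, _, _ in report2.contradictions} <= keys

    def test_marker_with_unknown_compartment_rejected(self, mito):
        with pytest.raises(InputError):
            validate_candidates([_lm("A", "nucleus")], [], mito)


class TestAugment:
    def test_manual_marker_without_links_accepted(self, mito):
        base = [_lm("A", "matrix")]
        merged, rejected = augment_candidates(base, [_lm("Z", "IMS")], [], mito)
        assert {lm.accession for lm in merged} == {"A", "Z"}
        assert not rejected

    def test_readding_contradictory_marker_rejected(self, mito):
        links = [CrossLink.create("A", 10, "B", 20)]
        cands = [_lm("A", "matrix"), _lm("B", "IMS")]
        _, validated = validate_candidates(cands, links, mito)
        assert validated == []
        merged, rejected = augment_candidates(validated, [_lm("A", "matrix"),
                                                          _lm("B", "IMS")], links, mito)
        assert merged == []
        assert set(rejected) == {"A", "B"}
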