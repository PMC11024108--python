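"""Vote collection, per-region prediction, classification and the full
inference driver."""

import pytest

from clasp import (CrossLink, LocalizationMarker, Vote, build_regions,
                   collect_votes, compare_runs, predict_target, run_clasp,
                   score_predictions, validate_candidates)
from clasp.errors import InputError
from clasp.predict import AMBIGUOUS, CONFIRMS, CONTRADICTS, NOVEL, UNAMBIGUOUS


def _lm(acc, comp, length=100):
    return LocalizationMarker(acc, [(1, length, comp)])


class TestCollectVotes:
    def test_target_without_marker_links_gets_no_votes(self):
        links = [CrossLink.create("T", 1, "X", 2)]
        assert collect_votes("T", links, {"L": _lm("L", "IMS")}) == []

    def test_one_vote_per_unique_residue_pair(self):
        lms = {"L1": _lm("L1", "IMS"), "L2": _lm("L2", "IMS")}
        links = [CrossLink.create("T", 5, "L1", 9),
                 CrossLink.create("T", 6, "L1", 9),
                 CrossLink.create("T", 7, "L2", 3)]
        votes = collect_votes("T", links, lms)
        assert len(votes) == 3
        assert {v.locale for v in votes} == {"IMS"}
        assert {v.lm for v in votes} == {"L1", "L2"}

    def test_votes_via_unresolved_marker_residues_skipped(self):
        membrane_lm = LocalizationMarker("M", [(1, 39, "IMS"), (61, 120, "matrix")])
        links = [CrossLink.create("T", 5, "M", 50),   # TM residue: no locale
                 CrossLink.create("M", 70, "T", 6)]   # matrix region
        votes = collect_votes("T", links, {"M": membrane_lm})
        assert votes == [Vote(6, "M", 70, "matrix")]

    def test_intra_links_never_vote(self):
        links = [CrossLink.create("T", 5, "T", 9)]
        assert collect_votes("T", links, {"T": _lm("T", "IMS")}) == []


class TestPredictTarget:
    def test_unanimous_votes_without_prior_are_novel(self, mito):
        votes = [Vote(i, f"L{j}", 9, "IMS") for i, j in ((5, 1), (6, 1), (7, 2), (8, 3))]
        pred, = predict_target("T", votes, model=mito, length=100)
        assert pred.status == UNAMBIGUOUS
        assert pred.compartment == "IMS"
        assert pred.classification == NOVEL
        assert pred.n_supporting_lms == 3
        assert pred.region == (1, 100)

    def test_matrix_votes_against_outer_membrane_prior_contradict(self, mito):
        votes = [Vote(5, "L1", 9, "matrix"), Vote(6, "L2", 9, "matrix")]
        pred, = predict_target("T", votes, prior="OMM", model=mito, length=100)
        assert pred.classification == CONTRADICTS

    def test_matching_prior_confirms(self, mito):
        pred, = predict_target("T", [Vote(5, "L1", 9, "matrix")], prior="matrix",
                               model=mito, length=100)
        assert pred.classification == CONFIRMS

    def test_mixed_votes_are_ambiguous_and_unclassified(self, mito):
        votes = [Vote(5, "L1", 9, "matrix"), Vote(6, "L2", 9, "IMS")]
        pred, = predict_target("T", votes, model=mito, length=100)
        assert pred.status == AMBIGUOUS
        assert pred.supported == frozenset({"matrix", "IMS"})
        assert pred.classification is None

    def test_cytosol_only_votes_flag_organelle_association(self, mito):
        """A protein linked only to the cytosolic face of outer-membrane
        markers is organelle-associated, not internal."""
        pred, = predict_target("T", [Vote(5, "L1", 9, "cytosol")], model=mito, length=80)
        assert "associated" in pred.note
        assert "OMM" in pred.note

    def test_no_votes_is_an_error(self, mito):
        with pytest.raises(InputError):
            predict_target("T", [], model=mito)

    def test_membrane_target_votes_grouped_per_region(self, mito):
        topo = build_regions(120, annotated_tm=[(40, 60)], accession="T")
        votes = [Vote(10, "L1", 5, "IMS"), Vote(100, "L2", 7, "matrix")]
        preds = predict_target("T", votes, topology=topo, model=mito)
        assert [(p.region, p.compartment) for p in preds] == \
            [((1, 39), "IMS"), ((61, 120), "matrix")]

    def test_unvoted_region_inferred_by_alternation(self, mito):
        topo = build_regions(120, annotated_tm=[(40, 60)], accession="T")
        preds = predict_target("T", [Vote(100, "L2", 7, "matrix")],
                               topology=topo, model=mito)
        assert len(preds) == 2
        inferred = next(p for p in preds if p.region == (1, 39))
        assert inferred.compartment == "IMS"
        assert "alternation" in inferred.note
        assert inferred.n_supporting_lms == 0

    def test_annotated_membrane_disambiguates_alternation(self, mito):
        """IMS-only votes fit both membranes; naming the host membrane
        lets alternation complete the unvoted regions."""
        topo = build_regions(180, annotated_tm=[(50, 70), (110, 130)], accession="T")
        votes = [Vote(150, "L1", 40, "IMS")]
        without = predict_target("T", votes, topology=topo, model=mito)
        assert len(without) == 1  # membrane ambiguous: nothing inferred
        with_host = predict_target("T", votes, topology=topo, model=mito,
                                   membrane="IMM")
        by_region = {p.region: p.compartment for p in with_host}
        # even TM count: both termini in the IMS, middle region in the matrix
        assert by_region == {(1, 49): "IMS", (71, 109): "matrix", (131, 180): "IMS"}

    def test_votes_inside_tm_segments_excluded(self, mito):
        topo = build_regions(120, annotated_tm=[(40, 60)], accession="T")
        votes = [Vote(50, "L1", 5, "IMS"), Vote(100, "L2", 7, "matrix")]
        preds = predict_target("T", votes, topology=topo, model=mito)
        assert all(40 > v.target_residue or v.target_residue > 60
                   for p in preds for v in p.votes)

    def test_all_votes_in_tm_segments_is_an_error(self, mito):
        topo = build_regions(120, annotated_tm=[(40, 60)], accession="T")
        with pytest.raises(InputError):
            predict_target("T", [Vote(50, "L1", 5, "IMS")], topology=topo, model=mito)


class TestRunClasp:
    def test_noise_free_simulation_recovers_ground_truth(self, mito, small_dataset,
                                                         small_annotations):
        org, links, _ = small_dataset
        _, validated = validate_candidates(org.markers(), links, mito)
        result = run_clasp(links, validated, mito, annotations=small_annotations)
        scores = score_predictions(org, result.predictions)
        assert scores["accuracy_pct"] == 100.0
        assert scores["unambiguous_pct"] == 100.0

    def test_empty_crosslink_set_is_fatal(self, mito):
        with pytest.raises(InputError):
            run_clasp([], [_lm("L", "IMS")], mito)

    def test_empty_marker_set_is_fatal(self, mito):
        with pytest.raises(InputError):
            run_clasp([CrossLink.create("A", 1, "B", 2)], [], mito)

    def test_deterministic_over_reruns(self, mito, small_dataset):
        org, links, _ = small_dataset
        _, validated = validate_candidates(org.markers(), links, mito)
        a = run_clasp(links, validated, mito)
        b = run_clasp(links, validated, mito)
        assert a.predictions == b.predictions
        assert a.summary == b.summary

    def test_evidence_only_from_markers(self, mito, small_dataset):
        org, links, _ = small_dataset
        _, validated = validate_candidates(org.markers(), links, mito)
        lm_accs = {lm.accession for lm in validated}
        result = run_clasp(links, validated, mito)
        for p in result.predictions:
            assert {v.lm for v in p.votes} <= lm_accs
            assert not set(p.consistent_neighbors) & lm_accs

    def test_adding_a_marker_only_adds_votes(self, mito):
        links = [CrossLink.create("T", 5, "L1", 9), CrossLink.create("T", 6, "L2", 9),
                 CrossLink.create("L1", 1, "L2", 2)]
        base = [_lm("L1", "IMS")]
        more = base + [_lm("L2", "IMS")]
        r1 = run_clasp(links, base, mito, min_component_size=2)
        r2 = run_clasp(links, more, mito, min_component_size=2)

        def votes_for_t(result):
            return {v for p in result.predictions if p.accession == "T"
                    for v in p.votes}

        assert votes_for_t(r1) <= votes_for_t(r2)
        # the agreeing second marker does not change the call
        t1, = [p for p in r1.predictions if p.accession == "T"]
        t2, = [p for p in r2.predictions if p.accession == "T"]
        assert t1.compartment == t2.compartment == "IMS"
        assert t2.n_supporting_lms > t1.n_supporting_lms

    def test_summary_counts_are_consistent(self, mito, small_dataset):
        org, links, _ = small_dataset
        _, validated = validate_candidates(org.markers(), links, mito)
        s = run_clasp(links, validated, mito).summary
        assert s["n_unambiguous"] <= s["n_predictions"]
        cls = s["classification_counts"]
        assert sum(cls.values()) <= s["n_predictions"]


class TestCompareRuns:
    def test_identical_sets_agree_fully(self, mito, small_dataset):
        org, links, _ = small_dataset
        _, validated = validate_candidates(org.markers(), links, mito)
        preds = run_clasp(links, validated, mito).predictions
        report = compare_runs(preds, preds)
        assert report["agreement_pct"] == 100.0
        assert report["n_common"] == report["n_agreeing"]

    def test_disjoint_sets_have_empty_overlap(self, mito):
        a = run_clasp([CrossLink.create("T", 5, "L1", 9)], [_lm("L1", "IMS")],
                      mito, min_component_size=2).predictions
        b = run_clasp([CrossLink.create("U", 5, "L2", 9)], [_lm("L2", "IMS")],
                      mito, min_component_size=2).predictions
        report = compare_runs(a, b)
        assert report["n_common"] == 0
        assert report["agreement_pct"] is None

    def test_two_noise_seeds_agreement_matches_hand_scan(self, mito, small_organelle):
        from clasp import simulate_crosslinks
        org = small_organelle
        results = []
        for seed in (101, 202):
            links, _ = simulate_crosslinks(org, 800, noise_rate=0.05, seed=seed)
            _, validated = validate_candidates(org.markers(), links, mito)
            results.append(run_clasp(links, validated, mito).predictions)
        report = compare_runs(*results)

        def profile(preds, acc):
            rows = [p for p in preds if p.accession == acc]
            if not all(r.status == UNAMBIGUOUS for r in rows):
                return None
            return tuple(sorted((r.region, r.compartment) for r in rows))

        accs = ({p.accession for p in results[0]} & {p.accession for p in results[1]})
        hand = {a: profile(results[0], a) == profile(results[1], a)
                for a in accs
                if profile(results[0], a) is not None and profile(results[1], a) is not None}
        assert report["per_protein"] == hand
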