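"""Localization markers: curation, auto-selection and consistency
validation.

A localization marker (LM) is a protein — or, for a membrane protein, a
set of soluble regions — whose aqueous-compartment assignment is firmly
established.  Markers are the source of the spatial votes that propagate
through the cross-link network.  Before use, candidate markers are
validated against each other: every cross-link between two candidate
residues must join residues of the same aqueous compartment; candidates
touching a contradictory link are removed (either endpoint could be
mislocalized or the identification could be a false positive, so both are
suspect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import InputError
from .io import CrossLink, ProteinAnnotation, TMPrediction
from .model import CompartmentGraph, may_crosslink
from . import topology as topo_mod

logger = logging.getLogger("clasp")


@dataclass(frozen=True)
class LocalizationMarker:
    """A protein (or membrane-protein region set) with established
    localization.

    ``regions`` lists ``(start, end, aqueous compartment)`` for the
    soluble parts of the protein; a soluble marker has one region
    spanning the whole sequence.  Residues outside every region (TM
    segments) carry no locale and are excluded from voting.
    """

    accession: str
    regions: Tuple[Tuple[int, int, str], ...]
    source: str = "manual"
    evidence: str = ""

    def __init__(self, accession, regions, source="manual", evidence=""):
        object.__setattr__(self, "accession", str(accession))
        object.__setattr__(self, "regions", tuple(
            (int(s), int(e), str(c)) for s, e, c in regions
        ))
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "evidence", evidence)
        for s, e, _ in self.regions:
            if not 1 <= s <= e:
                raise InputError(f"invalid marker region ({s}, {e}) for {accession}")

    @property
    def is_membrane(self) -> bool:
        return len(self.regions) > 1

    def locale_of(self, residue: int) -> Optional[str]:
        """Compartment of the marker region containing ``residue``; None
        for residues in TM segments or outside all regions."""
        for s, e, comp in self.regions:
            if s <= residue <= e:
                return comp
        return None

    def validate_against(self, model: CompartmentGraph) -> None:
        for _, _, comp in self.regions:
            if comp not in model or not model.is_aqueous(comp):
                raise InputError(
                    f"marker {self.accession}: {comp!r} is not an aqueous "
                    f"compartment of the model"
                )


# ---------------------------------------------------------------------------
# Location-text vocabulary
# ---------------------------------------------------------------------------

#: Controlled vocabulary mapping Swiss-Prot location phrases to
#: compartments of the mitochondrial model (longest match wins).
DEFAULT_MITO_VOCAB: Dict[str, str] = {
    "mitochondrion matrix": "matrix",
    "mitochondrion intermembrane space": "IMS",
    "mitochondrion inner membrane": "IMM",
    "mitochondrion outer membrane": "OMM",
    "cytoplasm": "cytosol",
    "cytosol": "cytosol",
}

#: Side phrases used by TOPO_DOM notes.
DEFAULT_SIDE_VOCAB: Dict[str, str] = {
    "mitochondrial matrix": "matrix",
    "matrix": "matrix",
    "mitochondrial intermembrane": "IMS",
    "intermembrane": "IMS",
    "cytoplasmic": "cytosol",
    "cytosolic": "cytosol",
    "vesicular lumen": "lumen",
    "lumenal": "lumen",
    "lumen": "lumen",
}


def normalize_location(text: Optional[str], vocab: Mapping[str, str]) -> List[str]:
    """Compartments named in a free-text location, longest phrase first.

    Returns the distinct matched compartments in order of appearance.
    """
    if not text:
        return []
    low = str(text).lower()
    hits: List[Tuple[int, str]] = []
    for phrase in sorted(vocab, key=len, reverse=True):
        start = low.find(phrase)
        if start >= 0 and not any(s <= start < s + len(p) for s, p in hits):
            hits.append((start, phrase))
    out: List[str] = []
    for _, phrase in sorted(hits):
        comp = vocab[phrase]
        if comp not in out:
            out.append(comp)
    return out


def _side_of_note(note: str, side_vocab: Mapping[str, str]) -> Optional[str]:
    low = note.lower()
    for phrase in sorted(side_vocab, key=len, reverse=True):
        if phrase in low:
            return side_vocab[phrase]
    return None


# ---------------------------------------------------------------------------
# Auto-selection
# ---------------------------------------------------------------------------

def auto_select_candidates(
    annotations: Mapping[str, ProteinAnnotation],
    model: CompartmentGraph,
    vocab: Optional[Mapping[str, str]] = None,
    side_vocab: Optional[Mapping[str, str]] = None,
    tm_predictions: Optional[Mapping[str, TMPrediction]] = None,
) -> Tuple[List[LocalizationMarker], Dict[str, str]]:
    """Select marker candidates from unequivocal database annotations.

    A soluble candidate needs a location text naming exactly one aqueous
    compartment of the model and no TM features.  A membrane candidate
    needs a single membrane location, TM features, and topological-domain
    notes that orient the topology completely.  Everything else is
    excluded, with the reason reported per accession; entries carrying a
    ``Note=`` qualifier are treated as equivocal.
    """
    vocab = vocab or DEFAULT_MITO_VOCAB
    side_vocab = side_vocab or DEFAULT_SIDE_VOCAB
    candidates: List[LocalizationMarker] = []
    excluded: Dict[str, str] = {}
    for acc in sorted(annotations):
        ann = annotations[acc]
        if not ann.location_text:
            excluded[acc] = "no location annotation"
            continue
        if "note=" in ann.location_text.lower():
            excluded[acc] = "equivocal (Note= qualifier)"
            continue
        comps = normalize_location(ann.location_text, vocab)
        comps = [c for c in comps if c in model]
        if not comps:
            excluded[acc] = "no recognized compartment term"
            continue
        if len(comps) > 1:
            excluded[acc] = "equivocal (multiple compartment terms)"
            continue
        comp = comps[0]
        pred_segments = ()
        if tm_predictions and acc in tm_predictions:
            pred_segments = tm_predictions[acc].segments
        if model.is_aqueous(comp):
            if ann.tm_features:
                excluded[acc] = "aqueous location but TM features annotated"
                continue
            candidates.append(LocalizationMarker(
                acc, [(1, ann.length, comp)], source="auto",
                evidence=str(ann.location_text)))
            continue
        # Membrane location: needs an orientable topology.
        if not ann.tm_features and not pred_segments:
            excluded[acc] = "membrane location without TM features"
            continue
        topo = topo_mod.build_regions(ann.length, pred_segments, ann.tm_features,
                                      accession=acc)
        anchors = []
        for s, e, note in ann.topo_domains:
            side = _side_of_note(note, side_vocab)
            if side is None or side not in model:
                continue
            mid = (s + e) // 2
            idx = topo.soluble_index_of(mid) if 1 <= mid <= ann.length else None
            if idx is not None:
                anchors.append((idx, side))
        if not anchors:
            excluded[acc] = "membrane protein without orientable side notes"
            continue
        oriented = topo_mod.orient(topo, anchors, model.sides(comp))
        if oriented.conflicts or oriented.orientation_state != topo_mod.FULL:
            excluded[acc] = "membrane topology could not be fully oriented"
            continue
        regions = [(r.start, r.end, r.compartment) for r in oriented.soluble_regions]
        candidates.append(LocalizationMarker(acc, regions, source="auto",
                                             evidence=str(ann.location_text)))
    for acc, reason in excluded.items():
        logger.debug("auto-selection excluded %s: %s", acc, reason)
    return candidates, excluded


# ---------------------------------------------------------------------------
# Consistency validation
# ---------------------------------------------------------------------------

def consistency_percentage(n_links: int, n_contradictions: int) -> float:
    """Percentage of marker-marker links consistent with the known
    marker localizations: 100 * (n - contradictions) / n."""
    if n_links < 0 or not 0 <= n_contradictions <= max(n_links, 0):
        raise InputError("contradiction count must lie in [0, n_links]")
    if n_links == 0:
        return 100.0
    return 100.0 * (n_links - n_contradictions) / n_links


@dataclass
class ConsistencyReport:
    """Outcome of mutual cross-link validation of marker candidates."""

    n_lm_links: int
    contradictions: List[Tuple[CrossLink, Optional[str], Optional[str]]]
    removed_candidates: List[str]
    n_skipped: int = 0

    @property
    def consistent_fraction(self) -> float:
        return consistency_percentage(self.n_lm_links, len(self.contradictions))

    def to_dict(self) -> dict:
        return {
            "n_lm_links": self.n_lm_links,
            "n_contradictions": len(self.contradictions),
            "consistent_fraction_pct": round(self.consistent_fraction, 1),
            "removed_candidates": self.removed_candidates,
            "n_links_skipped": self.n_skipped,
            "contradictions": [
                {"protein_a": xl.protein_a, "residue_a": xl.residue_a,
                 "protein_b": xl.protein_b, "residue_b": xl.residue_b,
                 "locale_a": la, "locale_b": lb}
                for xl, la, lb in self.contradictions
            ],
        }


def validate_candidates(
    candidates: Iterable[LocalizationMarker],
    crosslinks: Iterable[CrossLink],
    model: CompartmentGraph,
) -> Tuple[ConsistencyReport, List[LocalizationMarker]]:
    """Check every candidate-candidate cross-link for compartment
    agreement and drop all candidates touching a contradiction.

    Links whose endpoint falls inside a TM segment of a marker are
    skipped from the tally with a warning.  Idempotent: validating the
    validated set again removes nothing.
    """
    by_acc: Dict[str, LocalizationMarker] = {}
    for lm in candidates:
        lm.validate_against(model)
        by_acc[lm.accession] = lm
    n_links = 0
    n_skipped = 0
    contradictions: List[Tuple[CrossLink, Optional[str], Optional[str]]] = []
    for xl in crosslinks:
        a = by_acc.get(xl.protein_a)
        b = by_acc.get(xl.protein_b)
        if a is None or b is None:
            continue
        la = a.locale_of(xl.residue_a)
        lb = b.locale_of(xl.residue_b)
        if la is None or lb is None:
            n_skipped += 1
            logger.debug("marker link %s skipped: endpoint in TM segment", xl.key)
            continue
        n_links += 1
        if may_crosslink(la, lb, model) is False:
            contradictions.append((xl, la, lb))
    removed = sorted({acc for xl, _, _ in contradictions
                      for acc in (xl.protein_a, xl.protein_b)})
    validated = [by_acc[acc] for acc in sorted(by_acc) if acc not in removed]
    report = ConsistencyReport(n_links, contradictions, removed, n_skipped)
    logger.info("marker validation: %d links, %d contradictions (%.1f%% consistent), "
                "%d candidates removed", n_links, len(contradictions),
                report.consistent_fraction, len(removed))
    return report, validated


def augment_candidates(
    validated: Iterable[LocalizationMarker],
    manual: Iterable[LocalizationMarker],
    crosslinks: Iterable[CrossLink],
    model: CompartmentGraph,
) -> Tuple[List[LocalizationMarker], Dict[str, list]]:
    """Merge manually supplied markers into a validated set and
    re-validate the union.

    Manual entries replace auto entries with the same accession.  Any
    marker whose addition creates a contradiction is rejected, with the
    conflicting links reported per accession.
    """
    combined: Dict[str, LocalizationMarker] = {lm.accession: lm for lm in validated}
    for lm in manual:
        combined[lm.accession] = lm
    links = list(crosslinks)
    report, kept = validate_candidates(combined.values(), links, model)
    rejected: Dict[str, list] = {}
    for xl, la, lb in report.contradictions:
        for acc in (xl.protein_a, xl.protein_b):
            rejected.setdefault(acc, []).append((xl, la, lb))
    return kept, rejected
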