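"""Localization inference: propagate marker locales through direct
cross-links.

Every unique residue pair between a target protein and a localization
marker casts one *vote*: the aqueous compartment of the marker residue.
Because the cross-linker cannot bridge a membrane, the target residue
must share that compartment.  For soluble targets the votes address the
whole protein; for membrane targets they address the soluble region
containing the linked residue, and region-level assignments are then
completed by membrane-side alternation.  A prediction is unambiguous
when all its votes name a single compartment; unambiguous predictions
are classified against the prior annotation as confirming,
contradicting, or novel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .errors import InputError
from .io import CrossLink, ProteinAnnotation, TMPrediction
from .markers import (LocalizationMarker, DEFAULT_MITO_VOCAB, DEFAULT_SIDE_VOCAB,
                      normalize_location, _side_of_note)
from .model import CompartmentGraph, MEMBRANE_EMBEDDED
from .network import XLNetwork, build_network, coverage, filter_network, first_tier
from . import topology as topo_mod
from .topology import Topology

logger = logging.getLogger("clasp")

UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"

CONFIRMS = "confirms"
CONTRADICTS = "contradicts"
NOVEL = "novel"


@dataclass(frozen=True)
class Vote:
    """One marker-derived locale assignment for one target residue."""

    target_residue: int
    lm: str
    lm_residue: int
    locale: str


@dataclass(frozen=True)
class Prediction:
    """Inferred compartment set for one protein or protein region."""

    accession: str
    region: Optional[Tuple[int, int]]
    supported: frozenset
    status: str
    votes: Tuple[Vote, ...] = ()
    classification: Optional[str] = None
    n_supporting_lms: int = 0
    note: str = ""
    consistent_neighbors: Tuple[str, ...] = ()

    @property
    def compartment(self) -> Optional[str]:
        """The single supported compartment, when unambiguous."""
        if len(self.supported) == 1:
            return next(iter(self.supported))
        return None


def collect_votes(
    target: str,
    crosslinks: Iterable[CrossLink],
    lms: Mapping[str, LocalizationMarker],
) -> List[Vote]:
    """One vote per unique residue pair joining the target to a marker.

    Votes through marker residues that are membrane-embedded or
    unoriented are skipped with a log entry.
    """
    votes: List[Vote] = []
    n_skipped = 0
    for xl in crosslinks:
        if xl.is_intra:
            continue
        if xl.protein_a == target and xl.protein_b in lms:
            tgt_res, lm_acc, lm_res = xl.residue_a, xl.protein_b, xl.residue_b
        elif xl.protein_b == target and xl.protein_a in lms:
            tgt_res, lm_acc, lm_res = xl.residue_b, xl.protein_a, xl.residue_a
        else:
            continue
        locale = lms[lm_acc].locale_of(lm_res)
        if locale is None:
            n_skipped += 1
            continue
        votes.append(Vote(tgt_res, lm_acc, lm_res, locale))
    if n_skipped:
        logger.debug("%s: %d marker link(s) skipped (residue without aqueous locale)",
                     target, n_skipped)
    return sorted(votes, key=lambda v: (v.lm, v.lm_residue, v.target_residue))


def _classify(supported: frozenset, status: str, prior: Optional[str]) -> Optional[str]:
    if status != UNAMBIGUOUS:
        return None
    if prior is None:
        return NOVEL
    return CONFIRMS if supported == frozenset({prior}) else CONTRADICTS


def _prediction_from_votes(accession, region, votes, prior) -> Prediction:
    supported = frozenset(v.locale for v in votes)
    status = UNAMBIGUOUS if len(supported) == 1 else AMBIGUOUS
    return Prediction(
        accession=accession,
        region=region,
        supported=supported,
        status=status,
        votes=tuple(votes),
        classification=_classify(supported, status, prior),
        n_supporting_lms=len({v.lm for v in votes}),
    )


def _infer_membrane(supported_locales: Set[str], model: CompartmentGraph) -> Optional[str]:
    """The unique membrane whose two sides cover all vote locales."""
    hits = [m for m in model.membranes
            if supported_locales <= set(model.sides(m))]
    return hits[0] if len(hits) == 1 else None


def predict_target(
    target: str,
    votes: Sequence[Vote],
    topology: Optional[Topology] = None,
    prior: Optional[str] = None,
    model: Optional[CompartmentGraph] = None,
    length: Optional[int] = None,
    prior_topology: Optional[Topology] = None,
    membrane: Optional[str] = None,
) -> List[Prediction]:
    """Turn votes for one target into region-level predictions.

    Soluble targets yield one prediction over the whole sequence.  For
    membrane targets the votes are grouped per soluble region; regions
    without votes are completed by side alternation once the voted
    regions fix the orientation.  ``prior`` is the annotated compartment
    of a soluble target; ``prior_topology`` carries annotated region
    sides for membrane targets; ``membrane`` names the annotated host
    membrane, which disambiguates side alternation when the votes alone
    are compatible with more than one membrane.
    """
    if not votes:
        raise InputError(f"no votes for target {target}")

    if topology is None or not topology.is_membrane:
        if length is None and topology is not None:
            length = topology.length
        region = (1, length) if length else None
        pred = _prediction_from_votes(target, region, list(votes), prior)
        if (model is not None and prior is None
                and pred.supported == frozenset({model.aqueous[0]})):
            # Linked only to the cytosolic face of outer-membrane markers:
            # an organelle-associated protein rather than an internal one.
            pred = replace(pred, note=(
                f"associated ({model.membranes[0]}, {model.aqueous[0]}-facing)"))
        return [pred]

    # Membrane target: group votes by soluble region.
    groups: Dict[int, List[Vote]] = {}
    n_excluded = 0
    for v in votes:
        idx = topology.soluble_index_of(v.target_residue)
        if idx is None:
            n_excluded += 1
            continue
        groups.setdefault(idx, []).append(v)
    if n_excluded:
        logger.warning("%s: %d vote(s) addressed residues inside TM segments; excluded",
                       target, n_excluded)
    if not groups:
        raise InputError(f"all votes for {target} fall inside TM segments")

    def region_prior(sol: topo_mod.SolubleRegion) -> Optional[str]:
        if prior_topology is None:
            return None
        mid = (sol.start + sol.end) // 2
        try:
            loc = prior_topology.locale_of(mid)
        except InputError:
            return None
        return None if loc == MEMBRANE_EMBEDDED else loc

    sols = topology.soluble_regions
    preds: List[Prediction] = []
    anchors: List[Tuple[int, str]] = []
    for idx in sorted(groups):
        sol = sols[idx]
        pred = _prediction_from_votes(target, (sol.start, sol.end), groups[idx],
                                      region_prior(sol))
        preds.append(pred)
        if pred.status == UNAMBIGUOUS:
            anchors.append((idx, pred.compartment))

    sides = None
    if model is not None and anchors:
        anchor_comps = {c for _, c in anchors}
        host = None
        if membrane is not None and anchor_comps <= set(model.sides(membrane)):
            host = membrane
        else:
            host = _infer_membrane(anchor_comps, model)
        if host is not None:
            sides = model.sides(host)
    oriented = topo_mod.orient(topology, anchors, sides) if anchors else topology
    if oriented.conflicts:
        preds = [replace(p, note=(p.note + "; " if p.note else "") + "topology conflict")
                 for p in preds]
        return preds
    for idx, sol in enumerate(oriented.soluble_regions):
        if idx in groups or sol.compartment is None:
            continue
        supported = frozenset({sol.compartment})
        preds.append(Prediction(
            accession=target,
            region=(sol.start, sol.end),
            supported=supported,
            status=UNAMBIGUOUS,
            classification=_classify(supported, UNAMBIGUOUS, region_prior(sols[idx])),
            note="inferred by membrane-side alternation",
        ))
    preds.sort(key=lambda p: p.region or (0, 0))
    return preds


# ---------------------------------------------------------------------------
# Whole-pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class ClaspResult:
    """Everything one inference run produces."""

    network: XLNetwork
    filtered_network: XLNetwork
    filter_report: dict
    first_tier: List[str]
    predictions: List[Prediction]
    summary: dict


def _annotation_prior(ann: Optional[ProteinAnnotation], model: CompartmentGraph,
                      vocab: Mapping[str, str]) -> Optional[str]:
    if ann is None or not ann.location_text:
        return None
    if "note=" in str(ann.location_text).lower():
        return None
    comps = [c for c in normalize_location(ann.location_text, vocab) if c in model]
    return comps[0] if len(comps) == 1 else None


def _annotation_topology(ann: Optional[ProteinAnnotation], model: CompartmentGraph,
                         side_vocab: Mapping[str, str]) -> Optional[Topology]:
    """Topology with annotated region sides, for classifying membrane
    predictions against the prior annotation."""
    if ann is None or not ann.tm_features:
        return None
    topo = topo_mod.build_regions(ann.length, (), ann.tm_features, accession=ann.accession)
    anchors = []
    for s, e, note in ann.topo_domains:
        side = _side_of_note(note, side_vocab)
        mid = (s + e) // 2
        if side is None or side not in model or not 1 <= mid <= ann.length:
            continue
        idx = topo.soluble_index_of(mid)
        if idx is not None:
            anchors.append((idx, side))
    if not anchors:
        return None
    return topo_mod.orient(topo, anchors)


def run_clasp(
    crosslinks: Sequence[CrossLink],
    lms: Iterable[LocalizationMarker],
    model: CompartmentGraph,
    annotations: Optional[Mapping[str, ProteinAnnotation]] = None,
    tm_predictions: Optional[Mapping[str, TMPrediction]] = None,
    topologies: Optional[Mapping[str, Topology]] = None,
    min_component_size: int = 3,
    vocab: Optional[Mapping[str, str]] = None,
    side_vocab: Optional[Mapping[str, str]] = None,
) -> ClaspResult:
    """Run the full inference: network, filtering, first tier, votes,
    region predictions, classification and summary.

    ``lms`` must already be consistency-validated.  Inference is fully
    deterministic: no randomness anywhere, stable sort orders throughout.
    """
    crosslinks = list(crosslinks)
    lm_map: Dict[str, LocalizationMarker] = {}
    for lm in lms:
        lm.validate_against(model)
        lm_map[lm.accession] = lm
    if not crosslinks:
        raise InputError("empty cross-link set: nothing to predict from")
    if not lm_map:
        raise InputError("empty validated marker set: predictions are impossible")
    vocab = vocab or DEFAULT_MITO_VOCAB
    side_vocab = side_vocab or DEFAULT_SIDE_VOCAB
    annotations = annotations or {}

    net = build_network(crosslinks)
    for n in net.nodes():
        net.nodes[n]["is_lm"] = n in lm_map
    filtered, report = filter_network(net, min_component_size)
    tier = sorted(first_tier(filtered, set(lm_map)))
    cov = coverage(filtered, set(lm_map)) if filtered.number_of_nodes() else 0.0

    by_protein: Dict[str, List[CrossLink]] = {}
    for xl in crosslinks:
        if xl.is_intra:
            continue
        by_protein.setdefault(xl.protein_a, []).append(xl)
        by_protein.setdefault(xl.protein_b, []).append(xl)

    predictions: List[Prediction] = []
    n_targets = 0
    for target in tier:
        votes = collect_votes(target, by_protein.get(target, ()), lm_map)
        if not votes:
            continue
        ann = annotations.get(target)
        topo = topologies.get(target) if topologies else None
        if topo is None and ann is not None:
            pred_segs = ()
            if tm_predictions and target in tm_predictions:
                pred_segs = tm_predictions[target].segments
            if ann.tm_features or pred_segs:
                topo = topo_mod.build_regions(ann.length, pred_segs, ann.tm_features,
                                              accession=target)
        prior = _annotation_prior(ann, model, vocab)
        prior_topo = _annotation_topology(ann, model, side_vocab)
        membrane = prior if (prior is not None and prior in model
                             and not model.is_aqueous(prior)) else None
        length = ann.length if ann is not None else None
        try:
            preds = predict_target(target, votes, topology=topo, prior=prior,
                                   model=model, length=length,
                                   prior_topology=prior_topo, membrane=membrane)
        except InputError as exc:
            logger.warning("no prediction for %s: %s", target, exc)
            continue
        n_targets += 1
        predictions.extend(preds)

    # Corroborating non-marker neighbors: one propagation round only.
    comp_of: Dict[str, str] = {}
    for p in predictions:
        if p.status == UNAMBIGUOUS and (p.region is None or not _is_partial(p, predictions)):
            comp_of.setdefault(p.accession, p.compartment)
    final: List[Prediction] = []
    for p in predictions:
        if p.status == UNAMBIGUOUS and filtered.has_node(p.accession):
            neighbors = tuple(sorted(
                nb for nb in filtered.neighbors(p.accession)
                if nb not in lm_map and nb != p.accession
                and comp_of.get(nb) == p.compartment
            ))
            p = replace(p, consistent_neighbors=neighbors)
        final.append(p)
    predictions = sorted(final, key=lambda p: (p.accession, p.region or (0, 0)))

    n_unamb = sum(p.status == UNAMBIGUOUS for p in predictions)
    cls_counts = {c: sum(p.classification == c for p in predictions)
                  for c in (CONFIRMS, CONTRADICTS, NOVEL)}
    summary = {
        "n_crosslinks": len(crosslinks),
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_nodes_filtered": filtered.number_of_nodes(),
        "n_edges_filtered": filtered.number_of_edges(),
        "n_lms": len(lm_map),
        "n_first_tier": len(tier),
        "coverage_pct": round(cov, 1),
        "n_targets_predicted": n_targets,
        "n_predictions": len(predictions),
        "n_unambiguous": n_unamb,
        "unambiguous_pct": round(100.0 * n_unamb / len(predictions), 1) if predictions else None,
        "classification_counts": cls_counts,
        "n_membrane_region_predictions": sum(
            1 for p in predictions if p.region is not None and _is_partial(p, predictions)
        ),
    }
    return ClaspResult(net, filtered, report, tier, predictions, summary)


def _is_partial(p: Prediction, all_preds: Sequence[Prediction]) -> bool:
    """True when the prediction covers one region of a multi-region target."""
    return sum(q.accession == p.accession for q in all_preds) > 1


def compare_runs(predictions_a: Sequence[Prediction],
                 predictions_b: Sequence[Prediction]) -> dict:
    """Agreement between two prediction sets on proteins both localized
    unambiguously.

    A protein counts as unambiguously localized when every one of its
    region predictions is unambiguous; agreement requires identical
    region-to-compartment profiles.
    """
    def profiles(preds: Sequence[Prediction]) -> Dict[str, tuple]:
        by_acc: Dict[str, List[Prediction]] = {}
        for p in preds:
            by_acc.setdefault(p.accession, []).append(p)
        out = {}
        for acc, rows in by_acc.items():
            if all(r.status == UNAMBIGUOUS for r in rows):
                out[acc] = tuple(sorted((r.region, r.compartment) for r in rows))
        return out

    pa, pb = profiles(predictions_a), profiles(predictions_b)
    common = sorted(set(pa) & set(pb))
    per_protein = {acc: pa[acc] == pb[acc] for acc in common}
    n_agree = sum(per_protein.values())
    return {
        "n_unambiguous_a": len(pa),
        "n_unambiguous_b": len(pb),
        "n_common": len(common),
        "n_agreeing": n_agree,
        "agreement_pct": round(100.0 * n_agree / len(common), 1) if common else None,
        "per_protein": per_protein,
    }
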