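"""Membrane-protein region structure and orientation.

A topology partitions a protein sequence into alternating soluble regions
and transmembrane (TM) segments.  TM segments come from database
annotation and/or a TM predictor's posterior probabilities; soluble
regions are the complement.  Orientation assigns each soluble region to
one of the two aqueous sides of the membrane, alternating across every TM
segment.  A single anchored region therefore orients the whole chain, and
a protein with an even number of TM segments has both termini on the same
side while an odd count puts them on opposite sides.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from .errors import InputError, ModelError
from .model import MEMBRANE_EMBEDDED

HIGH = "high"
POTENTIAL = "potential"
SOLUBLE = "soluble"
ANNOTATED = "annotated"

UNORIENTED = "unoriented"
PARTIAL = "partial"
FULL = "full"

# Posterior-probability cutoffs for TM-helix confidence classes.
TM_HIGH_CUTOFF = 0.75
TM_SOLUBLE_CUTOFF = 0.037


def classify_tm(posterior: float) -> str:
    """Confidence class of a predicted TM segment from its posterior.

    > 0.75 is a high-confidence TM, 0.037-0.75 a potential TM, and below
    0.037 the segment is treated as soluble.
    """
    if not 0.0 <= posterior <= 1.0:
        raise InputError(f"posterior probability must lie in [0, 1], got {posterior}")
    if posterior > TM_HIGH_CUTOFF:
        return HIGH
    if posterior < TM_SOLUBLE_CUTOFF:
        return SOLUBLE
    return POTENTIAL


@dataclass
class TMSegment:
    start: int
    end: int
    confidence: str = ANNOTATED


@dataclass
class SolubleRegion:
    start: int
    end: int
    compartment: Optional[str] = None


Region = Union[TMSegment, SolubleRegion]


@dataclass
class Topology:
    """Alternating soluble/TM partition of one protein sequence."""

    accession: str
    length: int
    regions: List[Region] = field(default_factory=list)
    orientation_state: str = UNORIENTED
    conflicts: List[tuple] = field(default_factory=list)
    discrepancy: Optional[dict] = None

    @property
    def tm_segments(self) -> List[TMSegment]:
        return [r for r in self.regions if isinstance(r, TMSegment)]

    @property
    def soluble_regions(self) -> List[SolubleRegion]:
        return [r for r in self.regions if isinstance(r, SolubleRegion)]

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)

    @property
    def is_membrane(self) -> bool:
        return self.tm_count > 0

    def region_at(self, residue: int) -> Region:
        if residue < 1 or residue > self.length:
            raise InputError(
                f"residue {residue} outside [1, {self.length}] for {self.accession}"
            )
        for r in self.regions:
            if r.start <= residue <= r.end:
                return r
        raise AssertionError("regions do not tile the sequence")  # pragma: no cover

    def locale_of(self, residue: int) -> Optional[str]:
        """Aqueous compartment of ``residue``; MEMBRANE_EMBEDDED inside a
        TM segment; None in an unoriented soluble region."""
        r = self.region_at(residue)
        if isinstance(r, TMSegment):
            return MEMBRANE_EMBEDDED
        return r.compartment

    def soluble_index_of(self, residue: int) -> Optional[int]:
        """Index into ``soluble_regions`` containing ``residue``; None if
        the residue sits inside a TM segment."""
        r = self.region_at(residue)
        if isinstance(r, TMSegment):
            return None
        return self.soluble_regions.index(r)

    def soluble_parities(self) -> List[int]:
        """Number of TM segments preceding each soluble region, mod 2."""
        parities, n_tm = [], 0
        for r in self.regions:
            if isinstance(r, TMSegment):
                n_tm += 1
            else:
                parities.append(n_tm % 2)
        return parities


def _check_intervals(intervals: Iterable[Tuple[int, int]], length: int, what: str) -> list:
    out = []
    for s, e in intervals:
        if not (1 <= s <= e <= length):
            raise InputError(f"{what} interval ({s}, {e}) outside [1, {length}]")
        out.append((int(s), int(e)))
    return sorted(out)


def _merge(intervals: Sequence[Tuple[int, int]]) -> list:
    """Union of 1-based inclusive intervals; touching intervals merge."""
    merged: list = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_regions(
    length: int,
    predicted_tm: Sequence[tuple] = (),
    annotated_tm: Sequence[Tuple[int, int]] = (),
    accession: str = "",
) -> Topology:
    """Partition ``[1, length]`` into soluble and TM regions (unoriented).

    ``predicted_tm`` holds ``(start, end, posterior)`` triples from a TM
    predictor; segments classified soluble (posterior < 0.037) are
    dropped, high and potential segments are kept.  ``annotated_tm`` holds
    database TM intervals.  Overlapping or touching segments merge.  When
    the merged segment count disagrees in parity with the annotation
    alone, the annotation wins and the discarded prediction is recorded in
    ``Topology.discrepancy`` (parity decides which side each terminus
    faces, so it must not be changed silently by a low-confidence
    prediction).
    """
    if length < 1:
        raise InputError(f"protein length must be positive, got {length}")
    ann = _check_intervals(annotated_tm, length, "annotated TM")
    pred = []
    for item in predicted_tm:
        if len(item) == 3:
            s, e, post = item
            cls = classify_tm(float(post))
            if cls == SOLUBLE:
                continue
        else:
            s, e = item
            cls = HIGH
        pred.append(((int(s), int(e)), cls))
    _check_intervals([iv for iv, _ in pred], length, "predicted TM")

    merged = _merge(list(ann) + [iv for iv, _ in pred])
    discrepancy = None
    if ann and len(merged) % 2 != len(_merge(ann)) % 2:
        discrepancy = {"annotated": list(ann), "predicted": [iv for iv, _ in pred]}
        merged = _merge(ann)
        pred = []

    def confidence(seg: Tuple[int, int]) -> str:
        s, e = seg
        if any(a[0] <= e and s <= a[1] for a in ann):
            return ANNOTATED
        classes = {c for (ps, pe), c in pred if ps <= e and s <= pe}
        return HIGH if HIGH in classes else POTENTIAL

    regions: List[Region] = []
    cursor = 1
    for s, e in merged:
        if s > cursor:
            regions.append(SolubleRegion(cursor, s - 1))
        regions.append(TMSegment(s, e, confidence(( s, e))))
        cursor = e + 1
    if cursor <= length:
        regions.append(SolubleRegion(cursor, length))
    topo = Topology(accession=accession, length=length, regions=regions,
                    discrepancy=discrepancy)
    if not topo.tm_segments:
        topo.orientation_state = UNORIENTED
    return topo


AnchorRef = Union[int, Tuple[int, int], SolubleRegion]


def _resolve_anchor(topology: Topology, ref: AnchorRef) -> int:
    sols = topology.soluble_regions
    if isinstance(ref, SolubleRegion):
        ref = (ref.start, ref.end)
    if isinstance(ref, tuple):
        for i, r in enumerate(sols):
            if (r.start, r.end) == ref:
                return i
        raise InputError(f"no soluble region {ref} in {topology.accession}")
    i = int(ref)
    if not 0 <= i < len(sols):
        raise InputError(f"soluble region index {i} out of range for {topology.accession}")
    return i


def orient(
    topology: Topology,
    anchors: Iterable[Tuple[AnchorRef, str]],
    sides: Optional[Tuple[str, str]] = None,
) -> Topology:
    """Orient soluble regions from anchored compartment assignments.

    ``anchors`` pairs a soluble region (index, ``(start, end)`` interval
    or the region object) with an aqueous compartment.  ``sides`` names
    the two aqueous compartments flanking the protein's membrane (from
    :meth:`CompartmentGraph.sides`); with it, one consistent anchor
    propagates to every soluble region by side alternation across TM
    segments.  Without it only the anchored regions are set.  Conflicting
    anchors leave the topology flagged via ``Topology.conflicts``.
    """
    t = copy.deepcopy(topology)
    sols = t.soluble_regions
    resolved = sorted({(_resolve_anchor(t, ref), comp) for ref, comp in anchors})
    seen: dict = {}
    for i, comp in resolved:
        if seen.setdefault(i, comp) != comp:
            t.conflicts = resolved
            t.orientation_state = PARTIAL
            return t

    if sides is not None:
        side_a, side_b = sides
        if side_a == side_b:
            raise ModelError("the two membrane sides must differ")
        for _, comp in resolved:
            if comp not in (side_a, side_b):
                raise ModelError(
                    f"anchor compartment {comp!r} is not a side of this membrane"
                )
        parities = t.soluble_parities()
        bases = {(list(sides).index(comp) - parities[i]) % 2 for i, comp in resolved}
        if len(bases) > 1:
            t.conflicts = resolved
            for i, comp in resolved:  # keep the local evidence, flag globally
                sols[i].compartment = comp
            t.orientation_state = PARTIAL
            return t
        if bases:
            base = bases.pop()
            for i, r in enumerate(sols):
                r.compartment = sides[(base + parities[i]) % 2]
            t.orientation_state = FULL
            return t
        t.orientation_state = UNORIENTED
        return t

    for i, comp in resolved:
        sols[i].compartment = comp
    assigned = sum(r.compartment is not None for r in sols)
    t.orientation_state = (
        FULL if assigned == len(sols) else PARTIAL if assigned else UNORIENTED
    )
    return t


def soluble_topology(accession: str, length: int, compartment: Optional[str]) -> Topology:
    """Topology of a protein with no TM segment: one soluble region."""
    t = Topology(accession=accession, length=length,
                 regions=[SolubleRegion(1, length, compartment)])
    t.orientation_state = FULL if compartment is not None else UNORIENTED
    return t
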