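"""Synthetic organelles and distance-consistent cross-link datasets.

The generator builds a ground-truth organelle: proteins with known
compartment (soluble) or fully oriented membrane topology (1-6 TM
segments), simulated lysine sites (~7% of positions, mirroring the
lysine-reactive chemistry of DSSO/DSBSO-class cross-linkers), and a
designated marker subset.  Cross-links are then sampled only between
lysines sharing an aqueous compartment, plus a configurable noise
fraction that violates this rule.  Every file the simulator writes uses
the exact dialect the readers accept, so simulated datasets double as
end-to-end fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CrossLink, ProteinAnnotation, dedupe_crosslinks, write_crosslinks, write_lm_table
from .markers import LocalizationMarker
from .model import CompartmentGraph, default_mito_model
from .predict import Prediction, UNAMBIGUOUS
from .topology import SolubleRegion, Topology, build_regions, orient, soluble_topology

TM_LEN = 21          # residues per simulated TM helix
MIN_SOLUBLE = 15     # minimum soluble stretch between/flanking TMs
LYSINE_FRACTION = 0.07

#: Location phrases written into simulated annotation tables, the inverse
#: of the marker module's location vocabulary.
MITO_LOCATION_PHRASES = {
    "matrix": "Mitochondrion matrix",
    "IMS": "Mitochondrion intermembrane space",
    "cytosol": "Cytoplasm",
    "OMM": "Mitochondrion outer membrane",
    "IMM": "Mitochondrion inner membrane",
}
MITO_SIDE_PHRASES = {
    "matrix": "Mitochondrial matrix",
    "IMS": "Mitochondrial intermembrane",
    "cytosol": "Cytoplasmic",
}


@dataclass
class SimProtein:
    """One simulated protein with ground-truth topology and lysine sites."""

    accession: str
    length: int
    topology: Topology          # fully oriented; soluble proteins have one region
    is_lm: bool
    lysines: Tuple[int, ...]

    @property
    def is_membrane(self) -> bool:
        return self.topology.is_membrane

    @property
    def compartment(self) -> Optional[str]:
        """Compartment of a soluble protein (None for membrane proteins)."""
        if self.is_membrane:
            return None
        return self.topology.soluble_regions[0].compartment

    def locale_of(self, residue: int) -> Optional[str]:
        return self.topology.locale_of(residue)


@dataclass
class SyntheticOrganelle:
    """Ground-truth organelle: model, proteins, designated markers."""

    model: CompartmentGraph
    proteins: List[SimProtein]
    seed: int

    @property
    def by_accession(self) -> Dict[str, SimProtein]:
        return {p.accession: p for p in self.proteins}

    def locale(self, accession: str, residue: int) -> Optional[str]:
        return self.by_accession[accession].locale_of(residue)

    def markers(self) -> List[LocalizationMarker]:
        """Ground-truth localization markers for the designated subset."""
        out = []
        for p in self.proteins:
            if not p.is_lm:
                continue
            regions = [(r.start, r.end, r.compartment)
                       for r in p.topology.soluble_regions]
            out.append(LocalizationMarker(p.accession, regions, source="manual",
                                          evidence="simulated ground truth"))
        return out


def _membrane_topology(rng: np.random.Generator, accession: str, length: int,
                       membrane: str, model: CompartmentGraph) -> Topology:
    n_tm = int(rng.integers(1, 7))
    need = n_tm * TM_LEN + (n_tm + 1) * MIN_SOLUBLE
    length = max(length, need)
    # Spread the spare soluble residues evenly across the n_tm+1 stretches.
    spare = length - need
    extras = [spare // (n_tm + 1)] * (n_tm + 1)
    extras[0] += spare - sum(extras)
    tms = []
    cursor = 1
    for i in range(n_tm):
        cursor += MIN_SOLUBLE + extras[i]
        tms.append((cursor, cursor + TM_LEN - 1))
        cursor += TM_LEN
    topo = build_regions(length, (), tms, accession=accession)
    base = int(rng.integers(0, 2))
    sides = model.sides(membrane)
    anchored = orient(topo, [(0, sides[base])], sides)
    return anchored


def generate_organelle(
    n_proteins: int = 200,
    lm_fraction: float = 0.25,
    membrane_fraction: float = 0.3,
    model: Optional[CompartmentGraph] = None,
    seed: int = 0,
    lysine_fraction: float = LYSINE_FRACTION,
    length_range: Tuple[int, int] = (120, 600),
    compartment_weights: Optional[Sequence[float]] = None,
) -> SyntheticOrganelle:
    """Generate a reproducible ground-truth organelle.

    Soluble proteins draw their compartment from the model's aqueous
    compartments (uniformly unless ``compartment_weights`` is given);
    membrane proteins draw a membrane and receive 1-6 oriented TM
    segments.  Each aqueous compartment is guaranteed at least one
    marker so that localization inference has an anchor everywhere.
    """
    if n_proteins < 2:
        raise InputError("need at least 2 proteins")
    for frac, name in ((lm_fraction, "lm_fraction"),
                       (membrane_fraction, "membrane_fraction")):
        if not 0.0 <= frac <= 1.0:
            raise InputError(f"{name} must lie in [0, 1]")
    model = model or default_mito_model()
    aqueous = model.aqueous
    weights = np.asarray(compartment_weights if compartment_weights is not None
                         else [1.0] * len(aqueous), dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)

    proteins: List[SimProtein] = []
    for i in range(n_proteins):
        acc = f"SIM{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if rng.random() < membrane_fraction:
            membrane = model.membranes[int(rng.integers(len(model.membranes)))]
            topo = _membrane_topology(rng, acc, length, membrane, model)
            length = topo.length
        else:
            comp = aqueous[int(rng.choice(len(aqueous), p=weights))]
            topo = soluble_topology(acc, length, comp)
        lys_mask = rng.random(length) < lysine_fraction
        lysines = set((np.flatnonzero(lys_mask) + 1).tolist())
        for r in topo.soluble_regions:   # every soluble region needs a linkable site
            if not any(r.start <= k <= r.end for k in lysines):
                lysines.add((r.start + r.end) // 2)
        proteins.append(SimProtein(acc, length, topo,
                                   bool(rng.random() < lm_fraction),
                                   tuple(sorted(lysines))))

    # Guarantee at least one marker region per aqueous compartment.
    for comp in aqueous:
        if any(p.is_lm and any(r.compartment == comp for r in p.topology.soluble_regions)
               for p in proteins):
            continue
        for p in proteins:
            if any(r.compartment == comp for r in p.topology.soluble_regions):
                p.is_lm = True
                break
    if not any(p.is_lm for p in proteins):
        proteins[0].is_lm = True
    return SyntheticOrganelle(model, proteins, seed)


def _site_pools(org: SyntheticOrganelle) -> Dict[str, List[Tuple[str, int]]]:
    """Per aqueous compartment: all (accession, lysine) sites in soluble
    regions of that compartment."""
    pools: Dict[str, List[Tuple[str, int]]] = {c: [] for c in org.model.aqueous}
    for p in org.proteins:
        for r in p.topology.soluble_regions:
            pool = pools[r.compartment]
            pool.extend((p.accession, k) for k in p.lysines if r.start <= k <= r.end)
    return pools


def simulate_crosslinks(
    org: SyntheticOrganelle,
    n_links: int = 3000,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> Tuple[List[CrossLink], pd.DataFrame]:
    """Sample unique residue pairs obeying the same-compartment rule,
    plus ``noise_rate`` of membrane-violating pairs.

    Returns the deduplicated links and a truth table recording each
    link's endpoint compartments and whether it violates the rule.
    """
    if not 0.0 <= noise_rate < 1.0:
        raise InputError("noise_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    pools = _site_pools(org)
    usable = {c: pool for c, pool in pools.items() if len(pool) >= 2}
    for c in org.model.aqueous:
        if c not in usable:
            import logging
            logging.getLogger("clasp").warning(
                "compartment %s has fewer than 2 linkable sites; skipped", c)
    if not usable:
        raise InputError("no compartment has enough linkable sites")
    comps = sorted(usable)
    sizes = np.array([len(usable[c]) for c in comps], dtype=float)
    probs = sizes / sizes.sum()

    n_noise = int(round(n_links * noise_rate))
    n_good = n_links - n_noise
    seen = set()
    records = []

    def add(site_a, site_b) -> bool:
        (pa, ra), (pb, rb) = site_a, site_b
        if (pa, ra) == (pb, rb):
            return False
        xl = CrossLink.create(pa, ra, pb, rb)
        if xl.key in seen:
            return False
        seen.add(xl.key)
        la = org.locale(xl.protein_a, xl.residue_a)
        lb = org.locale(xl.protein_b, xl.residue_b)
        records.append({
            "protein_a": xl.protein_a, "residue_a": xl.residue_a,
            "protein_b": xl.protein_b, "residue_b": xl.residue_b,
            "compartment_a": la, "compartment_b": lb,
            "violating": la != lb,
        })
        return True

    max_attempts = 200 * n_links + 1000
    attempts = 0
    n_added = 0
    while n_added < n_good and attempts < max_attempts:
        attempts += 1
        c = comps[int(rng.choice(len(comps), p=probs))]
        pool = usable[c]
        i, j = rng.choice(len(pool), size=2, replace=False)
        if add(pool[int(i)], pool[int(j)]):
            n_added += 1
    if n_added < n_good:
        raise InputError("could not sample the requested number of consistent links")

    n_added = 0
    while n_added < n_noise and attempts < max_attempts:
        attempts += 1
        if len(comps) < 2:
            raise InputError("noise links need at least two usable compartments")
        ca, cb = rng.choice(len(comps), size=2, replace=False)
        site_a = usable[comps[int(ca)]][int(rng.integers(len(usable[comps[int(ca)]])))]
        site_b = usable[comps[int(cb)]][int(rng.integers(len(usable[comps[int(cb)]])))]
        if add(site_a, site_b):
            n_added += 1
    if n_added < n_noise:
        raise InputError("could not sample the requested number of noise links")

    links = dedupe_crosslinks(
        CrossLink.create(r["protein_a"], r["residue_a"], r["protein_b"], r["residue_b"])
        for r in records
    )
    truth = pd.DataFrame(records).sort_values(
        ["protein_a", "residue_a", "protein_b", "residue_b"]
    ).reset_index(drop=True)
    return links, truth


# ---------------------------------------------------------------------------
# File emission (reader-dialect fixtures)
# ---------------------------------------------------------------------------

def organelle_annotations(
    org: SyntheticOrganelle,
    annotated_fraction: float = 0.6,
    seed: int = 0,
    location_phrases: Optional[Dict[str, str]] = None,
    side_phrases: Optional[Dict[str, str]] = None,
) -> Dict[str, ProteinAnnotation]:
    """Swiss-Prot-style annotations for the organelle.

    Marker proteins always get a full annotation (location, TRANSMEM and
    TOPO_DOM features) so automatic marker selection can recover them.
    Membrane proteins always carry their TRANSMEM intervals — TM presence
    is obtainable for any protein from sequence-based prediction, and it
    is the orientation that inference must supply.  Of the non-marker
    proteins, only ``annotated_fraction`` get a location text; the rest
    stand in for previously unmapped proteins.
    """
    rng = np.random.default_rng(seed)
    location_phrases = location_phrases or MITO_LOCATION_PHRASES
    side_phrases = side_phrases or MITO_SIDE_PHRASES
    out: Dict[str, ProteinAnnotation] = {}
    for p in org.proteins:
        annotated = p.is_lm or rng.random() < annotated_fraction
        loc = None
        tms: List[Tuple[int, int]] = []
        topos: List[Tuple[int, int, str]] = []
        if p.is_membrane:
            tms = [(t.start, t.end) for t in p.topology.tm_segments]
        if annotated:
            if p.is_membrane:
                membrane = _membrane_of(p, org.model)
                loc = f"SUBCELLULAR LOCATION: {location_phrases[membrane]}."
                if p.is_lm:
                    topos = [
                        (r.start, r.end, f"{side_phrases[r.compartment]} side")
                        for r in p.topology.soluble_regions
                    ]
            else:
                loc = f"SUBCELLULAR LOCATION: {location_phrases[p.compartment]}."
        out[p.accession] = ProteinAnnotation(p.accession, p.length, loc, tms, topos)
    return out


def _membrane_of(p: SimProtein, model: CompartmentGraph) -> str:
    sides = {r.compartment for r in p.topology.soluble_regions}
    for m in model.membranes:
        if sides <= set(model.sides(m)):
            return m
    raise AssertionError(f"{p.accession}: region sides match no membrane")  # pragma: no cover


def annotations_to_tsv(annotations: Dict[str, ProteinAnnotation], path) -> None:
    rows = []
    for acc in sorted(annotations):
        ann = annotations[acc]
        feats = [f'TRANSMEM {s}..{e}; /note="Helical"' for s, e in ann.tm_features]
        topo = [f'TOPO_DOM {s}..{e}; /note="{note}"' for s, e, note in ann.topo_domains]
        rows.append({
            "Entry": acc,
            "Length": ann.length,
            "Subcellular location [CC]": ann.location_text or "",
            "Transmembrane": "; ".join(feats),
            "Topological domain": "; ".join(topo),
        })
    pd.DataFrame(rows, columns=["Entry", "Length", "Subcellular location [CC]",
                                "Transmembrane", "Topological domain"]).to_csv(
        Path(path), sep="\t", index=False)


def write_simulation(org: SyntheticOrganelle, links, truth: pd.DataFrame,
                     outdir, annotated_fraction: float = 0.6) -> Dict[str, Path]:
    """Write links.csv, annotations.tsv, lms.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "links": outdir / "links.csv",
        "annotations": outdir / "annotations.tsv",
        "lms": outdir / "lms.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_crosslinks(links, paths["links"])
    annotations_to_tsv(
        organelle_annotations(org, annotated_fraction, seed=org.seed), paths["annotations"]
    )
    write_lm_table(org.markers(), paths["lms"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Ground-truth scoring
# ---------------------------------------------------------------------------

def score_predictions(org: SyntheticOrganelle, predictions: Sequence[Prediction]) -> dict:
    """Compare predictions to the generator's ground truth.

    A region prediction is correct when its supported set is exactly the
    true compartment of that region.  Returns accuracy and unambiguous
    percentages over all prediction rows.
    """
    by_acc = org.by_accession
    n = n_correct = n_unamb = 0
    for p in predictions:
        prot = by_acc.get(p.accession)
        if prot is None:
            continue
        residue = p.region[0] if p.region else 1
        true = prot.locale_of(residue)
        n += 1
        n_correct += p.supported == frozenset({true})
        n_unamb += p.status == UNAMBIGUOUS
    if n == 0:
        raise InputError("no prediction addresses a simulated protein")
    return {
        "n_predictions": n,
        "accuracy_pct": 100.0 * n_correct / n,
        "unambiguous_pct": 100.0 * n_unamb / n,
    }
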