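"""Readers and writers for every external table the tool touches.

Cross-link tables (CSV/TSV with configurable column dialects, XlinkX-style
defaults), Swiss-Prot annotation TSVs, TMHMM-style TM prediction tables,
localization-marker tables, prediction tables, PDB structures plus residue
mapping tables, and GraphML/SIF network exports.

Conventions: residue coordinates are 1-based and intervals inclusive on
both ends (the Swiss-Prot feature convention); accessions are opaque keys
(isoform suffixes are not stripped).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, ParseError

logger = logging.getLogger("clasp")


# ---------------------------------------------------------------------------
# Cross-links
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossLink:
    """One unique cross-linked residue pair.

    Canonically ordered so that ``(protein_a, residue_a) <=
    (protein_b, residue_b)``; build instances through :meth:`create` to
    get the ordering for free.  ``n_csm`` counts the spectra supporting
    the pair; identity is the residue pair itself.
    """

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    score: Optional[float] = None
    n_csm: Optional[int] = None

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise InputError("residue positions are 1-based and must be >= 1")
        if (self.protein_a, self.residue_a) > (self.protein_b, self.residue_b):
            raise InputError("cross-link endpoints must be in canonical order; use CrossLink.create")
        if self.n_csm is not None and self.n_csm < 1:
            raise InputError("n_csm must be a positive integer")

    @classmethod
    def create(cls, protein_a: str, residue_a: int, protein_b: str, residue_b: int,
               score: Optional[float] = None, n_csm: Optional[int] = None) -> "CrossLink":
        a = (str(protein_a), int(residue_a))
        b = (str(protein_b), int(residue_b))
        if a > b:
            a, b = b, a
        return cls(a[0], a[1], b[0], b[1], score, n_csm)

    @property
    def is_intra(self) -> bool:
        return self.protein_a == self.protein_b

    @property
    def key(self) -> tuple:
        return (self.protein_a, self.residue_a, self.protein_b, self.residue_b)


#: Default column mapping for XlinkX-style exports.  Override any entry to
#: ingest MeroX or generic CSV layouts.
DEFAULT_XL_DIALECT: Dict[str, str] = {
    "protein_a": "Protein A",
    "residue_a": "Residue A",
    "protein_b": "Protein B",
    "residue_b": "Residue B",
    "score": "Score",
    "n_csm": "CSMs",
}

_OPTIONAL_XL_FIELDS = ("score", "n_csm")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def dedupe_crosslinks(links: Iterable[CrossLink]) -> List[CrossLink]:
    """Collapse duplicate unique residue pairs.

    CSM counts are summed; of conflicting scores the maximum is kept
    (conservative retention of the best evidence).
    """
    out: Dict[tuple, CrossLink] = {}
    for xl in links:
        prev = out.get(xl.key)
        if prev is None:
            out[xl.key] = xl
            continue
        n_csm = None
        if prev.n_csm is not None or xl.n_csm is not None:
            n_csm = (prev.n_csm or 0) + (xl.n_csm or 0)
        score = None
        scores = [s for s in (prev.score, xl.score) if s is not None]
        if scores:
            score = max(scores)
        out[xl.key] = CrossLink(*xl.key, score=score, n_csm=n_csm)
    return [out[k] for k in sorted(out)]


def read_crosslinks(path, dialect: Optional[Mapping[str, str]] = None,
                    sep: Optional[str] = None) -> List[CrossLink]:
    """Read a cross-link table into deduplicated, canonically ordered
    unique residue pairs."""
    path = Path(path)
    mapping = dict(DEFAULT_XL_DIALECT)
    mapping.update(dialect or {})
    df = pd.read_csv(path, sep=sep or _sep_for(path))
    for fld in ("protein_a", "residue_a", "protein_b", "residue_b"):
        col = mapping[fld]
        if col not in df.columns:
            raise ConfigError(
                f"cross-link table {path.name} is missing column {col!r} (mapped to {fld})"
            )
    links: List[CrossLink] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based plus header line
        try:
            ra = int(row[mapping["residue_a"]])
            rb = int(row[mapping["residue_b"]])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path.name} line {line_no}: residue positions must be integers"
            ) from None
        score = None
        if mapping["score"] in df.columns and pd.notna(row[mapping["score"]]):
            score = float(row[mapping["score"]])
        n_csm = None
        if mapping["n_csm"] in df.columns and pd.notna(row[mapping["n_csm"]]):
            n_csm = int(row[mapping["n_csm"]])
        try:
            links.append(CrossLink.create(row[mapping["protein_a"]], ra,
                                          row[mapping["protein_b"]], rb, score, n_csm))
        except InputError as exc:
            raise ParseError(f"{path.name} line {line_no}: {exc}") from None
    unique = dedupe_crosslinks(links)
    n_intra = sum(xl.is_intra for xl in unique)
    logger.info("%s: %d rows -> %d unique residue pairs (%d intra, %d inter)",
                path.name, len(links), len(unique), n_intra, len(unique) - n_intra)
    return unique


def write_crosslinks(links: Sequence[CrossLink], path,
                     dialect: Optional[Mapping[str, str]] = None) -> None:
    path = Path(path)
    mapping = dict(DEFAULT_XL_DIALECT)
    mapping.update(dialect or {})
    rows = []
    for xl in links:
        row = {
            mapping["protein_a"]: xl.protein_a,
            mapping["residue_a"]: xl.residue_a,
            mapping["protein_b"]: xl.protein_b,
            mapping["residue_b"]: xl.residue_b,
        }
        if xl.score is not None:
            row[mapping["score"]] = xl.score
        if xl.n_csm is not None:
            row[mapping["n_csm"]] = xl.n_csm
        rows.append(row)
    cols = [mapping[f] for f in ("protein_a", "residue_a", "protein_b", "residue_b")]
    for f in _OPTIONAL_XL_FIELDS:
        if any(mapping[f] in r for r in rows):
            cols.append(mapping[f])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Protein annotations (Swiss-Prot-style TSV)
# ---------------------------------------------------------------------------

@dataclass
class ProteinAnnotation:
    """Swiss-Prot-style localization and membrane-feature annotation."""

    accession: str
    length: int
    location_text: Optional[str] = None
    tm_features: List[Tuple[int, int]] = field(default_factory=list)
    topo_domains: List[Tuple[int, int, str]] = field(default_factory=list)


_TRANSMEM_RE = re.compile(r"TRANSMEM\s+(\d+)\.\.(\d+)")
_TOPO_DOM_RE = re.compile(r'TOPO_DOM\s+(\d+)\.\.(\d+);\s*/note="([^"]+)"')
_FEATURE_TOKEN_RE = re.compile(r"(TRANSMEM|TOPO_DOM)\s+\S+")

_ANNOTATION_COLUMNS = {
    "accession": ("Entry", "accession", "Accession"),
    "length": ("Length", "length"),
    "location": ("Subcellular location [CC]", "Subcellular location", "subcellular_location"),
    "transmembrane": ("Transmembrane", "transmembrane"),
    "topo_domain": ("Topological domain", "topological_domain"),
}


def _pick_column(df: pd.DataFrame, key: str, required: bool = True) -> Optional[str]:
    for cand in _ANNOTATION_COLUMNS[key]:
        if cand in df.columns:
            return cand
    if required:
        raise ConfigError(
            f"annotation table is missing a {key} column (looked for "
            f"{', '.join(map(repr, _ANNOTATION_COLUMNS[key]))})"
        )
    return None


def read_annotations(path) -> Dict[str, ProteinAnnotation]:
    """Read a Swiss-Prot TSV export into per-accession annotations.

    TRANSMEM feature strings of the form ``TRANSMEM a..b`` become
    inclusive intervals; TOPO_DOM features with a ``/note`` keep the note
    as a side label.  Malformed feature tokens are skipped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    acc_col = _pick_column(df, "accession")
    len_col = _pick_column(df, "length")
    loc_col = _pick_column(df, "location", required=False)
    tm_col = _pick_column(df, "transmembrane", required=False)
    topo_col = _pick_column(df, "topo_domain", required=False)

    out: Dict[str, ProteinAnnotation] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2
        acc = row[acc_col]
        try:
            length = int(row[len_col])
        except (TypeError, ValueError):
            raise ParseError(f"{path.name} line {line_no}: length must be an integer") from None
        loc = row[loc_col] if loc_col and pd.notna(row[loc_col]) else None
        if loc is not None and not str(loc).strip():
            loc = None
        feature_text = " ; ".join(
            str(row[c]) for c in (tm_col, topo_col) if c and pd.notna(row[c])
        )
        tms: List[Tuple[int, int]] = []
        topos: List[Tuple[int, int, str]] = []
        matched_spans = []
        for m in _TRANSMEM_RE.finditer(feature_text):
            s, e = int(m.group(1)), int(m.group(2))
            if not (1 <= s <= e <= length):
                logger.warning("%s line %d: TRANSMEM %d..%d outside [1, %d]; skipped",
                               path.name, line_no, s, e, length)
                continue
            tms.append((s, e))
            matched_spans.append(m.span())
        for m in _TOPO_DOM_RE.finditer(feature_text):
            topos.append((int(m.group(1)), int(m.group(2)), m.group(3)))
            matched_spans.append(m.span())
        for m in _FEATURE_TOKEN_RE.finditer(feature_text):
            if not any(s <= m.start() < e for s, e in matched_spans):
                logger.warning("%s line %d: malformed feature %r skipped",
                               path.name, line_no, m.group(0))
        tms = sorted(tms)
        for (s1, e1), (s2, _) in zip(tms, tms[1:]):
            if s2 <= e1:
                logger.warning("%s line %d: overlapping TRANSMEM features for %s",
                               path.name, line_no, acc)
        out[acc] = ProteinAnnotation(acc, length, loc, tms, sorted(topos))
    return out


# ---------------------------------------------------------------------------
# TM predictions (TMHMM-style)
# ---------------------------------------------------------------------------

@dataclass
class TMPrediction:
    """Predicted TM segments with posterior probabilities for one protein."""

    accession: str
    segments: List[Tuple[int, int, float]] = field(default_factory=list)


def read_tm_predictions(path) -> Dict[str, TMPrediction]:
    """Read a TMHMM-style table: accession, start, end, posterior."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("accession", "start", "end", "posterior"):
        if col not in df.columns:
            raise ConfigError(f"TM prediction table is missing column {col!r}")
    out: Dict[str, TMPrediction] = {}
    for acc, grp in df.groupby("accession", sort=True):
        segs = sorted(
            (int(r.start), int(r.end), float(r.posterior)) for r in grp.itertuples()
        )
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ParseError(f"overlapping TM predictions for {acc}: ({s1},{e1}) and start {s2}")
        out[str(acc)] = TMPrediction(str(acc), segs)
    return out


def write_tm_predictions(preds: Mapping[str, TMPrediction], path) -> None:
    rows = [
        {"accession": p.accession, "start": s, "end": e, "posterior": post}
        for p in preds.values() for s, e, post in p.segments
    ]
    pd.DataFrame(rows, columns=["accession", "start", "end", "posterior"]).sort_values(
        ["accession", "start"]
    ).to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


# ---------------------------------------------------------------------------
# Localization-marker tables
# ---------------------------------------------------------------------------

def write_lm_table(lms, path) -> None:
    """One row per marker region: accession, interval, compartment,
    source, evidence."""
    rows = []
    for lm in sorted(lms, key=lambda m: m.accession):
        for s, e, comp in lm.regions:
            rows.append({
                "accession": lm.accession, "region_start": s, "region_end": e,
                "compartment": comp, "source": lm.source, "evidence": lm.evidence or "",
            })
    pd.DataFrame(rows, columns=["accession", "region_start", "region_end",
                                "compartment", "source", "evidence"]).to_csv(
        Path(path), sep="\t", index=False)


def read_lm_table(path):
    from .markers import LocalizationMarker

    df = pd.read_csv(Path(path), sep="\t", dtype={"accession": str})
    grouped: Dict[str, dict] = {}
    for r in df.itertuples():
        d = grouped.setdefault(r.accession, {"regions": [], "source": r.source,
                                             "evidence": "" if pd.isna(r.evidence) else str(r.evidence)})
        d["regions"].append((int(r.region_start), int(r.region_end), str(r.compartment)))
    return [
        LocalizationMarker(acc, sorted(d["regions"]), d["source"], d["evidence"])
        for acc, d in sorted(grouped.items())
    ]


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = [
    "accession", "region_start", "region_end", "compartments", "status",
    "classification", "n_supporting_lms", "supporting_lms", "votes", "note",
    "consistent_neighbors",
]


def write_predictions(predictions, path) -> None:
    """Write predictions as a TSV that round-trips losslessly through
    :func:`read_predictions`."""
    rows = []
    for p in sorted(predictions, key=lambda p: (p.accession, p.region or (0, 0))):
        rows.append({
            "accession": p.accession,
            "region_start": "" if p.region is None else p.region[0],
            "region_end": "" if p.region is None else p.region[1],
            "compartments": ";".join(sorted(p.supported)),
            "status": p.status,
            "classification": p.classification or "",
            "n_supporting_lms": p.n_supporting_lms,
            "supporting_lms": ";".join(sorted({v.lm for v in p.votes})),
            "votes": ";".join(
                f"{v.lm}:{v.lm_residue}:{v.locale}>{v.target_residue}"
                for v in sorted(p.votes, key=lambda v: (v.lm, v.lm_residue, v.target_residue))
            ),
            "note": p.note,
            "consistent_neighbors": ";".join(p.consistent_neighbors),
        })
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(Path(path), sep="\t", index=False)


def read_predictions(path):
    from .predict import Prediction, Vote

    df = pd.read_csv(Path(path), sep="\t", dtype=str).fillna("")
    out = []
    for r in df.itertuples():
        votes = []
        for tok in filter(None, r.votes.split(";")):
            head, tgt = tok.rsplit(">", 1)
            lm, lm_res, locale = head.rsplit(":", 2)
            votes.append(Vote(int(tgt), lm, int(lm_res), locale))
        region = None
        if r.region_start != "":
            region = (int(float(r.region_start)), int(float(r.region_end)))
        out.append(Prediction(
            accession=r.accession,
            region=region,
            supported=frozenset(filter(None, r.compartments.split(";"))),
            status=r.status,
            votes=tuple(sorted(votes, key=lambda v: (v.lm, v.lm_residue, v.target_residue))),
            classification=r.classification or None,
            n_supporting_lms=int(r.n_supporting_lms),
            note=r.note,
            consistent_neighbors=tuple(filter(None, r.consistent_neighbors.split(";"))),
        ))
    return out


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path, fmt: Optional[str] = None) -> None:
    """Export a cross-link network as GraphML or SIF (for Cytoscape)."""
    path = Path(path)
    fmt = fmt or ("sif" if path.suffix.lower() == ".sif" else "graphml")
    if fmt == "graphml":
        g = nx.Graph()
        for n, data in sorted(graph.nodes(data=True)):
            g.add_node(n, is_lm=bool(data.get("is_lm", False)),
                       compartment=str(data.get("compartment") or ""))
        for u, v, data in sorted(graph.edges(data=True)):
            g.add_edge(u, v, weight=int(data.get("weight", 1)))
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
                fh.write(f"{u}\txl\t{v}\n")
            for n in sorted(nx.isolates(graph)):
                fh.write(f"{n}\n")
    else:
        raise ConfigError(f"unknown network format {fmt!r}")


def read_network(path) -> nx.Graph:
    return nx.read_graphml(Path(path))


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class StructureMap:
    """Cα coordinates of a structure plus a residue mapping.

    ``residue_map`` sends (accession, sequence position) to a
    (chain, residue number) pair that resolves to a coordinate;
    positions that could not be resolved are listed in ``unmapped``.
    """

    pdb_id: str
    chain_map: Dict[str, str] = field(default_factory=dict)
    residue_map: Dict[Tuple[str, int], Tuple[str, int]] = field(default_factory=dict)
    ca_coords: Dict[Tuple[str, int], np.ndarray] = field(default_factory=dict)
    unmapped: List[Tuple[str, int]] = field(default_factory=list)

    def coord_for(self, accession: str, position: int) -> Optional[np.ndarray]:
        target = self.residue_map.get((accession, position))
        if target is None and accession in self.chain_map:
            target = (self.chain_map[accession], position)
        if target is None:
            return None
        return self.ca_coords.get(target)


def read_structure(pdb_path, mapping_path=None,
                   chain_map: Optional[Mapping[str, str]] = None) -> StructureMap:
    """Read Cα coordinates from a PDB file, with an optional residue
    mapping table (accession, position, chain, residue_number) for
    homologous structures.  Mapped residues without a Cα are dropped with
    a warning and listed as unmapped."""
    import gemmi

    pdb_path = Path(pdb_path)
    st = gemmi.read_structure(str(pdb_path))
    ca: Dict[Tuple[str, int], np.ndarray] = {}
    for chain in st[0]:
        for res in chain:
            atom = res.find_atom("CA", "*")
            if atom is not None:
                ca[(chain.name, res.seqid.num)] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z]
                )
    smap = StructureMap(pdb_id=st.name or pdb_path.stem,
                        chain_map=dict(chain_map or {}), ca_coords=ca)
    if mapping_path is not None:
        df = pd.read_csv(Path(mapping_path), sep="\t")
        for col in ("accession", "position", "chain", "residue_number"):
            if col not in df.columns:
                raise ConfigError(f"residue mapping table is missing column {col!r}")
        for r in df.itertuples():
            key = (str(r.accession), int(r.position))
            target = (str(r.chain), int(r.residue_number))
            if target in ca:
                smap.residue_map[key] = target
            else:
                logger.warning("%s: no C-alpha for %s -> chain %s residue %s; dropped",
                               pdb_path.name, key, *target)
                smap.unmapped.append(key)
    return smap
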