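"""Distance-based plausibility checks.

The cross-linker defines a maximum bridgeable Cα-Cα distance (the
labeling radius): spacer arm plus two lysine side chains plus in-solution
flexibility, capped at 40 Å for DSSO/DSBSO-class reagents.  Three checks
build on it:

* structural satisfaction — measured Cα-Cα distances of cross-links
  mapped onto a high-resolution structure must fall under the cap;
* protrusion feasibility — two proteins anchored in membranes separated
  by a known aqueous gap can only cross-link if their protruding soluble
  stretches (at 3.5 Å per residue, fully extended) close the gap to
  within the cap;
* cross-membrane audit — no permitted link may join residues in
  different aqueous compartments, because membranes (~70 Å) are wider
  than the cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CrossLink, StructureMap
from .model import CompartmentGraph, may_crosslink

#: Fully extended polypeptide rise per residue, Å.
ANGSTROM_PER_RESIDUE = 3.5


@dataclass(frozen=True)
class RadiusModel:
    """Labeling-radius model of a lysine-reactive cross-linker (Å)."""

    spacer_A: float = 10.3
    side_chain_A: float = 7.6
    flexibility_A: float = 10.0
    max_ca_ca_A: float = 40.0

    def __post_init__(self) -> None:
        if self.max_ca_ca_A <= 0:
            raise InputError("max_ca_ca_A must be positive")


DSSO = RadiusModel()
DSBSO = RadiusModel()  # same 40 Å Cα-Cα constraint applies
RADIUS_PRESETS = {"DSSO": DSSO, "DSBSO": DSBSO}


def linear_length(n_residues: int) -> float:
    """Maximum reach (Å) of a fully extended stretch of ``n_residues``."""
    if n_residues < 0:
        raise InputError("residue count must be non-negative")
    return ANGSTROM_PER_RESIDUE * n_residues


def protrusion_feasible(ims_len_a: int, ims_len_b: int, gap_A: float,
                        radius: RadiusModel = DSSO) -> bool:
    """Can two membrane-anchored proteins bridge an aqueous gap?

    True iff the gap minus both fully extended protrusions is within the
    labeling radius (boundary equality admitted).
    """
    remaining = gap_A - linear_length(ims_len_a) - linear_length(ims_len_b)
    return remaining <= radius.max_ca_ca_A


def ca_distance(p, q) -> float:
    """Euclidean Cα-Cα distance between two 3-vectors (Å)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise InputError("coordinates must be finite")
    return float(np.linalg.norm(p - q))


def structural_satisfaction(
    crosslinks: Iterable[CrossLink],
    structure: StructureMap,
    radius: RadiusModel = DSSO,
) -> Tuple[float, pd.DataFrame]:
    """Fraction of mappable cross-links whose Cα-Cα distance satisfies
    the labeling radius, plus a per-link distance table.

    Links with an endpoint missing from the structure are excluded from
    the fraction and flagged ``mapped == False`` in the table.
    """
    rows: List[dict] = []
    n_mapped = n_ok = 0
    for xl in crosslinks:
        pa = structure.coord_for(xl.protein_a, xl.residue_a)
        pb = structure.coord_for(xl.protein_b, xl.residue_b)
        row = {"protein_a": xl.protein_a, "residue_a": xl.residue_a,
               "protein_b": xl.protein_b, "residue_b": xl.residue_b}
        if pa is None or pb is None:
            row.update(mapped=False, distance_A=np.nan, satisfied=False)
        else:
            d = ca_distance(pa, pb)
            ok = d <= radius.max_ca_ca_A
            n_mapped += 1
            n_ok += ok
            row.update(mapped=True, distance_A=d, satisfied=bool(ok))
        rows.append(row)
    if n_mapped == 0:
        raise InputError("no cross-link could be mapped onto the structure")
    table = pd.DataFrame(rows)
    return n_ok / n_mapped, table


LocaleSource = Union[Mapping[Tuple[str, int], Optional[str]],
                     Callable[[str, int], Optional[str]]]


def cross_membrane_audit(
    crosslinks: Iterable[CrossLink],
    locales: LocaleSource,
    model: CompartmentGraph,
) -> Tuple[list, list]:
    """List every cross-link joining residues that cannot share an
    aqueous compartment.

    ``locales`` resolves (accession, residue) to a locale (mapping or
    callable); unresolvable locales make a link indeterminate, reported
    separately rather than as a violation.
    """
    if callable(locales):
        resolve = locales
    else:
        resolve = lambda acc, res: locales.get((acc, res))  # noqa: E731
    violations: List[Tuple[CrossLink, Optional[str], Optional[str]]] = []
    indeterminate: List[CrossLink] = []
    for xl in crosslinks:
        la = resolve(xl.protein_a, xl.residue_a)
        lb = resolve(xl.protein_b, xl.residue_b)
        verdict = may_crosslink(la, lb, model)
        if verdict is None:
            indeterminate.append(xl)
        elif verdict is False:
            violations.append((xl, la, lb))
    return violations, indeterminate
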