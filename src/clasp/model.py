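"""Organelle compartment architecture.

An organelle is modeled as an ordered alternation of aqueous compartments
and membranes, e.g. ``cytosol | OMM | IMS | IMM | matrix`` for a
mitochondrion or ``lumen | SVM | cytosol`` for a synaptic vesicle.  Every
membrane therefore has exactly two aqueous *sides*.

The central spatial rule encoded here: a lysine-reactive cross-linker with
a maximum Cα-Cα labeling radius of ~40 Å cannot bridge a lipid bilayer
(~70 Å thick), so two residues can only be cross-linked if they occupy the
*same* aqueous compartment.  Residues buried inside a membrane are never
cross-linked at all (their lysine side chains are not solvent accessible),
and residues in regions of unknown orientation yield an indeterminate
verdict rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import yaml

from .errors import InputError, ModelError

AQUEOUS = "aqueous"
MEMBRANE = "membrane"

#: Sentinel locale for residues buried inside a lipid bilayer.
MEMBRANE_EMBEDDED = "membrane-embedded"


@dataclass(frozen=True)
class Compartment:
    """One layer of the organelle: an aqueous space or a membrane.

    ``thickness_A`` (Å) only applies to membranes; bilayers are ~70 Å,
    wider than any common cross-linker's labeling radius.
    """

    name: str
    kind: str
    thickness_A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in (AQUEOUS, MEMBRANE):
            raise ModelError(f"unknown compartment kind {self.kind!r}")
        if self.thickness_A is not None and self.thickness_A <= 0:
            raise ModelError(f"membrane thickness must be positive, got {self.thickness_A}")
        if self.kind == AQUEOUS and self.thickness_A is not None:
            raise ModelError("aqueous compartments carry no thickness")


class CompartmentGraph:
    """Ordered alternation of aqueous compartments and membranes.

    The first and last entries must be aqueous, so every membrane has
    exactly two aqueous neighbours (its two sides).  ``gap_distances``
    optionally records the aqueous distance (Å) between two membranes,
    e.g. the ~200 Å gap between the outer and inner mitochondrial
    membranes used for protrusion-feasibility checks.
    """

    def __init__(
        self,
        compartments: Sequence[Compartment],
        gap_distances: Optional[Mapping[tuple, float]] = None,
    ) -> None:
        cs = list(compartments)
        if len(cs) < 3:
            raise ModelError("a compartment graph needs at least aqueous|membrane|aqueous")
        if cs[0].kind != AQUEOUS or cs[-1].kind != AQUEOUS:
            raise ModelError("first and last compartments must be aqueous")
        for a, b in zip(cs, cs[1:]):
            if a.kind == b.kind:
                raise ModelError(
                    f"compartments must alternate aqueous/membrane ({a.name!r} then {b.name!r})"
                )
        names = [c.name for c in cs]
        if len(set(names)) != len(names):
            raise ModelError("compartment names must be unique")
        self.compartments = cs
        self._by_name = {c.name: c for c in cs}
        self._order = {c.name: i for i, c in enumerate(cs)}
        gaps = {}
        for (m1, m2), dist in dict(gap_distances or {}).items():
            for m in (m1, m2):
                if m not in self._by_name or self._by_name[m].kind != MEMBRANE:
                    raise ModelError(f"gap distance refers to non-membrane {m!r}")
            if dist <= 0:
                raise ModelError("gap distances must be positive")
            gaps[tuple(sorted((m1, m2)))] = float(dist)
        self.gap_distances = gaps

    # -- queries ---------------------------------------------------------

    @property
    def aqueous(self) -> list:
        return [c.name for c in self.compartments if c.kind == AQUEOUS]

    @property
    def membranes(self) -> list:
        return [c.name for c in self.compartments if c.kind == MEMBRANE]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Compartment:
        try:
            return self._by_name[name]
        except KeyError:
            raise ModelError(f"unknown compartment {name!r}") from None

    def is_aqueous(self, name: str) -> bool:
        return self[name].kind == AQUEOUS

    def sides(self, membrane: str) -> tuple:
        """The two aqueous compartments flanking ``membrane``."""
        c = self[membrane]
        if c.kind != MEMBRANE:
            raise ModelError(f"{membrane!r} is not a membrane")
        i = self._order[membrane]
        return (self.compartments[i - 1].name, self.compartments[i + 1].name)

    def gap(self, m1: str, m2: str) -> Optional[float]:
        return self.gap_distances.get(tuple(sorted((m1, m2))))

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "compartments": [
                {"name": c.name, "kind": c.kind, **({"thickness_A": c.thickness_A} if c.thickness_A else {})}
                for c in self.compartments
            ],
            "gap_distances": [
                {"membranes": list(k), "distance_A": v} for k, v in sorted(self.gap_distances.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompartmentGraph":
        comps = [
            Compartment(e["name"], e["kind"], e.get("thickness_A"))
            for e in d["compartments"]
        ]
        gaps = {tuple(e["membranes"]): e["distance_A"] for e in d.get("gap_distances", [])}
        return cls(comps, gaps)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CompartmentGraph":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_mito_model() -> CompartmentGraph:
    """Mitochondrial architecture: cytosol | OMM | IMS | IMM | matrix.

    Both membranes are ~70 Å thick; the OMM-IMM gap of ~200 Å comes from
    electron tomography and bounds OMM-IMM cross-link feasibility.
    """
    return CompartmentGraph(
        [
            Compartment("cytosol", AQUEOUS),
            Compartment("OMM", MEMBRANE, 70.0),
            Compartment("IMS", AQUEOUS),
            Compartment("IMM", MEMBRANE, 70.0),
            Compartment("matrix", AQUEOUS),
        ],
        gap_distances={("OMM", "IMM"): 200.0},
    )


def default_sv_model() -> CompartmentGraph:
    """Synaptic-vesicle architecture: a single membrane separating the
    vesicle lumen from the cytosol."""
    return CompartmentGraph(
        [
            Compartment("lumen", AQUEOUS),
            Compartment("SVM", MEMBRANE, 70.0),
            Compartment("cytosol", AQUEOUS),
        ]
    )

BUILTIN_MODELS = {"mito": default_mito_model, "sv": default_sv_model}


@dataclass(frozen=True)
class ResidueLocale:
    """Where one residue of one protein sits.

    ``locale`` is an aqueous compartment name, :data:`MEMBRANE_EMBEDDED`,
    or ``None`` when the residue lies in an unoriented region.
    """

    accession: str
    residue: int
    locale: Optional[str]


def residue_locale(topology, residue: int) -> ResidueLocale:
    """Locale of ``residue`` given a (possibly partially oriented) topology."""
    if residue < 1 or residue > topology.length:
        raise InputError(
            f"residue {residue} outside [1, {topology.length}] for {topology.accession}"
        )
    return ResidueLocale(topology.accession, residue, topology.locale_of(residue))


LocaleLike = Union[ResidueLocale, str, None]


def may_crosslink(locale_a: LocaleLike, locale_b: LocaleLike,
                  model: Optional[CompartmentGraph] = None) -> Optional[bool]:
    """Can two residue locales be bridged by the cross-linker?

    True iff both residues occupy the same aqueous compartment.
    Membrane-embedded residues never link; residues in different aqueous
    compartments are separated by at least one membrane and never link.
    An unknown locale yields ``None`` (indeterminate), not an error.
    """
    a = locale_a.locale if isinstance(locale_a, ResidueLocale) else locale_a
    b = locale_b.locale if isinstance(locale_b, ResidueLocale) else locale_b
    if a is None or b is None:
        return None
    if a == MEMBRANE_EMBEDDED or b == MEMBRANE_EMBEDDED:
        return False
    if model is not None:
        for x in (a, b):
            if not model.is_aqueous(x):
                raise ModelError(f"locale {x!r} is not an aqueous compartment of the model")
    return a == b
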