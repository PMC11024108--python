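# Methods

## Spatial model

An organelle is represented as an ordered alternation of aqueous
compartments and membranes; the first and last entries are aqueous, so
every membrane has exactly two aqueous sides.  Two presets ship with the
package: the mitochondrial model `cytosol | OMM | IMS | IMM | matrix`
(membrane thickness 70 Å, OMM–IMM gap 200 Å) and a single-membrane
vesicle model `lumen | SVM | cytosol`.  Arbitrary architectures can be
given as YAML.

The physical premise is that a lysine-reactive cross-linker has a maximum
bridgeable Cα–Cα distance of ~40 Å (10.3 Å spacer arm, two 7.6 Å lysine
side chains, ~10 Å in-solution flexibility).  The 40 Å cap is treated as
an independent constant rather than the sum of those terms, and is
configurable per cross-linker; the DSSO and DSBSO presets both use 40 Å.
Because a bilayer is ~70 Å thick, no admissible cross-link spans a
membrane: the set of permitted residue-locale pairs is exactly
{(c, c) : c aqueous}.  Membrane-embedded residues never cross-link
(their side chains are not solvent-accessible); residues in unoriented
regions yield an *indeterminate* verdict rather than an error, so missing
knowledge is never silently converted into evidence.

Assumptions worth keeping in mind: each protein (or protein region) is
treated as single-locale — dually localized proteins surface as
*ambiguous* predictions instead of being modeled explicitly; sub-membrane
microdomains and contact-site geometry beyond the pairwise gap distance
are out of scope.

## Network construction and filtering

Nodes are protein accessions; an edge joins two proteins with ≥ 1
inter-protein unique residue pair and is weighted by the number of such
pairs.  Intra-protein links are kept for marker validation but never
become edges.  Filtering removes isolated proteins and connected
components smaller than `min_component_size` (default 3; the value is a
mandatory, logged configuration field because "small disconnected
cluster" is inherently a per-dataset calibration).  Degree ranking breaks
ties by accession string so all outputs are reproducible.  Coverage is
the percentage of filtered-network proteins that are markers or first-tier
interactors of markers; the markers themselves count as covered, since
they are by definition localized.

## Markers and consistency validation

A localization marker carries one `(interval, compartment)` region per
soluble stretch; a soluble marker has a single full-length region.
Auto-selection accepts proteins whose Swiss-Prot location text maps to
exactly one model compartment through a controlled synonym vocabulary
(entries with `Note=` qualifiers or multiple location terms are treated
as equivocal), and membrane proteins whose TM features plus
topological-domain side notes produce a fully oriented topology.

Validation examines every cross-link between two marker candidates
(intra- and inter-protein).  Links with an endpoint inside a TM segment
are skipped from the tally.  A contradiction is a link whose two residue
locales are not the same aqueous compartment; the consistency metric is
`100 × (n_links − n_contradictions) / n_links`.  **Both** endpoints of a
contradictory link are removed — either marker may be mislocalized, or
the identification may be a false positive, and both explanations leave
both endpoints suspect.  The removal is conservative and idempotent, and
on noise-free simulated data it removes nothing.  Manually added markers
are merged (manual wins over auto on the same accession) and the union is
re-validated, so a rejected marker cannot be smuggled back in.

## Localization inference

Every unique residue pair between a target and a marker casts one vote:
the aqueous compartment of the marker residue.  Vote multiplicity is
counted at the unique-residue-pair level, not at spectrum (CSM) level,
matching the FDR unit of the input tables.  One vote suffices for a
prediction, but the number of distinct supporting markers is reported so
users can filter.  Soluble targets get one prediction over the full
sequence; membrane targets get one per voted soluble region, with votes
landing inside TM segments excluded.  Unambiguous region assignments then
serve as anchors for side alternation, which completes the unvoted
regions (flagged `inferred by membrane-side alternation`).  When the
votes alone are compatible with more than one membrane (e.g. IMS-only
votes fit both mitochondrial membranes), the annotated host membrane
disambiguates; without it the unvoted regions stay open rather than
being guessed.

Classification applies to unambiguous predictions only: *confirms* when
the supported compartment equals the prior annotation, *contradicts* when
it differs (the prior may be a membrane name — a predicted matrix protein
annotated as outer-membrane contradicts), *novel* when there is no prior.
A previously unannotated protein supported only by the outermost aqueous
compartment (the cytosolic face of the outer membrane) is additionally
flagged as organelle-associated.  Corroborating non-marker neighbors are
computed in a single propagation round — already-predicted first-tier
proteins that agree with a prediction are listed alongside it, never used
as votes; inference is strictly first-tier.

## Geometry checks

`structural_satisfaction` maps cross-links onto Cα coordinates (PDB via
gemmi, with an optional residue-mapping table for homologous structures)
and reports the fraction within the radius cap; it is invariant under
rigid-body motion.  `protrusion_feasible` checks whether two
membrane-anchored proteins can bridge a known inter-membrane gap given
their soluble protrusion lengths at 3.5 Å per fully extended residue
(boundary equality admitted).  `cross_membrane_audit` lists every link
whose endpoint locales violate the same-compartment rule, reporting
indeterminate locales separately.

## Synthetic organelles

The simulator is first-class, tested code, not a fixture.  Defaults: 200
proteins, lengths 120–600 residues, 30% membrane proteins with 1–6
oriented TM helices (21 residues each, ≥ 15-residue soluble stretches),
25% designated markers with at least one marker per aqueous compartment,
lysines at ~7% of positions (mirroring lysine-reactive chemistry), 3000
cross-links.  Consistent links are sampled between lysine sites sharing
an aqueous compartment, weighted by compartment site counts; noise links
are sampled across different compartments at the configured rate.  The
emitted files use exactly the dialects the readers accept.  Annotation
tables always include TRANSMEM intervals for membrane proteins (TM
presence is obtainable by sequence prediction for any protein; the
orientation is what inference must supply), but only markers receive
orienting side notes, and only a fraction (default 60%) of non-marker
proteins receive a location text, standing in for unmapped proteins.

What the simulator does *not* emulate: abundance-dependent
detectability, residue-level structural accessibility beyond the
TM/soluble split, dual localization, and false identifications that
happen to respect compartments.  Passing tests therefore demonstrate the
correctness of the propagation, validation and orientation logic under
the stated spatial rules — not the end-to-end error rate on real
search-engine output.

## Numerical and design choices

* Residue coordinates are 1-based, intervals inclusive on both ends
  (Swiss-Prot convention); a residue on a TM boundary belongs to the TM
  segment and is excluded from voting.
* TM posterior classes: > 0.75 high confidence, 0.037–0.75 potential,
  < 0.037 soluble.  Potential segments are used for region building but
  keep their confidence label.  When merged predicted+annotated TM
  segments disagree with the annotation on count parity, the annotation
  wins and the discarded prediction is recorded — parity decides which
  side each terminus faces and must not flip on a low-confidence call.
* Duplicate cross-link rows collapse with CSM counts summed and the
  maximum score kept.  Accessions are opaque; isoform suffixes are not
  stripped.
* Orientation is resolved by enumerating the two global side assignments
  and keeping the anchor-consistent one; conflicting anchors flag the
  topology and suppress alternation-based inference instead of guessing.
* All inference is deterministic: stable sort orders everywhere, no
  randomness outside the simulator, and run manifests carry config and
  input checksums but no timestamps, so reruns are byte-identical.

## Problem sizes used in validation

The test suite and the acceptance script run on simulated organelles of
60–200 proteins with 600–3000 links (plus a 10⁴-protein draw for the
compartment-proportion check and 1000 membrane proteins for the parity
law).  These sizes give every code path — multi-region membrane targets,
marker removal, alternation inference, noise auditing — while keeping a
full run in seconds.
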