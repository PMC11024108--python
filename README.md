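# clasp — cross-link assisted spatial proteomics

`clasp` infers **sub-organelle protein localizations** and **membrane-protein
topologies** from proteome-wide cross-linking mass spectrometry (XL-MS)
data.  It is aimed at proteomics groups who already produce FDR-filtered
cross-link tables (XlinkX, MeroX, or any CSV/TSV with configurable columns)
and want to turn them into spatial maps of a membrane-bound compartment
such as a mitochondrion or a synaptic vesicle.

## The idea

A lysine-reactive cross-linker (DSSO, DSBSO, ...) bridges two residues only
when their Cα–Cα distance is below a well-defined labeling radius,

```
d(Cα, Cα) ≤ spacer + 2 × side chain + flexibility  ≈ 10.3 + 2×7.6 + 10 ≈ 40 Å,
```

which is far less than the ~70 Å thickness of a lipid bilayer.  Two
cross-linked residues must therefore occupy the **same aqueous
sub-compartment**.  Modeling the organelle as an ordered alternation of
aqueous compartments and membranes (`cytosol | OMM | IMS | IMM | matrix`
for mitochondria), the pipeline:

1. builds the protein–protein network from inter-protein unique residue
   pairs and drops isolated proteins and small disconnected clusters;
2. curates **localization markers (LMs)** — proteins (or membrane-protein
   regions) of firmly established localization, auto-selected from
   Swiss-Prot annotations and/or supplied manually — and validates them
   against each other: any marker touching a cross-link that joins two
   different compartments is removed;
3. lets every marker–target cross-link cast a **vote** (the compartment of
   the marker residue) and assigns each target protein, or each soluble
   region of a membrane target, the set of voted compartments.  A
   prediction is *unambiguous* when all votes agree, and is classified as
   *confirming*, *contradicting* or *novel* against the prior annotation;
4. orients membrane proteins by alternating membrane sides across TM
   segments (a protein with an even number of TM helices has both termini
   on the same side), starting from the cross-link-anchored regions;
5. audits geometric plausibility: Cα–Cα distances on structures, the
   cross-membrane exclusion rule, and protrusion feasibility across known
   inter-membrane gaps (3.5 Å per extended residue against a 200 Å gap).

A synthetic-organelle simulator generates ground-truth proteins, oriented
topologies and distance-consistent cross-link sets (plus a configurable
violating-noise fraction), so every inference stage can be tested without
any external data.

## Worked example

```bash
python examples/01_simulate_and_predict.py
```

```
simulated 1500 unique cross-links, 0 violating the membrane rule
marker validation: 77 marker-marker links, 0 contradictions (100.0% consistent)
network: 100 proteins, 968 connections; 25 markers cover 100.0% via first-tier links
predictions: 142 region calls on 75 proteins, 100.0% unambiguous
vs ground truth: 100.0% of region calls correct
```

On a noise-free simulated organelle the marker set is fully
self-consistent, the markers' first-tier interactors cover the whole
filtered network, and every region-level call matches the generator's
ground truth — votes can never leak across a membrane because the
same-compartment rule forbids it.  `examples/02_membrane_topology.py`
shows the even-TM-count orientation logic on a two-TM inner-membrane
protein, and `examples/03_geometry_checks.py` the labeling-radius
arithmetic.

The same pipeline runs from the shell:

```bash
clasp simulate --n-proteins 200 --n-links 3000 --noise 0.02 --seed 7 --out simdir/
clasp predict --xl simdir/links.csv --annotations simdir/annotations.tsv \
              --lms simdir/lms.tsv --out predictions/
clasp validate-markers --xl links.csv --annotations swissprot.tsv --model mito
clasp network --xl links.csv --min-component 3 --out net.graphml
clasp struct-check --xl links.csv --pdb complex.pdb --map residues.tsv --max-dist 40
```

Every command writes a `manifest.json` with its configuration and input
checksums; inference commands are seed-free and bit-deterministic.

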