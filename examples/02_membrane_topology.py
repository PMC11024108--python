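"""Orient a membrane protein from a single anchored region.

A two-TM inner-membrane protein whose C-terminal region is cross-linked
to an IMS marker: side alternation across the TM segments fixes every
soluble region, and the even TM count puts both termini in the IMS.
"""

from clasp import build_regions, default_mito_model, predict_target
from clasp.predict import Vote

model = default_mito_model()

# 180-residue protein with TM helices at 50-70 and 110-130
topo = build_regions(180, annotated_tm=[(50, 70), (110, 130)], accession="TARGET")
print("regions:", [(r.start, r.end, type(r).__name__) for r in topo.regions])

# one cross-link from residue 150 (C-terminal region) to an IMS marker;
# the protein is annotated as inner-membrane, which pins the two sides
votes = [Vote(target_residue=150, lm="IMS_MARKER", lm_residue=40, locale="IMS")]
preds = predict_target("TARGET", votes, topology=topo, model=model, membrane="IMM")
for p in preds:
    source = f"{p.n_supporting_lms} marker(s)" if p.n_supporting_lms else p.note
    print(f"  region {p.region}: {sorted(p.supported)} [{source}]")
# the middle region alternates to the matrix; the even TM count places the
# unvoted N-terminal region back in the IMS, same side as the C-terminus
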