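"""Distance-based plausibility: labeling radius and membrane gaps.

The cross-linker bridges at most ~40 Å Cα-Cα (10.3 Å spacer + two 7.6 Å
lysine side chains + ~10 Å flexibility).  Two membranes ~200 Å apart can
therefore only be bridged when the proteins' soluble protrusions (3.5 Å
per fully extended residue) close the gap.
"""

from clasp import DSSO, linear_length, protrusion_feasible

print(f"labeling radius: {DSSO.max_ca_ca_A:.0f} A "
      f"(spacer {DSSO.spacer_A} + 2x side chain {DSSO.side_chain_A} "
      f"+ flexibility {DSSO.flexibility_A})")

gap = 200.0  # outer-to-inner membrane distance, A
for a, b in [(0, 0), (30, 20), (20, 10)]:
    reach = gap - linear_length(a) - linear_length(b)
    verdict = "feasible" if protrusion_feasible(a, b, gap) else "too far"
    print(f"protrusions of {a} and {b} residues: residual gap "
          f"{reach:.0f} A -> {verdict}")
# only protein pairs whose combined protrusions bring their lysines within
# 40 A of each other can form an outer-inner membrane cross-link
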