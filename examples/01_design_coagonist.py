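"""Reconstruct coagonist peptide sequences from shipped design rules.

Applies the MD-directed dual-agonist recipe (point mutations on the
glucagon template, back-mutation of positions 3 and 15 to Glu, C-terminal
graft of the GLP-1 Arg/Gly pair) and the Cotadutide reference recipe, then
prints each sequence with its provenance. The lengths (31 and 30) and the
mutation trail are the quantities to check.
"""

from coagdesign import GLUCAGON, build_design

print(f"template glucagon ({len(GLUCAGON)} aa): {GLUCAGON}\n")
for rules in ("mdd_gcgr", "mdd_glp1r", "mdd_gr", "cotadutide"):
    seq = build_design(None, rules)
    print(f"{seq.id:<10} ({len(seq)} aa): {seq.residues}")
    print(f"{'':<10} steps: {', '.join(seq.provenance)}\n")
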