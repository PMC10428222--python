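# Cotadutide (reference clinical dual agonist) modeled on the glucagon
# template: substitutions at positions 10, 12, 17, 20, 24, 27 and 28 plus
# an appended C-terminal Gly30 -> 30-mer. The fatty-acid modification on
# Lys10 is not modeled.
name: Cotadutide
template_id: GCG
template: HSQGTFTSDYSKYLDSRRAQDFVQWLMNT
mutations:
  - Y10K
  - K12E
  - R17E
  - Q20R
  - Q24A
  - M27E
  - N28A
graft:
  donor_id: GLY_TAIL
  donor: G
  from: 1
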