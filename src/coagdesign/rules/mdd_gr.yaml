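# MDD_GR: MD-directed dual GCGR/GLP-1R coagonist on the glucagon template.
# Built from the GLP-1R-oriented mutation set (S16W is the shipped choice;
# edit to S16M to explore the GCGR-oriented variant), plus R17Q for dual
# affinity, back-mutation of positions 3 and 15 to Glu (matching WT GLP-1),
# and a C-terminal graft of the GLP-1 Arg30/Gly31 pair -> 31-mer.
name: MDD_GR
template_id: GCG
template: HSQGTFTSDYSKYLDSRRAQDFVQWLMNT
mutations:
  - S16W
  - R17Q
  - Q24D
  - N28D
back_mutations:
  - {position: 3, to: E}
  - {position: 15, to: E}
graft:
  donor_id: GLP1
  donor: HAEGTFTSDVSSYLEGQAAKEFIAWLVKGRG
  from: 30
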