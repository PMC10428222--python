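# MDD_GLP-1R: GLP-1R-oriented design — S16W, Q24D, N28D plus R17Q on the
# glucagon template.
name: MDD_GLP1R
template_id: GCG
template: HSQGTFTSDYSKYLDSRRAQDFVQWLMNT
mutations:
  - S16W
  - R17Q
  - Q24D
  - N28D
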