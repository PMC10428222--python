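# MDD_GCGR: GCGR-oriented design — S16M, Q24D, N28D on the glucagon template.
name: MDD_GCGR
template_id: GCG
template: HSQGTFTSDYSKYLDSRRAQDFVQWLMNT
mutations:
  - S16M
  - Q24D
  - N28D
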