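# coagdesign

Rational design and trajectory-based scoring of peptides that co-target the
glucagon receptor (GCGR) and the glucagon-like peptide-1 receptor (GLP-1R),
two class B1 GPCRs whose dual agonists are of clinical interest for type-2
diabetes and obesity. The package provides, as a plain Python library:

- **Trajectory interaction metrics** — fraction of native contacts
  *Q(x)* (heavy-atom pairs of nonconsecutive residues within 5 Å of the
  reference), RMSD after Kabsch superposition, per-residue RMSF, radius of
  gyration, hydrogen-bond occupancy networks (strong if population > 80%),
  salt bridges (acidic/basic side chains, mean min N–O < 4 Å;
  strong ≥ 80% occupancy) and peptide-residue × receptor-domain
  (ECD/TM1–7/ECL1–3) contact maps.
- **MM-GB/SA binding energetics** — single-trajectory end-point scoring
  ΔG = ⟨ΔE_elec + ΔE_vdW + ΔG_polar + ΔG_nonpolar⟩ with a protein
  dielectric of 2.0, a Still-type generalized Born polar term (HCT
  descreening, OBC rescaling), γ·SASA nonpolar term (Shrake–Rupley), exact
  per-residue decomposition and variant difference maps.
- **A design engine** — validated point mutations ("S16W"-style), Glu
  back-mutations, C-terminal grafts, hotspot filtering (residue
  contribution < −50 kJ/mol), mutation-effect classification
  (improves/penalizes/neutral per receptor at a ±5 kJ/mol band) and
  candidate ranking by coupled affinity (ΔG_GCGR + ΔG_GLP1R, with the
  imbalance |ΔG_GCGR − ΔG_GLP1R| as a balance diagnostic).
- **Free-energy surfaces** — F = −kT ln(P/P_max) over order-parameter
  pairs such as (RMSD, R_g) or (interface energy, windowed TM6 RMSF).
- **A synthetic-complex generator** — ideal α-helical peptides
  (φ = −57°, ψ = −47°) docked in a toy receptor pocket, with H-bond and
  salt-bridge contacts planted at known occupancies and per-residue
  Gaussian fluctuation, so every analysis stage is testable against ground
  truth without an MD engine.

Shipped rule files reconstruct the published coagonist sequences on the
29-residue human glucagon template: `mdd_gr` (S16W, R17Q, Q24D, N28D;
positions 3 and 15 back to Glu; GLP-1 Arg/Gly C-terminal graft → 31-mer)
and `cotadutide` (substitutions at positions 10, 12, 17, 20, 24, 27, 28
plus an appended Gly30 → 30-mer, fatty-acid modification not modeled).

## Worked example

```sh
python examples/01_design_coagonist.py
```

prints (abridged):

```
template glucagon (29 aa): HSQGTFTSDYSKYLDSRRAQDFVQWLMNT

MDD_GR     (31 aa): HSEGTFTSDYSKYLEWQRAQDFVDWLMDTRG
           steps: S16W, R17Q, Q24D, N28D, Q3E, D15E, graft:GLP1[30:31]

Cotadutide (30 aa): HSQGTFTSDKSEYLDSERARDFVAWLEATG
           steps: Y10K, K12E, R17E, Q20R, Q24A, M27E, N28A, graft:GLY_TAIL[1:1]
```

i.e. the dual-agonist recipe turns the 29-residue glucagon template into a
31-residue coagonist whose C-terminal Arg/Gly pair comes from GLP-1, and
the reference recipe reproduces the 30-residue Cotadutide scaffold.
`examples/02_trajectory_metrics.py` then recovers planted interactions
from a synthetic trajectory:

```
H-bonds (strong = population > 80%):
  ('P', 2, 'N') -> ('R', 1, 'O'): occupancy 0.88, mean d 2.90 A, strong=True

salt bridges (mean min N-O < 4 A; strong >= 80% occupancy):
  ('P', 9) - ('R', 1): 3.17 A, occupancy 0.96, tier strong
  ('R', 3) - ('P', 12): 3.20 A, occupancy 0.96, tier strong
  ('P', 15) - ('R', 2): 3.30 A, occupancy 0.94, tier strong
```

matching the planted 0.9 / 0.95 occupancies to within binomial sampling
noise. The remaining examples cover per-residue energetics and difference
maps (`03`), free-energy surfaces (`04`) and the one-config pipeline
(`05`).

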