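# Methods

## Scope and model of the data

The package analyses peptide–receptor complexes of the class B1 GPCR
dual-agonist problem: a helical peptide hormone (glucagon template,
29 residues, author 1-based numbering) bound in a receptor pocket whose
residues are annotated by domain (ECD, TM1–7, ECL1–3, ICL1–3, CTR). All
coordinates are in Å throughout; energies in kJ/mol. Residues are
identified by `(chain_id, residue_index)` with indices taken verbatim from
the input — positional design notation such as S16W or Asp385^TM7 depends
on author numbering, so nothing renumbers.

Structures carry a deliberately minimal per-atom topology: backbone
N, H, CA, C, O plus either a single neutral pseudo-atom in the Cβ
direction or, for charged residues, explicit terminal atoms (Asp/Glu
carboxylate O pair, Lys NZ, Arg NH1/NH2, His NE2). The bundled parameter
table assigns a neutral backbone charge group (N −0.35, H +0.25, CA +0.10,
C +0.45, O −0.45), formal side-chain charges (Asp/Glu −1, Lys/Arg +1,
His 0) and one Lennard-Jones type per element. This is a scoring topology,
not a force field: the package compares variants and detects interactions;
it never integrates equations of motion.

## Synthetic trajectories

The generator emulates the statistics that downstream analyses consume,
not dynamics:

- **Helix builder.** Canonical α-helix by internal-coordinate (NeRF) chain
  extension with φ = −57°, ψ = −47°, ω = 180° and Engh–Huber-like bond
  geometry. The result has Cα–Cα ≈ 3.80 Å, rise ≈ 1.55 Å/residue and
  O(i)···N(i+4) ≈ 3.07 Å — the α-helical H-bond signature. Side-chain
  terminal atoms sit along the Cβ direction at residue-type-specific
  distances (Asp 3.6 Å … Arg 5.8 Å from Cα).
- **Toy receptor.** N pocket residues on a cylinder (default radius 16 Å)
  around the peptide axis, side chains pointing inward. The default
  radius keeps baseline peptide–receptor separations above the 5 Å
  contact cutoff, so interface contacts exist only where planted.
- **Planted interactions.** Per frame, each planned pair draws an
  independent Bernoulli(occupancy): an H-bond acceptor is placed on the
  donor's N–H axis at 2.9 Å (D–H···A = 180°), a salt-bridge partner's
  terminal N at the planned N–O distance along the acidic side-chain
  extension (Cα→carboxylate direction, which cannot clash with the
  backbone); broken contacts are displaced to 8 Å. Isotropic Gaussian
  noise with per-residue σ is applied *before* planting, so planted
  geometry is exact and realized occupancies are exactly binomial.
  There are no kinetics — occupancy is the only statistic the analyses
  consume — and no solvent, membrane or receptor fold.

Consequences for testing: realized occupancies converge to targets at the
binomial rate (tests use 3σ bands); per-residue RMSF of planted noise has
the closed form σ√3 (recovered within 10% at 2000 frames); a fixed seed
gives bit-identical trajectories. Passing these tests validates the
analysis code on data whose ground truth is known; it does not validate
force-field accuracy or conformational sampling on real trajectories.

## Trajectory metrics

- **Native contacts / Q(x).** A native contact is a residue pair, not on
  the same chain at sequence separation ≤ 1, with any heavy-atom pair
  within 5 Å in the reference. "Nonconsecutive" is read literally
  (|i−j| > 1, configurable); counting is hard (no switching function);
  hydrogens are excluded. Q is the per-frame fraction of native pairs
  retained, so Q = 1 on the reference by construction.
- **RMSD/RMSF/Rg.** RMSD after optimal rigid-body superposition
  (Kabsch via `scipy.spatial.transform.Rotation.align_vectors`). RMSF is
  computed about the time-averaged structure after two passes of
  align-to-mean refinement (skippable for pre-aligned data); per-atom
  values are averaged per residue. R_g is mass-weighted about the
  selection's centre of mass. Frames are weighted equally; no block
  averaging.
- **H-bonds.** Geometric criterion: donor–acceptor heavy-atom distance
  ≤ 3.5 Å and D–H···A angle ≥ 120° (both configurable; chosen because the
  thresholds of record in the field specify only the population cutoff).
  A record is "strong" when its population exceeds 80%.
- **Salt bridges.** Candidates are all acidic × basic residue pairs
  across the interface; distance is the minimum over side-chain N/O atom
  pairs (the literature's "contact distance" is not atom-specified). A
  bridge is reported when the frame-mean minimum N–O distance is < 4 Å;
  occupancy is the fraction of frames below 4 Å, tiered
  strong ≥ 0.80 > moderate ≥ 0.50 > weak (tier boundaries are
  package-defined).
- **Interaction maps.** Entry (p, domain) is the fraction of frames in
  which peptide residue p has any heavy atom within 5 Å of any residue of
  that receptor domain.

Every detector is cross-checked in the test suite against an independent
brute-force reimplementation on ≤ 10-residue, ≤ 50-frame instances.

## Binding energetics

Single-trajectory end-point scoring (complex frames only; the standard
approximation when separate receptor/ligand runs are unavailable), no
conformational entropy term:

ΔG = ⟨ΔE_elec + ΔE_vdW + ΔG_polar + ΔG_nonpolar⟩ over frames (stride
configurable), each Δ evaluated as complex − receptor − ligand on the
same coordinates, which reduces the MM terms to interface pair sums.

- **Electrostatics.** Coulomb with f = 1389.35458 kJ·mol⁻¹·Å·e⁻², uniform
  protein dielectric ε_in = 2.0, no cutoff for interface pairs.
- **van der Waals.** 12-6 Lennard-Jones with Lorentz–Berthelot
  combination.
- **Polar solvation.** Still-type generalized Born,
  E = −½(1/ε_in − 1/ε_out) f Σ_ij q_i q_j / f_GB with
  f_GB = √(r² + B_iB_j e^{−r²/4B_iB_j}), ε_out = 80. Born radii use HCT
  pairwise descreening (neighbour radii scaled by 0.8) with OBC tanh
  rescaling (α, β, γ = 1.0, 0.8, 4.85), which keeps radii positive for any
  geometry and reduces to the intrinsic vdW radius (2^{1/6}σ/2) for an
  isolated atom — so the single-ion Born energy is exact. This GB term is
  a closed-form surrogate for a grid Poisson–Boltzmann solution: it
  preserves the four-component decomposition and the sign structure
  (large positive polar penalty opposed by electrostatics) but absolute
  kJ/mol values are comparative scores only.
- **Nonpolar solvation.** γ·SASA + c with γ = 0.0227 kJ·mol⁻¹·Å⁻²
  (common SASA-model constant) and c = 0 by default. SASA is
  Shrake–Rupley with a deterministic 960-point Fibonacci sphere per atom
  and probe 1.4 Å. The fixed point grid makes the term invariant under
  rigid motion only to ~0.1% (grid-orientation discretization); the
  analytic terms are exactly invariant.
- **Decomposition.** Interface pair terms split 50/50 between partner
  residues; solvation Δ terms attributed per atom then summed per
  residue. Per-residue columns therefore sum to the totals to ≤ 1e-6
  relative — enforced by test. Difference maps subtract residue totals
  position-wise and report unmatched positions explicitly rather than
  imputing zero.

## Design engine

Point mutations are validated against the current sequence (wild-type
letter must match, guarding numbering drift) and are deliberately not
idempotent — re-applying a recipe fails. A recipe applies, in fixed
order: mutation set → back-mutations → optional C-terminal graft, with
provenance recorded at every step. ΔΔG convention is mutant − reference
(negative improves). Classification uses a symmetric ±5 kJ/mol neutral
band per receptor (configurable; the qualitative improve/penalize
vocabulary of the field has no published cutoff): improvement on a
receptor means ΔΔG ≤ −5; a mutation "penalizes" when either ΔΔG ≥ +5 and
neither improves. Hotspot filtering keeps residues contributing
< −50 kJ/mol (the conventional per-residue significance threshold, kept
distinct from the mutation band). Coupled affinity is scored as the sum
of the two receptor ΔG values — no published formula defines "coupled
binding affinity" numerically, and the sum is the simplest symmetric
choice — with |ΔG_GCGR − ΔG_GLP1R| reported as an imbalance diagnostic
and used as tie-breaker in ranking.

Two genuinely open choices in the shipped rule files: `mdd_gr` carries
S16W (it is built from the GLP-1R-oriented base, which uses S16W; the
GCGR-oriented alternative S16M is one edit away in the YAML), and the
C-terminal graft is exactly the GLP-1 Arg30/Gly31 pair (donor shipped as
GLP-1(7-37) renumbered 1–31 so those position labels hold). The
Cotadutide rule encodes the seven stated substitution positions plus the
appended Gly; the clinical molecule's fatty-acid modification on Lys10 is
out of scope.

## Free-energy surfaces

F = −kT ln(P/P_max) over a 2D histogram (default 50×50 bins spanning the
observed range; no smoothing), kT = 0.0083144621·T kJ/mol (2.478 at
298 K). The global minimum is 0 by normalization (surfaces are relative);
empty bins are masked, never zero. Minima are occupied bins that are
4-neighbourhood local minima within a depth of the global minimum. A
constant series is a degenerate-range error unless explicit edges are
passed. Because a fluctuation quantity has no per-frame value, the
RMSF-of-TM6 order parameter is computed over a sliding window of frames
(default 20) centred on each frame — a package-defined convention.

## Pipeline, determinism and problem sizes

`run_pipeline` drives synthesize-or-load → metrics → energetics →
design/ranking → FES from one config, writes TSV/FASTA/PDB/JSON with
units in headers, and a manifest with seed and config hash; a rerun with
the same config is bit-identical for all deterministic stages (verified
file-by-file in tests). Validation failures exit 2 from the CLI, runtime
failures 1.

Default demo problem sizes — 29-residue peptide, 12-residue pocket,
tens to hundreds of frames, stride-reduced MM-GB/SA averaging — were
chosen so every statistical check retains its designed power (binomial
3σ bands at 500 frames, 10% RMSF bands at 2000 frames) while the whole
suite and the reproduction script run in well under a minute each on one
core.

## Known limitations

- The GB/SASA surrogate yields comparative scores; absolute ΔG values do
  not transfer to PB- or experiment-scale numbers, and toy-complex totals
  can be net positive because the coarse topology has little favourable
  vdW surface.
- The generator has no kinetics, solvent, membrane or receptor fold;
  conclusions about real trajectories require real trajectories.
- Altloc/insertion-code PDBs are rejected; XTC/DCD readers, DSSP
  timelines and conformer clustering are out of scope.
- Planted-contact geometry moves single atoms, so bond lengths within a
  moved side chain are not preserved frame-to-frame (irrelevant to the
  distance/occupancy statistics analysed, but visible if fixtures are
  inspected as structures).
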