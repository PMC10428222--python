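"""MM-GB/SA-style binding free energy with four-component decomposition.

Single-trajectory end-point scoring: for each frame the binding free
energy is

    dG = dE_elec + dE_vdw + dG_polar + dG_nonpolar

where the Delta of every term is complex minus receptor minus ligand
evaluated on the same coordinates. The molecular-mechanics terms then
reduce to interface pair sums (Coulomb with a protein dielectric,
default 2.0, and Lennard-Jones with Lorentz-Berthelot combination). Polar
solvation uses a Still-type generalized Born model with HCT pairwise
descreening Born radii; nonpolar solvation is gamma * SASA from a
Shrake-Rupley surface. No conformational entropy term is included.

Per-residue decomposition splits each interface pair term 50/50 between
the partner residues and attributes solvation Deltas per atom, so the
per-residue columns sum exactly to the totals.

Because the polar term is a generalized Born surrogate rather than a
grid Poisson-Boltzmann solution, absolute energies are comparative
scores, not transferable thermodynamic predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .core import Structure, Trajectory, ValidationError
from .params import vdw_radius

#: Coulomb constant, kJ mol^-1 A e^-2
COULOMB_CONSTANT = 1389.35458


@dataclass
class EnergeticsConfig:
    """Knobs of the implicit-solvent scoring model.

    eps_in / eps_out : relative dielectrics of protein interior (2.0) and
        water (80). gamma_sasa (kJ/mol/A^2) and sasa_offset parameterize
        the nonpolar term; probe_radius is the solvent probe (A);
        frame_stride subsamples trajectory frames; sasa_points sets the
        Shrake-Rupley sphere resolution.
    """

    eps_in: float = 2.0
    eps_out: float = 80.0
    gamma_sasa: float = 0.0227
    sasa_offset: float = 0.0
    probe_radius: float = 1.4
    frame_stride: int = 1
    sasa_points: int = 960

    def __post_init__(self):
        if self.eps_in < 1:
            raise ValidationError("eps_in must be >= 1")
        if self.eps_out < self.eps_in:
            raise ValidationError("eps_out must be >= eps_in")
        if self.gamma_sasa < 0:
            raise ValidationError("gamma_sasa must be >= 0")
        if self.frame_stride < 1:
            raise ValidationError("frame_stride must be >= 1")


COMPONENTS = ("elec", "vdw", "polar_solv", "nonpolar_solv")


@dataclass
class EnergyDecomposition:
    """Per-residue and total energy components in kJ/mol."""

    per_residue: dict  # residue_key -> dict(component -> value, plus "total")
    frame_count: int = 1

    @property
    def totals(self) -> dict:
        tot = {c: 0.0 for c in COMPONENTS}
        for vals in self.per_residue.values():
            for c in COMPONENTS:
                tot[c] += vals[c]
        tot["total"] = sum(tot[c] for c in COMPONENTS)
        return tot

    def residue_total(self, key) -> float:
        return self.per_residue[key]["total"]

    def to_frame(self, resnames=None) -> pd.DataFrame:
        rows = []
        for key in sorted(self.per_residue):
            v = self.per_residue[key]
            rows.append((key[0], key[1],
                         resnames.get(key, "") if resnames else "",
                         v["elec"], v["vdw"], v["polar_solv"],
                         v["nonpolar_solv"], v["total"]))
        return pd.DataFrame(rows, columns=[
            "chain", "position", "resname",
            "elec (kJ/mol)", "vdw (kJ/mol)", "polar (kJ/mol)",
            "nonpolar (kJ/mol)", "total (kJ/mol)",
        ])


# ---------------------------------------------------------------------------
# molecular-mechanics kernels
# ---------------------------------------------------------------------------

def _pair_arrays(structure: Structure, pair_set):
    pairs = np.asarray(list(pair_set), dtype=int)
    if pairs.size == 0:
        return pairs.reshape(0, 2), np.empty(0)
    r = np.linalg.norm(
        structure.coords[pairs[:, 0]] - structure.coords[pairs[:, 1]], axis=1
    )
    if np.any(r < 1e-9):
        raise ValidationError("coincident atoms in pair set (r = 0 singularity)")
    return pairs, r


def coulomb_energy(structure: Structure, pair_set, eps_in: float = 2.0,
                   per_pair: bool = False):
    """Coulomb energy (kJ/mol) summed over *pair_set* (atom-index pairs),
    screened by the uniform dielectric *eps_in*; no distance cutoff."""
    pairs, r = _pair_arrays(structure, pair_set)
    if pairs.shape[0] == 0:
        return (0.0, np.empty(0)) if per_pair else 0.0
    q = np.array([a.partial_charge for a in structure.atoms])
    terms = COULOMB_CONSTANT * q[pairs[:, 0]] * q[pairs[:, 1]] / (eps_in * r)
    return (float(terms.sum()), terms) if per_pair else float(terms.sum())


def lj_energy(structure: Structure, pair_set, per_pair: bool = False):
    """Lennard-Jones 12-6 energy (kJ/mol) over *pair_set* with
    Lorentz-Berthelot combination rules."""
    pairs, r = _pair_arrays(structure, pair_set)
    if pairs.shape[0] == 0:
        return (0.0, np.empty(0)) if per_pair else 0.0
    sig = np.array([a.lj_sigma for a in structure.atoms])
    eps = np.array([a.lj_epsilon for a in structure.atoms])
    sij = 0.5 * (sig[pairs[:, 0]] + sig[pairs[:, 1]])
    eij = np.sqrt(eps[pairs[:, 0]] * eps[pairs[:, 1]])
    sr6 = (sij / r) ** 6
    terms = 4.0 * eij * (sr6 ** 2 - sr6)
    return (float(terms.sum()), terms) if per_pair else float(terms.sum())


def interface_pairs(ligand_atoms, receptor_atoms) -> list:
    """All cross (ligand atom, receptor atom) index pairs."""
    return [(int(i), int(j)) for i in ligand_atoms for j in receptor_atoms]


# ---------------------------------------------------------------------------
# generalized Born polar solvation
# ---------------------------------------------------------------------------

#: OBC II rescaling coefficients and the HCT neighbour-radius scale factor.
_OBC_ALPHA, _OBC_BETA, _OBC_GAMMA = 1.0, 0.8, 4.85
_HCT_SCALE = 0.8


def born_radii(structure: Structure, radii=None) -> np.ndarray:
    """Effective Born radii (A): HCT pairwise descreening with OBC
    tanh rescaling.

    The descreening integral I_j of each (scaled) neighbour sphere is
    accumulated into Psi_i = rho_i * sum_j I_j, and
    1/B_i = 1/rho_i - tanh(alpha Psi - beta Psi^2 + gamma Psi^3) / rho_i,
    which keeps B_i positive for any geometry and reduces to the intrinsic
    radius rho_i for an isolated atom. Raises on nonpositive radii as a
    numeric safeguard.
    """
    if radii is None:
        radii = np.array([vdw_radius(a) for a in structure.atoms])
    radii = np.asarray(radii, dtype=float)
    n = structure.n_atoms
    if n == 1:
        return radii.copy()
    r = squareform(pdist(structure.coords))
    rho_i = radii[:, None]
    srho_j = _HCT_SCALE * radii[None, :]

    separated = r >= rho_i + srho_j
    overlapping = (r > np.abs(rho_i - srho_j)) & ~separated
    engulfed = ~separated & ~overlapping & (rho_i < srho_j)
    active = separated | overlapping | engulfed
    np.fill_diagonal(active, False)  # no self-descreening
    r = np.where(active, r, 1.0)  # dummy distance where inactive

    upper = r + srho_j
    lower = np.where(separated, r - srho_j,
                     np.where(overlapping, np.broadcast_to(rho_i, r.shape),
                              np.maximum(srho_j - r, 1e-6)))
    lower = np.where(active, lower, 1.0)  # dummy to keep logs finite
    upper = np.where(active & (upper > lower), upper, lower * (1 + 1e-12))
    integral = 0.5 * (
        1.0 / lower - 1.0 / upper
        + 0.25 * (r - srho_j ** 2 / r) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
        + 0.5 * np.log(lower / upper) / r
    )
    integral = np.where(active, integral, 0.0)
    psi = radii * integral.sum(axis=1)
    inv_b = (1.0 - np.tanh(_OBC_ALPHA * psi - _OBC_BETA * psi ** 2
                           + _OBC_GAMMA * psi ** 3)) / radii
    if np.any(inv_b <= 0):
        raise ValidationError("nonpositive Born radius (overlapping atom cluster)")
    return 1.0 / inv_b


def gb_polar_energy(structure: Structure, config: EnergeticsConfig | None = None,
                    radii=None, per_atom: bool = False):
    """Still-type generalized Born polar solvation energy (kJ/mol).

    E = -1/2 (1/eps_in - 1/eps_out) k sum_ij q_i q_j / f_GB with
    f_GB = sqrt(r^2 + B_i B_j exp(-r^2 / (4 B_i B_j))); the i = j term is
    the Born self-energy q^2 / B. Vanishes when eps_in = eps_out or all
    charges are zero.
    """
    config = config or EnergeticsConfig()
    q = np.array([a.partial_charge for a in structure.atoms])
    tau = 1.0 / config.eps_in - 1.0 / config.eps_out
    if tau == 0.0 or not np.any(q):
        zeros = np.zeros(structure.n_atoms)
        return (0.0, zeros) if per_atom else 0.0
    b = born_radii(structure, radii=radii)
    r2 = squareform(pdist(structure.coords)) ** 2
    bb = np.outer(b, b)
    f_gb = np.sqrt(r2 + bb * np.exp(-r2 / (4.0 * bb)))
    qq = np.outer(q, q)
    pair_matrix = -0.5 * tau * COULOMB_CONSTANT * qq / f_gb
    total = float(pair_matrix.sum())
    if per_atom:
        return total, pair_matrix.sum(axis=1)  # symmetric half-attribution
    return total


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA and the nonpolar term
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Fibonacci spiral points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sasa(structure: Structure, probe: float = 1.4, n_points: int = 960,
         radii=None) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2), Shrake-Rupley.

    Each atom's extended sphere (vdW radius + probe) is sampled with a
    deterministic Fibonacci grid; points buried inside any neighbour's
    extended sphere are discarded.
    """
    if radii is None:
        radii = np.array([vdw_radius(a) for a in structure.atoms])
    ext = np.asarray(radii) + probe
    unit = _sphere_points(n_points)
    coords = structure.coords
    n = structure.n_atoms
    areas = np.empty(n)
    d = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        neighbours = np.where((d[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            accessible &= (
                np.linalg.norm(pts - coords[j], axis=1) >= ext[j]
            )
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


def nonpolar_energy(structure: Structure, config: EnergeticsConfig | None = None,
                    per_atom: bool = False):
    """Nonpolar solvation = gamma * total SASA + offset (kJ/mol)."""
    config = config or EnergeticsConfig()
    areas = sasa(structure, probe=config.probe_radius, n_points=config.sasa_points)
    terms = config.gamma_sasa * areas
    total = float(terms.sum()) + config.sasa_offset
    return (total, terms) if per_atom else total


# ---------------------------------------------------------------------------
# binding free energy
# ---------------------------------------------------------------------------

def _subset_structure(structure: Structure, atom_idx) -> Structure:
    atom_idx = np.asarray(atom_idx, dtype=int)
    return Structure([structure.atoms[i] for i in atom_idx],
                     structure.coords[atom_idx])


def _selection_atoms(topology, residue_keys) -> np.ndarray:
    keys = set(residue_keys)
    return np.array([i for i, a in enumerate(topology) if a.residue_key in keys],
                    dtype=int)


def per_residue_decomposition(traj: Trajectory, ligand_selection,
                              receptor_selection,
                              config: EnergeticsConfig | None = None) -> EnergyDecomposition:
    """Frame-averaged binding free energy attributed to residues.

    Selections are iterables of (chain, residue_index) keys; they must be
    disjoint and together cover the complex. Interface molecular-mechanics
    pair terms are split half/half between the partner residues; the polar
    and nonpolar solvation Deltas (complex - receptor - ligand on identical
    coordinates) are attributed per atom and summed per residue, so
    per-residue columns sum exactly to the totals.
    """
    config = config or EnergeticsConfig()
    lig_keys, rec_keys = set(ligand_selection), set(receptor_selection)
    if not lig_keys or not rec_keys:
        raise ValidationError("empty selection")
    if lig_keys & rec_keys:
        raise ValidationError("ligand and receptor selections overlap")
    all_keys = {a.residue_key for a in traj.topology}
    if lig_keys | rec_keys != all_keys:
        raise ValidationError("selections must cover the complex")

    topo = traj.topology
    lig_atoms = _selection_atoms(topo, lig_keys)
    rec_atoms = _selection_atoms(topo, rec_keys)
    pairs = interface_pairs(lig_atoms, rec_atoms)
    atom_res = [a.residue_key for a in topo]

    frames = range(0, traj.n_frames, config.frame_stride)
    accum = {k: {c: 0.0 for c in COMPONENTS} for k in all_keys}
    n_used = 0
    for f in frames:
        frame = Structure(topo, traj.frames[f])
        _, elec_terms = coulomb_energy(frame, pairs, config.eps_in, per_pair=True)
        _, vdw_terms = lj_energy(frame, pairs, per_pair=True)
        for (i, j), e, v in zip(pairs, elec_terms, vdw_terms):
            accum[atom_res[i]]["elec"] += 0.5 * e
            accum[atom_res[j]]["elec"] += 0.5 * e
            accum[atom_res[i]]["vdw"] += 0.5 * v
            accum[atom_res[j]]["vdw"] += 0.5 * v

        lig = _subset_structure(frame, lig_atoms)
        rec = _subset_structure(frame, rec_atoms)
        _, gb_cx = gb_polar_energy(frame, config, per_atom=True)
        _, gb_lig = gb_polar_energy(lig, config, per_atom=True)
        _, gb_rec = gb_polar_energy(rec, config, per_atom=True)
        _, np_cx = nonpolar_energy(frame, config, per_atom=True)
        _, np_lig = nonpolar_energy(lig, config, per_atom=True)
        _, np_rec = nonpolar_energy(rec, config, per_atom=True)
        d_gb = gb_cx.copy()
        d_np = np_cx.copy()
        d_gb[lig_atoms] -= gb_lig
        d_gb[rec_atoms] -= gb_rec
        d_np[lig_atoms] -= np_lig
        d_np[rec_atoms] -= np_rec
        for i, key in enumerate(atom_res):
            accum[key]["polar_solv"] += d_gb[i]
            accum[key]["nonpolar_solv"] += d_np[i]
        n_used += 1

    per_residue = {}
    for key, vals in accum.items():
        avg = {c: vals[c] / n_used for c in COMPONENTS}
        avg["total"] = sum(avg.values())
        per_residue[key] = avg
    return EnergyDecomposition(per_residue, frame_count=n_used)


def binding_free_energy(traj: Trajectory, ligand_selection, receptor_selection,
                        config: EnergeticsConfig | None = None) -> EnergyDecomposition:
    """Single-trajectory MM-GB/SA binding free energy (kJ/mol).

    Identical to :func:`per_residue_decomposition` (whose totals it
    returns); exposed separately so callers wanting only the headline
    dG and its four components have a direct entry point.
    """
    return per_residue_decomposition(traj, ligand_selection, receptor_selection, config)


def interaction_energy_series(traj: Trajectory, ligand_selection,
                              receptor_selection,
                              config: EnergeticsConfig | None = None):
    """Per-frame interface MM energy (elec + vdW, kJ/mol) — the
    interaction-energy order parameter for free-energy surfaces."""
    from .metrics import MetricSeries

    config = config or EnergeticsConfig()
    topo = traj.topology
    lig_atoms = _selection_atoms(topo, set(ligand_selection))
    rec_atoms = _selection_atoms(topo, set(receptor_selection))
    if lig_atoms.size == 0 or rec_atoms.size == 0:
        raise ValidationError("empty selection")
    pairs = interface_pairs(lig_atoms, rec_atoms)
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = Structure(topo, traj.frames[f])
        vals[f] = coulomb_energy(frame, pairs, config.eps_in) + lj_energy(frame, pairs)
    return MetricSeries("interaction_energy", vals, "kJ/mol")


def difference_map(a: EnergyDecomposition, b: EnergyDecomposition) -> dict:
    """Per-position difference of residue totals, a - b (kJ/mol).

    Positions present in only one decomposition are reported under the
    ``"only_a"`` / ``"only_b"`` keys rather than imputed as zero.
    """
    keys_a, keys_b = set(a.per_residue), set(b.per_residue)
    shared = keys_a & keys_b
    if not shared:
        raise ValidationError("decompositions share no positions")
    return {
        "delta": {k: a.residue_total(k) - b.residue_total(k) for k in sorted(shared)},
        "only_a": sorted(keys_a - keys_b),
        "only_b": sorted(keys_b - keys_a),
    }
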