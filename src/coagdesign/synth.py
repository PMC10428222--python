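"""Synthetic peptide-receptor complexes and trajectories with planted,
quantitatively known interaction structure.

The generator emulates the statistical structure of all-atom
peptide-GPCR trajectories at the level downstream analyses consume: a
helical peptide in a receptor pocket, hydrogen-bond pairs with controlled
per-frame occupancy, salt-bridge pairs at controlled contact distances,
and per-residue positional fluctuation amplitudes. There are no dynamics,
solvent or membrane — each frame draws planted contacts independently
(Bernoulli at the target occupancy) and perturbs every atom with isotropic
Gaussian noise, which makes every occupancy and RMSF statistic testable in
closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AA1_TO_3,
    ELEMENT_MASS,
    AtomRecord,
    PeptideSequence,
    ReceptorAnnotation,
    Structure,
    Trajectory,
    ValidationError,
    write_pdb,
)
from .params import assign_params

# backbone internal coordinates (Engh-Huber-like ideal values)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.2, 121.7
_A_CA_C_O, _A_C_N_H = 120.8, 119.5
PHI_HELIX, PSI_HELIX, OMEGA = -57.0, -47.0, 180.0

#: terminal side-chain atoms per charged residue: (atom names, element,
#: distance of first atom from CA along the outward side-chain direction)
_CHARGED_TERMINI = {
    "D": (("OD1", "OD2"), "O", 3.6),
    "E": (("OE1", "OE2"), "O", 4.8),
    "K": (("NZ",), "N", 5.0),
    "R": (("NH1", "NH2"), "N", 5.8),
    "H": (("NE2",), "N", 4.4),
}


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF: position d with |cd|=bond, angle(b,c,d)=angle, torsion(a,b,c,d)=torsion."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n, ca, c):
    # fitted ideal-geometry expression for the Cbeta direction
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec + ca


def build_ideal_helix(seq: PeptideSequence, chain_id: str = "P",
                      start_residue: int = 1) -> Structure:
    """Build a canonical alpha-helix (phi=-57, psi=-47) for *seq*.

    Backbone N, H, CA, C, O atoms are placed by internal-coordinate chain
    extension; charged residues (D/E/K/R/H) get explicit terminal
    side-chain atoms (carboxylate O pair, NZ, NH1/NH2, NE2), every other
    residue a single neutral pseudo-atom in the Cbeta direction. Charges
    and LJ types are assigned from the bundled minimal table.
    """
    if len(seq) < 4:
        raise ValidationError(f"helix needs >= 4 residues, got {len(seq)}")

    backbone = []  # per residue: dict of name -> coord
    for i in range(len(seq)):
        res = {}
        if i == 0:
            res["N"] = np.zeros(3)
            res["CA"] = np.array([_B_N_CA, 0.0, 0.0])
            ang = np.deg2rad(_A_N_CA_C)
            res["C"] = res["CA"] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
            res["H"] = _place_atom(res["C"], res["CA"], res["N"], _B_N_H, 118.0, 180.0)
        else:
            prev = backbone[i - 1]
            res["N"] = _place_atom(prev["N"], prev["CA"], prev["C"],
                                   _B_C_N, _A_CA_C_N, PSI_HELIX)
            res["CA"] = _place_atom(prev["CA"], prev["C"], res["N"],
                                    _B_N_CA, _A_C_N_CA, OMEGA)
            res["C"] = _place_atom(prev["C"], res["N"], res["CA"],
                                   _B_CA_C, _A_N_CA_C, PHI_HELIX)
            res["H"] = _place_atom(prev["O"], prev["C"], res["N"],
                                   _B_N_H, _A_C_N_H, 180.0)
        res["O"] = _place_atom(res["N"], res["CA"], res["C"],
                               _B_C_O, _A_CA_C_O, PSI_HELIX + 180.0)
        backbone.append(res)

    atoms, coords = [], []
    for i, aa in enumerate(seq.residues):
        res_id = start_residue + i
        res3 = AA1_TO_3[aa]
        bb = backbone[i]
        for name in ("N", "H", "CA", "C", "O"):
            el = name[0] if name != "CA" else "C"
            atoms.append(AtomRecord(name, el, res_id, res3, chain_id,
                                    mass=ELEMENT_MASS[el]))
            coords.append(bb[name])
        cb = _cb_position(bb["N"], bb["CA"], bb["C"])
        direction = cb - bb["CA"]
        direction /= np.linalg.norm(direction)
        if aa in _CHARGED_TERMINI:
            names, element, dist = _CHARGED_TERMINI[aa]
            # split paired terminal atoms perpendicular to the chain direction
            perp = np.cross(direction, bb["C"] - bb["N"])
            perp /= np.linalg.norm(perp)
            for k, name in enumerate(names):
                offset = (k - (len(names) - 1) / 2.0) * 2.2 * perp
                atoms.append(AtomRecord(name, element, res_id, res3, chain_id,
                                        mass=ELEMENT_MASS[element]))
                coords.append(bb["CA"] + dist * direction + offset)
        else:
            atoms.append(AtomRecord("CB", "C", res_id, res3, chain_id,
                                    mass=ELEMENT_MASS["C"]))
            coords.append(bb["CA"] + 1.53 * direction)

    return assign_params(Structure(atoms, np.array(coords)))


def helix_axis(structure: Structure, chain_id: str = "P") -> tuple:
    """Least-squares axis (point, unit direction) through the chain's CA atoms."""
    idx = structure.atom_indices(chain_id=chain_id, atom_name="CA")
    ca = structure.coords[idx]
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    return center, vt[0]


def build_toy_receptor(
    n_pocket_residues: int,
    annotation_spec: ReceptorAnnotation | None = None,
    residue_types: str = "DEKRSQ",
    cylinder_radius: float = 16.0,
    axis_length: float = 40.0,
    chain_id: str = "R",
    residue_ids=None,
) -> Structure:
    """A ring of pocket residues on a cylinder around the z axis.

    Not a folded receptor: each residue is an independent backbone cluster
    with its side-chain terminal atoms pointing inward, so all interface
    geometry is controlled by :func:`generate_trajectory`'s plan rather
    than by a fold.
    """
    if n_pocket_residues < 1:
        raise ValidationError("need at least one pocket residue")
    if residue_ids is None:
        residue_ids = list(range(1, n_pocket_residues + 1))
    if len(residue_ids) != n_pocket_residues:
        raise ValidationError("residue_ids length mismatch")

    atoms, coords = [], []
    for k in range(n_pocket_residues):
        aa = residue_types[k % len(residue_types)]
        res3 = AA1_TO_3[aa]
        res_id = residue_ids[k]
        theta = 2.0 * np.pi * k / n_pocket_residues
        z = -axis_length / 2.0 + axis_length * (k + 0.5) / n_pocket_residues
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        ca = cylinder_radius * radial + np.array([0.0, 0.0, z])
        inward = -radial
        bb = {
            "N": ca + 1.46 * tangent,
            "CA": ca,
            "C": ca - 1.52 * tangent,
            "O": ca - 1.52 * tangent + 1.23 * np.array([0.0, 0.0, 1.0]),
        }
        bb["H"] = bb["N"] + 1.01 * (0.6 * tangent + 0.8 * np.array([0.0, 0.0, -1.0]))
        for name in ("N", "H", "CA", "C", "O"):
            el = name[0] if name != "CA" else "C"
            atoms.append(AtomRecord(name, el, res_id, res3, chain_id,
                                    mass=ELEMENT_MASS[el]))
            coords.append(bb[name])
        if aa in _CHARGED_TERMINI:
            names, element, dist = _CHARGED_TERMINI[aa]
            for j, name in enumerate(names):
                offset = (j - (len(names) - 1) / 2.0) * 2.2 * tangent
                atoms.append(AtomRecord(name, element, res_id, res3, chain_id,
                                        mass=ELEMENT_MASS[element]))
                coords.append(ca + dist * inward + offset)
        else:
            atoms.append(AtomRecord("CB", "C", res_id, res3, chain_id,
                                    mass=ELEMENT_MASS["C"]))
            coords.append(ca + 1.53 * inward)

    return assign_params(Structure(atoms, np.array(coords)))


def merge(*structures: Structure) -> Structure:
    atoms = [a for s in structures for a in s.atoms]
    coords = np.vstack([s.coords for s in structures])
    return Structure(atoms, coords)


@dataclass
class InteractionPlan:
    """Ground-truth interaction targets for a synthetic trajectory.

    hbond_pairs : list of ((chain, res, atom), (chain, res, atom), occupancy)
        Donor heavy atom (must have an attached H), acceptor atom, target
        per-frame contact probability.
    saltbridge_pairs : list of ((chain, res), (chain, res), distance, occupancy)
        Acidic residue, basic residue, planted min N-O distance (A), target
        occupancy.
    fluctuation_profile : dict (chain, res) -> sigma, or float
        Per-coordinate isotropic Gaussian displacement amplitude (A).
    """

    hbond_pairs: list = field(default_factory=list)
    saltbridge_pairs: list = field(default_factory=list)
    fluctuation_profile: object = 0.0
    seed: int = 0

    def __post_init__(self):
        for _, _, occ in self.hbond_pairs:
            if not 0.0 <= occ <= 1.0:
                raise ValidationError(f"H-bond occupancy {occ} outside [0,1]")
        for _, _, dist, occ in self.saltbridge_pairs:
            if dist <= 0:
                raise ValidationError("salt-bridge contact distance must be > 0")
            if not 0.0 <= occ <= 1.0:
                raise ValidationError(f"salt-bridge occupancy {occ} outside [0,1]")
        if isinstance(self.fluctuation_profile, dict):
            if any(s < 0 for s in self.fluctuation_profile.values()):
                raise ValidationError("fluctuation sigma must be >= 0")
        elif self.fluctuation_profile < 0:
            raise ValidationError("fluctuation sigma must be >= 0")

    def sigma_for(self, residue_key) -> float:
        if isinstance(self.fluctuation_profile, dict):
            return float(self.fluctuation_profile.get(residue_key, 0.0))
        return float(self.fluctuation_profile)

    def to_json(self) -> dict:
        return {
            "hbond_pairs": [[list(d), list(a), occ] for d, a, occ in self.hbond_pairs],
            "saltbridge_pairs": [
                [list(a), list(b), dist, occ]
                for a, b, dist, occ in self.saltbridge_pairs
            ],
            "fluctuation_profile": (
                {f"{c}:{r}": s for (c, r), s in self.fluctuation_profile.items()}
                if isinstance(self.fluctuation_profile, dict)
                else self.fluctuation_profile
            ),
            "seed": self.seed,
        }


_DISPLACED = 8.0  # A; broken-contact donor-acceptor distance
_HB_CONTACT = 2.9  # A; planted donor-acceptor distance (within the 3.0 A criterion)


def _atom_index(structure: Structure, chain, res, name) -> int:
    idx = structure.atom_indices(chain_id=chain, residue_index=res, atom_name=name)
    if len(idx) == 0:
        raise ValidationError(f"plan refers to unknown atom {chain}/{res}/{name}")
    return int(idx[0])


def _terminal_atoms(structure: Structure, chain, res, elements) -> np.ndarray:
    idx = [
        i for i, a in enumerate(structure.atoms)
        if a.chain_id == chain and a.residue_index == res
        and a.element in elements and a.atom_name not in ("N", "O", "C", "CA", "CB", "H")
    ]
    if not idx:
        raise ValidationError(
            f"plan refers to residue {chain}/{res} with no charged terminal atoms"
        )
    return np.array(idx, dtype=int)


def generate_trajectory(complex_structure: Structure, plan: InteractionPlan,
                        n_frames: int, frame_interval: float = 2.0) -> Trajectory:
    """Sample *n_frames* synthetic frames implementing *plan*.

    Per frame and planted pair an independent Bernoulli(occupancy) draw
    decides contact: an H-bond acceptor is placed on the donor's N-H axis at
    2.9 A (angle 180 deg), a basic residue's terminal N at the planted N-O
    distance from the acidic carboxylate; broken contacts are displaced to
    8 A. Isotropic Gaussian noise with the profile's per-residue sigma is
    applied to every atom first, so planted geometry is exact. Reproducible
    for a fixed plan seed.
    """
    if n_frames < 1:
        raise ValidationError("need at least one frame")
    rng = np.random.default_rng(plan.seed)
    base = complex_structure.coords

    # resolve plan atoms once (also validates the plan against the topology)
    hb = []
    for donor, acceptor, occ in plan.hbond_pairs:
        d_idx = _atom_index(complex_structure, *donor)
        h_idx = _atom_index(complex_structure, donor[0], donor[1], "H")
        a_idx = _atom_index(complex_structure, *acceptor)
        hb.append((d_idx, h_idx, a_idx, occ))
    sb = []
    for acidic, basic, dist, occ in plan.saltbridge_pairs:
        o_idx = _terminal_atoms(complex_structure, *acidic, elements=("O",))
        n_idx = _terminal_atoms(complex_structure, *basic, elements=("N",))
        ca_idx = _atom_index(complex_structure, acidic[0], acidic[1], "CA")
        sb.append((o_idx, n_idx, ca_idx, dist, occ))

    sigmas = np.array(
        [plan.sigma_for(a.residue_key) for a in complex_structure.atoms]
    )[:, None]

    frames = np.empty((n_frames, base.shape[0], 3))
    for f in range(n_frames):
        coords = base + rng.standard_normal(base.shape) * sigmas
        for d_idx, h_idx, a_idx, occ in hb:
            u = coords[h_idx] - coords[d_idx]
            u /= np.linalg.norm(u)
            dist = _HB_CONTACT if rng.random() < occ else _DISPLACED
            coords[a_idx] = coords[d_idx] + dist * u
        for o_idx, n_idx, ca_idx, target, occ in sb:
            # plant along the acidic side-chain extension (CA -> carboxylate),
            # which points away from the backbone and cannot clash with it
            o_pos = coords[o_idx[0]]
            u = o_pos - coords[ca_idx]
            norm = np.linalg.norm(u)
            u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
            dist = target if rng.random() < occ else _DISPLACED
            for j, ni in enumerate(n_idx):
                coords[ni] = o_pos + (dist + 1.0 * j) * u
        frames[f] = coords

    return Trajectory(complex_structure.atoms, frames, frame_interval)


def save_fixture(traj: Trajectory, plan: InteractionPlan, pdb_path, json_path):
    """Persist a synthetic trajectory as multi-model PDB plus a JSON sidecar
    recording the plan (the ground truth tests compare against)."""
    write_pdb(traj, pdb_path)
    with open(json_path, "w") as fh:
        json.dump(plan.to_json(), fh, indent=1)
    return Path(pdb_path), Path(json_path)
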