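"""Trajectory-derived interaction and stability metrics.

Implements the standard tool-kit used to characterise peptide-receptor
binding in MD studies: fraction of native contacts Q(x) (hard-count,
heavy-atom pairs of nonconsecutive residues within 5 A of the reference),
RMSD after optimal superposition, per-residue RMSF, radius of gyration,
hydrogen-bond occupancy networks (strong if population > 80%), salt
bridges (acidic/basic side chains, mean min N-O distance < 4 A, occupancy
>= 80% for the strong tier) and peptide-residue x receptor-domain contact
frequency maps.

Residues are identified by (chain_id, residue_index) keys throughout;
"nonconsecutive" excludes pairs on the same chain with |i - j| <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import ReceptorAnnotation, Structure, Trajectory, ValidationError

NATIVE_CONTACT_CUTOFF = 5.0  # A, heavy-atom pair distance
HBOND_DISTANCE_MAX = 3.5  # A, donor-acceptor heavy-atom distance
HBOND_ANGLE_MIN = 120.0  # deg, D-H...A
SALTBRIDGE_CUTOFF = 4.0  # A, min side-chain N-O distance
STRONG_OCCUPANCY = 0.80

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2"), "HIS": ("NE2",)}


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ContactSet:
    """Reference (native) residue-pair contacts."""

    pairs: set  # of ((chain, res), (chain, res)) sorted tuples
    reference_id: str = "reference"
    cutoff: float = NATIVE_CONTACT_CUTOFF

    def __post_init__(self):
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"self-contact {a}")
            if a[0] == b[0] and abs(a[1] - b[1]) <= 1:
                raise ValidationError(f"consecutive pair {a}-{b}")

    def __len__(self):
        return len(self.pairs)


@dataclass
class HBondRecord:
    donor: tuple  # (chain, res, atom)
    acceptor: tuple
    occupancy: float
    mean_distance: float

    @property
    def strong(self) -> bool:
        return self.occupancy > STRONG_OCCUPANCY


def saltbridge_tier(occupancy: float) -> str:
    if occupancy >= 0.80:
        return "strong"
    if occupancy >= 0.50:
        return "moderate"
    return "weak"


@dataclass
class SaltBridgeRecord:
    acidic: tuple  # (chain, res)
    basic: tuple
    mean_min_NO_distance: float
    occupancy: float

    @property
    def tier(self) -> str:
        return saltbridge_tier(self.occupancy)


@dataclass
class MetricSeries:
    """One scalar per frame (Q, RMSD, Rg or interaction energy)."""

    name: str
    values: np.ndarray
    units: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.name}: non-finite values")

    def __len__(self):
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)),
                             f"{self.name} ({self.units})": self.values})


@dataclass
class ResidueProfile:
    """One value per residue (RMSF or an energy decomposition column)."""

    name: str
    values: dict  # residue_key -> float
    units: str

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, r, v) for (c, r), v in self.values.items()]
        return pd.DataFrame(rows, columns=["chain", "residue",
                                           f"{self.name} ({self.units})"])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _heavy_by_residue(atoms) -> dict:
    out: dict = {}
    for i, a in enumerate(atoms):
        if a.is_heavy:
            out.setdefault(a.residue_key, []).append(i)
    return {k: np.array(v, dtype=int) for k, v in out.items()}


def _pair_eligible(a, b) -> bool:
    return not (a[0] == b[0] and abs(a[1] - b[1]) <= 1)


def _min_dist(coords, idx_a, idx_b) -> float:
    return float(cdist(coords[idx_a], coords[idx_b]).min())


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

def native_contacts(reference: Structure, cutoff: float = NATIVE_CONTACT_CUTOFF,
                    min_separation: int = 2) -> ContactSet:
    """Residue pairs with any heavy-atom pair within *cutoff* in the reference.

    Hydrogens are excluded; same-chain pairs with sequence separation
    < *min_separation* are not counted (default: skip self and consecutive).
    """
    keys = reference.residue_keys()
    if len(keys) < 3:
        raise ValidationError("reference needs at least 3 residues")
    heavy = _heavy_by_residue(reference.atoms)
    pairs = set()
    for ia in range(len(keys)):
        for ib in range(ia + 1, len(keys)):
            a, b = keys[ia], keys[ib]
            if a[0] == b[0] and abs(a[1] - b[1]) < min_separation:
                continue
            if a not in heavy or b not in heavy:
                continue
            if _min_dist(reference.coords, heavy[a], heavy[b]) <= cutoff:
                pairs.add(tuple(sorted((a, b))))
    return ContactSet(pairs, cutoff=cutoff)


def fraction_native_contacts(traj: Trajectory, contacts: ContactSet) -> MetricSeries:
    """Per-frame Q = fraction of native pairs still within the cutoff."""
    if len(contacts) == 0:
        raise ValidationError("empty contact set: Q is undefined")
    heavy = _heavy_by_residue(traj.topology)
    pair_idx = [(heavy[a], heavy[b]) for a, b in sorted(contacts.pairs)]
    q = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        kept = sum(
            1 for ia, ib in pair_idx
            if _min_dist(coords, ia, ib) <= contacts.cutoff
        )
        q[f] = kept / len(contacts)
    return MetricSeries("Q", q, "fraction")


# ---------------------------------------------------------------------------
# superposition-based metrics
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid-body fit (Kabsch) of *mobile* onto *target*.

    Returns (rotation matrix, translation applied after rotation about
    centroids, rmsd).
    """
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    rmsd_val = rssd / np.sqrt(mobile.shape[0])
    return rot.as_matrix(), (mc, tc), float(rmsd_val)


def rmsd(traj: Trajectory, reference: Structure, selection=None) -> MetricSeries:
    """Per-frame RMSD of *selection* after optimal superposition onto the
    reference. *selection* is an atom-index array (default: all heavy atoms)."""
    if selection is None:
        selection = np.array([i for i, a in enumerate(traj.topology) if a.is_heavy])
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValidationError("empty selection")
    if reference.n_atoms != len(traj.topology):
        raise ValidationError("reference and trajectory topologies differ")
    ref = reference.coords[selection]
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, vals[f] = superpose(traj.frames[f][selection], ref)
    return MetricSeries("RMSD", vals, "A")


def rmsf(traj: Trajectory, selection=None, superpose_frames: bool = True) -> ResidueProfile:
    """Per-residue RMSF about the time-averaged position.

    Frames are first superposed onto the running mean of the selection
    (two refinement passes; disable with ``superpose_frames=False`` for
    pre-aligned trajectories); per-atom RMSF values are then averaged over
    each residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF needs >= 2 frames")
    if selection is None:
        selection = np.arange(len(traj.topology))
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValidationError("empty selection")

    coords = traj.frames[:, selection, :].copy()
    mean = coords[0]
    if superpose_frames:
        for _ in range(2):  # align to mean, recompute mean
            for f in range(coords.shape[0]):
                rot, (mc, tc), _ = superpose(coords[f], mean)
                coords[f] = (coords[f] - mc) @ rot.T + tc
            mean = coords.mean(axis=0)
    else:
        mean = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))

    values: dict = {}
    counts: dict = {}
    for j, i in enumerate(selection):
        key = traj.topology[i].residue_key
        values[key] = values.get(key, 0.0) + per_atom[j]
        counts[key] = counts.get(key, 0) + 1
    return ResidueProfile("RMSF", {k: values[k] / counts[k] for k in values}, "A")


def radius_of_gyration(traj: Trajectory, selection=None) -> MetricSeries:
    """Mass-weighted radius of gyration of the selection, per frame."""
    if selection is None:
        selection = np.arange(len(traj.topology))
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValidationError("empty selection")
    masses = np.array([traj.topology[i].mass for i in selection])
    total = masses.sum()
    if total <= 0:
        raise ValidationError("zero total mass")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.frames[f][selection]
        com = (masses[:, None] * x).sum(axis=0) / total
        vals[f] = np.sqrt((masses * ((x - com) ** 2).sum(axis=1)).sum() / total)
    return MetricSeries("Rg", vals, "A")


# ---------------------------------------------------------------------------
# hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

def _attached_hydrogens(topology, donor_index) -> list:
    donor = topology[donor_index]
    out = [
        i for i, a in enumerate(topology)
        if a.residue_key == donor.residue_key and a.element == "H"
        and (a.atom_name == "H" or a.atom_name.startswith("H" + donor.atom_name[1:]))
    ]
    return out


def hbond_occupancy(traj: Trajectory, donors, acceptors,
                    d_max: float = HBOND_DISTANCE_MAX,
                    angle_min: float = HBOND_ANGLE_MIN) -> list:
    """Occupancy of every donor-acceptor pair ever within the criterion.

    *donors* and *acceptors* are atom-index iterables. A frame counts when
    the donor-acceptor heavy-atom distance is <= d_max and the D-H...A
    angle is >= angle_min for any attached hydrogen. Records with zero
    occupancy are omitted; ``strong`` flags populations > 80%.
    """
    topo = traj.topology
    donor_h = {}
    for d in donors:
        hs = _attached_hydrogens(topo, d)
        if not hs:
            a = topo[d]
            raise ValidationError(
                f"donor {a.chain_id}/{a.residue_index}/{a.atom_name} has no attached hydrogen"
            )
        donor_h[int(d)] = hs
    acceptors = [int(a) for a in acceptors]

    records = []
    for d, hs in donor_h.items():
        for acc in acceptors:
            if topo[acc].residue_key == topo[d].residue_key:
                continue
            dists = np.linalg.norm(traj.frames[:, acc] - traj.frames[:, d], axis=1)
            ok = dists <= d_max
            if not ok.any():
                continue
            # angle criterion over attached hydrogens
            angle_ok = np.zeros(traj.n_frames, dtype=bool)
            for h in hs:
                v1 = traj.frames[:, d] - traj.frames[:, h]
                v2 = traj.frames[:, acc] - traj.frames[:, h]
                cosang = (v1 * v2).sum(axis=1) / (
                    np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                )
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                angle_ok |= angle >= angle_min
            hit = ok & angle_ok
            occ = hit.mean()
            if occ > 0:
                da, aa = topo[d], topo[acc]
                records.append(HBondRecord(
                    donor=(da.chain_id, da.residue_index, da.atom_name),
                    acceptor=(aa.chain_id, aa.residue_index, aa.atom_name),
                    occupancy=float(occ),
                    mean_distance=float(dists[hit].mean()),
                ))
    records.sort(key=lambda r: (-r.occupancy, r.donor, r.acceptor))
    return records


def charged_side_chain_atoms(topology) -> tuple:
    """(acidic, basic) maps residue_key -> atom index array of side-chain
    carboxylate O / amine-guanidinium-imidazole N atoms."""
    acidic: dict = {}
    basic: dict = {}
    for i, a in enumerate(topology):
        if a.residue_name in ACIDIC_ATOMS and a.atom_name in ACIDIC_ATOMS[a.residue_name]:
            acidic.setdefault(a.residue_key, []).append(i)
        if a.residue_name in BASIC_ATOMS and a.atom_name in BASIC_ATOMS[a.residue_name]:
            basic.setdefault(a.residue_key, []).append(i)
    return (
        {k: np.array(v, dtype=int) for k, v in acidic.items()},
        {k: np.array(v, dtype=int) for k, v in basic.items()},
    )


def salt_bridges(traj: Trajectory, interface_only: bool = True,
                 cutoff: float = SALTBRIDGE_CUTOFF) -> list:
    """Salt bridges over all acidic x basic residue pairs.

    A record is emitted when the mean (over frames) of the minimum
    side-chain N-O distance is below *cutoff*; occupancy is the fraction
    of frames below the cutoff and sets the strong/moderate/weak tier.
    With *interface_only*, only cross-chain pairs are considered (the
    peptide-receptor interface).
    """
    acidic, basic = charged_side_chain_atoms(traj.topology)
    records = []
    for a_key, a_idx in acidic.items():
        for b_key, b_idx in basic.items():
            if interface_only and a_key[0] == b_key[0]:
                continue
            if not _pair_eligible(a_key, b_key):
                continue
            min_no = np.array([
                _min_dist(traj.frames[f], a_idx, b_idx)
                for f in range(traj.n_frames)
            ])
            if min_no.mean() < cutoff:
                records.append(SaltBridgeRecord(
                    acidic=a_key, basic=b_key,
                    mean_min_NO_distance=float(min_no.mean()),
                    occupancy=float((min_no < cutoff).mean()),
                ))
    records.sort(key=lambda r: (-r.occupancy, r.acidic, r.basic))
    return records


# ---------------------------------------------------------------------------
# interaction maps
# ---------------------------------------------------------------------------

def interaction_map(traj: Trajectory, annotation: ReceptorAnnotation,
                    peptide_chain: str = "P", receptor_chain: str = "R",
                    cutoff: float = NATIVE_CONTACT_CUTOFF) -> pd.DataFrame:
    """Contact frequency of each peptide residue with each receptor domain.

    Entry (p, dom) is the fraction of frames in which peptide residue p has
    any heavy atom within *cutoff* of any heavy atom of a residue labeled
    dom. Returned as a DataFrame, peptide residues x domain labels.
    """
    heavy = _heavy_by_residue(traj.topology)
    pep_res = sorted(r for (c, r) in heavy if c == peptide_chain)
    domain_atoms: dict = {}
    for (c, r), idx in heavy.items():
        if c == receptor_chain:
            lab = annotation.label(r)
            domain_atoms.setdefault(lab, []).append(idx)
    domains = annotation.domains()
    domain_atoms = {
        lab: np.concatenate(v) for lab, v in domain_atoms.items()
    }

    freq = np.zeros((len(pep_res), len(domains)))
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        for i, p in enumerate(pep_res):
            p_idx = heavy[(peptide_chain, p)]
            for j, dom in enumerate(domains):
                if dom not in domain_atoms:
                    continue
                if _min_dist(coords, p_idx, domain_atoms[dom]) <= cutoff:
                    freq[i, j] += 1
    freq /= traj.n_frames
    return pd.DataFrame(freq, index=pd.Index(pep_res, name="peptide_residue"),
                        columns=domains)
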