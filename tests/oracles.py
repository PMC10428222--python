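"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plainly as possible — explicit double loops,
scalar arithmetic, textbook formulas — and deliberately shares no code
with the implementation it checks.
"""

import math

import numpy as np

COULOMB_K = 1389.35458


# --- contacts ---------------------------------------------------------------

def residue_heavy_atoms(atoms):
    out = {}
    for i, a in enumerate(atoms):
        if a.element != "H":
            out.setdefault((a.chain_id, a.residue_index), []).append(i)
    return out


def brute_native_contacts(atoms, coords, cutoff=5.0):
    res = residue_heavy_atoms(atoms)
    keys = list(res)
    pairs = set()
    for x in range(len(keys)):
        for y in range(x + 1, len(keys)):
            a, b = keys[x], keys[y]
            if a[0] == b[0] and abs(a[1] - b[1]) <= 1:
                continue
            hit = False
            for i in res[a]:
                for j in res[b]:
                    if math.dist(coords[i], coords[j]) <= cutoff:
                        hit = True
            if hit:
                pairs.add(tuple(sorted((a, b))))
    return pairs


def brute_q_series(atoms, frames, native_pairs, cutoff=5.0):
    res = residue_heavy_atoms(atoms)
    out = []
    for coords in frames:
        kept = 0
        for a, b in native_pairs:
            hit = False
            for i in res[a]:
                for j in res[b]:
                    if math.dist(coords[i], coords[j]) <= cutoff:
                        hit = True
            kept += hit
        out.append(kept / len(native_pairs))
    return np.array(out)


# --- superposition ----------------------------------------------------------

def kabsch_rmsd(mobile, target):
    """Classic SVD Kabsch: optimal rotation after centroid removal."""
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ p.T).T - q
    return math.sqrt((diff ** 2).sum() / len(p))


# --- hydrogen bonds / salt bridges ------------------------------------------

def brute_hbond_occupancy(atoms, frames, donor, hydrogen, acceptor,
                          d_max=3.5, angle_min=120.0):
    hits = 0
    for coords in frames:
        d = math.dist(coords[donor], coords[acceptor])
        v1 = coords[donor] - coords[hydrogen]
        v2 = coords[acceptor] - coords[hydrogen]
        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if d <= d_max and ang >= angle_min:
            hits += 1
    return hits / len(frames)


ACID = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASE = {"LYS": ("NZ",), "ARG": ("NH1", "NH2"), "HIS": ("NE2",)}


def brute_salt_bridges(atoms, frames, cutoff=4.0, interface_only=True):
    acidic, basic = {}, {}
    for i, a in enumerate(atoms):
        if a.residue_name in ACID and a.atom_name in ACID[a.residue_name]:
            acidic.setdefault((a.chain_id, a.residue_index), []).append(i)
        if a.residue_name in BASE and a.atom_name in BASE[a.residue_name]:
            basic.setdefault((a.chain_id, a.residue_index), []).append(i)
    records = {}
    for ak, aidx in acidic.items():
        for bk, bidx in basic.items():
            if interface_only and ak[0] == bk[0]:
                continue
            if ak[0] == bk[0] and abs(ak[1] - bk[1]) <= 1:
                continue
            mins = []
            for coords in frames:
                best = min(math.dist(coords[i], coords[j])
                           for i in aidx for j in bidx)
                mins.append(best)
            if np.mean(mins) < cutoff:
                records[(ak, bk)] = (
                    float(np.mean(mins)),
                    float(np.mean([m < cutoff for m in mins])),
                )
    return records


def brute_interaction_map(atoms, frames, annotation, pep_chain="P",
                          rec_chain="R", cutoff=5.0):
    res = residue_heavy_atoms(atoms)
    pep = sorted(r for c, r in res if c == pep_chain)
    domains = annotation.domains()
    # entry = fraction of frames with >= 1 heavy-atom contact to the domain
    freq = {(p, d): 0.0 for p in pep for d in domains}
    for coords in frames:
        for p in pep:
            touched = set()
            for (c, r), idx in res.items():
                if c != rec_chain:
                    continue
                if any(math.dist(coords[i], coords[j]) <= cutoff
                       for i in res[(pep_chain, p)] for j in idx):
                    touched.add(annotation.label(r))
            for d in touched:
                freq[(p, d)] += 1.0 / len(frames)
    return freq


# --- energies ---------------------------------------------------------------

def brute_coulomb(charges, coords, pairs, eps):
    total = 0.0
    for i, j in pairs:
        r = math.dist(coords[i], coords[j])
        total += COULOMB_K * charges[i] * charges[j] / (eps * r)
    return total


def brute_lj(sigmas, epsilons, coords, pairs):
    total = 0.0
    for i, j in pairs:
        r = math.dist(coords[i], coords[j])
        s = 0.5 * (sigmas[i] + sigmas[j])
        e = math.sqrt(epsilons[i] * epsilons[j])
        total += 4.0 * e * ((s / r) ** 12 - (s / r) ** 6)
    return total


def scalar_born_radii(coords, radii, scale=0.8, alpha=1.0, beta=0.8, gamma=4.85):
    """Scalar reimplementation of HCT descreening with OBC rescaling."""
    n = len(radii)
    out = []
    for i in range(n):
        rho_i = radii[i]
        acc = 0.0
        for j in range(n):
            if i == j:
                continue
            rij = math.dist(coords[i], coords[j])
            sj = scale * radii[j]
            if rij >= rho_i + sj:
                lo, up = rij - sj, rij + sj
            elif rij > abs(rho_i - sj):
                lo, up = rho_i, rij + sj
            elif rho_i < sj:
                lo, up = max(sj - rij, 1e-6), rij + sj
            else:
                continue
            if up <= lo:
                continue
            acc += 0.5 * (1.0 / lo - 1.0 / up
                          + 0.25 * (rij - sj ** 2 / rij) * (1.0 / up ** 2 - 1.0 / lo ** 2)
                          + 0.5 * math.log(lo / up) / rij)
        psi = rho_i * acc
        inv_b = (1.0 - math.tanh(alpha * psi - beta * psi ** 2 + gamma * psi ** 3)) / rho_i
        out.append(1.0 / inv_b)
    return out


def scalar_gb_energy(charges, coords, radii, eps_in, eps_out):
    """Still pairwise GB with scalar Born radii; includes self terms."""
    b = scalar_born_radii(coords, radii)
    tau = 1.0 / eps_in - 1.0 / eps_out
    total = 0.0
    n = len(charges)
    for i in range(n):
        for j in range(n):
            r2 = math.dist(coords[i], coords[j]) ** 2
            bb = b[i] * b[j]
            fgb = math.sqrt(r2 + bb * math.exp(-r2 / (4.0 * bb)))
            total += -0.5 * tau * COULOMB_K * charges[i] * charges[j] / fgb
    return total


def fine_grid_sasa(coords, radii, probe, n_points=20000, seed=0):
    """High-resolution random-sphere SASA integration."""
    rng = np.random.default_rng(seed)
    ext = np.asarray(radii) + probe
    areas = []
    for i in range(len(radii)):
        v = rng.standard_normal((n_points, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + ext[i] * v
        ok = np.ones(n_points, dtype=bool)
        for j in range(len(radii)):
            if j == i:
                continue
            ok &= np.linalg.norm(pts - coords[j], axis=1) >= ext[j]
        areas.append(4.0 * np.pi * ext[i] ** 2 * ok.mean())
    return np.array(areas)
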