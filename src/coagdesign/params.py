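"""Minimal per-atom parameter table for the simplified topology.

A deliberately small surrogate for a full protein force field: backbone
atoms carry a neutral charge group, charged side chains (Asp/Glu
carboxylate pair, Lys NZ, Arg NH1/NH2) carry the residue's formal charge,
and each element has a single Lennard-Jones type. The package scores and
compares complexes; it does not simulate them, so full force-field
fidelity is out of scope.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import Structure, ValidationError

#: Backbone charge group (sums to zero); applies to every residue.
_BACKBONE_CHARGES = {
    "N": -0.35,
    "H": 0.25,
    "CA": 0.10,
    "C": 0.45,
    "O": -0.45,
    "CB": 0.0,  # neutral side-chain pseudo-atom
}

#: Side-chain terminal atoms carrying formal charge.
_SIDECHAIN_CHARGES = {
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    ("HIS", "NE2"): 0.0,  # neutral (unprotonated) His
}

#: One LJ type per element: sigma (A), epsilon (kJ/mol).
_ELEMENT_LJ = {
    "H": (1.00, 0.065),
    "C": (3.40, 0.36),
    "N": (3.25, 0.71),
    "O": (2.96, 0.88),
    "S": (3.56, 1.05),
}

#: Formal residue net charges encoded by the table (validation reference).
RESIDUE_NET_CHARGE = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}

DEFAULT_TABLE = {
    "backbone": _BACKBONE_CHARGES,
    "sidechain": _SIDECHAIN_CHARGES,
    "lj": _ELEMENT_LJ,
}


class ParameterLookupError(KeyError):
    """A (residue, atom) pair has no entry in the parameter table."""


def lookup_charge(residue_name: str, atom_name: str, table=None) -> float:
    table = table or DEFAULT_TABLE
    if (residue_name, atom_name) in table["sidechain"]:
        return table["sidechain"][(residue_name, atom_name)]
    if atom_name in table["backbone"]:
        return table["backbone"][atom_name]
    raise ParameterLookupError(
        f"no parameters for atom {atom_name!r} in residue {residue_name!r}"
    )


def assign_params(structure: Structure, table=None) -> Structure:
    """Return a copy of *structure* with charges and LJ parameters filled in.

    Coordinates and atom ordering are never touched. Raises
    :class:`ParameterLookupError` naming the offending residue/atom when the
    table has no entry.
    """
    table = table or DEFAULT_TABLE
    new_atoms = []
    for atom in structure.atoms:
        charge = lookup_charge(atom.residue_name, atom.atom_name, table)
        try:
            sigma, eps = table["lj"][atom.element]
        except KeyError as exc:
            raise ParameterLookupError(
                f"no LJ type for element {atom.element!r} "
                f"(atom {atom.atom_name} / {atom.residue_name})"
            ) from exc
        new = dataclasses.replace(
            atom, partial_charge=charge, lj_sigma=sigma, lj_epsilon=eps
        )
        new.validate()
        new_atoms.append(new)
    return Structure(new_atoms, structure.coords.copy())


def residue_net_charges(structure: Structure) -> dict:
    """Sum of partial charges per (chain, residue_index)."""
    out: dict = {}
    for atom, q in zip(structure.atoms, (a.partial_charge for a in structure.atoms)):
        out[atom.residue_key] = out.get(atom.residue_key, 0.0) + q
    return out


def vdw_radius(atom) -> float:
    """Van der Waals radius (A) from the LJ sigma: r = 2^(1/6) * sigma / 2."""
    return float(2.0 ** (1.0 / 6.0) * atom.lj_sigma / 2.0)
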