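import numpy as np
import pytest

from coagdesign.core import AtomRecord, PeptideSequence, ReceptorAnnotation, Structure
from coagdesign.design import GLUCAGON
from coagdesign.pipeline import make_demo_system
from coagdesign.synth import build_ideal_helix


@pytest.fixture(scope="session")
def glucagon():
    return PeptideSequence("GCG", GLUCAGON)


@pytest.fixture(scope="session")
def glucagon_helix(glucagon):
    return build_ideal_helix(glucagon)


@pytest.fixture(scope="session")
def demo_system(glucagon):
    """A small synthetic glucagon-receptor complex trajectory (50 frames)."""
    return make_demo_system(glucagon, n_frames=50, seed=7, fluctuation_sigma=0.1)


def make_atom(name="X", element="C", res=1, resname="GLY", chain="A",
              charge=0.0, sigma=3.0, epsilon=0.5, mass=12.011):
    return AtomRecord(name, element, res, resname, chain,
                      partial_charge=charge, lj_sigma=sigma,
                      lj_epsilon=epsilon, mass=mass)


@pytest.fixture
def random_toy_complex():
    """6-residue two-chain toy with charged side chains at random positions."""
    rng = np.random.default_rng(42)
    atoms, coords = [], []
    spec = [("P", 1, "ASP", ("OD1", "OD2"), "O"),
            ("P", 2, "LYS", ("NZ",), "N"),
            ("P", 3, "GLY", ("CB",), "C"),
            ("R", 10, "ARG", ("NH1", "NH2"), "N"),
            ("R", 11, "GLU", ("OE1", "OE2"), "O"),
            ("R", 12, "SER", ("CB",), "C")]
    for chain, res, resname, side, element in spec:
        center = rng.uniform(-6, 6, 3)
        for bb, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(make_atom(bb, el, res, resname, chain,
                                   charge=rng.uniform(-0.3, 0.3)))
            coords.append(center + rng.uniform(-0.8, 0.8, 3))
        for name in side:
            atoms.append(make_atom(name, element, res, resname, chain,
                                   charge=rng.uniform(-0.6, 0.6)))
            coords.append(center + rng.uniform(-2.5, 2.5, 3))
    return Structure(atoms, np.array(coords))


@pytest.fixture
def toy_annotation():
    return ReceptorAnnotation([(1, 6, "ECD"), (7, 9, "TM6"), (10, 12, "TM7")])
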