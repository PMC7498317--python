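"""Shared fixtures: synthetic structures and profiles built once per session."""

import numpy as np
import pytest

from clampscope import (
    BDNAParams,
    build_bdna,
    build_helix_bundle,
    debye_profile,
)
from clampscope.saxs import default_q_grid
from clampscope.structure_io import Atom, Residue, StructureModel

TEN_A_SEQUENCE = "CCGAAAAAAAAAACGC"  # 16-mer with a 10-bp A-tract


@pytest.fixture(scope="session")
def duplex_10a():
    return build_bdna(BDNAParams(sequence=TEN_A_SEQUENCE))


@pytest.fixture(scope="session")
def bundle_compact():
    """Toy 'closed' conformer: tight 4-helix bundle."""
    return build_helix_bundle(n_helices=4, residues_per_helix=20, spacing=9.0)


@pytest.fixture(scope="session")
def bundle_extended():
    """Toy 'open' conformer: same helices on a wider lattice (larger Rg)."""
    return build_helix_bundle(n_helices=4, residues_per_helix=20, spacing=14.0)


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid(0.0, 0.30, 151)


@pytest.fixture(scope="session")
def profile_compact(bundle_compact, q_grid):
    return debye_profile(bundle_compact, q_grid)


@pytest.fixture(scope="session")
def profile_extended(bundle_extended, q_grid):
    return debye_profile(bundle_extended, q_grid)


def make_point_model(coords, element="C", name_prefix=None):
    """A one-residue model holding bare point scatterers (test helper)."""
    model = StructureModel(id="points")
    res = Residue("UNK", 1, kind="other")
    prefix = name_prefix or element
    for i, c in enumerate(coords):
        res.atoms.append(Atom(f"{prefix}{i + 1}", element, np.asarray(c, dtype=float)))
    model.chains["A"] = [res]
    return model


def make_residue(name, seq_number, atom_specs, kind="amino_acid"):
    """Residue from (atom_name, element, xyz) triples (test helper)."""
    res = Residue(name, seq_number, kind=kind)
    for atom_name, element, xyz in atom_specs:
        res.atoms.append(Atom(atom_name, element, np.asarray(xyz, dtype=float)))
    return res
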