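"""Rigid-body superposition, RMSD, and interface inventories.

Superposition is the standard least-squares (Kabsch) rotation over
correspondence-ordered selections.  Interface analysis covers residue-pair
salt bridges between charged side-chain groups and protein residues in
contact with DNA phosphate groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from clampscope._linalg import kabsch
from clampscope.structure_io import (
    Atom,
    AtomSelection,
    Residue,
    StructureModel,
    select_atoms,
)


@dataclass
class SuperpositionResult:
    """Optimal rigid transform of a mobile onto a reference selection."""

    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector, A
    rmsd: float  # A
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of two correspondence-ordered point sets.

    Returns the proper rotation and translation minimizing the RMSD of
    ``mobile`` against ``reference``; reflections are never returned.
    Requires n >= 3 non-degenerate points.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape:
        raise ValueError(
            f"selection size mismatch: {reference.shape[0]} reference vs "
            f"{mobile.shape[0]} mobile atoms"
        )
    if reference.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    R, t = kabsch(mobile, reference)
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=reference.shape[0])


def _selection_atoms(
    model: StructureModel, sel: AtomSelection, include_hydrogens: bool
) -> list[tuple[str, Residue, Atom]]:
    return [
        (c, r, a)
        for c, r, a in select_atoms(model, sel)
        if include_hydrogens or not a.is_hydrogen
    ]


def rmsd_between_models(
    model_1: StructureModel,
    sel_1: AtomSelection,
    model_2: StructureModel,
    sel_2: AtomSelection,
    pairing: str = "by_order",
    include_hydrogens: bool = False,
) -> SuperpositionResult:
    """Superpose two selections from (possibly different) models.

    ``pairing='by_order'`` pairs atoms in selection order; ``pairing=
    'by_residue_number'`` matches atoms by (residue number, atom name) and
    raises with the unmatched keys listed if the selections disagree.
    """
    atoms_1 = _selection_atoms(model_1, sel_1, include_hydrogens)
    atoms_2 = _selection_atoms(model_2, sel_2, include_hydrogens)
    if pairing == "by_order":
        if len(atoms_1) != len(atoms_2):
            raise ValueError(
                f"selections resolve to {len(atoms_1)} vs {len(atoms_2)} atoms"
            )
        ref = np.array([a.coordinates for _, _, a in atoms_1])
        mob = np.array([a.coordinates for _, _, a in atoms_2])
    elif pairing == "by_residue_number":
        key = lambda c, r, a: (r.seq_number, r.insertion_code, a.name)
        map_1 = {key(*t): t[2] for t in atoms_1}
        map_2 = {key(*t): t[2] for t in atoms_2}
        missing = sorted(set(map_1) ^ set(map_2))
        if missing:
            raise ValueError(
                f"{len(missing)} unmatched residue/atom keys under "
                f"by_residue_number pairing (first: {missing[:5]})"
            )
        keys = [key(*t) for t in atoms_1]  # model-1 order
        ref = np.array([map_1[k].coordinates for k in keys])
        mob = np.array([map_2[k].coordinates for k in keys])
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return superpose(ref, mob)


#: Charged side-chain atoms for salt-bridge detection.
_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
_BASIC_ATOMS_HIS = {"HIS": ("ND1", "NE2")}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class SaltBridge:
    """One residue-pair salt bridge (closest qualifying atom pair reported)."""

    basic_partner: tuple[str, str, int, str]  # (chain, residue name, number, atom)
    acidic_partner: tuple[str, str, int, str]
    distance: float


def _charged_atoms(
    model: StructureModel, chains: frozenset[str], table: dict, include_oxt: bool = False
) -> list[tuple[str, Residue, Atom]]:
    out = []
    for cid, res, atom in model.iter_atoms():
        if cid not in chains or res.kind != "amino_acid":
            continue
        names = table.get(res.name)
        if names and atom.name in names:
            out.append((cid, res, atom))
        elif include_oxt and atom.name == "OXT":
            out.append((cid, res, atom))
    return out


def find_salt_bridges(
    model: StructureModel,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cutoff: float = 4.0,
    include_his: bool = False,
    include_cterm: bool = False,
) -> list[SaltBridge]:
    """Residue-pair salt bridges between two disjoint chain groups.

    A bridge is counted once per (basic residue, acidic residue) pair with
    any side-chain nitrogen-oxygen distance <= cutoff (A); the closest atom
    pair is reported.  Histidine and the C-terminal carboxylate are excluded
    by default.  Ordering is deterministic (chain, residue number).
    """
    ga, gb = frozenset(group_a), frozenset(group_b)
    if ga & gb:
        raise ValueError(f"chain groups must be disjoint; shared: {sorted(ga & gb)}")
    basic_table = dict(_BASIC_ATOMS)
    if include_his:
        basic_table.update(_BASIC_ATOMS_HIS)

    bridges: dict[tuple, SaltBridge] = {}
    for chains_basic, chains_acidic in ((ga, gb), (gb, ga)):
        basics = _charged_atoms(model, chains_basic, basic_table)
        acidics = _charged_atoms(model, chains_acidic, _ACIDIC_ATOMS,
                                 include_oxt=include_cterm)
        for cb, rb, ab in basics:
            for ca, ra, aa in acidics:
                d = float(np.linalg.norm(ab.coordinates - aa.coordinates))
                if d > cutoff:
                    continue
                key = (cb, rb.seq_number, ca, ra.seq_number)
                cand = SaltBridge(
                    basic_partner=(cb, rb.name, rb.seq_number, ab.name),
                    acidic_partner=(ca, ra.name, ra.seq_number, aa.name),
                    distance=d,
                )
                if key not in bridges or d < bridges[key].distance:
                    bridges[key] = cand
    return [bridges[k] for k in sorted(bridges)]


#: Atoms of the DNA phosphate group for contact inventories.
_PHOSPHATE_ATOMS = ("P", "OP1", "OP2", "O5'", "O3'")
_PROTEIN_BACKBONE = ("N", "CA", "C", "O", "OXT")


@dataclass
class PhosphateContact:
    """A protein residue within the cutoff of any DNA phosphate-group atom."""

    chain: str
    residue_name: str
    residue_number: int
    min_distance: float


def dna_contact_residues(
    model: StructureModel,
    protein_chains: Sequence[str],
    dna_chains: Sequence[str],
    cutoff: float = 5.5,
    atoms: str = "side_chain",
) -> list[PhosphateContact]:
    """Protein residues contacting DNA phosphate groups.

    Every protein residue with a qualifying atom (side-chain heavy atoms by
    default, or all heavy atoms with ``atoms='all'``) within ``cutoff`` A of
    any DNA phosphate-group atom (P, OP1, OP2, O5', O3') is listed with its
    minimum distance, sorted by chain then residue number.
    """
    if atoms not in ("side_chain", "all"):
        raise ValueError(f"unknown atoms mode {atoms!r}")
    pc, dc = frozenset(protein_chains), frozenset(dna_chains)
    phos = [
        a.coordinates
        for cid, res, a in model.iter_atoms()
        if cid in dc and res.kind == "nucleotide" and a.name in _PHOSPHATE_ATOMS
    ]
    if not phos:
        raise ValueError("no phosphate-group atoms found in the DNA chains")
    phos = np.array(phos)

    contacts = []
    for cid in sorted(pc):
        for res in model.chains.get(cid, []):
            if res.kind != "amino_acid":
                continue
            coords = [
                a.coordinates
                for a in res.atoms
                if not a.is_hydrogen
                and (atoms == "all" or a.name not in _PROTEIN_BACKBONE)
            ]
            if not coords:
                continue
            d = float(np.sqrt(((np.array(coords)[:, None, :] - phos[None, :, :]) ** 2)
                              .sum(axis=2).min()))
            if d <= cutoff:
                contacts.append(
                    PhosphateContact(cid, res.name, res.seq_number, d)
                )
    contacts.sort(key=lambda c: (c.chain, c.residue_number))
    return contacts
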