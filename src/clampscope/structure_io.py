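"""Atomic structure models: parsing, selection, stripping, and writing.

The in-memory hierarchy is deliberately small — chains of residues of atoms,
with coordinates in Angstrom — and is produced either by reading PDB/mmCIF
files (via gemmi) or by the synthetic builders.  Heavier crystallographic
bookkeeping (symmetry, assemblies, anisotropic displacement) is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import gemmi
import numpy as np

ResidueKind = Literal["amino_acid", "nucleotide", "other"]

#: Elements resolvable in the scattering form-factor / atomic-mass tables.
_KNOWN_ELEMENTS = frozenset(
    e for e in (gemmi.Element(i).name for i in range(1, 93)) if e and e != "X"
)


@dataclass
class Atom:
    """One atom: name, element symbol, position (Angstrom), occupancy, B."""

    name: str
    element: str
    coordinates: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def element_known(self) -> bool:
        return self.element in _KNOWN_ELEMENTS

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """A residue with ordered atoms; ``kind`` drives component stripping."""

    name: str
    seq_number: int
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    kind: ResidueKind = "other"

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.coordinates


@dataclass
class StructureModel:
    """Hierarchical atomic model: ordered chains -> residues -> atoms."""

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def iter_atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for chain_id, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield chain_id, res, atom

    def atom_count(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coordinates(self, include_hydrogens: bool = False) -> np.ndarray:
        coords = [
            a.coordinates
            for _, _, a in self.iter_atoms()
            if include_hydrogens or not a.is_hydrogen
        ]
        return np.array(coords) if coords else np.empty((0, 3))

    def copy(self) -> "StructureModel":
        new = StructureModel(id=self.id, metadata=dict(self.metadata))
        for cid, residues in self.chains.items():
            new.chains[cid] = [
                Residue(
                    name=r.name,
                    seq_number=r.seq_number,
                    insertion_code=r.insertion_code,
                    kind=r.kind,
                    atoms=[
                        Atom(a.name, a.element, a.coordinates.copy(), a.occupancy, a.b_factor)
                        for a in r.atoms
                    ],
                )
                for r in residues
            ]
        return new


@dataclass
class AtomSelection:
    """Declarative atom selection: chains, residue range, atom names, elements.

    All fields are optional; an unset field matches everything.  The selection
    vocabulary expresses e.g. 'backbone heavy atoms N, CA, C, O of residues
    16-65 in chains A,B'.
    """

    chain_ids: Optional[frozenset[str]] = None
    residue_range: Optional[tuple[int, int]] = None
    atom_names: Optional[frozenset[str]] = None
    element_filter: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.chain_ids is not None:
            self.chain_ids = frozenset(self.chain_ids)
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)
        if self.element_filter is not None:
            self.element_filter = frozenset(self.element_filter)
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise ValueError("residue_range start must be <= end")

    def matches(self, chain_id: str, residue: Residue, atom: Atom) -> bool:
        if self.chain_ids is not None and chain_id not in self.chain_ids:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= residue.seq_number <= hi):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.element_filter is not None and atom.element not in self.element_filter:
            return False
        return True


def _residue_kind(name: str) -> ResidueKind:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_amino_acid():
            return "amino_acid"
        if info.is_nucleic_acid():
            return "nucleotide"
    return "other"


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is read.  Alternate locations
    are resolved to the highest-occupancy conformer (ties: first in file);
    zero-occupancy atoms are dropped.  Waters and ligands are retained with
    ``kind='other'``.  Atoms whose element cannot be resolved are kept and
    flagged (a warning is emitted).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"structure file not found: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")

    model = StructureModel(id=st.name or path.stem)
    if st.resolution:
        model.metadata["resolution"] = st.resolution

    unknown: list[str] = []
    for chain in st[0]:
        residues: list[Residue] = []
        for res in chain:
            # resolve altlocs: keep highest occupancy, ties -> first in file
            groups: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.occ <= 0:
                    continue
                prev = groups.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    groups[atom.name] = atom
            if not groups:
                continue
            out = Residue(
                name=res.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                kind=_residue_kind(res.name),
            )
            for atom in res:  # preserve file order
                picked = groups.get(atom.name)
                if picked is not atom:
                    continue
                el = atom.element.name if atom.element and atom.element.name != "X" else ""
                if not el:
                    unknown.append(f"{chain.name}/{res.name}{res.seqid.num}/{atom.name}")
                    el = "X"
                out.atoms.append(
                    Atom(atom.name, el, np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                         occupancy=atom.occ, b_factor=atom.b_iso)
                )
            residues.append(out)
        if residues:
            model.chains.setdefault(chain.name, []).extend(residues)
    if unknown:
        warnings.warn(
            f"{len(unknown)} atoms with unresolvable element kept and flagged "
            f"(first: {unknown[0]})",
            stacklevel=2,
        )
    return model


def write_structure(model: StructureModel, path) -> None:
    """Write a model as a PDB file (fixed-column, 3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = model.id or "model"
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gc = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            if res.kind == "other":
                gr.het_flag = "H"
            else:
                gr.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element if atom.element != "X" else "")
                ga.pos = gemmi.Position(*atom.coordinates)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def select_atoms(
    model: StructureModel, sel: AtomSelection
) -> list[tuple[str, Residue, Atom]]:
    """All atoms matching ``sel`` in deterministic file order.

    An empty result is a valid outcome, not an error.
    """
    return [
        (cid, res, atom)
        for cid, res, atom in model.iter_atoms()
        if sel.matches(cid, res, atom)
    ]


def strip_component(model: StructureModel, kind: ResidueKind) -> StructureModel:
    """Return a new model without residues of the named kind.

    Used e.g. to obtain a protein-only model from a protein/DNA complex
    before computing its scattering profile.  The input is not modified.
    """
    new = model.copy()
    for cid in list(new.chains):
        new.chains[cid] = [r for r in new.chains[cid] if r.kind != kind]
        if not new.chains[cid]:
            del new.chains[cid]
    return new


def selection_coordinates(
    selection: Sequence[tuple[str, Residue, Atom]],
    include_hydrogens: bool = False,
) -> np.ndarray:
    """Coordinate array of a select_atoms result (hydrogens dropped by default)."""
    coords = [
        a.coordinates for _, _, a in selection if include_hydrogens or not a.is_hydrogen
    ]
    return np.array(coords) if coords else np.empty((0, 3))
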