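"""DNA duplex geometry: base pairing, Watson-Crick hydrogen bonds, base-pair
and step parameters, and groove widths.

Conventions
-----------
Base frames come from least-squares superposition of the standard reference
base onto the observed base atoms; pair and step parameters are the
axis-angle components of the relative rotations between those frames
(buckle/propeller/opening about the pair x/y/z, tilt/roll/twist about the
step x/y/z).  This matches the standard-reference-frame family of schemes to
fractions of a degree for near-planar pairs; a curvilinear-axis scheme is
not implemented.  Groove widths use the refined phosphate-phosphate
convention: the minimal cross-strand P-P distance within a stagger window,
minus a 5.8 A backbone correction, with candidates assigned to the minor or
major groove by which side of the pair plane (the sign of x in the mid-level
pair frame) the P-P midpoint falls on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from clampscope._dna_templates import (
    LETTER_FROM_RESIDUE,
    PAIR_FLIP,
    standard_base_array,
)
from clampscope._linalg import kabsch, orthonormalize, rotation_vector
from clampscope.structure_io import Residue, StructureModel

#: Canonical Watson-Crick hydrogen bonds, keyed by purine letter.
#: Entries: (label, purine atom, pyrimidine atom, donor side).
_CANONICAL_BONDS = {
    "A": (  # A.T
        ("N1-N3", "N1", "N3", "pyrimidine"),
        ("N6-O4", "N6", "O4", "purine"),
    ),
    "G": (  # G.C
        ("N1-N3", "N1", "N3", "purine"),
        ("N2-O2", "N2", "O2", "purine"),
        ("O6-N4", "O6", "N4", "pyrimidine"),
    ),
}
_PURINES = {"A", "G"}


@dataclass
class HBond:
    """One hydrogen bond: donor and acceptor atom references and distance."""

    donor_atom: tuple[str, int, str]  # (chain, residue number, atom name)
    acceptor_atom: tuple[str, int, str]
    distance: float
    label: str

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("hydrogen-bond distance must be positive")


@dataclass
class BasePairRecord:
    """A designed base pair with its hydrogen-bond inventory and geometry."""

    index: int  # 1-based position along the duplex
    chain_1: str
    residue_1: Residue
    chain_2: str
    residue_2: Residue
    designed_type: str  # e.g. "A.T", "G.C" (strand-1 base first)
    hbonds: list[HBond] = field(default_factory=list)
    bond_distances: dict[str, Optional[float]] = field(default_factory=dict)
    classification: Optional[str] = None  # watson_crick | non_watson_crick | absent
    opening: Optional[float] = None  # degrees, signed
    propeller: Optional[float] = None  # degrees, signed

    @property
    def opening_magnitude(self) -> Optional[float]:
        return None if self.opening is None else abs(self.opening)


@dataclass
class StepGeometry:
    """Helical parameters between consecutive pairs i and i+1."""

    step_index: int  # 1-based, between pairs step_index and step_index+1
    twist: float  # degrees
    rise: float  # A

    def __post_init__(self) -> None:
        if abs(self.twist) > 180.0:
            raise ValueError("twist outside (-180, 180]")


@dataclass
class GrooveProfile:
    """Backbone-corrected minor/major groove widths per pair level.

    ``None`` marks levels where a width is undefined (missing phosphates near
    the duplex ends), never zero-filled.
    """

    minor_width: list[Optional[float]]
    major_width: list[Optional[float]]


@dataclass
class PairFrames:
    """Base and pair reference frames of one base pair.

    Rotations hold the frame axes as columns (x toward the major groove,
    y toward the strand-1 backbone, z along the helix); the strand-2 base
    frame is reported after the 180-degree x-flip so that both z-axes point
    along the helix.
    """

    rotation_1: np.ndarray
    origin_1: np.ndarray
    rotation_2: np.ndarray  # flipped
    origin_2: np.ndarray
    pair_rotation: np.ndarray
    pair_origin: np.ndarray


def _base_letter(res: Residue) -> str:
    letter = LETTER_FROM_RESIDUE.get(res.name.strip().upper())
    if letter is None or letter not in "ACGT":
        raise ValueError(f"residue {res.name!r} is not a standard deoxynucleotide")
    return letter


def pair_strands(model: StructureModel, chain_1: str, chain_2: str) -> list[BasePairRecord]:
    """Pair two antiparallel nucleotide chains residue-by-residue.

    Residue i of strand 1 is paired with residue L+1-i of strand 2 (by list
    position).  The register is validated by requiring a C1'-C1' distance
    below 15 A for the majority of pairs.
    """
    for cid in (chain_1, chain_2):
        if cid not in model.chains:
            raise KeyError(f"chain {cid!r} not in model")
        if any(r.kind != "nucleotide" for r in model.chains[cid]):
            raise ValueError(f"chain {cid!r} contains non-nucleotide residues")
    s1 = model.chains[chain_1]
    s2 = model.chains[chain_2]
    if len(s1) != len(s2):
        raise ValueError(
            f"strands have unequal lengths ({len(s1)} vs {len(s2)}); "
            "cannot pair residue-by-residue"
        )
    L = len(s1)
    records = []
    n_close = 0
    for i in range(L):
        r1, r2 = s1[i], s2[L - 1 - i]
        b1, b2 = _base_letter(r1), _base_letter(r2)
        c1p_1, c1p_2 = r1.coord("C1'"), r2.coord("C1'")
        if c1p_1 is not None and c1p_2 is not None:
            if np.linalg.norm(c1p_1 - c1p_2) < 15.0:
                n_close += 1
        records.append(
            BasePairRecord(
                index=i + 1,
                chain_1=chain_1, residue_1=r1,
                chain_2=chain_2, residue_2=r2,
                designed_type=f"{b1}.{b2}",
            )
        )
    if n_close <= L / 2:
        raise ValueError(
            "antiparallel register validation failed (C1'-C1' > 15 A for most "
            "pairs); supply an explicit register offset or re-order chains"
        )
    return records


def _purine_pyrimidine(pair: BasePairRecord) -> tuple[Residue, Residue, str, str, str]:
    b1, b2 = pair.designed_type.split(".")
    if b1 in _PURINES and b2 not in _PURINES:
        return pair.residue_1, pair.residue_2, b1, pair.chain_1, pair.chain_2
    if b2 in _PURINES and b1 not in _PURINES:
        return pair.residue_2, pair.residue_1, b2, pair.chain_2, pair.chain_1
    raise ValueError(
        f"pair {pair.index} ({pair.designed_type}) is not a purine-pyrimidine "
        "combination; canonical Watson-Crick bonds are undefined"
    )


def hbond_inventory(pair: BasePairRecord, cutoff: float = 3.5) -> BasePairRecord:
    """Measure the canonical Watson-Crick donor-acceptor distances of a pair.

    The canonical bond set is fixed by the designed type (A.T: N1-N3, N6-O4;
    G.C: N1-N3, N2-O2, O6-N4).  Bonds within ``cutoff`` (A) populate
    ``hbonds``; all measured distances are kept in ``bond_distances``.
    Classification: all canonical bonds present -> watson_crick; none ->
    absent; otherwise non_watson_crick.  Missing atoms count as absent bonds
    (with a warning).
    """
    pur, pyr, pur_letter, pur_chain, pyr_chain = _purine_pyrimidine(pair)
    pair.hbonds = []
    pair.bond_distances = {}
    n_present = 0
    n_bonds = 0
    for label, pur_atom, pyr_atom, donor_side in _CANONICAL_BONDS[pur_letter]:
        n_bonds += 1
        a1, a2 = pur.coord(pur_atom), pyr.coord(pyr_atom)
        if a1 is None or a2 is None:
            warnings.warn(
                f"pair {pair.index}: missing atom for bond {label}; recorded as absent",
                stacklevel=2,
            )
            pair.bond_distances[label] = None
            continue
        d = float(np.linalg.norm(a1 - a2))
        pair.bond_distances[label] = d
        if d <= cutoff:
            n_present += 1
            pur_ref = (pur_chain, pur.seq_number, pur_atom)
            pyr_ref = (pyr_chain, pyr.seq_number, pyr_atom)
            donor, acceptor = (
                (pur_ref, pyr_ref) if donor_side == "purine" else (pyr_ref, pur_ref)
            )
            pair.hbonds.append(HBond(donor, acceptor, d, label))
    if n_present == n_bonds:
        pair.classification = "watson_crick"
    elif n_present == 0:
        pair.classification = "absent"
    else:
        pair.classification = "non_watson_crick"
    return pair


def _fit_base_frame(res: Residue) -> tuple[np.ndarray, np.ndarray]:
    """(rotation, origin) of one base from a standard-base superposition."""
    letter = _base_letter(res)
    names, standard = standard_base_array(letter)
    observed, used = [], []
    for n, s in zip(names, standard):
        c = res.coord(n)
        if c is not None:
            observed.append(c)
            used.append(s)
    if len(observed) < 6:
        raise ValueError(
            f"residue {res.name}{res.seq_number}: only {len(observed)} canonical "
            "base atoms present; need >= 6 to define a frame"
        )
    R, t = kabsch(np.array(used), np.array(observed))
    return R, t


def base_frames(pair: BasePairRecord) -> PairFrames:
    """Base frames of both bases and the averaged pair frame.

    The strand-2 frame is flipped 180 degrees about its x-axis (the standard
    convention) so that both frames are co-oriented; the pair frame is the
    orthonormalized average, its origin the midpoint of the base origins.
    """
    R1, o1 = _fit_base_frame(pair.residue_1)
    R2_raw, o2 = _fit_base_frame(pair.residue_2)
    R2 = R2_raw @ PAIR_FLIP
    R_pair = orthonormalize(R1 + R2)
    return PairFrames(
        rotation_1=R1, origin_1=o1,
        rotation_2=R2, origin_2=o2,
        pair_rotation=R_pair, pair_origin=0.5 * (o1 + o2),
    )


def pair_and_step_parameters(
    pairs: list[BasePairRecord],
) -> tuple[list[BasePairRecord], list[StepGeometry]]:
    """Opening/propeller per pair and twist/rise per step.

    Opening is the z-component and propeller the y-component of the
    axis-angle vector of the relative rotation between the two base frames
    of a pair; twist and rise come from the relative rotation and origin
    displacement of consecutive pair frames.
    """
    frames = [base_frames(p) for p in pairs]
    for pair, fr in zip(pairs, frames):
        rel = fr.rotation_2.T @ fr.rotation_1
        v = np.rad2deg(rotation_vector(rel))
        pair.propeller = float(v[1])
        pair.opening = float(v[2])
    steps = []
    for i in range(len(pairs) - 1):
        fa, fb = frames[i], frames[i + 1]
        rel = fa.pair_rotation.T @ fb.pair_rotation
        v = np.rad2deg(rotation_vector(rel))
        z_mid = orthonormalize(fa.pair_rotation + fb.pair_rotation)[:, 2]
        rise = float(np.dot(fb.pair_origin - fa.pair_origin, z_mid))
        steps.append(StepGeometry(step_index=i + 1, twist=float(v[2]), rise=rise))
    return pairs, steps


def _phosphorus_positions(residues: list[Residue]) -> list[Optional[np.ndarray]]:
    return [r.coord("P") for r in residues]


def groove_widths(
    model: StructureModel,
    chain_1: str,
    chain_2: str,
    backbone_correction: float = 5.8,
    window: int = 6,
) -> GrooveProfile:
    """Minor/major groove widths per pair level (refined P-P convention).

    For level i, cross-strand P-P distances are collected for strand-2
    phosphates within ``window`` pair levels; each candidate is assigned to
    the minor or major groove by the sign of the x-coordinate of the P-P
    midpoint in the mid-level pair frame (minor groove at x < 0).  The width
    is the minimal candidate distance minus ``backbone_correction`` (floored
    at 0); levels with no candidate (e.g. missing terminal phosphates) are
    reported as ``None``.
    """
    pairs = pair_strands(model, chain_1, chain_2)
    L = len(pairs)
    s1 = model.chains[chain_1]
    s2 = model.chains[chain_2]
    p1 = _phosphorus_positions(s1)
    # strand-2 phosphate at pair level j is residue L-1-j by list position
    p2 = [_phosphorus_positions(s2)[L - 1 - j] for j in range(L)]
    for strand_p, cid in ((p1, chain_1), (p2, chain_2)):
        if sum(p is not None for p in strand_p) < 4:
            raise ValueError(f"chain {cid!r}: fewer than 4 phosphorus atoms")

    frames: list[Optional[PairFrames]] = []
    for pair in pairs:
        try:
            frames.append(base_frames(pair))
        except ValueError:
            frames.append(None)

    def mid_frame(i: int, j: int) -> Optional[tuple[np.ndarray, np.ndarray]]:
        lo, hi = (i + j) // 2, (i + j + 1) // 2
        fa, fb = frames[lo], frames[hi]
        if fa is None or fb is None:
            f = fa or fb
            return None if f is None else (f.pair_rotation, f.pair_origin)
        R = orthonormalize(fa.pair_rotation + fb.pair_rotation)
        return R, 0.5 * (fa.pair_origin + fb.pair_origin)

    minor: list[Optional[float]] = []
    major: list[Optional[float]] = []
    for i in range(L):
        cand = {"minor": [], "major": []}
        if p1[i] is not None:
            for k in range(-window, window + 1):
                j = i + k
                if not (0 <= j < L) or p2[j] is None:
                    continue
                mf = mid_frame(i, j)
                if mf is None:
                    continue
                R, o = mf
                midpoint = 0.5 * (p1[i] + p2[j])
                x_local = float(np.dot(R[:, 0], midpoint - o))
                d = float(np.linalg.norm(p1[i] - p2[j]))
                cand["minor" if x_local < 0 else "major"].append(d)
        minor.append(max(min(cand["minor"]) - backbone_correction, 0.0) if cand["minor"] else None)
        major.append(max(min(cand["major"]) - backbone_correction, 0.0) if cand["major"] else None)
    return GrooveProfile(minor_width=minor, major_width=major)


def analyze_duplex(
    model: StructureModel,
    chain_1: str,
    chain_2: str,
    cutoff: float = 3.5,
) -> tuple[list[BasePairRecord], list[StepGeometry], GrooveProfile]:
    """Full per-duplex analysis: pairing, H-bonds, parameters, grooves."""
    pairs = pair_strands(model, chain_1, chain_2)
    for pair in pairs:
        hbond_inventory(pair, cutoff=cutoff)
    pairs, steps = pair_and_step_parameters(pairs)
    grooves = groove_widths(model, chain_1, chain_2)
    return pairs, steps, grooves
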