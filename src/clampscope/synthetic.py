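"""Synthetic structures and scattering data with known ground truth.

Everything downstream (geometry, superposition, scattering, ensemble
decomposition) is testable against these generators without any external
input: ideal and perturbed B-form DNA duplexes, toy poly-alanine helix
bundles standing in for coiled-coil assemblies, and noisy two-component
mixture scattering profiles with a known mixing fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from clampscope._dna_templates import (
    COMPLEMENT,
    PAIR_FLIP,
    RESIDUE_NAME,
    nucleotide_template,
)
from clampscope._linalg import rotation_about_axis
from clampscope.structure_io import Atom, Residue, StructureModel

_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])

#: Atoms of the phosphate group absent from a 5'-OH terminus.
_TERMINAL_5P = ("P", "OP1", "OP2")


@dataclass
class BDNAParams:
    """Parameters of an ideal (optionally perturbed) B-form duplex.

    ``sequence`` is strand 1 read 5'->3'; strand 2 is the antiparallel
    Watson-Crick complement.  ``twist_per_step`` defaults to the canonical
    36 degrees of B-form DNA and ``rise_per_step`` to 3.38 A.  ``opening``
    and ``propeller`` are per-pair perturbations in degrees (default 0),
    split symmetrically between the two bases of the pair.
    """

    sequence: str = "CCGAAAAAAAAAACGC"
    twist_per_step: float = 36.0
    rise_per_step: float = 3.38
    opening: Optional[Sequence[float]] = None
    propeller: Optional[Sequence[float]] = None
    chain_ids: tuple[str, str] = ("A", "B")
    blunt_5prime: bool = True  # drop the 5'-terminal phosphate group

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 2:
            raise ValueError("sequence must have length >= 2")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
        for name in ("opening", "propeller"):
            vals = getattr(self, name)
            if vals is not None and len(vals) != len(self.sequence):
                raise ValueError(f"{name} must have one value per base pair")


def _per_pair(values: Optional[Sequence[float]], n: int) -> np.ndarray:
    return np.zeros(n) if values is None else np.asarray(values, dtype=float)


def build_bdna(params: BDNAParams) -> StructureModel:
    """Build a full-heavy-atom ideal B-form duplex.

    Pair i (1-based) of the duplex sits at helical frame Rz((i-1)*twist),
    z = (i-1)*rise.  Strand 1 bases are the standard-frame templates carried
    by that frame; strand 2 bases are the complementary templates after the
    180-degree x-flip, so every unperturbed designed pair forms all of its
    canonical Watson-Crick hydrogen bonds by construction.  Strand 2 residues
    are numbered 5'->3' (residue j pairs with strand-1 residue L+1-j).
    """
    seq = params.sequence
    L = len(seq)
    twist = np.deg2rad(params.twist_per_step)
    opening = np.deg2rad(_per_pair(params.opening, L))
    propeller = np.deg2rad(_per_pair(params.propeller, L))

    model = StructureModel(id=f"bdna_{seq}")
    model.metadata["sequence"] = seq
    c1, c2 = params.chain_ids
    strand1: list[Residue] = []
    strand2_by_level: list[Residue] = []

    for i in range(L):
        Rz = rotation_about_axis(_Z, i * twist)
        origin = np.array([0.0, 0.0, i * params.rise_per_step])
        # opening about pair z and propeller about pair y, split half-half
        D1 = rotation_about_axis(_Y, 0.5 * propeller[i]) @ rotation_about_axis(_Z, 0.5 * opening[i])
        D2 = rotation_about_axis(_Y, -0.5 * propeller[i]) @ rotation_about_axis(_Z, -0.5 * opening[i])

        for strand, letter, D in ((1, seq[i], D1), (2, COMPLEMENT[seq[i]], D2)):
            names, coords, elements = nucleotide_template(letter)
            xyz = coords @ PAIR_FLIP.T if strand == 2 else coords
            # perturbations act in the pair frame, after the strand-2 flip
            xyz = (xyz @ D.T) @ Rz.T + origin
            res = Residue(name=RESIDUE_NAME[letter], seq_number=0, kind="nucleotide")
            for n, e, c in zip(names, elements, xyz):
                res.atoms.append(Atom(n, e, c))
            if strand == 1:
                res.seq_number = i + 1
                strand1.append(res)
            else:
                res.seq_number = L - i  # 5'->3' numbering on strand 2
                strand2_by_level.append(res)

    strand2 = list(reversed(strand2_by_level))  # order by seq_number
    if params.blunt_5prime:
        for res in (strand1[0], strand2[0]):
            res.atoms = [a for a in res.atoms if a.name not in _TERMINAL_5P]
    model.chains[c1] = strand1
    model.chains[c2] = strand2
    return model


def perturb_pair(
    model: StructureModel,
    pair_index: int,
    displacement: Optional[Sequence[float]] = None,
    opening: Optional[float] = None,
    strand: int = 2,
    chain_ids: tuple[str, str] = ("A", "B"),
) -> StructureModel:
    """Rigidly displace or rotate one base of a built duplex.

    ``pair_index`` is 1-based along the duplex.  ``displacement`` is a global
    3-vector in A applied to every atom of the chosen residue; ``opening``
    rotates the residue about the pair z-axis through the pair origin by the
    given angle in degrees.  All other atoms are unchanged; the input model
    is not modified.
    """
    from clampscope.dna_geometry import base_frames, pair_strands

    c1, c2 = chain_ids
    L = len(model.chains[c1])
    if not 1 <= pair_index <= L:
        raise IndexError(f"pair_index {pair_index} outside duplex of {L} pairs")
    if strand not in (1, 2):
        raise ValueError("strand must be 1 or 2")

    new = model.copy()
    res = (
        new.chains[c1][pair_index - 1]
        if strand == 1
        else new.chains[c2][L - pair_index]
    )
    if displacement is not None:
        d = np.asarray(displacement, dtype=float)
        for atom in res.atoms:
            atom.coordinates = atom.coordinates + d
    if opening:
        pairs = pair_strands(model, c1, c2)
        frames = base_frames(pairs[pair_index - 1])
        R = rotation_about_axis(frames.pair_rotation[:, 2], np.deg2rad(opening))
        o = frames.pair_origin
        for atom in res.atoms:
            atom.coordinates = R @ (atom.coordinates - o) + o
    return new


# poly-alanine heavy-atom offsets relative to CA, in a local frame with
# x radially outward from the helix axis and z along it (idealized alpha
# helix: 1.5 A rise and 100 degrees per residue)
_ALA_OFFSETS = {
    "N": (-0.45, -1.22, -0.50),
    "CA": (0.00, 0.00, 0.00),
    "C": (-0.46, 1.16, 0.55),
    "O": (-1.58, 1.61, 0.32),
    "CB": (1.52, 0.16, -0.11),
}
_ALA_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_HELIX_RADIUS = 2.3  # A, alpha-carbon radius


def build_helix_bundle(
    n_helices: int = 4,
    residues_per_helix: int = 20,
    spacing: float = 10.0,
) -> StructureModel:
    """Deterministic toy assembly of parallel poly-alanine alpha-helices.

    Helices (rise 1.5 A/residue, 100 deg/residue, 5 heavy atoms per residue)
    are placed on a regular square lattice with the given spacing in A.
    A stand-in for coiled-coil oligomers in superposition and scattering
    tests; not a physically refined protein model.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    if residues_per_helix < 1:
        raise ValueError("residues_per_helix must be >= 1")
    model = StructureModel(id=f"bundle_{n_helices}x{residues_per_helix}")
    ncols = int(np.ceil(np.sqrt(n_helices)))
    chain_labels = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for h in range(n_helices):
        cx = (h % ncols) * spacing
        cy = (h // ncols) * spacing
        residues = []
        for i in range(residues_per_helix):
            phi = np.deg2rad(100.0 * i)
            z = 1.5 * i
            radial = np.array([np.cos(phi), np.sin(phi), 0.0])
            tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
            ca = np.array([cx, cy, 0.0]) + _HELIX_RADIUS * radial + z * _Z
            res = Residue(name="ALA", seq_number=i + 1, kind="amino_acid")
            for name, (ox, oy, oz) in _ALA_OFFSETS.items():
                pos = ca + ox * radial + oy * tangent + oz * _Z
                res.atoms.append(Atom(name, _ALA_ELEMENTS[name], pos))
            residues.append(res)
        model.chains[chain_labels[h % len(chain_labels)]] = residues
    return model


@dataclass
class MixtureSpec:
    """Two-component mixture: mass fraction of component B ('open'), relative
    Gaussian noise level, q grid, and RNG seed."""

    fraction_open: float
    noise_level: float = 0.0
    q_grid: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_open <= 1.0:
            raise ValueError("fraction_open must lie in [0, 1]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.q_grid is not None:
            self.q_grid = np.asarray(self.q_grid, dtype=float)


def simulate_mixture_profile(profile_a, profile_b, spec: MixtureSpec):
    """Noisy linear combination I = (1-w) I_a + w I_b of two profiles.

    Zero-mean Gaussian noise with sigma(q) = noise_level * I(q) is added and
    recorded in the sigma column (a small floor keeps sigma positive for the
    noise-free case so the result remains usable in chi-square fits).
    Bit-reproducible for a fixed seed.
    """
    from clampscope.saxs import ScatteringProfile

    q = profile_a.q
    if spec.q_grid is not None and not np.array_equal(q, spec.q_grid):
        raise ValueError("profile_a is not on the q grid of the mixture spec")
    if not np.array_equal(q, profile_b.q):
        raise ValueError("mixture components must share one q grid")
    w = spec.fraction_open
    intensity = (1.0 - w) * profile_a.intensity + w * profile_b.intensity
    sigma = spec.noise_level * np.abs(intensity)
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, 1.0, size=intensity.size) * sigma
    floor = 1e-6 * float(np.max(np.abs(intensity))) if intensity.size else 1.0
    sigma_out = np.where(sigma > 0, sigma, floor)
    return ScatteringProfile(q=q.copy(), intensity=intensity, sigma=sigma_out)
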