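"""Idealized B-form nucleotide templates.

Each base's heavy atoms are expressed in the standard base reference frame
(the frame convention in which an ideal Watson-Crick pair is formed by the
180-degree x-flip of the complementary base): origin on the pseudo-dyad,
x toward the major groove, y toward the strand-1 backbone, z along the helix.
The in-plane base-atom coordinates below are the published standard-frame
values used throughout base-morphology software.

Full heavy-atom nucleotides are assembled at import time: the ideal-geometry
residue from the Chemical Component Dictionary (bundled with biotite) is
superposed onto the standard-frame base, and the sugar-phosphate moiety is
rotated about five backbone torsions (glycosidic, C4'-C5', C5'-O5', the O3'
cone, and the phosphate-oxygen spin) to put the phosphorus at a canonical
B-form backbone position (radius 9.1 A, azimuth 95 deg, 1.0 A below the base
plane) with a continuous O3'...P linkage.  The torsion angles were calibrated
once against canonical B-DNA groove widths and are frozen here; exact
backbone torsions are not critical downstream, which relies on base atoms
and phosphorus positions.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from clampscope._linalg import kabsch, rotation_about_axis

#: Standard-reference-frame coordinates (A) of the base heavy atoms + C1'.
STANDARD_BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000), "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000), "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000), "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000), "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000), "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000), "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000), "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000), "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000), "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000), "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001), "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000), "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000), "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000), "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001), "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000), "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000), "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000), "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000), "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001), "C6": (-0.024, 5.057, 0.000),
    },
}

#: Glycosidic nitrogen per base letter.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}

#: Watson-Crick complement.
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: PDB residue name per base letter.
RESIDUE_NAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
LETTER_FROM_RESIDUE = {
    "DA": "A", "DT": "T", "DG": "G", "DC": "C",
    "A": "A", "T": "T", "G": "G", "C": "C", "U": "U",
    "ADE": "A", "THY": "T", "GUA": "G", "CYT": "C",
}

#: Frozen backbone torsion angles (degrees) per base:
#: (glycosidic, C4'-C5', C5'-O5', O3' cone about C4'-C3', OP spin about O5'-P).
_BACKBONE_TORSIONS_DEG = {
    "A": (43.363, -127.589, 119.609, 53.674, -27.0),
    "C": (191.642, -123.744, 115.297, 52.607, -27.0),
    "G": (-21.209, -1.243, 105.925, 20.939, -144.0),
    "T": (-16.535, 3.598, -179.972, -43.072, 177.0),
}

_MOVING_SETS = (
    # (moving atoms, axis tail atom, axis head atom)
    ({"C2'", "C3'", "C4'", "C5'", "O3'", "O4'", "O5'", "P", "OP1", "OP2"}, None, "C1'"),
    ({"O5'", "P", "OP1", "OP2"}, "C4'", "C5'"),
    ({"P", "OP1", "OP2"}, "C5'", "O5'"),
    ({"O3'"}, "C4'", "C3'"),
    ({"OP1", "OP2"}, "O5'", "P"),
)

#: 180-degree rotation about x: maps the complementary base's standard frame
#: onto its Watson-Crick position opposite a strand-1 base.
PAIR_FLIP = np.diag([1.0, -1.0, -1.0])


@lru_cache(maxsize=None)
def nucleotide_template(letter: str) -> tuple[tuple[str, ...], np.ndarray, tuple[str, ...]]:
    """Heavy-atom template for one deoxynucleotide in the standard base frame.

    Returns (atom_names, coordinates (n,3), element symbols).
    """
    import biotite.structure.info as struc_info

    letter = letter.upper()
    if letter not in STANDARD_BASE_COORDS:
        raise ValueError(f"no template for base {letter!r}")
    res = struc_info.residue(RESIDUE_NAME[letter])
    mask = (res.element != "H") & (res.atom_name != "OP3")
    names = [str(n) for n in res.atom_name[mask]]
    elements = [str(e) for e in res.element[mask]]
    coords = res.coord[mask].astype(float)
    idx = {n: i for i, n in enumerate(names)}

    base_names = [n for n in STANDARD_BASE_COORDS[letter] if n != "C1'"]
    observed = coords[[idx[n] for n in base_names]]
    standard = np.array([STANDARD_BASE_COORDS[letter][n] for n in base_names])
    R, t = kabsch(observed, standard)
    coords = coords @ R.T + t

    angles = np.deg2rad(_BACKBONE_TORSIONS_DEG[letter])
    for (moving, tail, head), ang in zip(_MOVING_SETS, angles):
        tail_name = tail if tail is not None else GLYCOSIDIC_N[letter]
        a = coords[idx[tail_name]]
        b = coords[idx[head]]
        Rr = rotation_about_axis(b - a, ang)
        mi = [idx[n] for n in moving if n in idx]
        coords[mi] = (coords[mi] - a) @ Rr.T + a
    return tuple(names), coords, tuple(elements)


def base_atom_names(letter: str, include_c1p: bool = False) -> list[str]:
    """Canonical base heavy-atom names for a base letter."""
    names = list(STANDARD_BASE_COORDS[letter.upper()])
    if not include_c1p:
        names.remove("C1'")
    return names


def standard_base_array(letter: str, include_c1p: bool = False) -> tuple[list[str], np.ndarray]:
    """(names, coords) of the standard-frame base atoms."""
    names = base_atom_names(letter, include_c1p)
    return names, np.array([STANDARD_BASE_COORDS[letter.upper()][n] for n in names])
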