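"""Closed-form binding and oligomer thermodynamics.

Dissociation constants from titration calorimetry are converted to Gibbs
free energies (dG = RT ln Kd, Kd in molar, so nanomolar affinities give
strongly negative dG) and entropic terms (TdS = dH - dG).  Molecular-weight
bookkeeping covers protein oligomers and DNA duplexes, and NMR minor-state
populations are estimated from peak-intensity ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.SeqUtils import molecular_weight

GAS_CONSTANT_KJ = 8.314e-3  # kJ / (mol K)

#: Mass of HPO3 removed per strand when oligonucleotides have 5'-OH termini
#: (synthetic oligos are normally supplied without the 5'-phosphate).
_HPO3_DA = 79.980


@dataclass
class ThermoRecord:
    """Kd, dH and T with the derived dG and TdS for one binding pair."""

    kd: float  # molar
    delta_h: float  # kJ/mol
    temperature: float  # K
    delta_g: float  # kJ/mol, derived
    t_delta_s: float  # kJ/mol, derived

    @property
    def endothermic_entropy_driven(self) -> bool:
        """True for dH > 0 and TdS > 0: binding paid for purely by entropy."""
        return self.delta_h > 0 and self.t_delta_s > 0


def thermo_from_kd(kd: float, delta_h: float, temperature: float) -> ThermoRecord:
    """Derive dG and TdS from a dissociation constant and binding enthalpy.

    dG = R T ln(Kd) with Kd in molar (kJ/mol; negative for Kd < 1 M) and
    TdS = dH - dG.
    """
    import math

    if kd <= 0:
        raise ValueError("kd must be positive (molar)")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    delta_g = GAS_CONSTANT_KJ * temperature * math.log(kd)
    return ThermoRecord(
        kd=kd,
        delta_h=delta_h,
        temperature=temperature,
        delta_g=delta_g,
        t_delta_s=delta_h - delta_g,
    )


@dataclass
class MassLedger:
    """Molecular-weight bookkeeping for an oligomer/DNA assembly (kDa)."""

    protein_monomer_mw: float
    oligomer_n: int
    dna_duplex_mw: float
    complex_mw: float  # = n * monomer + duplex


def _strand_mw_da(sequence: str, five_prime_phosphate: bool) -> float:
    sequence = sequence.upper().replace("U", "T")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid nucleotide codes: {sorted(bad)}")
    mw = molecular_weight(sequence, seq_type="DNA")  # 5'-monophosphate form
    if not five_prime_phosphate:
        mw -= _HPO3_DA
    return mw


def mass_ledger(
    protein_sequence: Optional[str] = None,
    monomer_mw: Optional[float] = None,
    oligomer_n: int = 1,
    dna_strands: Sequence[str] = (),
    five_prime_phosphate: bool = False,
) -> MassLedger:
    """Assemble the mass ledger of an n-mer protein bound to a DNA duplex.

    The protein monomer mass comes either from ``protein_sequence`` (average
    residue masses, one water removed per peptide bond) or from an explicit
    ``monomer_mw`` in kDa.  DNA strand masses use average nucleotide
    monophosphate masses with 5'-OH termini by default.
    """
    if (protein_sequence is None) == (monomer_mw is None):
        raise ValueError("give exactly one of protein_sequence or monomer_mw")
    if oligomer_n < 1:
        raise ValueError("oligomer_n must be >= 1")
    if protein_sequence is not None:
        try:
            monomer_mw = molecular_weight(protein_sequence.upper(), seq_type="protein") / 1e3
        except ValueError as exc:
            raise ValueError(f"invalid protein sequence: {exc}") from exc
    dna_mw = sum(_strand_mw_da(s, five_prime_phosphate) for s in dna_strands) / 1e3
    return MassLedger(
        protein_monomer_mw=monomer_mw,
        oligomer_n=oligomer_n,
        dna_duplex_mw=dna_mw,
        complex_mw=oligomer_n * monomer_mw + dna_mw,
    )


@dataclass
class PopulationEstimate:
    """Minor-state population from per-probe (minor, major) intensity pairs."""

    per_probe: list[float]
    fraction_minor: float  # unweighted mean over probes


def population_fraction(pairs: Sequence[tuple[float, float]]) -> PopulationEstimate:
    """Average minor-state fraction over probe residues.

    Each probe contributes i_minor / (i_minor + i_major); probes with zero
    total intensity are excluded with a warning.  The estimate is the
    unweighted mean over the remaining probes.
    """
    if not pairs:
        raise ValueError("no intensity pairs given")
    fractions = []
    n_zero = 0
    for i_minor, i_major in pairs:
        if i_minor < 0 or i_major < 0:
            raise ValueError("intensities must be non-negative")
        total = i_minor + i_major
        if total == 0:
            n_zero += 1
            continue
        fractions.append(i_minor / total)
    if n_zero:
        warnings.warn(f"{n_zero} probes with zero total intensity excluded",
                      stacklevel=2)
    if not fractions:
        raise ValueError("no probe with positive total intensity")
    return PopulationEstimate(
        per_probe=fractions,
        fraction_minor=sum(fractions) / len(fractions),
    )
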