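# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## Scattering (saxs)

**Debye profile.**  Intensities are the exact orientationally averaged
double sum over atom pairs, `I(q) = Σᵢⱼ fᵢ fⱼ sinc(q·rᵢⱼ)`, grouped by
element pair so the form factor is evaluated once per element.  The q = 0
singularity is removed by the sinc limit, giving `I(0) = (Σ fᵢ(0))²` in
vacuum contrast.  The cost is O(N²) in atoms, evaluated exactly — for the
few thousand heavy atoms of the assemblies this package targets that is
seconds on one core, so no multipole or histogram approximation is used.
Hydrogens are excluded by default (crystal structures at these resolutions
carry none); a flag re-enables them.

**Form factors.**  4-Gaussian international-tables coefficients, read from
gemmi's element tables, with `f(0)` equal to the electron count to within
0.1 e (asserted in tests).  The optional excluded-volume contrast subtracts
a Fraser-style Gaussian dummy atom, `ρ_s·V·exp(−q²V^{2/3}/4π)` with
ρ_s = 0.334 e/Å³ and tabulated per-element displaced volumes.  No explicit
hydration shell is modelled; because shell-aware calculators report slightly
larger radii, `coordinate_rg` exposes an additive `shell_delta` (default
0 Å) and comparisons against shell-aware published radii carry a documented
±1.0 Å tolerance.

**Guinier analysis.**  Weighted linear fit of ln I vs q², iterated to
self-consistency over the largest low-q window satisfying `q·Rg ≤ qrg_max`
(default 1.3, the usual globular-particle bound; polymer-like profiles need
a tighter window — the coil test uses 0.5).  At least 5 points are required;
non-positive intensities inside the window are an error, not silently
dropped.

**χ² and decompositions.**  `χ² = (1/(N−1))·Σ[(I_exp − c·I_calc)/σ]²` with
the scale c in closed form; the 1/(N−1) normalization is the package
convention.  The two-state fit scans the open fraction w on a uniform grid
(default step 0.005) with the analytic scale at each w, returning the global
minimum and breaking ties toward smaller w (the more closed, parsimonious
mixture).  The N-state fit solves the same problem by non-negative least
squares on σ-weighted intensities and renormalizes the coefficients to
weights; for two components it reproduces the grid scan to within one step.
The apparent-Rg mixture rule `Rg_app² = (C_A Rg_A² + C_B Rg_B²)/(C_A+C_B)`
is implemented directly; its bracketing property (Rg_app between the
component radii) is what lets population reasoning exclude any *smaller*
minor conformer when the apparent radius exceeds the major conformer's.

## DNA geometry (dna_geometry)

**Pairing.**  Two equal-length antiparallel strands are paired by position
(i with L+1−i); the register is sanity-checked by requiring C1'–C1'
distances below 15 Å for a majority of pairs.  Designed pair types come
from residue names; canonical Watson–Crick bonds are fixed per type
(A·T: N1–N3, N6–O4; G·C: N1–N3, N2–O2, O6–N4) and measured as
acceptor–donor heavy-atom distances at a 3.5 Å cutoff.  A pair with all
canonical bonds is `watson_crick`, with none `absent`, otherwise
`non_watson_crick`; missing atoms count as absent bonds with a warning.

**Frames and parameters.**  Each base frame is the least-squares (Kabsch)
superposition of the embedded standard-reference-frame base onto the
observed base atoms (≥ 6 atoms required); the strand-2 frame is flipped
180° about x so both z-axes run along the helix, and the pair frame is the
orthonormalized average.  Opening and propeller are the z- and y-components
of the axis-angle vector of the relative rotation between the two base
frames; twist is the z-component between consecutive pair frames and rise
the origin displacement projected on the mid-frame z.  This axis-angle
decomposition agrees with the standard-reference-frame parameter schemes to
fractions of a degree for near-planar pairs, which covers every comparative
statement the package is used for (a curvilinear-axis scheme is out of
scope).  Opening is reported signed; threshold comparisons use the
magnitude.

**Groove widths.**  Refined phosphate–phosphate convention: for each pair
level, cross-strand P–P distances within a ±6-level stagger window are
classified minor/major by the side of the pair plane the P–P midpoint falls
on (sign of x in the mid-level pair frame; x points toward the major
groove), and the width is the minimal distance in each class minus a 5.8 Å
backbone correction, floored at 0.  Levels with no candidate (missing
terminal phosphates) are flagged `None`, never zero-filled or imputed.
Absolute widths depend mildly on the convention; cross-structure
*comparisons* (which duplex is wider, by how many Å) are robust to it.

## Synthetic structures (synthetic)

**B-DNA builder.**  Pair i sits at frame Rz((i−1)·twist), z = (i−1)·rise
(defaults 36°, 3.38 Å — canonical B-form).  Strand-1 nucleotides are
standard-frame templates carried by that frame; strand-2 nucleotides are the
complementary templates after the 180° x-flip, so every unperturbed pair
forms its full canonical hydrogen-bond set by construction.  Templates are
assembled at import: the ideal-geometry residue from the Chemical Component
Dictionary (bundled with biotite) is posed onto embedded standard-frame base
coordinates and its sugar-phosphate moiety rotated about five frozen
backbone torsions, calibrated once so phosphorus sits at a canonical B-form
position (radius 9.1 Å, azimuth 95°, 1.0 Å below the base plane) and the
resulting ideal duplex shows canonical groove widths (≈ 6.4 / 11.2 Å
corrected).  5'-terminal phosphate groups are removed (5'-OH oligo
termini).  Per-pair opening/propeller perturbations are split half-and-half
between the two bases so the analysis modules recover them exactly.

The builder emulates geometry, not physics: backbone torsions are idealized
(the O3'…P linkage is plausible, not refined), there is no
sequence-dependent structure, no solvent, no thermal disorder.  Passing
round-trip tests therefore demonstrates the *analysis* conventions are
self-consistent and correctly implemented — not that real A-tract DNA has
these parameters.

**Helix bundles.**  Poly-alanine α-helices (1.5 Å rise, 100°/residue, 5
heavy atoms per residue) on a square lattice: deterministic stand-ins with
controllable size/shape contrast for superposition, Rg and mixture tests;
not physically refined proteins.

**Mixture profiles.**  `I = (1−w)·I_a + w·I_b` plus zero-mean Gaussian noise
with σ(q) = noise_level·I(q), the simplest noise model consistent with the
χ² definition (Poisson statistics are not emulated).  The σ column is
populated (with a tiny floor in the noise-free case so χ² stays defined);
generation is bit-reproducible under a seed.

## Superposition and interfaces (compare)

Kabsch superposition with SVD sign correction (proper rotations only;
collinear sets rejected).  Salt bridges use the common side-chain
criterion — Lys NZ / Arg NE,NH1,NH2 nitrogen to Asp/Glu carboxylate oxygen
≤ 4.0 Å — counted per residue pair with the closest atom pair reported;
histidine (protonation unknown at crystallization pH) and the C-terminal
carboxylate are excluded by default, toggleable.  Phosphate contacts list
every protein residue with a side-chain heavy atom within 5.5 Å of any DNA
phosphate-group atom (P, OP1, OP2, O5', O3').

## Thermodynamics (thermo)

`ΔG = RT·ln Kd` (Kd in molar, R = 8.314 J mol⁻¹ K⁻¹) and `TΔS = ΔH − ΔG`;
the default temperature for the bundled titration constants is 277.15 K
(4 °C), at which the derived columns reproduce the measured table within
0.2 kJ/mol.  Protein masses are average-isotopic from sequence (one water
per peptide bond); affinity-tag mass is included only when the tag sequence
is supplied explicitly.  DNA strands use average nucleotide-monophosphate
masses with 5'-OH termini (synthetic oligos; one HPO₃ ≈ 80 Da per strand
versus the 5'-phosphate form, within the 0.1 kDa rounding of the quantities
compared).  NMR minor-state populations are the unweighted mean of
i_minor/(i_minor+i_major) over probe residues, excluding zero-sum probes
with a warning.

## Pipeline

Stages run in the order oligomer/scattering → mixture decomposition → DNA
geometry → interfaces → thermodynamics, from one YAML config; outputs are
tidy CSVs plus a JSON manifest carrying the config hash, package version and
input checksums.  The default configuration is fully synthetic, so a run
requires no network and identical configs yield byte-identical tables.

## Problem sizes and determinism

Tests and the acceptance script use 16-bp duplexes, 4×20-residue bundles,
151–301-point q grids and 200-replicate recovery studies — sizes chosen so
the full suite completes in well under a minute while keeping every
statistical check comfortably powered.  All randomness flows through
explicitly seeded NumPy generators; hypothesis property tests run
derandomized.

## Known limitations

- No hydration-shell scattering model; published shell-aware calculated
  radii are matched only within ±1.0 Å.
- No curvilinear-axis DNA parameters (no bending/register); non-canonical
  pair taxonomies (wobble, Hoogsteen) are not named, only classified as
  non-Watson–Crick.
- The B-DNA builder's backbone is idealized; do not use it for
  torsion-angle or sugar-pucker studies.
- Salt-bridge counts depend on the 4.0 Å convention; other programs'
  criteria can differ by a bridge at boundary distances.
- The structure reader takes the first model of multi-model files and
  resolves altlocs to the highest-occupancy conformer (ties: first in
  file); no symmetry/assembly expansion is performed — callers name chains
  explicitly.
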