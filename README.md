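# clampscope

Structural analysis of DNA-clamping protein assemblies — written for
structural biologists studying nucleoid-associated proteins (NAPs) that
oligomerize around DNA, such as the *Caulobacter crescentus* protein GapR,
whose tetramer encircles AT-rich duplex DNA and exchanges between a closed
clamp and open, C-clamp-like conformations.

The package answers, from coordinates and printed constants alone, the
questions that characterize such a system:

- **What does each conformer scatter like, and what mixture explains the
  measured curve?**  Profiles are computed with the exact Debye double sum
  `I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sin(q·rᵢⱼ)/(q·rᵢⱼ)`, radii of gyration by Guinier
  analysis (`ln I = ln I₀ − q²Rg²/3` over `q·Rg ≤ 1.3`), model/data agreement
  by reduced χ² with an analytic scale, and conformer populations by an
  exhaustive two-state scan or non-negative least squares.  The apparent
  radius of a mixture follows
  `Rg_app = √((C_A·Rg_A² + C_B·Rg_B²)/(C_A + C_B))`, which forces any minor
  conformer that *raises* the apparent Rg to be larger than the major one.
- **How is the bound DNA deformed?**  Base pairs are identified and their
  Watson–Crick hydrogen bonds inventoried at a 3.5 Å donor–acceptor cutoff
  (A·T: N1–N3, N6–O4; G·C: N1–N3, N2–O2, O6–N4); opening, propeller, twist
  and rise come from standard-reference-frame base fitting, and minor/major
  groove widths from the refined phosphate–phosphate convention (minimal
  cross-strand P–P distance minus 5.8 Å).
- **How do the subunits assemble?**  Kabsch superposition/RMSD over arbitrary
  selections, residue-pair salt bridges (charged N–O ≤ 4.0 Å), and
  protein-to-DNA phosphate contact inventories (≤ 5.5 Å).
- **What do the binding constants imply?**  `ΔG = RT·ln Kd` and
  `TΔS = ΔH − ΔG` per titration, plus oligomer/complex molecular-weight
  bookkeeping and NMR minor-state populations from peak-intensity ratios.

A synthetic-structure module builds ideal and perturbed B-form duplexes,
toy helix bundles, and noisy two-component mixture profiles with known
ground truth, so the entire pipeline is testable without downloading any
structure.

## Worked example

Build the 16-bp A-tract duplex used throughout (strand 1
`5'-CCGAAAAAAAAAACGC`), analyze its geometry, and check the thermodynamics
of its binding constants:

```sh
$ clampscope synth bdna --seq CCGAAAAAAAAAACGC --out 10a.pdb
wrote 16-bp duplex to 10a.pdb

$ clampscope dna 10a.pdb --chains A,B | head -4
 pair designed_type classification  n_hbonds  opening_deg  ...  twist_to_next_deg  minor_width_A  major_width_A
    1           C.G   watson_crick         3    -0.003911  ...          35.999641            NaN            NaN
    2           C.G   watson_crick         3    -0.002399  ...          36.002497      11.009706      11.227058
    3           G.C   watson_crick         3     0.005559  ...          35.998191       8.736974      11.226634

$ clampscope thermo --kd 11.6e-9 --dh 46.2
dG = -42.1 kJ/mol  TdS = 88.3 kJ/mol  (T = 277.15 K, entropy-driven: True)

$ clampscope mass --monomer 11.2 --n 4 --dna CCGAAAAAAAAAACGC,GCGTTTTTTTTTTCGG
monomer 11.20 kDa x 4 + DNA 9.76 kDa = complex 54.56 kDa
```

Reading the output: every designed pair is classified Watson–Crick with all
canonical bonds under 3.5 Å, each step twists by 36.00° (canonical B-form;
the first groove level is undefined — `NaN` — because a 5'-OH terminus has
no phosphate).  An 11.6 nM dissociation constant at 4 °C corresponds to
−42.1 kJ/mol of binding free energy; with ΔH = +46.2 kJ/mol the binding is
endothermic and entirely entropy-driven (TΔS = +88.3 kJ/mol).  Four 11.2 kDa
monomers plus the 9.76 kDa duplex give a 54.6 kDa complex.

The same stages run end-to-end from one config:

```sh
clampscope run config.yaml        # synth -> saxs -> mixture fit -> dna -> interfaces -> thermo
clampscope run config.yaml --dry-run
```

emitting tidy CSV tables and a manifest (config hash, version, input
checksums); identical configs produce byte-identical tables.

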