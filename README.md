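# fibrilmetrics

Analysis of D-periodic collagen fibril models: inter-monomer hydrogen
bonding under triclinic periodicity, persistent residue contact maps,
gap/width/length structural metrics, and constant-strain elasticity —
together with a synthetic Hodge–Petruska microfibril generator that provides
exact ground truth for every analysis.

## The problem

A collagen fibril is built from ~300 nm triple-helix monomers packed with an
axial stagger of D ≈ 67 nm, the famous D-band. The smallest crystallographic
repeating unit of such a fibril is a triclinic cell whose longest lattice
constant equals D and which contains exactly **one** monomer of length
4.46 D; under periodic boundary conditions every neighbouring monomer is a
periodic image of that one molecule. Analysing simulations of this system
therefore requires lattice-aware machinery:

- a *hydrogen bond to a neighbouring monomer* is a donor–acceptor pair whose
  minimum-image partner carries a nonzero lattice shift (after correcting
  for the wrapped storage of a molecule that threads the cell 4.46 times);
- the *gap/overlap structure* (axial zones with 4 vs 5 monomer segments in
  cross-section, ideally 0.54 D of gap) appears as a two-level axial mass
  density profile;
- the *monomer width* is the largest of the three nearest-neighbour backbone
  N–N distances across the triple helix;
- the *Young's modulus* E follows from Hooke's law σ∥ − σ0 = E ε∥ fitted to
  constant-strain simulations (linear regime ε∥ < 5%), and *monomer
  slippage* from the shortfall of monomer elongation, s(ε) = 1 − (L/L0 − 1)/ε.

The package is aimed at people analysing such periodic fibril trajectories
(or testing analysis pipelines before the expensive simulations exist): the
synthetic generator emits structures, trajectories, strained states and
stress time series with *known* gap fraction, width, end-to-end length,
modulus and slippage, so every operation can be validated against ground
truth.

## Worked example

Generate a default synthetic microfibril (one triple helix, 3 × 1014
residues, D = 67 nm, 10% of residues hydroxylated) and analyse it:

```bash
$ fibrilmetrics generate --out demo --seed 1 --n-frames 3
wrote structure, 3-frame trajectory and ground truth to demo

$ fibrilmetrics report demo/traj.pdb
{"dband_length_nm": 67.0, "dband_length_err": 0.0,
 "gap_fraction_pct": 54.0, "gap_fraction_err": 0.0,
 "monomer_width_nm": 0.7071912298520373, "monomer_width_err": 0.0035808674589880426,
 "end_to_end_nm": 298.8119573267464, "end_to_end_err": 0.00442746466995563}

$ fibrilmetrics dehydroxylate demo/structure.pdb --out demo/dehyd.pdb --report demo/edit.tsv
edited 304 residues, removed 608 atoms
```

Reading the numbers: the D-band length is the longest lattice constant
(67 nm by construction); the gap occupies 54% of the axial period — the
ideal Hodge–Petruska value 5 − 4.46 = 0.54 D; the monomer width is the
0.70 nm calibration (helix radius 0.70/√3 nm, slightly inflated by thermal
jitter since the width is a maximum over three distances); the end-to-end
length matches the built 4.46 × 67 ≈ 298.8 nm monomer. De-hydroxylation
removed exactly two atoms (hydroxyl O and H) per hydroxylated residue.

The same operations are available as a library:

```python
from fibrilmetrics.core import Trajectory
from fibrilmetrics.synthetic import FibrilSpec, build_microfibril
from fibrilmetrics.metrics import axial_density_profile, gap_fraction

frame = build_microfibril(FibrilSpec(seed=1))
profile = axial_density_profile(Trajectory.from_frame(frame))
print(gap_fraction(profile))   # 54.0
```

`fibrilmetrics mechanics fit --manifest manifest.json --out fit.json`
reduces per-strain stress CSVs (block-averaged tail means, σ0 subtracted)
to a stress–strain curve, fits E by zero-intercept weighted least squares
over ε ≤ 5%, and reports per-strain slippage when end-to-end lengths are
supplied.

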