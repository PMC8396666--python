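# Methods

## The periodic fibril model

All analyses assume the smallest repeating unit of a D-banded fibril: a
triclinic cell with lattice vectors **a**, **b**, **c** (Cartesian nm,
positive scalar triple product) whose longest vector defines both the
fibril axis and the D-period D. The cell contains one triple-helix monomer
of axial extent 4.46 D; applying periodicity turns it into an infinitely
long and wide fibril in which every neighbouring monomer is a lattice image
of the one molecule.

Minimum-image displacements are found by rounding the fractional
displacement and refining over the 3×3×3 shift neighbourhood; exact ties
resolve to the lexicographically smallest shift. This is exact for
compact ("reduced") cells — the dialect produced by common MD engines — and
`TriclinicCell.is_reduced()` lets loaders reject pathological skew. The
equivalence with exhaustive image enumeration is asserted in the test suite
on thousands of random instances.

### Monomer-relative lattice shifts

A monomer longer than the cell is stored wrapped, so a raw minimum-image
shift between two stored atoms conflates two things: genuine neighbouring-
monomer geometry and the bookkeeping of which cell each stored atom was
folded into. The physically meaningful shift between monomer *copies* is

    relative_shift = raw_shift + n_partner − n_self

where `n_x` is the integer lattice offset of stored atom x from the
unwrapped molecule. Offsets come from generator provenance when present,
else from a covalent-walk unwrap (bonded steps via minimum image; a step
longer than 0.3 nm aborts the walk); for disconnected constructions all
offsets are zero and raw shifts are used. Without this correction, backbone
contacts between covalently bonded residues straddling the cell boundary
would be miscounted as inter-monomer bonds.

## Hydrogen bonds

Geometric criterion, strict inequalities: donor–acceptor distance
< 0.35 nm and angle at the donor between the D→A and D→H vectors < 30°.
Donors are N/O heavy atoms with a hydrogen resolved by name template
(H/HN… for N, HD1 for OD1, …) or, for unclaimed hydrogens only, by
proximity within 0.12 nm; acceptors are all oxygens plus template-listed
nitrogens. Donor–acceptor pairs within one residue are excluded. Classes:
nonzero relative shift between protein atoms → inter-monomer; zero shift →
intra-chain or inter-chain-intra-monomer; water on one side →
protein-water (water–water is out of scope). A residue "engages" in a frame
if any of its atoms is donor, donor-hydrogen or acceptor of an
inter-monomer event; the per-residue probability is the fraction of frames
with ≥ 1 such event (not a time-averaged bond count — the alternative
reading; this choice is deliberate and documented here). Multiple
simultaneous bonds count once for the probability and individually for
totals.

## Contacts

Two residues are in contact in a frame when any heavy-atom pair is within
0.6 nm (minimum image); pairs persisting in strictly more than half the
frames are retained. The closest atom pair in a frame supplies the
inter/intra flag; the majority over qualifying frames labels the pair, with
ties falling to intra-monomer. Sequence neighbours are not excluded;
same-residue pairs are excluded by construction. Map comparison intersects
canonical (chain, index) pair keys, so hydroxylation-state renames (HYP vs
PRO) do not affect identity.

## Structural metrics

- **Axial density profile**: protein mass histogrammed by fractional
  coordinate along the fibril axis, trajectory-averaged, normalised per nm
  axial per nm² lateral. Default 100 bins (~0.7 nm over 67 nm). Two
  considerations fix this default: bins must not under-resolve the ~0.3 nm
  residue spacing (finer bins turn the two-level profile into grid noise),
  and the ideal gap boundary at 0.46 of the period should fall on a bin
  edge so boundary bins are not split between levels — with 134 bins a
  ~50%-filled boundary bin sits exactly at the threshold and the measured
  gap fraction becomes a coin flip of ±1 bin.
- **Gap fraction**: threshold at the midpoint of the 5th and 95th
  percentile bin densities; gap = % of bins strictly below. The percentile
  midpoint recovers the ideal 4:5 step exactly and tolerates level-internal
  fluctuations; profiles without contrast (spread < 1% of the mean) are
  rejected. Real-fibril thresholding dialects differ (reported gap
  fractions for equilibrated all-atom trajectories run several points
  higher than the ideal 54%); this package does not attempt to match any
  particular dialect beyond the deterministic rule stated here.
- **Monomer width**: per cross-sectional rung — one backbone N per chain,
  matched by minimal axial separation on the unwrapped molecule, tolerance
  0.6 of the median rise, tie-break lowest residue index — the width is the
  *largest* of the three pairwise N–N distances; averaged over rungs and
  frames, excluding the terminal 3% of residues per chain (telopeptide
  stand-ins). Incomplete rungs are skipped and counted.
- **End-to-end length L**: distance between the centroid of the three
  N-terminal backbone nitrogens and the centroid of the three C-terminal
  carbonyl carbons on the unwrapped molecule (termini included). Chains are
  unwrapped independently and re-registered against the first chain.
- **D-band length**: per-frame longest lattice constant.

Uncertainties are block-averaged standard errors: 10 contiguous blocks
(trailing remainder joins the last block), sample (n−1) standard deviation
of block means over √n_blocks. The block mean equals the plain mean
exactly.

## Mechanics

Each constant-strain run contributes one stress series σ∥(t). The default
reduction averages a fixed final window (one third of the span, mirroring
the use of the final stretch of long runs); an automatic mode instead
starts at the detected equilibration time — the earliest point from which
the two halves of the remaining tail agree within twice the pooled block
SE (a constant series equilibrates at its first point; a monotone drift
raises). Note the rule is scale-free for a noiseless exponential decay and
only discriminates in the presence of noise; the fixed window is therefore
the default. σ0 (0.1 MPa) is subtracted; E is fitted through the origin by
weighted least squares (weights 1/SE², falling back to unweighted when SEs
are zero) over 0 < ε ≤ 0.05, with the fit SE propagated from the known
per-point errors. Slippage is reported per strain as s = 1 − (L/L0 − 1)/ε:
0 for affine monomer elongation, 1 for pure sliding.

## The synthetic generator

The generator emulates the statistical structure the analyses assume — not
collagen physics. One coarse triple helix (per residue: N, H, CA, C, O at
fixed sub-rise offsets; OD1/HD1 on hydroxylated residues) is wound at
helix radius r = 0.70/√3 nm (so the width observable is exactly 0.70 nm)
about a local axis threaded through five lateral sites on a 1.5 nm circle
inside a ~4 nm lateral cell, one site per successive D-segment, with
smoothstep lateral transitions (1.5 nm axial width) so bonded steps stay
below the unwrap tolerance. Key choices:

- **Flush axial grid, staggered indexing.** All chains share one axial
  residue grid spanning exactly [0, 4.46 D); the canonical one-residue
  stagger is realized in residue numbering (the rung at z = (j−1)·rise
  holds residue j+2, j+1, j of the three chains). Matched rungs therefore
  sit at identical z with chain phases exactly 120° apart (width = r√3
  analytically), and the gap/overlap boundaries are sharp (a literal
  per-chain z-offset leaves half-filled boundary bins exactly at the
  density threshold).
- **Terminal taper.** The first and last 3% of each chain taper onto the
  local axis — a crude stand-in for the non-helical telopeptides — which
  also places the terminal centroids exactly on the lateral site centres,
  making L analytic and exactly affine under strain.
- **Hydroxylation** flags are drawn as an exact count (10% of residues by
  default) among non-glycine positions of the G-X-Y pattern; flagged
  prolines become HYP, flagged lysines LYZ, each carrying an OD1/HD1
  pseudo-hydroxyl (+2 atoms, +17 amu).
- **Strain** scales the axial lattice constant by (1+ε); the molecule's
  axial coordinates and lateral site centres scale by (1+(1−f)ε) — slippage
  f acts as rigid re-registration of D-segments — while helix offsets about
  the site centres scale by (1 − width_contraction·ε), the winding
  tightening that accompanies stretch (default 0.3 per unit strain,
  matching the observed ~0.70 → 0.69 nm width change at 5% strain). With
  generator provenance these relations are exact: L/L0 − 1 = (1−f)ε to
  machine precision.
- **Trajectories** add i.i.d. isotropic Gaussian jitter (default
  σ = 0.01 nm) about the built frame, without re-wrapping, so image
  registration is frame-independent and connectivity decoding stays
  unambiguous. Real thermal fluctuations are larger and correlated; the
  generator makes no attempt at dynamics, solvent, or energetics.
- **Stress series**: σ(t) = σ0 + Eε(1 − e^(−t/τ)) + AR(1) noise
  (stationary initialization), defaults E = 500 MPa, τ = 10 ns, innovation
  SD 2 MPa, lag-1 coefficient 0.8, 100 ns at 0.1 ns resolution — noise of
  the right order for block-averaged virial stress traces, with an
  equilibration transient long enough to exercise tail-window logic.
- **Planted boundary bonds** reposition hydroxyl groups of chosen residues
  to laterally clear spots (computed with clearance from every site-centre
  image) just across the axial boundary, giving an exact, countable set of
  inter-monomer hydrogen bonds that de-hydroxylation must remove.

What passing tests on this generator shows: the *operations* are correct —
oracle-equivalent detection, exact geometric anchors, unbiased parameter
recovery at the stated noise. What it does not show: agreement with real
trajectories, whose lateral packing, sequence, solvent and correlated
dynamics the generator deliberately omits.

## Degenerate inputs and numerical conventions

Zero-volume or left-handed cells are rejected at construction; extreme
skew fails `is_reduced()`. Strict inequalities at every stated threshold
(0.35 nm, 30°, 0.6 nm, half-trajectory persistence). Pearson correlation of
two residue profiles is NaN with a warning when either profile is constant.
Percentile thresholds, tie-breaks (lex-smallest shift, lowest residue
index, ties-to-intra labels) and the sample (n−1) SD convention are fixed
as documented above so that identical inputs give byte-identical outputs;
every CLI run records its resolved configuration, input hashes and seed in
a provenance JSON.

## Problem sizes

Default analyses run on the full-size model (3 × 1014 residues, ~16k
atoms) in under a second per frame; the test suite exercises a 1/10-scale
model (D = 6.7 nm, 102 residues per chain) for trajectory-level tests and
the full-size model for density/gap anchors, with Monte-Carlo recoveries at
50 seeds × 6 strains × 1000 stress points.

## Known limitations

- Gap-fraction thresholding on real data is dialect-sensitive; only the
  ideal-geometry anchor is claimed.
- The contact label for image-ambiguous pairs uses a majority rule over
  qualifying frames; other conventions exist.
- `stagger_D` other than 1.0 is rejected: in a one-cell periodic model the
  stagger *is* the axial lattice constant.
- The equilibration detector cannot discriminate transients in noiseless
  deterministic series (see Mechanics).
- Residues bonded to their own periodic image are excluded by the
  same-residue rule, following the stated exclusion verbatim.
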