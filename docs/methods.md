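# Methods

## Conventions

Internal units are Å for length and ns for time; all readers convert on
ingest (XTC nm → Å, ps → ns). The pore axis is a z-vector pointing from the
extracellular side toward the cytosol, so the site order along +z is
vestibule < Sa < S3 < Sb < Sc < cavity. Atoms and frames are 0-based;
residue numbers follow the source file's author numbering (C479, I480,
I511, T515, residues 507–511). All z-interval assignments use half-open
intervals [lo, hi) along +z and all distance cutoffs are inclusive (≤), so
boundary behaviour is bit-exact and double counting is impossible.

The two carbonyl-oxygen planes of the filter are configuration, not
constants: the default maps p23 to the residue-480 backbone O and p34 to
residue 479 (the assignment consistent with the cylinder-height rule used
for zone construction), and the alternative residue labelling can be
selected through `TemplateConfig` / plane-residue arguments, since the two
labelling schemes in circulation disagree.

## Site model and boundaries

Site z-centers (Å relative to the filter midpoint) default to
vestibule −6, Sa −2, S3 0, Sb +2, Sc +4, cavity +9, with p23 at z(Sa) and
p34 at z(Sb). Binding-site windows are derived from the plane gap
g = z34 − z23: Sa = [z23 − 0.5 g, z23 + 0.25 g), S3 = [z23 + 0.25 g,
z34 − 0.2 g), Sb = [z34 ± 0.2 g), Sc = [z34 + 0.2 g, z34 + 0.8 g),
vestibule above Sa and cavity below Sc. The fractions are package defaults —
no published z-windows exist for these sites — and are exposed in
configuration; every choice of fractions that keeps the intervals ordered
is accepted.

## Trajectory filtering and state assignment

Per-ion z-series are smoothed with a third-order Butterworth low-pass at
10 ns⁻¹ before assignment. The default is zero-phase (forward–backward,
`scipy.signal.filtfilt`), because a causal pass delays every site entry by
the group delay and biases dwell boundaries late; a causal mode is kept for
parity checks. Whether the original analyses filtered causally or
zero-phase is not documented anywhere we know of, so this is flagged as a
reproduction risk; the test suite cross-checks the filter against an
independent from-scratch Butterworth (analytic analog poles, bilinear
transform, hand-rolled recursion) to 10⁻⁶ RMS on interior samples.

Sampling must satisfy the Nyquist precondition dt < 1/(2·10 ns⁻¹) = 0.05 ns;
the generator default is dt = 0.02 ns (Nyquist 25 ns⁻¹). At coarser spacing
the 10 ns⁻¹ cutoff sits close to Nyquist, the filter stops attenuating the
positional noise, and label flicker inflates dwell counts — this is a
property of the method, not of the implementation.

A permeation is an inward event when an ion's label series visits Sa and
later reaches the cavity without returning to the vestibule or external
bulk in between; the outward rule is the mirror image (Sc → vestibule
without touching the cavity/internal bulk). Dwells are maximal
constant-label runs; a run of n frames at spacing dt has duration n·dt, so
durations sum exactly to the covered span. Aggregated statistics discard
the first 50 ns of each trajectory (equilibration convention); single-
trajectory event listings keep full time.

## Zone densities

The cylinder stack is built from the initial structure: centered on the
center of mass of the filter carbonyl oxygens, with common height equal to
the z-distance between the two plane centers, 14 pore cylinders spanning
cavity to vestibule plus 4 bulk cylinders on each side (22 total — the
stated total fixes the per-side reading of "four additional cylinders").
Pore radii are the minimal xy distance from any flanking Cα whose z falls
in the cylinder's height interval to the cylinder axis; bulk cylinders use
a fixed configured radius (15 Å default) because no radius rule is stated
for them. Recentering translates all cylinder centers by the per-frame
displacement of the filter-oxygen center of mass, in x, y and z by default
(xy-only is available): full 3-D recentering also corrects membrane drift.
Densities are time-mean counts divided by π r² h (in nm³); the CDF is
count-weighted by default (density weighting is a flag) and is accumulated
from the cytosolic bulk toward the extracellular bulk.

## Coordination counting

Water oxygens are solvent-residue O atoms; carbonyl donors are backbone O
atoms of the plane residues (configurable list). Counts use plain Euclidean
distance without minimum-image correction — filter-bound ions are many Å
from the box boundary, so images cannot contribute; a PBC-aware mode would
be needed only for bulk ions and is out of scope. "Time-averaged" site
values average over all frames in which the ion is resident in the site
(not within-event averages; the alternative is not distinguishable from
published material). The site-aggregated median pools all filter-site
frames.

## Synthetic generator

The generator reproduces the *statistical structure* the analysis assumes,
not the physics: there is no force field, membrane, electrostatics or water
structure. Specifically:

- **Kinetics.** Site hopping is an exact-stochastic (Gillespie) CTMC over
  bulk_ext ↔ vestibule ↔ Sa ↔ S3 ↔ Sb ↔ Sc ↔ cavity ↔ bulk_int, with
  optional single-occupancy exclusion on non-bulk sites and a knock-on
  factor multiplying the +z-ward exit rates of downstream ions while Sa is
  occupied. No published rate constants exist for this system, so preset
  rates encode only ordinal/ratio statements: the two-species preset sets
  per-site exponential mean dwells of 2 ns (K⁺) and 12 ns (Cs⁺), i.e. the
  six-fold median residence contrast, and consists of 140 independent
  single-permeation runs per species (an ion started in the vestibule,
  absorbed in the internal bulk) so that no ion is ever recycled through
  the filter. Recycling a single ion through a periodic jump would drag the
  filtered z-trace back through every site and contaminate the dwell pool
  with sub-frame transit artifacts.
- **Exact event counts.** Where an exact printed count is the point (eight
  Rb⁺ and three Cs⁺ full passages in 500 ns), fixtures are deterministic
  scripts, not samples, so the expectation is exact and portable across RNG
  implementations.
- **Coordinates.** An ion at a site is emitted at the site z-center plus
  N(0, σ_z) with N(0, σ_xy) lateral jitter (defaults 0.3 Å — small compared
  with the 2 Å site spacing, large enough to exercise the filter). The
  carbonyl planes breathe: while a site adjacent to a plane is occupied
  (Sa for p23; Sb or Sc for p34) the inter-subunit gap is drawn from
  N(μΔ(bound species), σΔ), otherwise from N(μΔ(apo), σΔ), with σΔ =
  0.15 Å. The μΔ table is a set of placeholders recorded in configuration
  that respects the ordinal facts only: μΔ grows with ionic radius at both
  planes, every species contracts p23 relative to apo (Na⁺ most), Li⁺
  contracts p34 while larger species widen it.
- **Solvation.** For each filter-resident ion frame, the generator counts
  the carbonyl oxygens already inside the species cutoff geometrically and
  adds `shell_total − n_carbonyl` water oxygens isotropically at distances
  uniform in (0.7·cutoff, cutoff), clamped at zero with a warning. Shell
  totals default to 6/6/7/8/9 oxygens for Li⁺/Na⁺/K⁺/Rb⁺/Cs⁺. By
  construction a recount with the same cutoff returns the shell total
  exactly, which is what makes the coordination stage testable to ±0.

What passing these tests shows — and does not show. They verify that the
pipeline recovers known kinetic, coordination and geometric parameters from
data with the assumed structure (piecewise-stationary sites, Gaussian
noise, exponential dwells). They cannot certify behaviour on force-field
artifacts the generator does not emulate: correlated noise, partial-
occupancy or off-axis binding, water exchange dynamics, PBC wrapping of
bulk ions, or non-exponential dwell distributions.

## Problem sizes

Default verification sizes were chosen so results are statistically
decisive at interactive cost: 140 single-pass runs per species (≥ 500
pooled filter dwells each, pooled-median recovery within a few % of the
exponential ln 2 · mean), 260 ns at dt = 0.02 ns (≥ 10⁴ filter-resident
frames) for coordination recovery, 10³ random placements for the
point-in-cylinder oracle, and 4·10⁴-sample series for the filter-response
checks.

## Electrophysiology auxiliaries

The neutralizing-ion formula is the water-molarity convention:
n_anion = round(n_water · c / 55.5 mol/L), with the protein's negative net
charge added to the cations (a positive charge would go to the anions
symmetrically). Rounding is half-away-from-zero; the worked example
(11,650 waters, 900 mM, −8 e → 197/189) does not exercise the tie rule, so
the convention is documented here. A box-volume interpretation of the
concentration does not reproduce those printed counts and was rejected.

ΔI/V ramp subtraction normalises each sweep by its current at the sample
nearest −130 mV (a small averaging window is available as an option),
interpolates linearly to a 1-mV grid over [−250, −130] mV, and subtracts
the normalised pc-40 sweep from the normalised pc-130 sweep. Aggregation
across cells is a pointwise mean with sample SD (n − 1); a single curve
aggregates to itself with SD 0 by convention.

## Known limitations

- Site windows, generator rates, σ parameters and μΔ values are package
  defaults, not measured constants; every output that depends on them
  records them in configuration.
- The plane-residue labelling ambiguity (see Conventions) is shipped as
  two presets without asserting which is correct.
- No PMF/free-energy estimation, no HMM/Bayesian state estimation, no
  rate-matrix inference, no pore-radius (HOLE-style) profiling, and no
  block-model (Woodhull) fitting.
- PBC handling is limited to whole-frame recentering; bulk-ion densities
  from wrapped trajectories should be interpreted with the wrapping policy
  in mind.
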