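# poreflux

Post-processing toolkit for molecular-dynamics trajectories of tetrameric
cation-channel pores, built around the weakly K⁺-selective HCN4 pore and the
five alkali metal cations (Li⁺, Na⁺, K⁺, Rb⁺, Cs⁺). It is aimed at people who
run channel MD and want reproducible, testable answers to four questions:

1. **Where are the ions?** Cation number densities in recentered cylindrical
   volume elements stacked along the pore axis (14 pore + 8 bulk cylinders by
   default), and the empirical CDF of those densities along z.
2. **How do they move?** Per-ion z-trajectories are smoothed with a zero-phase
   third-order Butterworth low-pass filter (cutoff 10 ns⁻¹) and mapped to the
   discrete binding sites vestibule/Sa/S3/Sb/Sc/cavity; from the label series
   the package extracts dwell times, multi-ion occupancy states such as
   `{Sa,Sc}`, and full permeation events (Sa → cavity without returning to the
   external side).
3. **How are they coordinated?** Water and backbone-carbonyl oxygens within a
   species-specific first-shell cutoff (2.74/3.21/3.55/3.8/4.1 Å for
   Li⁺/Na⁺/K⁺/Rb⁺/Cs⁺) are counted per frame and summarised per site,
   including the filter-aggregated median total coordination number.
4. **How does the filter respond?** Inter-subunit carbonyl-oxygen distances
   Δp23/Δp34 between opposing monomers (A|C, B|D), gated on binding events of
   ≥ 12 ns; KDE occupancy profiles along z; cavity hydration (waters within
   5 Å of residues 507–511) and the I511/T515 Cα gate distances.

Because real channel trajectories are expensive, the package ships a
first-class synthetic generator (`poreflux.synthetic_data`): an event-driven
continuous-time Markov simulator of site hopping with single-occupancy
exclusion and knock-on coupling, deterministic scripted fixtures for exact
event counts, Cartesian emission with species-dependent breathing of the
carbonyl planes, and solvation-shell decoration with a species-specific total
oxygen count. Every stage of the analysis can therefore be scored against
exact ground truth.

Two auxiliary computations are included: neutralizing-ion-count arithmetic
for system solvation (water-molarity convention, 55.5 mol/L) and the
electrophysiology ramp-subtraction ΔI/V procedure (normalise two prepulse
sweeps at −130 mV, interpolate, subtract).

## Worked example

Detect permeations on the scripted Rb⁺ fixture (eight full passages in a
500-ns window) and recover the Cs⁺/K⁺ dwell-time ratio:

```python
import pandas as pd
import poreflux as pf
from poreflux.synthetic_data import PRESETS, FILTER_SITES, run_duration

site_model = pf.SiteModel()
noise = pf.GeometryNoiseConfig()
bounds = pf.derive_boundaries(site_model.z_p23, site_model.z_p34)

spec = PRESETS["rb_conduction"](0)
events = []
for k, path in enumerate(spec["paths"]):
    t, z, _ = pf.emit_ion_z(path, site_model, noise, dt=0.02, seed=k, duration=500.0)
    labels = pf.assign_sites(pf.lowpass_filter(z, 0.02), bounds)
    events.append(pf.detect_permeations(labels, t, ion=k))
ev = pd.concat(events, ignore_index=True)
print(ev.head(3))
print("inward permeations:", (ev["direction"] == "inward").sum())
```

prints

```
   ion  t_enter  t_exit direction
0    0     29.0   44.98    inward
1    1     84.0   99.98    inward
2    2    139.0  154.98    inward
inward permeations: 8
```

i.e. every scripted passage is found, each entering Sa (`t_enter`) and
reaching the cavity (`t_exit`) with no spurious events. Running the pooled
dwell analysis on the two-species preset (`dwell_ratio_cs_k`, 140
single-permeation runs per species) prints

```
K median filter dwell: 1.29 ns over 562 dwells
Cs median filter dwell: 8.62 ns over 562 dwells
Cs/K median dwell ratio: 6.68
```

recovering the six-fold Cs⁺/K⁺ residence-time contrast the generator encodes
(true medians ln 2 · 2 ns ≈ 1.39 and ln 2 · 12 ns ≈ 8.32).

The same operations are available from the shell, e.g.

```sh
poreflux ions --waters 11650 --conc-mm 900 --charge -8
# cations: 197  anions: 189
poreflux simulate --preset cs_block --seed 5 --out fixtures/cs
poreflux permeation --topology fixtures/cs/topology_ions.pdb \
    --traj fixtures/cs/trajectory_ions.tsv --species Cs --dt 0.02 --out events.tsv
# 3 events (3 inward)
```

## Layout

- `src/poreflux/trajectory_io.py` — PDB/TSV/XTC ingestion, atom selection,
  Å/ns unit conventions
- `src/poreflux/synthetic_data.py` — templates, Markov site kinetics,
  scripted fixtures, coordinate emission, solvation decoration
- `src/poreflux/pore_zones.py` — cylinder stack, recentering, densities, CDF
- `src/poreflux/site_kinetics.py` — Butterworth filtering, site assignment,
  dwells, permeations, occupancy states
- `src/poreflux/coordination.py` — coordinating-oxygen counting
- `src/poreflux/filter_geometry.py` — Δp23/Δp34, KDE profiles, hydration,
  gate distances
- `src/poreflux/aux_analysis.py` — ion-count arithmetic, ΔI/V ramp subtraction
- `docs/methods.md` — models, parameter choices and limitations
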