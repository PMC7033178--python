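# nanotraffic

Quantitative analysis of lipid-nanoparticle (LNP) mRNA-delivery experiments,
for formulation scientists and imaging groups asking *where the delivery
bottleneck is*: does a formulation change alter particle structure, how much
mRNA is encapsulated, how do internalized particles move inside cells, and
how much mRNA actually escapes the endosome into the cytosol?

The package implements four analysis stages plus seeded synthetic-data
generators that emulate each instrument's output, so every stage can be
validated against known ground truth without instruments or raw data:

- **`trajmetrics`** — sliding-window linear transport efficiency of 3D
  single-particle trajectories sampled at 1 ms,

  E_j = ‖r_{j+w} − r_j‖² / [(w−1) Σ_{i=j+1}^{j+w} ‖r_i − r_{i−1}‖²],

  1 for unidirectional (microtubule-like) transport, →0 for random diffusion.
  Per-trajectory mean efficiencies are bimodal on a log₁₀ scale; a two-term
  Gaussian fit of the histogram yields *stationary* and *mobile* population
  fractions, compared between formulations with a bootstrap-SE t test.
- **`saxs`** — small-angle X-ray scattering reduction: buffer subtraction,
  Guinier radius of gyration (ln I ≈ ln I₀ − q²R_g²/3), and lamellar Bragg
  peak detection with repeat spacing d = 2π/q_peak.
- **`formqc`** — lipid-recipe planning from molar ratios and the N:P ratio,
  and dye-exclusion encapsulation efficiency
  EE = (1 − unencapsulated/total) × 100.
- **`imaging_quant`** — smFISH object-table quantification: single-mRNA
  intensity calibration from electroporated standards, cytosolic-vs-entrapped
  classification, per-cell endosomal-escape ratio (cytosolic mRNA per
  internalized LNP), perinuclear uptake, and uptake-rate curves.
- **`synthdata`** — generators for all four input kinds: two-state
  (stationary/mobile) 3D trajectories with localization noise, scattering
  profiles with a Guinier regime and a lamellar peak, spot fields with known
  per-cell counts, and RiboGreen-style plates with known encapsulated
  fraction.

## Worked example

Compare two simulated formulations end to end (two trajectory cohorts with
30% vs 60% mobile particles, two scattering profiles, a plate assay, a spot
field):

```python
from nanotraffic import RunConfig, run_pipeline

config = RunConfig.from_dict({
    "seed": 1,
    "trajectories": {"n_traj": 150, "duration": 12.0, "n_boot": 100,
                     "groups": {"LNP-like": {"mobile_fraction": 0.3},
                                "eLNP-like": {"mobile_fraction": 0.6}}},
})
report = run_pipeline(config)
```

Selected output (exact numbers for this seed):

```
trajectories:
  LNP-like   mobile_fraction 0.312  (bootstrap SE 0.059, n = 150)
  eLNP-like  mobile_fraction 0.592  (bootstrap SE 0.059, n = 150)
  t = -3.35, p = 0.00091
saxs d_spacing_table:
  LNP-like   q_peak 0.8679 nm^-1  d = 7.239 nm   Rg = 11.96 nm
  eLNP-like  q_peak 0.9469 nm^-1  d = 6.636 nm   Rg = 11.96 nm
qc:      ee_percent 94.0  (configured 94.0)
escape:  mean_escape_ratio 0.277  (11.0 cytosolic mRNA / 40.4 LNPs per cell)
```

Reading it: the decomposition recovers the configured mobile fractions of
the two cohorts (0.31 vs 0.59) and calls the difference significant; the
lamellar spacings follow d = 2π/q from the configured peak positions; the
encapsulation assay round-trips its configured 94%; and the escape stage
recounts the simulated cytosolic molecules and particles to give ~0.28
escaped mRNAs per internalized LNP.

The same stages are scriptable from the shell:

```sh
nanotraffic simulate trajectories --seed 3 --out traj.csv
nanotraffic traj analyze --input traj.csv --window 10
nanotraffic saxs peak --input profile.dat --window 0.5 1.5
nanotraffic qc plan --np 5.67 --ratios 50:38.5:10:1.5 --mass-ug 1
nanotraffic run --config run.yaml --seed 1 --outdir out/
```

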