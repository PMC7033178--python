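# Methods

## Linear transport efficiency

A 3D trajectory r_0 … r_{n−1} sampled uniformly at interval dt (nominally
1 ms) is scored window by window. For a window of w samples starting at j,

    E_j = ‖r_{j+w} − r_j‖² / [(w − 1) · Σ_{i=j+1}^{j+w} ‖r_i − r_{i−1}‖²].

The numerator is the squared net displacement, the denominator the
accumulated squared step lengths over the same w steps; by Cauchy–Schwarz
0 ≤ E_j ≤ w/(w−1). Constant-velocity straight motion attains the upper
bound (≈1 for large w); an ideal random walk has E[E_j] = 1/(w−1) ≈ 0. The
window slides one sample at a time and the E_j are averaged into one
efficiency per trajectory.

Choices and edge cases:

- The step sum runs over the w steps *inside* the window (i = j+1 … j+w).
  A lower limit of i = j would pull in the step entering the window, which
  references a point outside it; that variant is available via
  `include_entry_step=True` (its windows start at j = 1).
- Positions are 3D vectors; all squares are squared Euclidean norms.
- A window whose squared-step sum is below 10⁻¹² µm² is motionless at
  floating-point scale; its efficiency is defined as 0 (a stalled particle
  is maximally non-directed), not NaN.
- The default 10 s window at 1 ms sampling gives w = 10 000. Trajectories
  shorter than one window raise a dedicated skip signal;
  `analyze_trajectories` catches it and reports the skipped ids rather than
  dropping them silently. Sampling intervals deviating more than 1% from
  their median raise an error rather than silently mis-scaling the window.
- E is invariant under rotation, translation, and uniform spatial rescaling
  of the trajectory (tested).

## Mobility decomposition

Across a population of tracked particles, log₁₀ of the per-trajectory mean
efficiency is bimodal: a *stationary* mode (diffusive/stalled cargo) and a
*mobile* mode (directed transport). `decompose_mobility` histograms the log
values (efficiencies floored at 10⁻⁸ first) and fits a sum of two Gaussians
to the counts by bounded nonlinear least squares. The population fractions
are the components' analytic areas (amplitude · sd · √(2π)), normalised to
sum to one; the lower-mean component is reported as stationary.

Numerical choices:

- Bins: Freedman–Diaconis by default, floored at 20 bins — with two narrow,
  widely separated modes the FD rule alone can make bins so wide that a mode
  occupies a single bin and its area is unidentifiable.
- Initialization: a deterministic 1D two-means split of the log values. A
  quantile-based split (means at the 25th/75th percentiles) fails whenever
  one mode holds less than a quarter of the data — both starting means land
  in the majority mode and the minority peak is absorbed — whereas two-means
  locks onto both modes for any mixing fraction once they are separated.
- Bounds: amplitudes ≥ 0; component means confined to the observed log
  range (an edge spike cannot be fit by a phantom component outside the
  data); sigmas in [half a bin width, half the data range] so a component
  can neither collapse to a delta nor blanket both modes.
- A degenerate fit returns `converged=False` with a diagnostic message
  instead of raising; identical-valued input raises, since its histogram
  carries no shape information.
- `MobilityDecomposition.classify` labels trajectories by the nearer
  component mean in log space; on well-separated synthetic cohorts this
  agrees with the generator's ground truth for ≥ 90% of trajectories.

## Group comparison

`compare_groups` compares the mobile fractions of exactly two cohorts. The
point estimate per cohort comes from the full-data decomposition; its
standard error from a seeded bootstrap over trajectories (decomposition
re-run per replicate, non-converged replicates dropped). The statistic is

    t = (f₁ − f₂) / √(SE₁² + SE₂²),

with a two-sided p-value from a t distribution with Welch–Satterthwaite
degrees of freedom based on the cohort sizes. Treating the n_boot bootstrap
replicates themselves as i.i.d. observations in a t test would shrink the
standard error by ≈ √(n_boot/2) and reject essentially always under the
null, so the bootstrap is used only to estimate the SE of each fraction.
Per-group bootstrap streams are keyed on the seed plus a checksum of the
group's data, so comparing a cohort against an exact copy of itself gives
t = 0 and p = 1 identically. An alternative per-trajectory test (Welch t on
the raw log-efficiencies) is deliberately not the default: it compares mean
efficiency, not mode occupancy.

## Trajectory generator

`simulate_trajectories` draws, per trajectory, an initial state (mobile with
probability `mobile_fraction`) and then steps of dt:

- stationary: isotropic Brownian displacement, variance 2·D_stationary·dt
  per axis;
- mobile: v·dt along a persistent unit direction plus Brownian jitter with
  D_mobile. The direction is re-drawn uniformly on the sphere at Poisson
  turn events (rate `turn_rate`) and on each entry into the mobile state.
  The run speed v is drawn once per trajectory from a lognormal with median
  `v_mobile` and CV `v_cv`: motor-driven cargo speeds genuinely vary between
  particles, and without this heterogeneity every mobile trajectory would
  have an almost identical mean efficiency — a delta spike no Gaussian mode
  can represent.

Optional two-state Markov switching (`switch_rate_to_mobile`,
`switch_rate_to_stationary`) is off by default, matching the
one-state-per-trajectory summary the efficiency statistic assumes.
Gaussian localization noise (`loc_noise_sd` per axis) is added to every
recorded position. Ground-truth per-point state labels are retained.

Defaults — D_stationary = 0.01 µm²/s (confined endosome), v_mobile = 1 µm/s
(motor transport), v_cv = 0.3, turn_rate = 0.1 s⁻¹, loc_noise_sd = 0.02 µm,
dt = 1 ms — put the stationary mode near log₁₀E ≈ −5.7 and the mobile mode
near −3.6 under a 10 s window, a clean two-decade separation. Note that at
millisecond sampling the localization noise dominates the instantaneous
steps (0.02 µm noise vs 0.001 µm directed step), which deflates all
efficiencies below their noise-free limits; the *separation* between the
classes, which is what the decomposition uses, is preserved. Default
cohort duration is 12 s (≥ one full window plus 2 000 sliding starts);
trajectory counts default to 200 and are set per experiment (the acceptance
checks use 300 for recovery and 120 per cohort for ordering, sizes at which
the fraction estimate stabilises to ±0.05).

## Scattering model and reduction

`simulate_scattering` builds I(q) = c·P(q;R) + A·exp(−(q−q₀)²/2σ²) +
b·q^(−m), with P the normalised sphere form factor
[3(sin x − x cos x)/x³]², x = qR. The default grid spans the instrument
range 0.06–4 nm⁻¹ (1000 points); the default core radius 15 nm keeps the
Guinier regime (q·R_g ≤ 1.3) inside that grid. Gaussian (relative) or
Poisson (counting) noise is applied last; a noiseless call is
deterministic.

`guinier_fit` fits ln I vs q² (σ-weighted when uncertainties are present)
over a self-consistently chosen range: an initial fit on the lowest 10% of
points gives a provisional R_g, the range is trimmed to q ≤ 1.3/R_g and
refit until the point set is stable. With noise the range can cycle between
two adjacent windows; a revisited window counts as converged and the
smaller one is kept. A non-decaying low-q slope is an error, not an R_g.
The q·R_g ≤ 1.3 convention for globular particles is adopted since no fit
range is prescribed by the assay itself.

`find_lamellar_peak` fits a power law to the outer 15% flanks of the search
window (default 0.5–1.5 nm⁻¹), subtracts it, takes the maximum of the
detrended signal (ties resolve to the lowest q, logged), refines the
position with a 3-point parabola for sub-grid precision, and reports
d = 2π/q_peak plus an interpolated FWHM. A maximum below the prominence
threshold, or sitting on a window edge, is a *no-peak* result (`None`), not
an error. Profile files with max q < 0.7 are assumed to be in Å⁻¹ and
converted (logged; explicit override available) — lamellar peaks of these
systems sit near 1 nm⁻¹ = 0.1 Å⁻¹, so the magnitude is unambiguous in
practice.

## Formulation QC

`encapsulation_efficiency` blank-corrects the mean unlysed (unencapsulated
mRNA) and detergent-lysed (total mRNA) fluorescence and applies
EE = (1 − unenc/total)·100; per-replicate EEs and their SD are reported when
the plate pairs wells by replicate. Negative blank-corrected signals are
floored at zero and EE is clamped to [0, 100], both flagged on the result;
a non-positive total is an error. EE is invariant to a global fluorescence
gain and to a common blank shift (tested as properties). No standard-curve
interpolation is applied: the ratio form needs none as long as the dye
response is linear over the plate's range.

`plan_formulation` converts an mRNA mass to phosphate moles with a mean
nucleotide mass of 330 g/mol (one phosphate per nucleotide), scales by the
N:P ratio assuming one protonatable amine per ionizable lipid (true for the
MC3/DODMA class; both constants overridable), distributes total lipid by
the molar ratios (default 50:38.5:10:1.5 ionizable:sterol:phospholipid:PEG),
and derives phase volumes from the lipid-mix concentration (default 5.5 mM)
and the 3:1 aqueous:organic ratio.

## Imaging quantification

Single-mRNA calibration is the median and MAD of electroporation-standard
spot intensities (≥ 20 required) — robust to the occasional doublet or
debris object. A FISH spot is counted as a cytosolic single molecule iff
its intensity lies within [0.25·unit, unit + k·1.4826·MAD], k = 3 by
default; brighter objects are entrapped clusters (multiple mRNA copies per
organelle) and are not decomposed into copy numbers, since the escape
metric needs only the cytosolic count. The 0.25·unit floor discards
sub-molecular debris. The gate is a pure intensity ratio, so a global
detector gain leaves classification unchanged. LNP counts are round(total
lnp-channel intensity / single-particle-on-glass intensity) per cell.

The endosomal-escape ratio is cytosolic mRNA count / LNP count per cell;
cells with zero internalized particles have an undefined ratio and are
excluded from the cohort mean and SD but counted in the result. Perinuclear
uptake is total tracer intensity divided by nuclei count; uptake-rate
curves are centered finite differences (one-sided at the ends) after an
optional 3-point moving average.

## Synthetic spot fields and plates

Spot fields default to 10 cytosolic mRNAs, 4 entrapped clusters (2–6 mRNAs
each) and 40 LNPs per cell (Poisson-distributed), lognormal intensity
spread CV 0.2 around a single-mRNA median of 100 AU, 300 standard objects
— an escape ratio of ~0.25, i.e. most delivered mRNA still entrapped, as is
typical for LNP delivery. Plates default to EE 94%, total signal 200 AU
over a 10 AU blank, 3 replicates. With CV 0.2, ~1% of genuine singles
exceed the k = 3 gate and ~13% of 2-mRNA clusters fall below it; at the
default cluster-size mix this biases cytosolic counts by well under the 10%
recovery tolerance.

## What the generators do and do not emulate

The generators reproduce the *data products* of the instruments — position
time series, 1D reduced profiles, object tables, plate reads — with known
ground truth, which is exactly what the analysis stages consume. They do
not emulate photon statistics or the real-time tracking control loop, pixel
images or segmentation errors (objects arrive pre-detected), detector
geometry or absolute intensity calibration, inter-plate drift, or cell
biology (states are a Markov caricature; real cargo switches, pauses, and
experiences crowding). Passing tests therefore validate the estimators'
correctness and calibration under the stated generative models, not their
robustness to segmentation artefacts or instrument systematics.

## Reproducibility

All randomness flows from one integer seed through named substreams
(`_utils.substream`); no global RNG state is touched. Pipeline reports
embed the seed and a config hash. Problem sizes used by the acceptance
checks: 60–120 s single trajectories at 1 ms for the limit cases, 20 seeds
× 300 trajectories for fraction recovery, 20 null runs and one 156/286
power run for the comparison test, 20 seeds × 2 × 120 trajectories for the
cohort-ordering check.

## Known limitations

- The two-Gaussian area model is only as meaningful as the bimodality of
  the input; overlapping modes yield fractions with large bootstrap SEs
  (reported, not hidden).
- Guinier fitting assumes a dilute, globular, monodisperse scatterer;
  structure factors or aggregation at low q will bias R_g.
- The lamellar detrending assumes a locally power-law background within
  the search window; a steep form-factor oscillation inside the window can
  shift weak peaks.
- `compare_groups` is a two-cohort test by design; multi-formulation
  screens should run pairwise comparisons with their own multiplicity
  control.
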