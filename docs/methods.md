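# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the analysis recipe is genuinely
open. Problem sizes quoted for the validation experiments are the ones
the test suite and `scripts/acceptance.py` actually run.

## Cardiac signal processing

**Beat detection.** Pulse arrival produces a fast rise in the
photoplethysmographic waveform, so beats are located on the first
derivative of the pulse signal. The signal is first band-limited with a
zero-phase 4th-order low-pass at 8 Hz (the upstroke's energy lies well
below this; broadband sensor noise otherwise dominates the derivative).
The fiducial is the derivative maximum within each upstroke; a candidate
counts when it exceeds an adaptive threshold of 0.4 × the rolling
10-second derivative maximum (robust to slow amplitude drift), and a
300 ms refractory period enforces at most one beat per plausible cardiac
cycle.

**Interval cleaning.** Automated artifact handling stands in for manual
inspection of the detections, and is documented as such — its defaults
are a pragmatic stand-in, not a reconstruction of any expert criterion.
An interval is invalid when outside 300–2000 ms or when deviating more
than 30% from an 11-beat running median; invalid intervals are linearly
interpolated from their valid neighbors and flagged `corrected` so the
repairs are auditable. Beat times are rebuilt from the repaired
intervals to keep `intervals == diff(beat_times)` exact. A recording
with more than 20% invalid intervals raises (`unusable recording`); the
rule is applied only to recordings of at least 10 intervals, where a
fraction is meaningful. Cleaning is idempotent.

**Metrics.** HR is defined as 60000/mean(IBI), not the mean of
instantaneous rates — one convention, applied everywhere. SDNN uses the
n−1 denominator (sample statistic on a finite recording). RMSSD is the
root mean square of successive differences. At least 3 intervals are
required.

**Respiration.** Maxima are local peaks separated by ≥ 1.5 s with
prominence ≥ 10% of the signal range (guards against small superimposed
wiggles); one trough — the minimum between consecutive maxima — is kept
per breath so extrema alternate strictly. Breathing rate is the inverse
mean interval between maxima.

## Physiological-noise model and BOLD cleaning

The cleaning chain runs in a fixed order: volume discard (default 20),
nuisance regression, temporal band-pass, spatial smoothing.

**Respiratory phase** advances linearly from 0 at one inspiratory
maximum to 2π at the next (wrapped to (−π, π]). This simple-phase
construction was chosen over the amplitude-histogram variant because it
is deterministic, testable, and amplitude-invariant by construction;
phase is computed volume-wise (not slice-wise). Volumes outside the
recorded breath span get nearest-cycle phase with a warning. The Fourier
expansion uses order 2 — sin φ, cos φ, sin 2φ, cos 2φ, i.e. exactly four
respiratory regressors. Cardiac phase regressors are deliberately not
included; the noise model is respiratory.

**RVT** (respiration volume per time) is breath amplitude over breath
period: per maximum, the peak value minus the trough value interpolated
to the peak time, divided by the local peak-to-peak interval, then
linearly interpolated to volume times with constant extrapolation beyond
the first/last breath. Delayed copies at 0/5/10/15/20 s (edge-padded
with the first value) model the slow blood-oxygenation response to
breathing changes — five RVT columns in total.

**Regression** is ordinary least squares per voxel on an intercept,
Legendre-style linear and quadratic trends, and the supplied nuisance
columns (motion, CSF/WM, respiratory terms). Rank-deficient designs are
repaired by pivoted-QR column dropping with a warning naming the dropped
columns. Residuals are mean-zero and orthogonal to every retained column
to machine precision.

**Band-pass** is a 4th-order Butterworth, 0.01–0.1 Hz, applied
forward–backward (zero phase). A high corner at or above Nyquist is a
parameter error.

**Smoothing** is a per-volume 3-D Gaussian with σ = FWHM/(2√(2 ln 2))
per axis, scaled by the voxel size from the affine (default FWHM 6 mm);
FWHM 0 is the identity.

## Seed connectivity and group maps

Spheres include every voxel whose center lies within the radius
(inclusive boundary), with the NIfTI affine authoritative for the
voxel↔mm mapping (RAS+). On the 2.5 mm grid the 10 mm seed sphere holds
257 voxels and a 5 mm parcel sphere 33 — both checked against
brute-force lattice enumeration in the tests.

Seed maps correlate the seed-mean series against all voxels and apply
z = atanh(r). |r| at the boundary is clamped to 1 − 10⁻⁶ and flagged;
interior values pass through untouched, so atanh∘tanh is the identity to
10⁻⁹ on (−8, 8). Zero-variance voxels are flagged undefined (NaN).

Group tests: one-sample and paired designs use df = n − 1 (paired is
exactly the one-sample test on differences); two-sample uses pooled
variance with df = n₁ + n₂ − 2 (the classic neuroimaging convention;
Welch is not currently offered). Cluster inference thresholds the map at
two-sided voxel p (default 0.005), labels face-connected (6-neighbor)
clusters separately by sign, and builds the null of the maximum cluster
extent by permutation — sign flips of subject maps for one-sample and
paired designs, group-label shuffles for two-sample — with
p = (1 + #{null ≥ observed})/(1 + n_perm). Because the published
analysis is described both as FWE- and FDR-corrected at cluster level,
the permutation FWE p is the default and a Benjamini–Hochberg adjustment
over cluster p values is available via `correction="fdr"`; neither is
asserted to be what the original analysis ran.

## Sliding-window coupling

Windows are defined in volumes — length 90, step 45 (50% overlap); at
TR = 0.484 s that is 43.56 s per window, nominally "45 s". The number of
windows is ⌊(n_volumes − length)/step⌋ + 1 (40 for 1880 retained
volumes, 26 for 1230). An interval belongs to a window when its later
beat falls inside the window's time span; windows with fewer than 10
intervals are flagged missing. Windowed seed maps use each window's
samples only, rectangular (no taper). The subject-level coupling map is
the per-voxel OLS slope of windowed z on the windowed SDNN z-scored over
usable windows — so slopes are in z per SD of SDNN and comparable across
subjects (whether to normalize the regressor was open; standardization
is the documented choice, and slopes are invariant to affine rescaling
of the raw SDNN). Windows missing on either side are dropped pairwise;
at least 8 usable windows are required. The group analysis is the
one-sample cluster-corrected test above.

## Connectomes and the network-based statistic

Parcels are 10 mm-diameter spheres on supplied center coordinates; a
loader warns when centers come closer than 10 mm (overlap). Edges are
pairwise Fisher-z correlations of the mean parcel series (≥ 30 time
points required); node pairs closer than 20 mm are invalidated because
short-range correlations are inflated by smoothing and reslicing, and
edges invalid in any subject are excluded from the whole analysis
(complete-case). Matrices are exactly symmetric (the correlation matrix
is symmetrized against floating-point rounding).

The NBS forms components from edges whose paired (or two-sample) t
exceeds the primary threshold — default t > 4.17, the value used for
paired T2-vs-T1 connectome contrasts; treated as a plain user parameter
since its provenance is not derivable. The default direction is
one-sided A > B (pass T2 as A to test for increases); two-sided and
reversed directions are available. The component statistic is extent in
edges (an intensity statistic is a possible extension; extent matches
how such networks are reported). The permutation null swaps conditions
within subjects independently (sign flips of the paired differences);
the familywise p uses the +1 correction so it is never exactly zero. For
n ≤ 20 pairs the null can be enumerated exhaustively over all 2ⁿ sign
patterns, in which case p = count/2ⁿ with the identity pattern included.
Given a seed, results are bit-reproducible.

## Synthetic data

The generators define the study conditions for all validation
experiments. Defaults mirror the baseline population of the kind of
cohort this pipeline targets: mean IBI 857 ms (HR ≈ 70 beats/min), SDNN
54.4 ms, breathing rate 16 breaths/min, TR 0.484 s, cohorts of 15
subjects. Every generator is a deterministic function of a `SimConfig`
(seed mandatory) and returns its ground truth for exact recovery
scoring.

- **IBI series**: mean + respiratory sinus arrhythmia (sinusoid at the
  breathing frequency, 25 ms), a slow 0.1 Hz oscillation (15 ms), and
  AR(1) noise (15 ms, φ = 0.4); the zero-mean part is rescaled uniformly
  so the sample SDNN equals the target exactly.
- **Pulse waveform**: an asymmetric template (80 ms raised-cosine
  upstroke, 120 ms exponential decay) placed so the maximum-derivative
  instant lands on each beat time to within one sample.
- **Respiration**: a sinusoid with slow frequency drift (±5%) and
  band-limited amplitude jitter (±10%).
- **Coupled BOLD**: node 0 carries a latent band-limited (0.01–0.1 Hz)
  seed signal s(t); coupled nodes follow (a + κ·S̃(t))·s(t) + noise,
  where S̃ is the standardized windowed-SDNN envelope interpolated to
  volume times. Amplitude modulation is the simplest mechanism whose
  window-wise correlation tracks SDNN; it is a modeling device, not a
  physiological claim. All node noise is band-limited, so the cleaned
  band is where everything lives.
- **Paired connectomes**: session matrix = shared baseline + subject
  random effect (common to T1/T2) + independent session edge noise
  (SD 0.1); T2 adds a shift on the planted effect edges. The effect size
  d is standardized against the within-pair difference SD (√2 × session
  noise SD) — the quantity that governs paired-test power. Planted
  effects are random trees (connected, acyclic), mirroring how a
  single connected subnetwork of m edges spans m + 1 nodes.
- **Coordinates**: a jittered 3-D lattice with 14 mm pitch and jitter
  bounded so no two centers come closer than 10 mm.

What the generators do **not** emulate: hemodynamic response shape,
scanner noise spectra (thermal/physiological 1/f), head motion, spatial
autocorrelation of real BOLD, and ECG morphology (the pulse template is
idealized). Passing validation therefore demonstrates the correctness
and calibration of the algorithms under the stated statistical model,
not performance on any particular scanner's data.

## Validation experiments

`neurocardiac.validation` runs four end-to-end experiments (sizes chosen
to be informative at single-CPU scale):

- **NBS null calibration**: 200 exchangeable paired cohorts (60 nodes,
  n = 15, 200 permutations); the familywise false-positive rate should
  sit near α = 0.05.
- **NBS planted recovery**: 20 cohorts with a 20-edge tree effect at
  d = 1.2, n = 15; recovery = planted edges inside the union of
  FWE-significant components.
- Both experiments form components at the one-sided p = 0.01 t-quantile
  (t(14) ≈ 2.62) rather than the strict connectome default 4.17. At a
  strict threshold the null suprathreshold graph is nearly empty and the
  max-extent statistic nearly degenerate; the permutation test still
  controls FWE but becomes conservative purely through discreteness
  (measured: FPR 0.022 at t = 4.17 vs 0.047 at t = 2.62 over 1000 null
  cohorts), and a d = 1.2 effect cannot survive a threshold demanding
  per-edge power at p ≈ 0.0005. A milder threshold keeps both the
  calibration and the recovery experiment informative about the
  statistic itself.
- **Dynamic coupling recovery**: 20 runs × 30 subjects × 1880 volumes
  (20 nodes, 4 coupled); κ = 0.6 should be detected (≥ half the coupled
  nodes in a significant cluster) in ≥ 90% of runs, and κ = 0 should
  trigger at the nominal false-positive rate.
- **Cleaning efficacy**: a 1880-volume toy volume with two voxels
  sharing an in-band 0.05 Hz signal (r = 0.6) and one voxel carrying a
  respiratory-phase-locked artifact; after regression + band-pass the
  artifact correlation collapses (|r| < 0.1) while the planted coupling
  changes by < 0.05.

## API shape

The fit-shaped stages are exposed as scikit-learn-style estimators —
`BOLDCleaner` (transform), `SeedCorrelation`, `SlidingWindowCoupling`
and `NetworkBasedStatistic` (fit, fitted attributes with a trailing
underscore, `get_params`/`set_params`) — so they compose with sklearn
tooling; signal detection, geometry helpers and the generators are plain
functions, which is their natural shape, and every pipeline operation is
also available as a module-level function.

## Known limitations

- Starts from registered/normalized images: realignment, skull
  stripping, and anatomical registration are out of scope (motion
  parameters are consumed as a TSV).
- No frequency-domain or nonlinear HRV, no ECG R-peak detection (the
  pulse path assumes a finger sensor).
- Cluster inference is permutation-based only; random-field-theory
  corrections are not provided.
- The artifact-repair defaults approximate, but cannot reproduce,
  expert visual inspection.
- Anatomical labeling of clusters/nodes (atlas lookup) is not included.
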