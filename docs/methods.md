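# Methods

This note documents the models, numerical choices and open design
decisions behind `voigtnmr`, and states precisely what the synthetic-data
experiments do and do not demonstrate.

## Lineshape

NMR resonances are Lorentzian in theory; shimming imperfection and field
inhomogeneity add a Gaussian broadening component. The exact Voigt profile
(Lorentzian ⊛ Gaussian) is expensive and its two width parameters are
poorly identifiable at metabolomics signal-to-noise, so the package fits the
standard pseudo-Voigt approximation: an η-weighted sum of an area-A
Lorentzian and an area-A Gaussian with one shared FWHM `w`,

    pv(x; A, μ, w, η) = η·A·(w/2)/(π((x−μ)² + (w/2)²))
                      + (1−η)·A·(2/w)·√(ln2/π)·exp(−4 ln2 (x−μ)²/w²).

Conventions that matter:

* **η is the Lorentzian fraction** (η = 1 pure Lorentzian, η = 0 pure
  Gaussian). The opposite convention exists in the literature; ours matches
  lmfit's `PseudoVoigtModel`, which a test uses as an independent
  cross-check of the fitter.
* **The amplitude parameter is total area, not height.** Peak integrals are
  the workflow's deliverable; height is derived
  (`h = A/w·(η·2/π + (1−η)·2√(ln2/π))`).
* The reported per-peak "area" is the analytic integral over
  μ ± k_width·FWHM (default k_width = 3: ≈ 96 % of a Gaussian but only
  ≈ 79 % of a Lorentzian — the heavy Lorentzian tail converges slowly and
  its far mass is statistically degenerate with the local baseline, so a
  truncated integral is both better-posed and closer to what a manual
  integration window measures). The untruncated A is also reported
  (`area_total`).

## Peak picking and the noise filter

Candidates are all interior local maxima (plateaus collapse to their
central point). Each candidate carries a *net intensity*: height minus the
higher of its two flanking minima, the minima being the lowest points
between the peak and the nearest higher point on each side (prominence
bases, via `scipy.signal.peak_prominences`). Anchoring at prominence bases
rather than the first adjacent dip is essential on noisy data — noise
ripple on the flank of a tall peak would otherwise truncate its net
intensity to a few σ and the filter would discard real peaks. Net intensity
is clipped to [0, height]; a maximum below zero carries net 0 and can never
pass a threshold.

The filter keeps candidates with net intensity ≥ k_noise·σ. Defaults:
k_noise = 5, matching the downstream S/N > 5 feature filter. σ comes from
either the standard deviation of a signal-free window (default
9.5–10.0 ppm, ≥ 50 points required) or, by default, the median absolute
deviation of first differences divided by √2·Φ⁻¹(3/4) ≈ √2·0.67449 —
robust to peaks, hence usable on the entire trace.

## Segmentation and the nonlinear fit

The axis is cut into independent windows wherever the trace stays within
3σ of a running-median baseline (window 301 points ≈ 0.075 ppm at the
default 2.5×10⁻⁴-ppm step) for ≥ 20 consecutive points. The median tracker
is deliberate: a lower-envelope (morphological opening) detrender sits
~2.5σ below the noise and never reports sub-3σ runs. Each window is padded
with 50 points (≈ 3 maximal FWHM) of baseline flank per side — enough to
pin the window's constant baseline offset, which is otherwise degenerate
with the Lorentzian tails of the peaks inside. Windows holding more than 30
candidates are split at their weakest internal minimum to keep the joint
fit conditioned.

Each window is fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`, `method="trf"`, analytic Jacobian,
`x_scale="jac"`, gtol 1e-10, ftol/xtol 1e-12, iteration budget 200 per
attempt) over per-peak (A, μ, w, η) plus one constant offset:

* initialization: μ₀ at the picked maximum; w₀ from the half-maximum
  crossings (fallback 4 axis steps); η₀ = 0.5; A₀ inverted from the height
  formula; offset₀ = window minimum;
* bounds: μ within ± max(w₀, 2 steps) of the pick; w ∈ [2 steps, window
  span]; η ∈ [0, 1]; A ∈ (0, 10 × window integral]; the offset may go
  below the trace minimum by a quarter of the window's dynamic range (the
  minimum of a window filled with Lorentzian tails overestimates the true
  baseline);
* one restart from 10 %-widened initial widths on non-convergence; the
  best attempt is returned flagged `converged=False` if both fail;
* standard errors from the Jacobian at the solution,
  se = √(diag((JᵀJ)⁻¹)·rss/(n−p)); peaks at the area or width bound are
  flagged.

The per-window constant offset is a deliberate extension of the per-peak
parameter set: residual baseline is precisely the variance source the
deconvolution approach exists to remove, and without a nuisance offset it
leaks into fitted areas. Everything is deterministic — fixed
initialization, no randomness anywhere in the fit path — so identical
inputs produce bit-identical outputs.

## Alignment, features, filters

Features are defined by the peaks of a reference spectrum (pointwise mean
by default, or a QC/median spectrum). Reference peaks are processed in
descending area; each claims, per sample, the nearest unclaimed peak within
the shift window (default 0.005 ppm — typical post-alignment residual
jitter), distance ties going to the larger area. Unmatched sample peaks
seed additional features by the same greedy rule (largest orphan first), so
novel signals survive alignment; chained clustering was rejected because it
can place members farther than one window from the feature center. Every
sample peak is used at most once. Features are then pruned by detection
frequency (≥ 30 % of samples, boundary inclusive) and median S/N (≥ 5).
Missing cells are zero-filled by default (a non-detected peak is below
noise); NaN filling is available for downstream imputation.

## Baseline methods and the standard-addition protocol

*Full spectra*: the preprocessed intensity matrix as is; a target's
response is its height at the nearest axis point. *Binning*: equidistant
0.01-ppm buckets per contiguous axis segment, trapezoidal AUC per bucket;
adjacent buckets share their boundary point so bucket AUCs sum exactly to
the segment integral. Counting convention: each axis point owns one
step-wide cell; a segment's trailing partial bucket is kept when its cells
span at least half a bucket and merged into its neighbor otherwise (on the
−1…10 ppm grid with the water region removed this yields 1085 buckets at
0.01 ppm and 543 at 0.02 ppm).

The standard-addition comparison spikes known amounts into several
biological backgrounds (default 5/10/15 µg into 4 backgrounds → 12
spectra). Because endogenous levels differ per background, a single pooled
curve over raw responses is not identifiable; each background's
extrapolated amount-0 response (per-background OLS intercept) is subtracted
first, then all points feed one pooled OLS curve. Reported error is the
mean over points of 100·|back-calculated − true|/true (%). Two protocol
choices worth stating:

* the deconvolution method's response is the **summed** integral of all
  features within the shift window of the target, not the single nearest
  feature: a pair overlapped by half a linewidth resolves into one or two
  picked peaks essentially at random from sample to sample, and while the
  split of the cluster area between sub-peaks is unstable, their sum is
  not — summing the cluster is what an analyst integrating the multiplet
  does;
* the discovery filters (frequency, S/N) are off in this targeted
  protocol, for the same reason: a rarely-resolved sub-peak must not be
  discarded in exactly the samples where it carries part of the target's
  area. PQN is also off by default here — across different backgrounds the
  quotient tracks total matrix concentration and would rescale the spike
  response per background, distorting the pooled curve.

## UV-scaled PCA

Columns are mean-centered and divided by their standard deviation (ddof 1);
constant columns are dropped with a warning. Scores/loadings come from the
SVD of the scaled matrix; explained variance per component is s²/(n−1) and
sums to the total variance. Sign convention: the largest-magnitude loading
of each component is positive, making outputs deterministic.

## The synthetic-data generator

All tests and scaled-down experiments run on simulated spectra:

    y = dilution · Σᵢ pv(x; Aᵢ, μᵢ + δᵢ, wᵢ, ηᵢ) + b·baseline(x) + ε,

with per-peak jitter δᵢ ~ N(0, sdᵢ), per-sample baseline scale b and
dilution drawn uniformly from configured ranges, and white Gaussian noise
ε. All draws come from `numpy.random.default_rng([seed, sample_index])` in
a fixed order (dilution, baseline scale, jitters, noise), so adding samples
never perturbs earlier ones and outputs are platform-stable. Peaks are
sorted canonically before jitter assignment, making the spectrum invariant
to the order of the configured peak list.

The default urine-like template holds ~30 peaks over 0.8–9.2 ppm with
FWHM 0.0018–0.004 ppm (≈ 1–2 Hz at 800 MHz), η 0.3–0.9, residual jitter
sd 5×10⁻⁴ ppm, including an isolated alanine-like doublet at 1.48 ppm
(J ≈ 7 Hz) and a strongly overlapped pair at 3.30 ppm separated by half a
linewidth. The baseline is a gentle quadratic (amplitude a few × noise).

The canned spiking scenario (`crowded_spike_scenario`) places the target at
3.3080 ppm in a crowded 2.8–3.8 ppm window with an overlapped neighbor half
a linewidth away. The target's position is generic relative to the 0.01-ppm
bin grid (2 mFWHM from a bucket edge), so shift jitter moves tail mass
across a bucket boundary the way it does for real resonances that do not
align with the grid; a mid-bucket placement would artificially immunize
binning against its best-known failure mode (peaks migrating between
buckets). Spike response is 0.02 area-units/µg, giving spiked-peak S/N
≈ 100; the baseline drifts by a per-sample factor U(0.5, 1.5); aliquots are
volumetrically exact (the protocol quantifies method error, not pipetting).
Endogenous matrix levels vary per background (lognormal, sd 0.25; target
endogenous level U(0.7, 1.3) × its template area).

**What passing these experiments shows — and what it does not.** The
simulations demonstrate that the implementation is correct under the stated
noise model and that the qualitative method ordering (deconvolution <
binning < full spectra in back-calculation error) is a robust consequence
of residual shift jitter, baseline drift and peak overlap. They do not
reproduce any instrument's absolute error levels: real urine adds J-coupled
multiplet structure, pH-dependent shifts, lineshape distortions and
alignment artifacts that the generator does not model, and the absolute RSE
percentages measured here are specific to the simulated conditions.

## Scale of the shipped experiments

The default experiment sizes are chosen so the whole test suite and the
acceptance script each complete in about half a minute on one CPU: spiking
replicates run on a 2.8–3.8 ppm window (4001 points, 11 peaks, 12 spectra,
25 replicates), the two-class recovery on a 0.8–2.0 ppm window with 8 + 8
samples, and the full −1…10 ppm grid (44,001 points) is exercised where the
printed matrix dimensions themselves are the quantity under test. All
functions accept the full-scale axis unchanged.

## Known limitations

* No multiplet/J-coupling model: every resonance line is fitted
  independently.
* No baseline-correction or segment-wise alignment algorithms: spectra are
  expected phased, baseline-corrected and aligned on entry;
  `global_shift_align` only removes a rigid per-sample offset.
* The exact-Voigt (complex error function) backend is not implemented; the
  pseudo-Voigt η-mixture is the only lineshape.
* The Bruker reader handles processed real-part 1D data (`1r` + `procs`)
  with a documented axis convention (endpoints OFFSET and OFFSET−SW_p/SF);
  raw FIDs, JCAMP-DX and 2D data are out of scope.
* Quantification of strongly overlapped clusters is reliable only at the
  cluster-sum level; individual sub-peak areas trade off within a cluster.
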