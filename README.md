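# voigtnmr

Untargeted processing of 1D ¹H-NMR metabolomics spectra by pseudo-Voigt
lineshape deconvolution — plus the two conventional processing baselines
(full-spectra analysis and equidistant binning) and a standard-addition
protocol for comparing their quantification error.

## Who this is for

NMR metabolomics of urine produces information-rich but messy spectra:
resonances overlap, peaks drift with pH and salt, and residual baseline adds
variance that is indistinguishable from biology in downstream multivariate
analysis. The two dominant untargeted processing strategies — using every
spectral point as a variable ("full spectra") or integrating fixed 0.01-ppm
buckets ("binning") — carry that positional and baseline noise straight into
PCA/PLS. `voigtnmr` implements the alternative: deconvolve each spectrum
into fitted lineshapes, keep only the peak integrals, and align them across
samples into a compact feature matrix. No spectral library or target list is
required.

## The model

Each spectrum is decomposed into pseudo-Voigt peaks. The pseudo-Voigt is the
η-weighted sum of a Lorentzian (the theoretical NMR lineshape) and a
Gaussian (field-inhomogeneity broadening) sharing one full width at half
maximum *w*, parameterized by total area *A*:

    pv(x; A, μ, w, η) = η·L(x; A, μ, w) + (1−η)·G(x; A, μ, w),  η ∈ [0, 1]

so ∫pv dx = A for every η. Per spectrum, the pipeline is

1. **peak picking** — all interior local maxima; each candidate's *net
   intensity* is its height above the higher of its two flanking minima
   (prominence), which separates real peaks from baseline ripple;
2. **noise filter** — discard candidates with net intensity < k·σ
   (default k = 5; σ estimated from first differences by a robust MAD
   estimator or from a signal-free region);
3. **segmentation** — split the axis into independent fit windows at
   stretches that stay within 3σ of a running-median baseline;
4. **bounded trust-region least squares** — fit each window as a sum of
   pseudo-Voigt peaks (free A, μ, w, η per peak, plus a constant nuisance
   offset per window) with `scipy.optimize.least_squares(method="trf")`,
   with parameter standard errors from the Jacobian at the solution;
5. **integration** — report each peak's analytic integral over
   μ ± k_width·w (default ±3 FWHM);
6. **alignment & filtering** — match integrals across samples to the peaks
   of a reference (mean/QC) spectrum within a shift window (default
   0.005 ppm), then keep features detected in ≥ 30 % of samples with
   median S/N ≥ 5.

The result is a samples × features matrix of peak integrals, ready for
UV-scaled PCA (`pca_uv`) or any multivariate method.

## Worked example

```python
import voigtnmr as v

# simulate a 10-sample urine-like dataset with known ground truth
cfg = v.urine_config(n_samples=10, seed=0)
sset, truth = v.simulate_dataset(cfg)

# run the deconvolution workflow
sset = v.remove_region(sset, 4.70, 4.85)          # drop residual water
dec = v.deconvolve_dataset(sset)                  # fit + align + filter
print(dec.feature_matrix.values.shape)
print(dec.feature_matrix.to_dataframe().iloc[:2, :3].round(4))
```

prints

```
(10, 37)
      0.920222  1.179860  1.475363
S000    0.1073    0.1520    0.2309
S001    0.1239    0.1755    0.2666
```

— 37 aligned features survived the frequency and S/N filters (the ~30
template peaks plus a few noise-split sub-peaks); the columns are named by
the reference peak centers (ppm) and the entries are per-sample peak
integrals (a.u.·ppm), which track each sample's dilution factor (S001 was
drawn ~15 % more concentrated than S000).

The same workflows are available from the shell:

```bash
voigtnmr simulate --out data/ --seed 0
voigtnmr fit      --input data/spectra.csv --out run/        # features + fit report + plots
voigtnmr bin      --input data/spectra.csv --width 0.01 --out binned.csv
voigtnmr evaluate --input spiked.csv --design design.csv --target caffeine=3.308 --out report.json
voigtnmr pca      --input run/features.csv --out pca/
```

Every run writes a `manifest.json` (config hash, input hashes, versions) so
results can be reproduced exactly; rerunning `fit` on the same input gives a
byte-identical feature matrix.

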