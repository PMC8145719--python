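"""Synthetic urine-like 1D NMR spectra with known ground truth.

Every test and scaled-down experiment in this package runs on simulated
spectra: sums of pseudo-Voigt peaks with per-sample chemical-shift jitter,
a gentle polynomial baseline (optionally drifting in amplitude between
samples), multiplicative dilution, and additive Gaussian noise. The
generator always returns the ground-truth peak tables alongside the data,
and all randomness flows from one root seed through per-sample substreams
(``default_rng([seed, sample_index])``), so changing the number of samples
never perturbs earlier samples and identical seeds give bit-identical data
on any platform.

What this emulates — and what it does not: peak overlap, baseline offsets,
positional jitter, dilution and thermal noise are represented; J-coupled
multiplet structure, pH-dependent shifts and real lineshape distortions are
not. Passing tests therefore demonstrate correctness of the algorithms
under the stated noise model, not instrument-grade performance on real
urine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_spectra import SpectraSet, Spectrum1D
from .peakfit import _pv_unchecked, pseudo_voigt_height

__all__ = [
    "PeakSpec",
    "SimConfig",
    "make_axis",
    "gentle_baseline",
    "urine_template",
    "urine_config",
    "crowded_spike_scenario",
    "two_class_scenario",
    "simulate_spectrum",
    "simulate_dataset",
    "simulate_spike_design",
    "simulate_two_class",
]


@dataclass
class PeakSpec:
    """Ground-truth counterpart of a fitted peak. ``area`` 0 is allowed and
    means the peak is absent (used for spike targets with no endogenous
    signal)."""

    center: float
    area: float
    fwhm: float
    eta: float
    shift_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if self.shift_jitter_sd < 0:
            raise ValueError("shift_jitter_sd must be >= 0")


@dataclass
class SimConfig:
    """Synthetic-dataset description.

    axis: (lo, hi, step) in ppm — default mirrors a urine acquisition
    digitized at 2.5e-4 ppm from -1 to 10 ppm. baseline: polynomial
    coefficients, ascending powers (a.u. per ppm^k). dilution_range and
    baseline_scale_range are per-sample multiplicative draws (uniform);
    (1, 1) disables the effect.
    """

    axis: tuple[float, float, float] = (-1.0, 10.0, 2.5e-4)
    peaks: list[PeakSpec] = field(default_factory=lambda: urine_template())
    baseline: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.0
    dilution_range: tuple[float, float] = (1.0, 1.0)
    baseline_scale_range: tuple[float, float] = (1.0, 1.0)
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.axis[2] > 0:
            raise ValueError("axis step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.dilution_range[0] > 0 and self.dilution_range[1] > 0):
            raise ValueError("dilution bounds must be positive")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")


def make_axis(lo: float, hi: float, step: float) -> np.ndarray:
    """Ascending ppm grid lo, lo+step, ..., hi (endpoint included)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def gentle_baseline(axis: tuple[float, float, float], amplitude: float) -> tuple[float, ...]:
    """Quadratic baseline coefficients: non-negative over the axis, zero at
    both ends, peaking at ``amplitude`` mid-axis."""
    lo, hi, _ = axis
    m, h = 0.5 * (lo + hi), 0.5 * (hi - lo)
    a = amplitude
    return (a * (1 - m * m / (h * h)), 2 * a * m / (h * h), -a / (h * h))


def urine_template() -> list[PeakSpec]:
    """~30 peaks over 0.8-9.2 ppm emulating the difficulty regimes of a
    urine spectrum: an isolated alanine-like doublet at 1.48 ppm (J ~ 7 Hz
    at 800 MHz), a caffeine-like strongly overlapped pair at 3.3 ppm
    (separation 0.5 FWHM), crowded mid-field signals, and sparse aromatic
    peaks downfield."""
    j = 5e-4  # residual post-alignment jitter sd, ppm
    specs = [
        # aliphatic
        (0.92, 0.10, 0.0022, 0.6), (1.18, 0.14, 0.0020, 0.5),
        # alanine-like doublet (isolated, easy to integrate)
        (1.4755, 0.22, 0.0018, 0.8), (1.4845, 0.22, 0.0018, 0.8),
        (1.92, 0.30, 0.0025, 0.7), (2.14, 0.12, 0.0021, 0.4),
        (2.41, 0.16, 0.0024, 0.6), (2.55, 0.08, 0.0019, 0.5),
        (2.72, 0.11, 0.0023, 0.7), (2.93, 0.09, 0.0020, 0.3),
        # crowded carbohydrate region, incl. overlapped caffeine-like pair
        (3.05, 0.20, 0.0022, 0.6), (3.12, 0.13, 0.0024, 0.5),
        (3.19, 0.18, 0.0021, 0.6), (3.27, 0.15, 0.0023, 0.7),
        (3.3000, 0.14, 0.0020, 0.6), (3.3010, 0.17, 0.0020, 0.6),  # sep 0.5 FWHM
        (3.42, 0.19, 0.0026, 0.5), (3.55, 0.23, 0.0028, 0.6),
        (3.64, 0.12, 0.0024, 0.4), (3.72, 0.16, 0.0030, 0.7),
        (3.89, 0.10, 0.0026, 0.5), (4.05, 0.13, 0.0028, 0.6),
        (4.32, 0.08, 0.0024, 0.5),
        # mid/downfield
        (5.23, 0.06, 0.0030, 0.6), (6.52, 0.05, 0.0032, 0.5),
        (7.18, 0.09, 0.0034, 0.7), (7.54, 0.11, 0.0036, 0.8),
        (7.83, 0.07, 0.0035, 0.6), (8.46, 0.12, 0.0038, 0.9),
        (9.12, 0.04, 0.0040, 0.5),
    ]
    return [PeakSpec(c, a, w, e, shift_jitter_sd=j) for c, a, w, e in specs]


def urine_config(n_samples: int = 10, seed: int = 0, noise_sd: float = 0.05,
                 axis: tuple[float, float, float] = (-1.0, 10.0, 2.5e-4)) -> SimConfig:
    """Urine-like dataset defaults: full template, gentle quadratic baseline
    (3x noise amplitude), mild dilution spread."""
    return SimConfig(
        axis=axis,
        peaks=urine_template(),
        baseline=gentle_baseline(axis, 3.0 * noise_sd),
        noise_sd=noise_sd,
        dilution_range=(0.7, 1.4),
        n_samples=n_samples,
        seed=seed,
    )


def _canonical(peaks: list[PeakSpec]) -> list[PeakSpec]:
    # jitter draws are assigned to peaks in canonical order, so permuting the
    # config's peak list cannot change the simulated spectrum
    return sorted(peaks, key=lambda p: (p.center, p.area, p.fwhm, p.eta, p.shift_jitter_sd))


def simulate_spectrum(cfg: SimConfig, sample_index: int) -> tuple[Spectrum1D, pd.DataFrame]:
    """One spectrum plus its ground-truth peak table.

    intensity = dilution * sum of jittered pseudo-Voigt peaks
                + baseline_scale * polynomial baseline + Gaussian noise,
    with jitter ~ N(0, shift_jitter_sd) per peak and all draws taken from
    the substream ``default_rng([cfg.seed, sample_index])`` in a fixed
    order (dilution, baseline scale, jitters, noise).
    """
    lo, hi, step = cfg.axis
    x = make_axis(lo, hi, step)
    rng = np.random.default_rng([int(cfg.seed), int(sample_index)])
    dilution = float(rng.uniform(*cfg.dilution_range))
    bscale = float(rng.uniform(*cfg.baseline_scale_range))
    peaks = _canonical(cfg.peaks)
    jit_sd = np.array([p.shift_jitter_sd for p in peaks])
    jitter = rng.normal(0.0, 1.0, size=len(peaks)) * jit_sd
    y = np.zeros_like(x)
    rows = []
    for p, dj in zip(peaks, jitter):
        c = p.center + float(dj)
        if p.area > 0:
            y += _pv_unchecked(x, p.area, c, p.fwhm, p.eta)
        h = dilution * (pseudo_voigt_height(p.area, p.fwhm, p.eta) if p.area > 0 else 0.0)
        rows.append(
            {
                "center_spec": p.center,
                "center_true": c,
                "area_true": dilution * p.area,
                "fwhm": p.fwhm,
                "eta": p.eta,
                "height_true": h,
                "snr_true": h / cfg.noise_sd if cfg.noise_sd > 0 else np.inf,
            }
        )
    y *= dilution
    if any(c != 0.0 for c in cfg.baseline):
        y = y + bscale * np.polynomial.polynomial.polyval(x, cfg.baseline)
    noise = rng.normal(0.0, cfg.noise_sd, size=x.size) if cfg.noise_sd > 0 else 0.0
    y = y + noise
    truth = pd.DataFrame(rows)
    truth.attrs["dilution"] = dilution
    truth.attrs["baseline_scale"] = bscale
    return Spectrum1D(x, y, id=f"S{sample_index:03d}"), truth


def simulate_dataset(cfg: SimConfig) -> tuple[SpectraSet, dict]:
    """n_samples spectra with independent per-sample draws.

    Returns the SpectraSet and a truth dict with per-sample peak tables and
    the drawn dilution/baseline factors.
    """
    if cfg.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    specs, tables = [], {}
    for i in range(cfg.n_samples):
        sp, truth = simulate_spectrum(cfg, i)
        specs.append(sp)
        tables[sp.id] = truth
    sset = SpectraSet(
        specs[0].ppm,
        np.vstack([sp.intensity for sp in specs]),
        [sp.id for sp in specs],
    )
    truth_info = {
        "per_sample": tables,
        "dilution": np.array([tables[sid].attrs["dilution"] for sid in sset.sample_ids]),
        "baseline_scale": np.array([tables[sid].attrs["baseline_scale"] for sid in sset.sample_ids]),
    }
    return sset, truth_info


def simulate_spike_design(
    base_cfg: SimConfig,
    target: PeakSpec,
    amounts: tuple[float, ...] = (5.0, 10.0, 15.0),
    response_per_ug: float = 1.0,
    n_backgrounds: int = 4,
    endo_scale_range: tuple[float, float] = (0.7, 1.3),
    matrix_scale_sd: float = 0.25,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Standard-addition design: ``n_backgrounds`` randomized biological
    backgrounds, each spiked at every amount (default 5/10/15 ug in 4
    backgrounds -> 12 spectra).

    Per background, all matrix-peak areas are rescaled (lognormal,
    ``matrix_scale_sd``) and the target's endogenous area is
    ``target.area`` times a uniform draw from ``endo_scale_range``; each
    spiked spectrum then carries target area = endogenous +
    amount * response_per_ug. The returned design table records the truth.
    """
    if len(amounts) == 0 or any(a <= 0 for a in amounts):
        raise ValueError("amounts must be non-empty and positive")
    specs, rows = [], []
    for b in range(n_backgrounds):
        rng_b = np.random.default_rng([int(base_cfg.seed), 10_000 + b])
        scales = rng_b.lognormal(0.0, matrix_scale_sd, size=len(base_cfg.peaks))
        endo = target.area * float(rng_b.uniform(*endo_scale_range))
        bg_peaks = [replace(p, area=p.area * s) for p, s in zip(base_cfg.peaks, scales)]
        for j, amount in enumerate(amounts):
            total = endo + amount * response_per_ug
            cfg_i = replace(base_cfg, peaks=bg_peaks + [replace(target, area=total)], n_samples=1)
            sp, _ = simulate_spectrum(cfg_i, 20_000 + 100 * b + j)
            sid = f"bg{b}_amt{amount:g}"
            sp.id = sid
            specs.append(sp)
            rows.append(
                {
                    "sample_id": sid,
                    "background": b,
                    "amount": float(amount),
                    "endo_area": endo,
                    "true_area": total,
                }
            )
    sset = SpectraSet(
        specs[0].ppm,
        np.vstack([sp.intensity for sp in specs]),
        [sp.id for sp in specs],
    )
    return sset, pd.DataFrame(rows)


def simulate_two_class(
    cfg: SimConfig,
    effect_peaks: list[tuple[int, float]],
    n_per_class: tuple[int, int],
) -> tuple[SpectraSet, pd.DataFrame]:
    """Two labeled classes; class B multiplies the listed peak areas (by
    index into ``cfg.peaks``) by their fold-change. Returns the labeled set
    and the ground-truth effect table."""
    if any(fold <= 0 for _, fold in effect_peaks):
        raise ValueError("fold-changes must be positive")
    n_a, n_b = n_per_class
    peaks_b = list(cfg.peaks)
    for idx, fold in effect_peaks:
        peaks_b[idx] = replace(peaks_b[idx], area=peaks_b[idx].area * fold)
    specs, labels = [], []
    for i in range(n_a):
        sp, _ = simulate_spectrum(cfg, i)
        specs.append(sp)
        labels.append("A")
    cfg_b = replace(cfg, peaks=peaks_b)
    for i in range(n_b):
        sp, _ = simulate_spectrum(cfg_b, n_a + i)
        specs.append(sp)
        labels.append("B")
    sset = SpectraSet(
        specs[0].ppm,
        np.vstack([sp.intensity for sp in specs]),
        [sp.id for sp in specs],
        labels=labels,
    )
    effect = pd.DataFrame(
        {
            "peak_index": [i for i, _ in effect_peaks],
            "center": [cfg.peaks[i].center for i, _ in effect_peaks],
            "fold_change": [f for _, f in effect_peaks],
        }
    )
    return sset, effect


# ---------------------------------------------------------------------------
# canned scenarios for the scaled-down experiments
# ---------------------------------------------------------------------------

def crowded_spike_scenario(seed: int = 0, noise_sd: float = 0.3) -> tuple[SimConfig, PeakSpec]:
    """Spiking scenario in a crowded region (caffeine-like target).

    A 2.8-3.8 ppm window holding 10 matrix peaks, one of which sits 0.5 FWHM
    from the spike target (3.3080 ppm — a generic position relative to the
    0.01-ppm bin grid, so shift jitter moves tail mass across a bin edge
    exactly as it does for real resonances that do not align with the
    grid). Degradations are residual jitter (sd 5e-4 ppm) and a quadratic
    baseline of amplitude 4x noise drifting by a per-sample factor
    U(0.5, 1.5); aliquots are assumed volumetrically exact. With response
    0.02 area/ug, spike heights give S/N ~ 100.
    """
    axis = (2.8, 3.8, 2.5e-4)
    j = 5e-4
    matrix = [
        (2.86, 0.12, 0.0022, 0.5), (2.95, 0.09, 0.0020, 0.4),
        (3.05, 0.20, 0.0022, 0.6), (3.12, 0.13, 0.0024, 0.5),
        (3.19, 0.18, 0.0021, 0.6),
        (3.3090, 0.15, 0.0020, 0.6),   # overlapped neighbor, 0.5 FWHM away
        (3.42, 0.19, 0.0026, 0.5), (3.55, 0.23, 0.0028, 0.6),
        (3.64, 0.12, 0.0024, 0.4), (3.72, 0.16, 0.0030, 0.7),
    ]
    cfg = SimConfig(
        axis=axis,
        peaks=[PeakSpec(c, a, w, e, shift_jitter_sd=j) for c, a, w, e in matrix],
        baseline=gentle_baseline(axis, 4.0 * noise_sd),
        noise_sd=noise_sd,
        baseline_scale_range=(0.5, 1.5),
        seed=seed,
    )
    target = PeakSpec(center=3.3080, area=0.12, fwhm=0.0020, eta=0.6, shift_jitter_sd=j)
    return cfg, target


def two_class_scenario(seed: int = 0) -> tuple[SimConfig, int]:
    """Small two-class scenario: 0.8-2.0 ppm window with an alanine-like
    doublet and an isolated marker peak at 1.20 ppm (returned index) whose
    area is fold-changed in class B."""
    axis = (0.8, 2.0, 2.5e-4)
    j = 3e-4
    noise_sd = 0.1
    peaks = [
        PeakSpec(0.92, 0.10, 0.0022, 0.6, j),
        PeakSpec(1.05, 0.14, 0.0020, 0.5, j),
        PeakSpec(1.20, 0.15, 0.0020, 0.6, j),   # marker
        PeakSpec(1.33, 0.12, 0.0022, 0.5, j),
        PeakSpec(1.4755, 0.22, 0.0018, 0.8, j),
        PeakSpec(1.4845, 0.22, 0.0018, 0.8, j),
        PeakSpec(1.62, 0.16, 0.0024, 0.6, j),
        PeakSpec(1.85, 0.09, 0.0026, 0.5, j),
    ]
    cfg = SimConfig(
        axis=axis,
        peaks=peaks,
        baseline=gentle_baseline(axis, 2.0 * noise_sd),
        noise_sd=noise_sd,
        dilution_range=(1.0, 1.0),
        baseline_scale_range=(0.8, 1.2),
        seed=seed,
    )
    return cfg, 2
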