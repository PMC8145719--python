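"""Pre-fitting spectral preparation: region removal, dilution normalization,
reference construction, and a rigid global-shift alignment convenience.

The workflow consumes spectra that are already phased, baseline-corrected
and (ideally) peak-aligned; segment-wise alignment algorithms such as RSPA
are deliberately out of scope. ``global_shift_align`` only corrects a rigid
per-sample offset and is not a substitute for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_spectra import SpectraSet, Spectrum1D

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "remove_region",
    "pqn_normalize",
    "mean_reference",
    "median_reference",
    "global_shift_align",
]

#: tolerance used when matching interval bounds against grid values, as a
#: fraction of the axis step; protects inclusive bounds from float rounding
_EDGE_TOL_FRAC = 1e-6


@dataclass
class PreprocessConfig:
    """Settings for the preparation stage.

    water_lo/water_hi bound the residual-water region removed before any
    analysis (default 4.70-4.85 ppm). ``pqn_reference`` selects the spectrum
    that dilution quotients are computed against. ``global_shift_max`` is the
    largest rigid shift (ppm) the convenience aligner may apply; 0 disables it.
    """

    water_lo: float = 4.70
    water_hi: float = 4.85
    pqn_enabled: bool = True
    pqn_reference: str = "median_spectrum"  # median_spectrum | mean_spectrum | provided
    global_shift_max: float = 0.0

    def __post_init__(self) -> None:
        if not self.water_lo < self.water_hi:
            raise ValueError("water_lo must be < water_hi")
        if self.global_shift_max < 0:
            raise ValueError("global_shift_max must be >= 0")


def remove_region(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Drop all axis points with lo <= ppm <= hi (inclusive both ends).

    Bounds landing exactly on grid points are removed too (a small
    step-relative tolerance absorbs float rounding of the grid). An interval
    disjoint from the axis is a warned no-op.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    tol = abs(s.step) * _EDGE_TOL_FRAC
    keep = ~((s.ppm >= lo - tol) & (s.ppm <= hi + tol))
    if keep.all():
        logger.warning("remove_region: [%g, %g] does not overlap the axis; no-op", lo, hi)
        return SpectraSet(s.ppm.copy(), s.intensities.copy(), list(s.sample_ids), s.labels)
    return SpectraSet(s.ppm[keep], s.intensities[:, keep], list(s.sample_ids), s.labels)


def _diff_mad_sigma(y: np.ndarray) -> float:
    d = np.diff(y)
    return float(np.median(np.abs(d - np.median(d))) / (np.sqrt(2.0) * 0.67449))


def pqn_normalize(
    s: SpectraSet,
    reference: Spectrum1D,
    noise_floor_k: float = 5.0,
) -> tuple[SpectraSet, np.ndarray]:
    """Probabilistic quotient normalization against ``reference``.

    Each sample is divided by the median of pointwise quotients
    sample/reference, the quotients being evaluated only where the reference
    exceeds ``noise_floor_k`` times its own noise level (quotients at noise
    points are unstable). Returns the normalized set and the per-sample
    dilution factors.
    """
    if reference.n_points != s.n_points or not np.allclose(reference.ppm, s.ppm):
        raise ValueError("reference must share the axis of the SpectraSet")
    if not np.sum(reference.intensity) > 0:
        raise ValueError("reference must have positive total intensity")
    sigma = _diff_mad_sigma(reference.intensity)
    mask = reference.intensity > noise_floor_k * sigma
    if mask.sum() < 10:  # degenerate noise estimate; fall back to positive points
        mask = reference.intensity > 0
    factors = np.empty(s.n_samples)
    out = np.empty_like(s.intensities)
    for i in range(s.n_samples):
        y = s.intensities[i]
        if not np.any(y != 0):
            raise ValueError(f"pqn_normalize: sample {s.sample_ids[i]!r} is all zero")
        factors[i] = float(np.median(y[mask] / reference.intensity[mask]))
        out[i] = y / factors[i]
    return SpectraSet(s.ppm.copy(), out, list(s.sample_ids), s.labels), factors


def mean_reference(s: SpectraSet) -> Spectrum1D:
    """Pointwise arithmetic mean across samples (id ``"mean"``)."""
    if s.n_samples < 1:
        raise ValueError("empty SpectraSet")
    return Spectrum1D(s.ppm.copy(), s.intensities.mean(axis=0), id="mean")


def median_reference(s: SpectraSet) -> Spectrum1D:
    """Pointwise median across samples (id ``"median"``)."""
    if s.n_samples < 1:
        raise ValueError("empty SpectraSet")
    return Spectrum1D(s.ppm.copy(), np.median(s.intensities, axis=0), id="median")


def _best_integer_shift(y: np.ndarray, ref: np.ndarray, max_pts: int) -> int:
    """Integer shift k (apply y -> y shifted right by k) maximizing
    correlation with ref; ties break toward the smaller |k|, then negative."""
    best_k, best_c = 0, -np.inf
    for k in sorted(range(-max_pts, max_pts + 1), key=lambda k: (abs(k), k)):
        if k >= 0:
            c = float(np.dot(ref[k:], y[: y.size - k]))
        else:
            c = float(np.dot(ref[: y.size + k], y[-k:]))
        if c > best_c:
            best_c, best_k = c, k
    return best_k


def _shift_with_edge_pad(y: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return y.copy()
    out = np.empty_like(y)
    if k > 0:
        out[k:] = y[:-k]
        out[:k] = y[0]
    else:
        out[:k] = y[-k:]
        out[k:] = y[-1]
    return out


def global_shift_align(s: SpectraSet, reference: Spectrum1D, max_shift: float) -> SpectraSet:
    """Rigidly shift each spectrum by the integer-point offset (|offset| <=
    max_shift) maximizing cross-correlation with the reference; edges are
    padded with the edge value. ``max_shift`` 0 is the identity."""
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    step = s.step
    max_pts = int(np.floor(max_shift / step + 1e-9)) if step > 0 else 0
    if max_pts == 0:
        return SpectraSet(s.ppm.copy(), s.intensities.copy(), list(s.sample_ids), s.labels)
    out = np.empty_like(s.intensities)
    for i in range(s.n_samples):
        k = _best_integer_shift(s.intensities[i], reference.intensity, max_pts)
        out[i] = _shift_with_edge_pad(s.intensities[i], k)
    return SpectraSet(s.ppm.copy(), out, list(s.sample_ids), s.labels)
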