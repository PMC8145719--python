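"""From per-spectrum peak tables to one reference-aligned feature matrix.

Even after spectral alignment, the fitted centers of one metabolite peak
scatter by a fraction of a linewidth across samples. Features are therefore
defined by the peaks of a *reference* spectrum (mean or QC), and every
sample's peak table is matched against them inside a user-defined shift
window. Features are then pruned by detection frequency (default: present
in at least 30% of samples) and by median S/N (default > 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakFeature",
    "FeatureMatrix",
    "align_to_reference",
    "frequency_filter",
    "snr_filter",
    "assemble_feature_matrix",
]


@dataclass
class PeakFeature:
    """One aligned feature: a reference center plus per-sample matched areas."""

    ref_center: float
    per_sample_area: dict[str, float] = field(default_factory=dict)
    per_sample_snr: dict[str, float] = field(default_factory=dict)
    per_sample_fwhm: dict[str, float] = field(default_factory=dict)
    frequency: float = 0.0
    median_snr: float = 0.0

    @property
    def mean_fwhm(self) -> float:
        vals = list(self.per_sample_fwhm.values())
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class FeatureMatrix:
    """Samples x features matrix of peak areas (features sorted by center)."""

    sample_ids: list[str]
    features: list[PeakFeature]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.features)):
            raise ValueError("values shape does not match sample_ids x features")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{f.ref_center:.6f}" for f in self.features]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


def _claim_nearest(
    center: float,
    window: float,
    table: pd.DataFrame,
    claimed: set[int],
) -> int | None:
    """Index (into table) of the nearest unclaimed peak within window of
    center; distance ties break toward the larger area."""
    best = None
    for i in range(len(table)):
        if i in claimed:
            continue
        d = abs(float(table["center"].iat[i]) - center)
        if d > window:
            continue
        key = (d, -float(table["area"].iat[i]))
        if best is None or key < best[0]:
            best = (key, i)
    return None if best is None else best[1]


def align_to_reference(
    tables: dict[str, pd.DataFrame],
    ref_table: pd.DataFrame,
    window: float,
) -> list[PeakFeature]:
    """Match every sample's peaks to the reference peaks.

    Reference peaks are processed in descending reference area; for each,
    every sample contributes at most its nearest unclaimed peak within
    ``window`` (distance ties break toward the larger area). Sample peaks
    matching no reference peak seed additional features by the same greedy
    claiming rule (largest-area orphan first), so genuinely novel signals
    survive alignment — though they typically die at the frequency filter.
    Every sample peak is used at most once.

    Peak tables need columns ``center``, ``area``, ``snr`` and optionally
    ``fwhm`` (as produced by :func:`voigtnmr.peakfit.fit_spectrum`).
    """
    if not window > 0:
        raise ValueError("window must be > 0")
    if len(ref_table) == 0:
        raise ValueError("reference peak table is empty")
    n_samples = len(tables)
    claimed: dict[str, set[int]] = {sid: set() for sid in tables}
    features: list[PeakFeature] = []

    ref_order = np.argsort(-ref_table["area"].to_numpy(), kind="stable")
    for ri in ref_order:
        center = float(ref_table["center"].iat[ri])
        feat = PeakFeature(ref_center=center)
        for sid, tab in tables.items():
            j = _claim_nearest(center, window, tab, claimed[sid])
            if j is not None:
                claimed[sid].add(j)
                feat.per_sample_area[sid] = float(tab["area"].iat[j])
                feat.per_sample_snr[sid] = float(tab["snr"].iat[j])
                if "fwhm" in tab:
                    feat.per_sample_fwhm[sid] = float(tab["fwhm"].iat[j])
        features.append(feat)

    # orphan pooling: greedy, seeded at the largest-area unmatched peak
    orphans = []  # (area, center, sid, row)
    for sid, tab in tables.items():
        for i in range(len(tab)):
            if i not in claimed[sid]:
                orphans.append((float(tab["area"].iat[i]), float(tab["center"].iat[i]), sid, i))
    orphans.sort(key=lambda t: (-t[0], t[1], t[2]))
    for area, center, sid, i in orphans:
        if i in claimed[sid]:
            continue
        feat = PeakFeature(ref_center=center)
        for sid2, tab in tables.items():
            j = _claim_nearest(center, window, tab, claimed[sid2])
            if j is not None:
                claimed[sid2].add(j)
                feat.per_sample_area[sid2] = float(tab["area"].iat[j])
                feat.per_sample_snr[sid2] = float(tab["snr"].iat[j])
                if "fwhm" in tab:
                    feat.per_sample_fwhm[sid2] = float(tab["fwhm"].iat[j])
        features.append(feat)

    for f in features:
        f.frequency = len(f.per_sample_area) / n_samples if n_samples else 0.0
        snrs = list(f.per_sample_snr.values())
        f.median_snr = float(np.median(snrs)) if snrs else 0.0
    features.sort(key=lambda f: f.ref_center)
    return features


def frequency_filter(features: list[PeakFeature], min_frac: float) -> list[PeakFeature]:
    """Keep features detected in at least ``min_frac`` of samples (inclusive)."""
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must be in [0, 1]")
    return [f for f in features if f.frequency >= min_frac]


def snr_filter(features: list[PeakFeature], min_snr: float) -> list[PeakFeature]:
    """Keep features with median S/N >= min_snr (inclusive)."""
    if min_snr < 0:
        raise ValueError("min_snr must be >= 0")
    return [f for f in features if f.median_snr >= min_snr]


def assemble_feature_matrix(
    features: list[PeakFeature],
    sample_ids: list[str],
    missing: str = "zero",
) -> FeatureMatrix:
    """Build the samples x features area matrix.

    Missing entries (no matched peak) are filled with 0.0 (a non-detected
    peak is below noise) or NaN for downstream imputation, per ``missing``.
    """
    if not features:
        raise ValueError("feature list is empty")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    if missing not in ("zero", "nan"):
        raise ValueError("missing must be 'zero' or 'nan'")
    fill = 0.0 if missing == "zero" else float("nan")
    feats = sorted(features, key=lambda f: f.ref_center)
    values = np.full((len(sample_ids), len(feats)), fill)
    for j, f in enumerate(feats):
        for i, sid in enumerate(sample_ids):
            if sid in f.per_sample_area:
                values[i, j] = f.per_sample_area[sid]
    return FeatureMatrix(sample_ids=list(sample_ids), features=feats, values=values)
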