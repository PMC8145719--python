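"""Containers and text I/O for 1D NMR spectra and derived feature matrices.

Spectra are stored on an ascending ppm axis regardless of file order (NMR
plots reverse the axis at display time only). The interchange format is
plain UTF-8 CSV with a mandatory header row, "." decimal separator, and the
first column named ``ppm``.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum1D",
    "SpectraSet",
    "SpectraFormatError",
    "SpectraParseError",
    "UnsupportedFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_bruker_processed",
    "write_feature_matrix",
    "write_fit_report",
]


class SpectraFormatError(ValueError):
    """Structural problem in a spectra file (missing/duplicated columns...)."""


class SpectraParseError(ValueError):
    """A cell could not be parsed as a number; message reports row/column."""


class UnsupportedFormatError(ValueError):
    """A vendor directory is missing required files."""


def _validated_axis(ppm: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return (ascending axis, was_descending); reject non-finite or ties."""
    ppm = np.asarray(ppm, dtype=float)
    if ppm.ndim != 1 or ppm.size == 0:
        raise SpectraFormatError("ppm axis must be a non-empty 1-D array")
    if not np.all(np.isfinite(ppm)):
        raise SpectraFormatError("ppm axis contains non-finite values")
    d = np.diff(ppm)
    if ppm.size > 1 and np.all(d > 0):
        return ppm, False
    if ppm.size > 1 and np.all(d < 0):
        return ppm[::-1].copy(), True
    if ppm.size == 1:
        return ppm, False
    raise SpectraFormatError("ppm axis must be strictly monotone (duplicate or unordered values found)")


@dataclass
class Spectrum1D:
    """One 1D spectrum: shared chemical-shift axis plus an intensity trace."""

    ppm: np.ndarray
    intensity: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.ppm, flipped = _validated_axis(self.ppm)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if flipped:
            self.intensity = self.intensity[::-1].copy()
        if self.intensity.shape != self.ppm.shape:
            raise SpectraFormatError(
                f"intensity length {self.intensity.size} != axis length {self.ppm.size}"
            )

    @property
    def n_points(self) -> int:
        return self.ppm.size

    @property
    def step(self) -> float:
        """Median axis step (robust to a removed water gap)."""
        if self.ppm.size < 2:
            return 0.0
        return float(np.median(np.diff(self.ppm)))


@dataclass
class SpectraSet:
    """A sample x data-point matrix on one shared ppm axis."""

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.ppm, flipped = _validated_axis(self.ppm)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if flipped:
            self.intensities = self.intensities[:, ::-1].copy()
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.intensities.shape != (len(self.sample_ids), self.ppm.size):
            raise SpectraFormatError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"({len(self.sample_ids)} samples, {self.ppm.size} points)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraFormatError("sample ids must be unique")
        if len(self.sample_ids) == 0:
            raise SpectraFormatError("SpectraSet requires at least one sample")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise SpectraFormatError("labels length must equal number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_points(self) -> int:
        return self.ppm.size

    @property
    def step(self) -> float:
        if self.ppm.size < 2:
            return 0.0
        return float(np.median(np.diff(self.ppm)))

    def spectrum(self, i: int) -> Spectrum1D:
        return Spectrum1D(self.ppm.copy(), self.intensities[i].copy(), self.sample_ids[i])


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a spectra CSV: first column ``ppm``, one column per sample.

    The axis is returned ascending with intensity rows reordered to match.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SpectraFormatError(f"{path}: empty file")
    if df.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need a ppm column plus at least one sample column")
    if df.columns[0] != "ppm":
        raise SpectraFormatError(f"{path}: first column must be named 'ppm', got {df.columns[0]!r}")
    num = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SpectraParseError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row + 2}, column {col!r}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise SpectraFormatError(f"{path}: missing value (ragged row?) at row {row + 2}, column {col!r}")
        num[col] = converted
    ppm = num["ppm"].to_numpy()
    if np.unique(ppm).size != ppm.size:
        raise SpectraFormatError(f"{path}: duplicate ppm values")
    order = np.argsort(ppm)
    sample_ids = list(df.columns[1:])
    mat = num[sample_ids].to_numpy().T[:, order]
    return SpectraSet(ppm[order], mat, sample_ids)


def write_spectra_csv(s: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet as CSV at full float precision (17 significant digits)."""
    path = Path(path)
    cols = {"ppm": s.ppm, **{sid: s.intensities[i] for i, sid in enumerate(s.sample_ids)}}
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_feature_matrix(fm, path: str | Path) -> Path:
    """Write a FeatureMatrix as values CSV plus a companion metadata CSV.

    Value columns are named by the feature's reference center formatted with
    6 decimal places. Returns the metadata file path
    (``<stem>_meta.csv`` next to the values file).
    """
    path = Path(path)
    fm.to_dataframe().to_csv(path, index=True, index_label="sample_id", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "ref_center_ppm": [f.ref_center for f in fm.features],
            "mean_fwhm_ppm": [f.mean_fwhm for f in fm.features],
            "frequency": [f.frequency for f in fm.features],
            "median_snr": [f.median_snr for f in fm.features],
        }
    )
    meta_path = path.with_name(path.stem + "_meta.csv")
    meta.to_csv(meta_path, index=False, float_format="%.17g")
    return meta_path


def write_fit_report(report: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


# -- optional vendor reader ---------------------------------------------------

_REQUIRED_PROCS = ("OFFSET", "SW_p", "SF", "SI")


def _parse_procs(path: Path) -> dict[str, float]:
    params: dict[str, float] = {}
    for line in path.read_text(errors="replace").splitlines():
        if line.startswith("##$"):
            key, _, val = line[3:].partition("=")
            try:
                params[key.strip()] = float(val.strip())
            except ValueError:
                continue
    return params


def read_bruker_processed(dirpath: str | Path) -> Spectrum1D:
    """Read Bruker processed real-part 1D data (``1r`` + ``procs``).

    Accepts either the ``pdata/<n>`` directory itself or an experiment
    directory containing ``pdata/1``. The axis is reconstructed from
    OFFSET/SW_p/SF as ppm_i = OFFSET - i * (SW_p/SF)/(SI-1), i.e. the axis
    endpoints are OFFSET and OFFSET - SW_p/SF; data are stored as int32
    scaled by 2**NC_proc.
    """
    dirpath = Path(dirpath)
    if not (dirpath / "procs").exists() and (dirpath / "pdata" / "1" / "procs").exists():
        dirpath = dirpath / "pdata" / "1"
    procs = dirpath / "procs"
    data = dirpath / "1r"
    if not procs.exists():
        raise UnsupportedFormatError(f"{dirpath}: missing required parameter file 'procs'")
    if not data.exists():
        raise UnsupportedFormatError(f"{dirpath}: missing processed data file '1r'")
    params = _parse_procs(procs)
    for key in _REQUIRED_PROCS:
        if key not in params:
            raise UnsupportedFormatError(f"{procs}: missing required parameter {key}")
    si = int(params["SI"])
    sw_ppm = params["SW_p"] / params["SF"]
    offset = params["OFFSET"]
    byteorder = "<" if int(params.get("BYTORDP", 0)) == 0 else ">"
    raw = data.read_bytes()
    n = len(raw) // 4
    values = np.array(struct.unpack(f"{byteorder}{n}i", raw[: 4 * n]), dtype=float)
    values = values[:si] * 2.0 ** int(params.get("NC_proc", 0))
    if si == 1:
        ppm = np.array([offset])
    else:
        ppm = offset - np.arange(si) * (sw_ppm / (si - 1))
    return Spectrum1D(ppm, values, id=dirpath.name)
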