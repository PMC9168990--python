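"""Spectrum ingest, top-hat baseline subtraction, peak picking, m/z windowing,
and affine internal mass calibration."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import find_peaks

__all__ = [
    "Spectrum",
    "Peak",
    "CalibrationFit",
    "SpectrumFormatError",
    "CalibrationError",
    "read_spectrum",
    "write_spectrum",
    "tophat_baseline",
    "pick_peaks",
    "window_filter",
    "internal_calibrate",
]


class SpectrumFormatError(ValueError):
    """Raised for unreadable or malformed spectrum files."""


class CalibrationError(RuntimeError):
    """Raised when fewer than two internal calibrants can be matched."""


@dataclass
class Spectrum:
    """A raw or processed MALDI trace: m/z (Da) vs intensity (mV)."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectrumFormatError("m/z and intensity must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise SpectrumFormatError("non-finite values in spectrum")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise SpectrumFormatError("m/z axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class Peak:
    """A picked peak: interpolated apex m/z and baseline-subtracted height."""

    mz: float
    height: float

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("peak height must be positive")


@dataclass
class CalibrationFit:
    """Affine observed→theoretical m/z map with fit diagnostics."""

    slope: float
    offset: float
    n_calibrants_used: int
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def apply(self, mz: float | np.ndarray) -> float | np.ndarray:
        return self.slope * mz + self.offset


_SPLIT_RE = re.compile(r"[,\s]+")


def read_spectrum(
    path: str | Path,
    fmt: str = "text",
    sample_id: str = "",
    replicate_index: int = 0,
) -> Spectrum:
    """Read a spectrum from two-column text (``m/z intensity``) or mzML.

    The text dialect accepts whitespace- or comma-separated rows and ignores
    blank lines and lines starting with ``#``.  Rows are sorted by m/z on
    read; duplicate m/z values are a format error.
    """
    path = Path(path)
    if fmt == "mzml":
        return _read_mzml(path, sample_id, replicate_index)
    if fmt != "text":
        raise ValueError(f"unknown spectrum format {fmt!r}")
    mzs: list[float] = []
    intens: list[float] = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise SpectrumFormatError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = _SPLIT_RE.split(line)
        if len(parts) != 2:
            raise SpectrumFormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            mzs.append(float(parts[0]))
            intens.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: non-numeric row") from exc
    if not mzs:
        raise SpectrumFormatError(f"{path}: no data rows")
    mz = np.asarray(mzs)
    intensity = np.asarray(intens)
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    if mz.size >= 2 and np.any(np.diff(mz) <= 0):
        raise SpectrumFormatError(f"{path}: duplicate m/z values after sorting")
    return Spectrum(mz, intensity, sample_id=sample_id, replicate_index=replicate_index)


def _read_mzml(path: Path, sample_id: str, replicate_index: int) -> Spectrum:
    try:
        from pyteomics import mzml  # optional dependency
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise SpectrumFormatError("mzML support requires the pyteomics package") from exc
    with mzml.MzML(str(path)) as reader:
        for scan in reader:
            mz = np.asarray(scan["m/z array"], dtype=float)
            intensity = np.asarray(scan["intensity array"], dtype=float)
            order = np.argsort(mz, kind="stable")
            return Spectrum(mz[order], intensity[order], sample_id, replicate_index)
    raise SpectrumFormatError(f"{path}: no spectra found")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write the two-column text dialect."""
    with open(path, "w") as fh:
        fh.write("# m/z intensity_mV\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.4f} {i:.6g}\n")


def _window_points(mz: np.ndarray, window_da: float) -> int:
    spacing = float(np.median(np.diff(mz)))
    if window_da < spacing:
        raise ValueError(
            f"top-hat window {window_da} Da is below the median point spacing {spacing:.4g} Da"
        )
    n = int(round(window_da / spacing))
    return max(n | 1, 3)  # odd, at least 3 points


def tophat_baseline(spectrum: Spectrum, window_da: float = 20.0) -> Spectrum:
    """Morphological top-hat: subtract the opening (moving minimum followed by
    moving maximum over a flat window of ``window_da``) from the signal.

    Removes baseline structure broader than the window while preserving the
    height of peaks narrower than it; output intensities are >= 0.
    """
    if window_da <= 0:
        raise ValueError("window_da must be positive")
    n = _window_points(spectrum.mz, window_da)
    eroded = minimum_filter1d(spectrum.intensity, size=n, mode="nearest")
    opened = maximum_filter1d(eroded, size=n, mode="nearest")
    return Spectrum(
        spectrum.mz,
        spectrum.intensity - opened,
        sample_id=spectrum.sample_id,
        replicate_index=spectrum.replicate_index,
    )


def _parabolic_apex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex abscissa of the parabola through points i-1, i, i+1."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return float(x1)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # not a maximum; fall back to the grid apex
        return float(x1)
    return float(-b / (2 * a))


def pick_peaks(spectrum: Spectrum, threshold_mv: float = 0.050) -> list[Peak]:
    """Local maxima with apex height >= ``threshold_mv``.

    Plateaus are resolved to their midpoint; the apex m/z is refined by
    3-point parabolic interpolation around the grid maximum.
    """
    if threshold_mv < 0:
        raise ValueError("threshold_mv must be >= 0")
    y = spectrum.intensity
    if y.size < 3:
        return []
    idx, props = find_peaks(y, height=max(threshold_mv, np.finfo(float).tiny), plateau_size=1)
    peaks: list[Peak] = []
    for i, left, right in zip(idx, props["left_edges"], props["right_edges"]):
        mid = (left + right) // 2
        apex_mz = (
            float(spectrum.mz[mid])
            if right > left
            else _parabolic_apex(spectrum.mz, y, i)
        )
        peaks.append(Peak(mz=apex_mz, height=float(y[i])))
    return peaks


def window_filter(peaks: Sequence[Peak], lo: float, hi: float) -> list[Peak]:
    """Retain peaks with lo <= m/z <= hi, preserving order."""
    if not lo < hi:
        raise ValueError("window requires lo < hi")
    return [p for p in peaks if lo <= p.mz <= hi]


def internal_calibrate(
    peaks: Sequence[Peak],
    calibrant_mzs: Sequence[float],
    match_tol: float = 1.5,
) -> tuple[list[Peak], CalibrationFit]:
    """Affine internal calibration against theoretical calibrant masses.

    For each calibrant the highest peak within ``match_tol`` Da is taken as
    its observed partner; a least-squares affine observed→theoretical fit is
    then applied to every peak.  At least two calibrants must be matched.
    """
    pairs: list[tuple[float, float]] = []
    for theo in calibrant_mzs:
        candidates = [p for p in peaks if abs(p.mz - theo) <= match_tol]
        if candidates:
            obs = max(candidates, key=lambda p: p.height)
            pairs.append((obs.mz, theo))
    if len(pairs) < 2:
        raise CalibrationError(
            f"only {len(pairs)} of {len(calibrant_mzs)} calibrants matched (need >= 2)"
        )
    obs_arr = np.array([p[0] for p in pairs])
    theo_arr = np.array([p[1] for p in pairs])
    # Centre the fit for numerical stability at m/z ~3000.
    x0 = obs_arr.mean()
    slope, off_c = np.polyfit(obs_arr - x0, theo_arr, 1)
    offset = off_c - slope * x0
    fit = CalibrationFit(
        slope=float(slope),
        offset=float(offset),
        n_calibrants_used=len(pairs),
        residuals=theo_arr - (slope * obs_arr + offset),
    )
    calibrated = [Peak(mz=float(fit.apply(p.mz)), height=p.height) for p in peaks]
    return calibrated, fit
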