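"""Peak-to-library assignment, relative quantification, replicate averaging,
and replicate-precision (RSD) quality control."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .glycolib import TheoreticalGlycopeptide
from .spectra import Peak

__all__ = [
    "GlycoProfile",
    "RsdReport",
    "QuantificationError",
    "assign_peaks",
    "relative_intensity",
    "average_replicates",
    "rsd_qc",
]

Key = tuple[str, str]  # (subclass, glycoform)


class QuantificationError(RuntimeError):
    """Raised when a replicate yields no quantifiable signal."""


@dataclass
class GlycoProfile:
    """Per-sample relative abundances over the (non-overlapped) library.

    ``abundances`` maps (subclass, glycoform) to a relative intensity in
    [0, 1]; values sum to 1.
    """

    sample_id: str
    abundances: dict[Key, float]
    n_replicates: int = 1

    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def as_array(self, keys: Sequence[Key]) -> np.ndarray:
        return np.array([self.abundances.get(k, 0.0) for k in keys])


@dataclass
class RsdReport:
    """Relative standard deviation (%) per QC target m/z."""

    rsd_pct: dict[float, float]
    threshold_pct: float
    pass_qc: bool = field(init=False)

    def __post_init__(self) -> None:
        self.pass_qc = all(
            np.isfinite(v) and v < self.threshold_pct for v in self.rsd_pct.values()
        )


def assign_peaks(
    peaks: Sequence[Peak],
    library: Sequence[TheoreticalGlycopeptide],
    assign_tol: float = 1.0,
) -> dict[Key, float]:
    """Assign calibrated peaks to non-overlapped library entries.

    Each entry receives the height of the nearest peak within ``assign_tol``
    Da; entries with no matching peak get 0 (missing values are zero).  Each
    peak is consumed by at most one entry — when two entries want the same
    peak the nearer entry wins; exact distance ties go to the higher peak
    and then to the lower-m/z entry.
    """
    targets = [e for e in library if not e.overlapped]
    heights: dict[Key, float] = {e.key: 0.0 for e in targets}
    # Candidate (distance, -height, entry m/z, entry idx, peak idx) tuples,
    # processed greedily by increasing distance.
    candidates = []
    for ei, entry in enumerate(targets):
        for pi, peak in enumerate(peaks):
            d = abs(peak.mz - entry.mz_theoretical)
            if d <= assign_tol:
                candidates.append((d, -peak.height, entry.mz_theoretical, ei, pi))
    candidates.sort()
    used_entries: set[int] = set()
    used_peaks: set[int] = set()
    for _, neg_h, _, ei, pi in candidates:
        if ei in used_entries or pi in used_peaks:
            continue
        used_entries.add(ei)
        used_peaks.add(pi)
        heights[targets[ei].key] = -neg_h
    return heights


def relative_intensity(heights: Mapping[Key, float], sample_id: str = "") -> GlycoProfile:
    """Normalize peak heights to relative intensities summing to 1."""
    total = float(sum(heights.values()))
    if total <= 0:
        raise QuantificationError(f"all-zero heights for sample {sample_id!r}")
    return GlycoProfile(
        sample_id=sample_id,
        abundances={k: v / total for k, v in heights.items()},
        n_replicates=1,
    )


def average_replicates(profiles: Sequence[GlycoProfile]) -> GlycoProfile:
    """Element-wise arithmetic mean of 1-4 replicate profiles of one sample."""
    if not profiles:
        raise QuantificationError("no replicate profiles to average")
    if len(profiles) < 4:
        warnings.warn(
            f"averaging only {len(profiles)} replicate(s) for "
            f"sample {profiles[0].sample_id!r}",
            stacklevel=2,
        )
    keys: list[Key] = sorted({k for p in profiles for k in p.abundances})
    n = len(profiles)
    mean = {k: sum(p.abundances.get(k, 0.0) for p in profiles) / n for k in keys}
    return GlycoProfile(
        sample_id=profiles[0].sample_id,
        abundances=mean,
        n_replicates=n,
    )


def rsd_qc(
    replicate_heights: Sequence[Mapping[float, float]],
    targets: Sequence[float],
    threshold_pct: float = 15.0,
) -> RsdReport:
    """Relative SD (100 * sample SD / mean) per target m/z across replicates.

    ``replicate_heights`` maps target m/z to a measured height for each
    replicate.  A zero mean makes the RSD undefined and fails that target.
    """
    if len(replicate_heights) < 2:
        raise QuantificationError("RSD QC needs at least 2 replicates")
    rsd: dict[float, float] = {}
    for t in targets:
        vals = np.array([rep.get(t, 0.0) for rep in replicate_heights], dtype=float)
        mean = vals.mean()
        if mean <= 0:
            rsd[t] = float("nan")
        else:
            rsd[t] = float(100.0 * vals.std(ddof=1) / mean)
    return RsdReport(rsd_pct=rsd, threshold_pct=threshold_pct)
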