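"""Synthetic cohorts and linear-mode spectra with the statistical structure
the analysis assumes: compositional glycopeptide profiles with targeted
case/control fold changes, replicate-to-replicate intensity jitter, and
spectra with broad Gaussian peaks, a drifting baseline, white noise, and an
affine mass error.

The template profile is a plausible IgG Fc glycoform distribution dominated
by G0F/G1F/G2F with subclass weights ~60/32/8 (IgG1/IgG2/IgG3-4); it is a
documented fixture for exercising the pipeline, not a measured dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .glycolib import SUBCLASSES, VOCABULARY, TheoreticalGlycopeptide, build_library
from .quantify import GlycoProfile, Key
from .spectra import Spectrum

__all__ = [
    "EffectSpec",
    "InstrumentModel",
    "Subject",
    "SyntheticCohort",
    "template_profile",
    "generate_cohort",
    "synthesize_spectrum",
    "generate_qc_replicates",
]

# Relative weight of each glycoform within one subclass; biantennary,
# largely core-fucosylated, mostly neutral — normalized at build time.
_GLYCOFORM_WEIGHTS = {
    "G0": 0.040, "G0F": 0.240, "G0N": 0.015, "G0NF": 0.055, "G0-NF": 0.015,
    "G1": 0.030, "G1F": 0.200, "G1FS": 0.035, "G1-N": 0.006, "G1N": 0.010,
    "G1NF": 0.040, "G1-NF": 0.006, "G1NFS": 0.008, "G1S": 0.010,
    "G2": 0.015, "G2F": 0.110, "G2FS": 0.045, "G2N": 0.008, "G2NF": 0.020,
    "G2NFS": 0.008, "G2S": 0.010, "G2S2": 0.012,
}

_SUBCLASS_WEIGHTS = {"IgG1": 0.60, "IgG2": 0.32, "IgG3/4": 0.08}


def template_profile(
    subclasses: Sequence[str] = SUBCLASSES, sample_id: str = "template"
) -> GlycoProfile:
    """The bundled mean compositional profile over subclass x glycoform."""
    raw = {
        (sub, name): _SUBCLASS_WEIGHTS[sub] * _GLYCOFORM_WEIGHTS[name]
        for sub in subclasses
        for name in VOCABULARY
    }
    total = sum(raw.values())
    return GlycoProfile(sample_id, {k: v / total for k, v in raw.items()})


@dataclass
class EffectSpec:
    """Per-glycopeptide multiplicative effects and noise levels."""

    case_fold_changes: dict[Key, float] = field(default_factory=dict)
    aura_fold_changes: dict[Key, float] = field(default_factory=dict)
    family_history_fold_changes: dict[Key, float] = field(default_factory=dict)
    between_subject_log_sd: float = 0.15
    replicate_cv_pct: float = 5.0

    def __post_init__(self) -> None:
        for d in (
            self.case_fold_changes,
            self.aura_fold_changes,
            self.family_history_fold_changes,
        ):
            for key, fc in d.items():
                if fc <= 0:
                    raise ValueError(f"fold change for {key} must be > 0")
                if key[1] not in VOCABULARY or key[0] not in SUBCLASSES:
                    raise ValueError(f"effect target {key} not in the vocabulary")
        if self.replicate_cv_pct < 0:
            raise ValueError("replicate_cv_pct must be >= 0")


@dataclass
class InstrumentModel:
    """Linear-mode acquisition model for spectrum synthesis."""

    fwhm: float = 2.5
    grid_step: float = 0.1
    mz_lo: float = 2300.0
    mz_hi: float = 3600.0
    baseline_amplitude: float = 0.05
    baseline_decay: float = 600.0
    noise_sd: float = 0.001
    mass_slope: float = 1.0
    mass_offset: float = 0.0
    total_signal_mv: float = 50.0

    def __post_init__(self) -> None:
        if self.grid_step >= self.fwhm:
            raise ValueError("grid step must be finer than the peak FWHM")


@dataclass
class Subject:
    subject_id: str
    group: str  # "case" | "control"
    aura: bool
    ictal: bool
    family_history: bool
    age: float
    sex: str
    profile: GlycoProfile
    spectra: list[Spectrum] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    subjects: list[Subject]
    seed: int
    library: list[TheoreticalGlycopeptide]

    @property
    def cases(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "case"]

    @property
    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "control"]


def _perturb(
    template: GlycoProfile,
    log_shift: dict[Key, float],
    log_sd: float,
    rng: np.random.Generator,
    sample_id: str,
) -> GlycoProfile:
    """Logistic-normal draw around the template with additive log shifts."""
    keys = list(template.abundances)
    z = np.log([template.abundances[k] for k in keys])
    if log_sd > 0:
        z = z + rng.normal(0.0, log_sd, size=len(keys))
    for k, shift in log_shift.items():
        if k in template.abundances:
            z[keys.index(k)] += shift
    p = np.exp(z - z.max())
    p /= p.sum()
    return GlycoProfile(sample_id, dict(zip(keys, p)))


def generate_cohort(
    n_cases: int = 20,
    n_controls: int = 20,
    effects: EffectSpec | None = None,
    seed: int = 0,
    n_aura: int = 5,
    n_ictal: int = 7,
    n_family_history: int = 11,
    with_spectra: bool = False,
    instrument: InstrumentModel | None = None,
    n_replicates: int = 4,
    subclasses: Sequence[str] = SUBCLASSES,
) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort.

    Case profiles receive the case fold changes; aura and family-history
    subgroup effects are layered onto randomly chosen case subsets of the
    given sizes.  With ``with_spectra=True`` each subject additionally gets
    ``n_replicates`` synthetic replicate spectra.
    """
    effects = effects if effects is not None else EffectSpec()
    rng = np.random.default_rng(seed)
    template = template_profile(subclasses)
    library = build_library(subclasses=subclasses)

    aura_ids = set(rng.choice(n_cases, size=min(n_aura, n_cases), replace=False).tolist())
    ictal_ids = set(rng.choice(n_cases, size=min(n_ictal, n_cases), replace=False).tolist())
    fh_ids = set(
        rng.choice(n_cases, size=min(n_family_history, n_cases), replace=False).tolist()
    )

    subjects: list[Subject] = []
    for i in range(n_cases + n_controls):
        is_case = i < n_cases
        aura = is_case and i in aura_ids
        ictal = is_case and i in ictal_ids
        fh = is_case and i in fh_ids
        log_shift: dict[Key, float] = {}
        if is_case:
            for k, fc in effects.case_fold_changes.items():
                log_shift[k] = log_shift.get(k, 0.0) + math.log(fc)
            if aura:
                for k, fc in effects.aura_fold_changes.items():
                    log_shift[k] = log_shift.get(k, 0.0) + math.log(fc)
            if fh:
                for k, fc in effects.family_history_fold_changes.items():
                    log_shift[k] = log_shift.get(k, 0.0) + math.log(fc)
        sid = f"{'case' if is_case else 'ctrl'}{(i if is_case else i - n_cases) + 1:03d}"
        profile = _perturb(template, log_shift, effects.between_subject_log_sd, rng, sid)
        subjects.append(
            Subject(
                subject_id=sid,
                group="case" if is_case else "control",
                aura=aura,
                ictal=ictal,
                family_history=fh,
                age=float(np.round(rng.normal(40.0, 11.0), 1)),
                sex="M" if rng.random() < 0.4 else "F",
                profile=profile,
            )
        )

    if with_spectra:
        instrument = instrument if instrument is not None else InstrumentModel()
        for subj in subjects:
            for r in range(n_replicates):
                spec = synthesize_spectrum(
                    subj.profile,
                    instrument,
                    seed=rng.integers(2**31),
                    library=library,
                    replicate_cv_pct=effects.replicate_cv_pct,
                    sample_id=subj.subject_id,
                    replicate_index=r,
                )
                subj.spectra.append(spec)
    return SyntheticCohort(subjects=subjects, seed=seed, library=library)


def synthesize_spectrum(
    profile: GlycoProfile,
    instrument: InstrumentModel | None = None,
    seed: int = 0,
    library: Sequence[TheoreticalGlycopeptide] | None = None,
    replicate_cv_pct: float = 0.0,
    sample_id: str = "",
    replicate_index: int = 0,
) -> Spectrum:
    """Sum-of-Gaussians spectrum for one profile.

    Peaks sit at affinely distorted theoretical m/z with apex heights
    proportional to abundances (scaled to ``total_signal_mv``), on a
    decaying-exponential baseline plus white noise; ``replicate_cv_pct``
    applies per-peak multiplicative height jitter.
    """
    instrument = instrument if instrument is not None else InstrumentModel()
    rng = np.random.default_rng(seed)
    if library is None:
        library = build_library()
    mz_by_key = {e.key: e.mz_theoretical for e in library}
    grid = np.arange(instrument.mz_lo, instrument.mz_hi + instrument.grid_step / 2,
                     instrument.grid_step)
    signal = np.zeros_like(grid)
    sigma = instrument.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    for key, abundance in profile.abundances.items():
        if key not in mz_by_key or abundance <= 0:
            continue
        centre = instrument.mass_slope * mz_by_key[key] + instrument.mass_offset
        height = abundance * instrument.total_signal_mv
        if replicate_cv_pct > 0:
            height *= max(0.0, 1.0 + rng.normal(0.0, replicate_cv_pct / 100.0))
        signal += height * np.exp(-0.5 * ((grid - centre) / sigma) ** 2)
    baseline = instrument.baseline_amplitude * np.exp(
        -(grid - instrument.mz_lo) / instrument.baseline_decay
    )
    noise = (
        rng.normal(0.0, instrument.noise_sd, size=grid.size)
        if instrument.noise_sd > 0
        else 0.0
    )
    return Spectrum(grid, signal + baseline + noise,
                    sample_id=sample_id, replicate_index=replicate_index)


def generate_qc_replicates(
    profile: GlycoProfile,
    n: int = 3,
    cv_pct: float = 5.0,
    seed: int = 0,
    instrument: InstrumentModel | None = None,
    library: Sequence[TheoreticalGlycopeptide] | None = None,
) -> list[Spectrum]:
    """Replicate spectra of one standard with per-peak multiplicative jitter
    of the given CV, for repeatability QC."""
    if n < 2:
        raise ValueError("QC needs n >= 2 replicates")
    if cv_pct < 0:
        raise ValueError("cv_pct must be >= 0")
    rng = np.random.default_rng(seed)
    return [
        synthesize_spectrum(
            profile,
            instrument,
            seed=rng.integers(2**31),
            library=library,
            replicate_cv_pct=cv_pct,
            sample_id=profile.sample_id,
            replicate_index=r,
        )
        for r in range(n)
    ]
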