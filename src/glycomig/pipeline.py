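"""End-to-end orchestration: spectra -> calibrated peaks -> profiles ->
traits -> group statistics -> cross-validated classifier."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifier, cohortstats, quantify, traits
from .config import PipelineConfig
from .glycolib import (
    TheoreticalGlycopeptide,
    build_library,
    calibrant_mzs,
    library_to_frame,
    qc_target_mzs,
)
from .quantify import GlycoProfile
from .spectra import (
    CalibrationError,
    Spectrum,
    SpectrumFormatError,
    internal_calibrate,
    pick_peaks,
    read_spectrum,
    tophat_baseline,
    window_filter,
)

__all__ = [
    "feature_name",
    "process_spectrum",
    "profile_sample",
    "profiles_to_frame",
    "estimate_cohort_profiles",
    "grouping_labels",
    "run_pipeline",
]

log = logging.getLogger("glycomig")


def feature_name(key: tuple[str, str]) -> str:
    return f"{key[0]} {key[1]}"


def process_spectrum(
    spectrum: Spectrum,
    library: Sequence[TheoreticalGlycopeptide],
    cfg: PipelineConfig,
) -> dict[tuple[str, str], float]:
    """Baseline-subtract, pick, window, calibrate, and assign one spectrum;
    returns per-glycopeptide heights (missing -> 0)."""
    flat = tophat_baseline(spectrum, cfg.tophat_width_da)
    peaks = pick_peaks(flat, cfg.threshold_mv)
    peaks = window_filter(peaks, cfg.window_lo, cfg.window_hi)
    try:
        peaks, _fit = internal_calibrate(peaks, calibrant_mzs(), cfg.cal_match_tol)
    except CalibrationError as exc:
        warnings.warn(f"{spectrum.sample_id}/{spectrum.replicate_index}: {exc}; "
                      "falling back to identity calibration", stacklevel=2)
    return quantify.assign_peaks(peaks, library, cfg.assign_tol)


def profile_sample(
    spectra: Sequence[Spectrum],
    library: Sequence[TheoreticalGlycopeptide],
    cfg: PipelineConfig,
    sample_id: str,
) -> GlycoProfile:
    """Replicate spectra -> per-replicate relative intensities -> mean profile."""
    profile, _ = profile_sample_with_qc(spectra, library, cfg, sample_id)
    return profile


def profile_sample_with_qc(
    spectra: Sequence[Spectrum],
    library: Sequence[TheoreticalGlycopeptide],
    cfg: PipelineConfig,
    sample_id: str,
) -> tuple[GlycoProfile, quantify.RsdReport | None]:
    """As :func:`profile_sample`, also reporting replicate RSD at the six
    repeatability QC masses (None with a single replicate)."""
    qc_mzs = qc_target_mzs()
    # map theoretical QC m/z -> library key, via the library itself
    key_by_mz = {}
    for entry in library:
        for mz in qc_mzs:
            if abs(entry.mz_theoretical - mz) < 1e-6:
                key_by_mz[mz] = entry.key
    reps = []
    rep_qc_heights = []
    for spec in spectra:
        heights = process_spectrum(spec, library, cfg)
        rep_qc_heights.append(
            {mz: heights.get(key, 0.0) for mz, key in key_by_mz.items()}
        )
        reps.append(quantify.relative_intensity(heights, sample_id=sample_id))
    report = None
    if len(reps) >= 2 and key_by_mz:
        report = quantify.rsd_qc(
            rep_qc_heights, sorted(key_by_mz), threshold_pct=cfg.rsd_threshold_pct
        )
    return quantify.average_replicates(reps), report


def profiles_to_frame(profiles: Sequence[GlycoProfile]) -> pd.DataFrame:
    keys = sorted({k for p in profiles for k in p.abundances})
    data = {
        feature_name(k): [p.abundances.get(k, 0.0) for p in profiles] for k in keys
    }
    frame = pd.DataFrame(data, index=[p.sample_id for p in profiles])
    frame.index.name = "sample_id"
    frame["n_replicates"] = [p.n_replicates for p in profiles]
    return frame


def estimate_cohort_profiles(
    sample_spectra: dict[str, list[Spectrum]],
    cfg: PipelineConfig,
    library: Sequence[TheoreticalGlycopeptide] | None = None,
) -> list[GlycoProfile]:
    if library is None:
        library = build_library(
            glycoform_names=cfg.include_glycoforms, overlap_tol=cfg.overlap_tol
        )
    return [
        profile_sample(spectra, library, cfg, sample_id)
        for sample_id, spectra in sample_spectra.items()
    ]


_GROUPINGS = {
    "case_control": ("group", None),
    "aura": ("aura", "case"),
    "phase": ("ictal", "case"),
    "family_history": ("family_history", "case"),
}


def grouping_labels(manifest: pd.DataFrame, grouping: str) -> pd.Series:
    """Binary labels for a grouping; subgroup contrasts are within cases."""
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {sorted(_GROUPINGS)}")
    column, restrict_to = _GROUPINGS[grouping]
    if column not in manifest.columns:
        raise ValueError(f"manifest lacks column {column!r}")
    sub = manifest
    if restrict_to is not None:
        sub = manifest[manifest["group"] == restrict_to]
    return sub[column]


def _manifest_spectra(
    manifest: pd.DataFrame, base_dir: Path
) -> dict[str, list[Spectrum]]:
    out: dict[str, list[Spectrum]] = {}
    for row in manifest.itertuples():
        paths = [p for p in str(row.replicate_paths).split(";") if p]
        spectra = []
        for r, rel in enumerate(paths):
            path = base_dir / rel
            try:
                spectra.append(
                    read_spectrum(path, sample_id=str(row.sample_id), replicate_index=r)
                )
            except (SpectrumFormatError, OSError) as exc:
                log.warning("sample %s: skipping replicate %s (%s)", row.sample_id, rel, exc)
        if not spectra:
            raise SpectrumFormatError(f"sample {row.sample_id}: no readable replicates")
        out[str(row.sample_id)] = spectra
    return out


def run_pipeline(
    cfg: PipelineConfig,
    manifest: pd.DataFrame,
    outdir: str | Path,
    base_dir: str | Path = ".",
) -> dict[str, Path]:
    """Run the full chain and write profiles/traits/stats/CV outputs.

    Returns a map of artifact name -> written path.  Deterministic for a
    fixed config seed; every CSV carries the config hash in a header comment
    line written alongside (run_config.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_dir = Path(base_dir)
    manifest = manifest.set_index("sample_id", drop=False)

    library = build_library(
        glycoform_names=cfg.include_glycoforms, overlap_tol=cfg.overlap_tol
    )
    sample_spectra = _manifest_spectra(manifest, base_dir)
    profiles = []
    qc_rows = []
    for sample_id, spectra in sample_spectra.items():
        profile, report = profile_sample_with_qc(spectra, library, cfg, sample_id)
        profiles.append(profile)
        if report is not None:
            for mz, rsd in report.rsd_pct.items():
                qc_rows.append({"sample_id": sample_id, "target_mz": mz, "rsd_pct": rsd})
    qc_frame = pd.DataFrame(qc_rows)
    prof_frame = profiles_to_frame(profiles).loc[[str(s) for s in manifest.index]]
    if not qc_frame.empty:
        qc_pass = (
            qc_frame.assign(ok=lambda d: d["rsd_pct"] < cfg.rsd_threshold_pct)
            .groupby("sample_id")["ok"]
            .all()
        )
        prof_frame["qc_pass"] = qc_pass.reindex(
            prof_frame.index, fill_value=False
        ).astype(bool).to_numpy()

    trait_rows = []
    for p in profiles:
        for scope in ("IgG1", "IgG2", "total"):
            t = traits.compute_traits(p, scope=scope, extended=cfg.extended_traits)
            trait_rows.append(
                {
                    "sample_id": t.sample_id,
                    "scope": t.scope,
                    "bi_n": t.bi_n,
                    "fuc_total": t.fuc_total,
                    "fuc_neutral": t.fuc_neutral,
                    "fuc_sialo": t.fuc_sialo,
                    "sial": t.sial,
                    "g0": t.g0,
                    "g1": t.g1,
                    "g2": t.g2,
                    "gal_ratio": t.gal_ratio,
                }
            )
    trait_frame = pd.DataFrame(trait_rows)

    feature_cols = [c for c in prof_frame.columns if c not in ("n_replicates", "qc_pass")]
    features = prof_frame[feature_cols]
    labels = grouping_labels(manifest, cfg.grouping)
    stats_frame = cohortstats.compare_all(features.loc[labels.index], labels)

    y = (manifest["group"] == "case").astype(int).to_numpy()
    cv = classifier.cross_validate(
        features,
        y,
        n_folds=cfg.n_folds,
        seed=cfg.seed,
        hyper=classifier.Hyper(lr=cfg.lr, epochs=cfg.epochs, seed=cfg.seed, l2=cfg.l2),
        stratified=cfg.stratified,
        select_k=cfg.k_features,
        paper_mode=cfg.paper_mode,
    )
    chosen = [
        name
        for name, _ in cohortstats.f_rank_features(features, y, cfg.k_features)
    ]
    final = classifier.fit_final(
        features[chosen].to_numpy(),
        y,
        hyper=classifier.Hyper(lr=cfg.lr, epochs=cfg.epochs, seed=cfg.seed, l2=cfg.l2),
        feature_names=chosen,
    )

    paths = {
        "library": outdir / "library.csv",
        "profiles": outdir / "profiles.csv",
        "traits": outdir / "traits.csv",
        "stats": outdir / "stats.csv",
        "cv": outdir / "cv_result.json",
        "model": outdir / "model.json",
        "config": outdir / "run_config.json",
        "rsd": outdir / "rsd_report.csv",
    }
    library_to_frame(library).to_csv(paths["library"], index=False)
    qc_frame.to_csv(paths["rsd"], index=False)
    prof_frame.to_csv(paths["profiles"])
    trait_frame.to_csv(paths["traits"], index=False)
    stats_frame.to_csv(paths["stats"], index=False)
    cv_payload = {
        "seed": cv.seed,
        "mean_auc": cv.mean_auc,
        "fold_aucs": cv.fold_aucs,
        "fold_test_indices": [f.test_indices.tolist() for f in cv.folds],
        "config_hash": cfg.config_hash(),
    }
    paths["cv"].write_text(json.dumps(cv_payload, indent=1))
    classifier.save_model(final, paths["model"])
    paths["config"].write_text(
        json.dumps({"config": cfg.to_dict(), "hash": cfg.config_hash()}, indent=1)
    )
    log.info("pipeline complete: mean CV AUC %.3f (config %s)", cv.mean_auc, cfg.config_hash())
    return paths
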