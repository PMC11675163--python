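"""End-to-end cohort analysis orchestration.

Per subject: extract the analysis segment, band-pass both traces with a
zero-phase filter, z-score, differentiate the processed RSP, then
compute the coupling metrics (time-lag, peak correlation, mutual
information) and the two HR model fits with their AICc comparison.
Per cohort: flag lag outliers with the 3-scaled-MAD rule, summarize
coupling over non-outliers (lag) / all subjects (MI), and tally model
wins and slope signs.

Subjects whose analysis fails (degenerate signal, too-short trace, ...)
are skipped with a logged warning rather than aborting the run — but a
run in which more than half the subjects fail raises.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .coupling import (
    CohortCouplingSummary,
    CouplingResult,
    estimate_lag,
    flag_outliers,
    mutual_information,
    summarize_coupling,
)
from .errors import DegenerateSignalError, RespCouplingError, SummaryError
from .hr_models import (
    CohortModelSummary,
    ModelComparison,
    ModelFit,
    compare_models,
    fit_cmodel1,
    fit_cmodel2,
    summarize_models,
)
from .preprocess import (
    PreprocessConfig,
    bandpass_zero_phase,
    extract_segment,
    time_derivative,
    zscore,
)
from .signal_io import SubjectRecording, iter_cohort, load_manifest

logger = logging.getLogger("respcoupling")

#: Fixed per-subject CSV column order, for diff-based regression testing.
PER_SUBJECT_COLUMNS = [
    "subject_id",
    "n_samples",
    "lag_ms",
    "peak_corr",
    "mi_nats",
    "is_outlier",
    "b0",
    "b1",
    "b2",
    "r2_m1",
    "r2_m2",
    "aicc_m1",
    "aicc_m2",
    "delta_aicc",
    "winner",
]


@dataclass
class RunConfig:
    """Everything one analysis run needs."""

    manifest_path: str = ""
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    max_lag_s: float = 10.0
    mi_bins: int = 16
    mi_base: float | None = None  # None = nats
    out_dir: str | None = None
    log_level: str = "INFO"


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML.

    Recognized keys: ``manifest``, ``preprocess`` (low_cut, high_cut,
    filter_order, segment_seconds), ``coupling`` (max_lag_s, mi_bins,
    mi_base), ``out_dir``, ``log_level``. Relative paths resolve against
    the config file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pp = raw.get("preprocess") or {}
    coupling = raw.get("coupling") or {}
    manifest = raw.get("manifest", "")
    if manifest and not Path(manifest).is_absolute():
        manifest = str(path.parent / manifest)
    out_dir = raw.get("out_dir")
    if out_dir and not Path(out_dir).is_absolute():
        out_dir = str(path.parent / out_dir)
    return RunConfig(
        manifest_path=manifest,
        preprocess=PreprocessConfig(**pp),
        max_lag_s=float(coupling.get("max_lag_s", 10.0)),
        mi_bins=int(coupling.get("mi_bins", 16)),
        mi_base=coupling.get("mi_base"),
        out_dir=out_dir,
        log_level=str(raw.get("log_level", "INFO")),
    )


@dataclass(frozen=True)
class SubjectAnalysis:
    """All per-subject outputs of one pipeline pass."""

    coupling: CouplingResult
    fit1: ModelFit
    fit2: ModelFit
    comparison: ModelComparison


def analyze_subject(recording: SubjectRecording, config: RunConfig) -> SubjectAnalysis:
    """Run the full per-subject analysis on one recording."""
    pp = config.preprocess

    def _prep(trace):
        segment = extract_segment(trace, pp)
        # a constant trace band-passed becomes numerical dust, not an
        # exact constant — reject it before it slips past the z-score check
        if np.ptp(segment.samples) == 0:
            raise DegenerateSignalError(
                f"trace {trace.label!r} is constant over the analysis segment"
            )
        return zscore(bandpass_zero_phase(segment, pp))

    rsp = _prep(recording.rsp)
    hr = _prep(recording.hr)
    drsp = time_derivative(rsp)

    lag = estimate_lag(rsp, hr, config.max_lag_s)
    mi = mutual_information(rsp, hr, config.mi_bins, config.mi_base)
    fit1 = fit_cmodel1(hr, rsp)
    fit2 = fit_cmodel2(hr, rsp, drsp)
    comparison = compare_models(fit1, fit2, recording.subject_id)
    result = CouplingResult(
        subject_id=recording.subject_id,
        lag_ms=lag.lag_ms,
        peak_corr=lag.peak_corr,
        mi=mi,
    )
    logger.info(
        "analyzed %s: lag=%.0f ms peak=%.3f mi=%.3f winner=%s",
        recording.subject_id,
        lag.lag_ms,
        lag.peak_corr,
        mi,
        comparison.winner,
    )
    return SubjectAnalysis(result, fit1, fit2, comparison)


def _to_row(a: SubjectAnalysis) -> dict:
    return {
        "subject_id": a.coupling.subject_id,
        "n_samples": a.fit1.n,
        "lag_ms": a.coupling.lag_ms,
        "peak_corr": a.coupling.peak_corr,
        "mi_nats": a.coupling.mi,
        "is_outlier": a.coupling.is_outlier,
        "b0": a.fit2.b0,
        "b1": a.fit2.b1,
        "b2": a.fit2.b2,
        "r2_m1": a.fit1.r2,
        "r2_m2": a.fit2.r2,
        "aicc_m1": a.comparison.aicc1,
        "aicc_m2": a.comparison.aicc2,
        "delta_aicc": a.comparison.delta_aicc,
        "winner": a.comparison.winner,
    }


def analyze_recordings(
    recordings: Iterable[SubjectRecording], config: RunConfig
) -> tuple[pd.DataFrame, CohortCouplingSummary, CohortModelSummary]:
    """Analyze a cohort of in-memory recordings.

    Returns the per-subject table (sorted by subject id, so manifest
    ordering does not matter) plus the coupling and model summaries.
    """
    analyses: list[SubjectAnalysis] = []
    n_seen = 0
    for recording in recordings:
        n_seen += 1
        try:
            analyses.append(analyze_subject(recording, config))
        except RespCouplingError as exc:
            logger.warning("skipping %s: %s", recording.subject_id, exc)
    if n_seen == 0:
        raise SummaryError("no subjects to analyze")
    if len(analyses) * 2 <= n_seen:
        raise SummaryError(
            f"{n_seen - len(analyses)} of {n_seen} subjects failed; aborting run"
        )
    analyses.sort(key=lambda a: a.coupling.subject_id)

    mask = flag_outliers([a.coupling.lag_ms for a in analyses])
    results = []
    for a, flagged in zip(analyses, mask):
        result = CouplingResult(
            a.coupling.subject_id,
            a.coupling.lag_ms,
            a.coupling.peak_corr,
            a.coupling.mi,
            is_outlier=bool(flagged),
        )
        if flagged:
            logger.warning(
                "subject %s flagged as lag outlier (lag %.0f ms, peak %.3f)",
                result.subject_id,
                result.lag_ms,
                result.peak_corr,
            )
        results.append(result)
    analyses = [
        SubjectAnalysis(res, a.fit1, a.fit2, a.comparison)
        for res, a in zip(results, analyses)
    ]

    table = pd.DataFrame([_to_row(a) for a in analyses])[PER_SUBJECT_COLUMNS]
    coupling_summary = summarize_coupling(results)
    model_summary = summarize_models(
        [a.comparison for a in analyses], [a.fit2 for a in analyses]
    )
    return table, coupling_summary, model_summary


def summaries_to_dict(
    coupling_summary: CohortCouplingSummary, model_summary: CohortModelSummary
) -> dict:
    return {
        "coupling": {
            "n_total": coupling_summary.n_total,
            "n_excluded": coupling_summary.n_excluded,
            "lag_mean_ms": coupling_summary.lag_mean_ms,
            "lag_sd_ms": coupling_summary.lag_sd_ms,
            "mi_mean": coupling_summary.mi_mean,
            "mi_sd": coupling_summary.mi_sd,
            "corr_mi_vs_peak": coupling_summary.corr_mi_vs_peak,
            "corr_mi_vs_peak_p": coupling_summary.corr_mi_vs_peak_p,
        },
        "models": {
            "n_subjects": model_summary.n_subjects,
            "n_cmodel2_wins": model_summary.n_cmodel2_wins,
            "n_b1_positive": model_summary.n_b1_positive,
            "n_b2_negative": model_summary.n_b2_negative,
        },
    }


def write_outputs(
    out_dir: str | Path,
    table: pd.DataFrame,
    coupling_summary: CohortCouplingSummary,
    model_summary: CohortModelSummary,
) -> None:
    """Write ``per_subject.csv`` and ``summary.json`` deterministically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "per_subject.csv", index=False, float_format="%.10g")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(
            summaries_to_dict(coupling_summary, model_summary),
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def analyze_cohort(
    config: RunConfig,
) -> tuple[pd.DataFrame, CohortCouplingSummary, CohortModelSummary]:
    """Load the manifest cohort, analyze it, and write outputs if asked."""
    manifest = load_manifest(config.manifest_path)
    log_handler = None
    if config.out_dir:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(Path(config.out_dir) / "run.log", mode="w")
        log_handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(log_handler)
        logger.setLevel(config.log_level)
    try:
        table, coupling_summary, model_summary = analyze_recordings(
            iter_cohort(manifest), config
        )
    finally:
        if log_handler is not None:
            logger.removeHandler(log_handler)
            log_handler.close()
    if config.out_dir:
        write_outputs(config.out_dir, table, coupling_summary, model_summary)
    return table, coupling_summary, model_summary
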