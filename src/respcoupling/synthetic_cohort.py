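"""Synthetic resting cohort generator.

Generates a cohort of simulated subjects with the statistical structure
the analysis pipeline assumes: 3-minute paired RSP/HR recordings at
1000 Hz, breath rates drawn uniformly from the resting range
0.15-0.30 Hz, RSP->HR delays drawn from N(849.21, 344.84^2) ms truncated
positive, and HR built by the delay-plus-gain-weighted-derivative
mechanism of :mod:`respcoupling.rsa_simulator`. Measurement noise is
white Gaussian added to the HR trace before the pipeline's band-pass, so
the analyzed noise is band-limited like real measurement noise.

Optionally, ``n_outliers`` subjects receive an HR trace that is
independent band-passed noise (0.1-1 Hz): such subjects show a large
spurious lag and a low peak correlation, emulating recordings in which
the two signals are not actually coupled.

Per-subject randomness derives deterministically from ``master_seed``
via ``numpy.random.SeedSequence`` spawning, so a cohort is reproducible
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import PreprocessConfig, bandpass_zero_phase, zscore
from .rsa_simulator import SimulationParams, generate_rsp, simulate_hr
from .signal_io import (
    DEFAULT_COLUMNS,
    CohortManifest,
    SignalTrace,
    SubjectRecording,
    save_manifest,
    write_recording,
)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the resting-study conditions: 45 subjects,
    180 s at 1000 Hz, delays near 849 +- 345 ms, unit signal gain and a
    negative derivative gain whose magnitude keeps
    ``|gain2| * 2*pi*breath_rate >= 0.3`` even at the slowest breath rate,
    so the derivative term is identifiable for every subject.
    """

    n_subjects: int = 45
    duration: float = 180.0
    fs: float = 1000.0
    breath_rate_range: tuple[float, float] = (0.15, 0.30)
    delay_mean_ms: float = 849.21
    delay_sd_ms: float = 344.84
    gain1: float = 1.0
    gain2_range: tuple[float, float] = (-0.6, -0.35)
    gain3_range: tuple[float, float] = (1.0, 1.0)
    asymmetry: float = 0.4
    smooth_seconds: float = 0.5
    noise_sd: float = 0.2
    n_outliers: int = 0
    master_seed: int = 7
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 0 <= self.n_outliers < self.n_subjects:
            raise ConfigError(
                f"n_outliers must lie in [0, n_subjects), got {self.n_outliers}"
            )
        lo, hi = self.breath_rate_range
        if not 0.05 <= lo <= hi <= 0.5:
            raise ConfigError(
                f"breath_rate_range must lie within [0.05, 0.5], got {self.breath_rate_range}"
            )
        if self.delay_sd_ms < 0 or self.delay_mean_ms <= 0:
            raise ConfigError("delay distribution must have positive mean, SD >= 0")

    def subject_ids(self) -> list[str]:
        width = max(3, len(str(self.n_subjects)))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_subjects)]


def _outlier_indices(spec: CohortSpec) -> np.ndarray:
    if spec.n_outliers == 0:
        return np.empty(0, dtype=int)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.master_seed, spawn_key=(0xA11,))
    )
    return np.sort(
        rng.choice(spec.n_subjects, size=spec.n_outliers, replace=False)
    )


def _draw_subject(spec: CohortSpec, index: int) -> dict:
    """Deterministic per-subject parameter draw."""
    seq = np.random.SeedSequence(spec.master_seed, spawn_key=(index,))
    param_seq, noise_seq = seq.spawn(2)
    rng = np.random.default_rng(param_seq)
    breath = float(rng.uniform(*spec.breath_rate_range))
    delay = -1.0
    for _ in range(1000):
        delay = float(rng.normal(spec.delay_mean_ms, spec.delay_sd_ms))
        if 0 < delay < spec.duration * 250.0:
            break
    else:  # pragma: no cover - delay SD would have to dwarf the mean
        raise ConfigError("could not draw a positive delay; check delay parameters")
    gain2 = float(rng.uniform(*spec.gain2_range))
    gain3 = float(rng.uniform(*spec.gain3_range))
    sim_seed = int(noise_seq.generate_state(1)[0] % (2**31))
    # injected delay after rounding (half up) to the sample grid,
    # matching apply_delay's quantization
    delay_realized = math.floor(delay * spec.fs / 1000.0 + 0.5) * 1000.0 / spec.fs
    return {
        "subject_index": index,
        "breath_rate_hz": breath,
        "delay_drawn_ms": delay,
        "delay_ms": delay_realized,
        "gain1": spec.gain1,
        "gain2": gain2,
        "gain3": gain3,
        "noise_sd": spec.noise_sd,
        "sim_seed": sim_seed,
    }


def _simulation_params(spec: CohortSpec, draw: dict) -> SimulationParams:
    return SimulationParams(
        duration=spec.duration,
        fs=spec.fs,
        breath_rate=draw["breath_rate_hz"],
        asymmetry=spec.asymmetry,
        smooth_seconds=spec.smooth_seconds,
        delay_ms=draw["delay_drawn_ms"],
        gain1=draw["gain1"],
        gain2=draw["gain2"],
        gain3=draw["gain3"],
        noise_sd=spec.noise_sd,
        seed=draw["sim_seed"],
    )


def _outlier_hr(spec: CohortSpec, draw: dict, n: int) -> SignalTrace:
    """Independent band-limited noise standing in for an uncoupled HR."""
    rng = np.random.default_rng(draw["sim_seed"])
    white = SignalTrace(rng.standard_normal(n), spec.fs, "HR")
    return zscore(bandpass_zero_phase(white, spec.preprocess))


def make_recording(spec: CohortSpec, index: int) -> tuple[SubjectRecording, dict]:
    """Build one subject: recording plus its ground-truth parameter row."""
    draw = _draw_subject(spec, index)
    subject_id = spec.subject_ids()[index]
    is_outlier = index in set(_outlier_indices(spec))
    params = _simulation_params(spec, draw)
    rsp = generate_rsp(params)
    if is_outlier:
        hr = _outlier_hr(spec, draw, len(rsp))
    else:
        _, hr = simulate_hr(rsp, params)
    draw["subject_id"] = subject_id
    draw["is_outlier"] = is_outlier
    return SubjectRecording(subject_id, rsp, hr.with_samples(hr.samples, "HR")), draw


def iter_recordings(spec: CohortSpec):
    """Yield ``(SubjectRecording, truth_row)`` for every subject, in order."""
    for index in range(spec.n_subjects):
        yield make_recording(spec, index)


def cohort_truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Ground-truth per-subject parameters, without re-simulating traces."""
    outliers = set(_outlier_indices(spec))
    rows = []
    for index, subject_id in enumerate(spec.subject_ids()):
        draw = _draw_subject(spec, index)
        draw["subject_id"] = subject_id
        draw["is_outlier"] = index in outliers
        rows.append(draw)
    columns = [
        "subject_id",
        "breath_rate_hz",
        "delay_ms",
        "delay_drawn_ms",
        "gain1",
        "gain2",
        "gain3",
        "noise_sd",
        "sim_seed",
        "is_outlier",
    ]
    return pd.DataFrame(rows)[columns]


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortManifest:
    """Write one trace file per subject plus ``manifest.yaml`` and
    ``truth.csv`` (synthetic ground truth); returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects: dict[str, str] = {}
    for recording, _ in iter_recordings(spec):
        filename = f"{recording.subject_id}.csv"
        write_recording(recording, out_dir / filename)
        subjects[recording.subject_id] = filename
    manifest = CohortManifest(
        subjects=subjects,
        sampling_rate=spec.fs,
        columns=dict(DEFAULT_COLUMNS),
        base_dir=out_dir,
    )
    save_manifest(manifest, out_dir / "manifest.yaml")
    cohort_truth_table(spec).to_csv(
        out_dir / "truth.csv", index=False, float_format="%.10g"
    )
    return manifest
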