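"""Trace-file and cohort-manifest I/O.

A recording is stored as delimited text (comma or tab) with a header row.
The canonical layout written by this package is ``t,rsp,hr`` with time in
seconds, but arbitrary column names can be mapped through the manifest.
The manifest's sampling rate is authoritative; a time column, when
present, is only validated against it (within 1 %) and then discarded.

Time convention: sample ``i`` of a trace lives at ``t = i / sampling_rate``
seconds, 0-based.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    PairingError,
    SamplingRateError,
    TraceFormatError,
    TraceLengthError,
    TraceParseError,
)

logger = logging.getLogger("respcoupling")

#: Relative tolerance on time-column spacing vs 1/sampling_rate.
TIME_SPACING_RTOL = 0.01


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled 1-D physiological signal.

    Parameters
    ----------
    samples
        Signal values (arbitrary units, or z-units after standardization).
    sampling_rate
        Sampling rate in Hz; must be positive.
    label
        Free-text label such as ``"RSP"`` or ``"HR"``.
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise TraceFormatError("trace samples must be one-dimensional")
        if samples.size < 2:
            raise TraceLengthError(
                f"trace needs at least 2 samples, got {samples.size}"
            )
        if not self.sampling_rate > 0:
            raise SamplingRateError(
                f"sampling rate must be positive, got {self.sampling_rate}"
            )
        if not np.all(np.isfinite(samples)):
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise TraceParseError(
                f"trace {self.label!r} contains a non-finite value at sample {bad}"
            )

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n / fs)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds, ``i / sampling_rate``."""
        return np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "SignalTrace":
        """Return a new trace sharing this trace's rate."""
        return SignalTrace(samples, self.sampling_rate, self.label if label is None else label)


@dataclass(frozen=True)
class SubjectRecording:
    """Paired RSP and HR traces for one subject."""

    subject_id: str
    rsp: SignalTrace
    hr: SignalTrace

    def __post_init__(self) -> None:
        if len(self.rsp) != len(self.hr):
            raise PairingError(
                f"subject {self.subject_id}: RSP has {len(self.rsp)} samples "
                f"but HR has {len(self.hr)}"
            )
        if self.rsp.sampling_rate != self.hr.sampling_rate:
            raise PairingError(
                f"subject {self.subject_id}: RSP at {self.rsp.sampling_rate} Hz "
                f"but HR at {self.hr.sampling_rate} Hz"
            )

    @property
    def sampling_rate(self) -> float:
        return self.rsp.sampling_rate


DEFAULT_COLUMNS = {"time": "t", "rsp": "rsp", "hr": "hr"}


@dataclass
class CohortManifest:
    """Maps subject ids to trace files and carries the column layout.

    ``subjects`` maps subject_id -> file path (relative paths are resolved
    against ``base_dir``). ``columns`` names the time/rsp/hr columns; the
    time entry may be ``None`` when files carry no time column.
    """

    subjects: dict[str, str]
    sampling_rate: float
    columns: dict[str, str | None] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if not self.subjects:
            raise TraceFormatError("manifest lists no subjects")
        if len(set(self.subjects)) != len(self.subjects):  # dict keys already unique
            raise TraceFormatError("duplicate subject ids in manifest")
        if not self.sampling_rate > 0:
            raise SamplingRateError(
                f"manifest sampling rate must be positive, got {self.sampling_rate}"
            )
        for key in ("rsp", "hr"):
            if not self.columns.get(key):
                raise TraceFormatError(f"manifest column mapping lacks {key!r}")

    def path_for(self, subject_id: str) -> Path:
        return Path(self.base_dir) / self.subjects[subject_id]


def load_manifest(path: str | Path) -> CohortManifest:
    """Load a YAML (or JSON, a YAML subset) cohort manifest."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "subjects" not in raw:
        raise TraceFormatError(f"{path}: manifest must be a mapping with a 'subjects' key")
    columns = dict(DEFAULT_COLUMNS)
    columns.update(raw.get("columns") or {})
    return CohortManifest(
        subjects={str(k): str(v) for k, v in raw["subjects"].items()},
        sampling_rate=float(raw["sampling_rate"]),
        columns=columns,
        base_dir=path.parent,
    )


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "subjects": dict(manifest.subjects),
        "sampling_rate": float(manifest.sampling_rate),
        "columns": {k: v for k, v in manifest.columns.items() if v},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def _numeric_column(df: pd.DataFrame, name: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1  # 1-based data row, header excluded
        raise TraceParseError(
            f"{path}: column {name!r} has a non-numeric or non-finite value at row {row}"
        )
    return values


def read_recording(
    path: str | Path,
    manifest: CohortManifest,
    subject_id: str | None = None,
) -> SubjectRecording:
    """Read one subject's paired traces from a delimited text file.

    The delimiter is auto-detected between comma and tab; a header row is
    required. If the manifest maps a time column and the file has it, its
    spacing is checked against ``1/sampling_rate`` (1 % relative tolerance)
    and then discarded.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = manifest.columns
    for key in ("rsp", "hr"):
        if cols[key] not in df.columns:
            raise TraceFormatError(
                f"{path}: required column {cols[key]!r} ({key}) not found; "
                f"file has {list(df.columns)}"
            )
    if len(df) < 2:
        raise TraceLengthError(f"{path}: needs at least 2 data rows, got {len(df)}")

    fs = manifest.sampling_rate
    time_col = cols.get("time")
    if time_col and time_col in df.columns:
        t = _numeric_column(df, time_col, path)
        dt = np.diff(t)
        expected = 1.0 / fs
        if np.any(np.abs(dt - expected) > TIME_SPACING_RTOL * expected):
            raise SamplingRateError(
                f"{path}: time spacing {np.median(dt):g} s disagrees with "
                f"1/fs = {expected:g} s (fs = {fs:g} Hz from manifest)"
            )

    sid = subject_id if subject_id is not None else path.stem
    rsp = SignalTrace(_numeric_column(df, cols["rsp"], path), fs, "RSP")
    hr = SignalTrace(_numeric_column(df, cols["hr"], path), fs, "HR")
    logger.info("loaded %s: n=%d fs=%g Hz", sid, len(rsp), fs)
    return SubjectRecording(sid, rsp, hr)


def write_recording(recording: SubjectRecording, path: str | Path) -> Path:
    """Write a recording as ``t,rsp,hr`` CSV, losslessly round-trippable.

    Values are written with 17 significant digits so that
    ``read_recording(write_recording(x))`` reproduces the samples to well
    within 1e-9 relative tolerance.
    """
    path = Path(path)
    n = len(recording.rsp)
    fs = recording.sampling_rate
    df = pd.DataFrame(
        {
            "t": np.arange(n) / fs,
            "rsp": recording.rsp.samples,
            "hr": recording.hr.samples,
        }
    )
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise TraceFormatError(f"cannot write {path}: {exc}") from exc
    return path


def iter_cohort(manifest: CohortManifest):
    """Yield ``SubjectRecording`` objects for every manifest entry."""
    for subject_id in manifest.subjects:
        yield read_recording(manifest.path_for(subject_id), manifest, subject_id)
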