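"""Simulator of the respiration -> heart-rate gain model.

The simulator builds, in order: (i) a quasi-periodic respiration trace
RSP(t) as an asymmetric, smoothed triangular wave (inspiration = rising
ramp, expiration = falling ramp); (ii) a *delayed* HR as a pure time
shift of RSP, standing for the physiological conduction delay; (iii) the
time derivative of the delayed trace; and (iv) an *advanced* HR

    advanced_HR(t) = gain3 * (gain1 * delayed(t) + gain2 * d(delayed)/dt) + noise,

the direct generative counterpart of the two-regressor HR model. For a
sinusoid of angular frequency ``omega``, the gain-weighted sum is an
exact phase shift:

    a sin(w(t-d)) + b w cos(w(t-d)) = A sin(w(t-d) + psi),
    psi = atan2(b*w, a),

so the effective RSP->HR lag is ``d - psi/omega``: raising gain2 advances
the simulated HR back toward RSP. ``sinusoid_lag_oracle`` returns this
closed form and is the analytic reference the measured lag is tested
against. gain2 carries units of seconds so the derivative term is
commensurate with the signal term; gain1 and gain3 are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .preprocess import time_derivative
from .signal_io import SignalTrace


@dataclass(frozen=True)
class SimulationParams:
    """Waveform, delay, gains and noise for one simulated subject."""

    duration: float = 180.0
    fs: float = 1000.0
    breath_rate: float = 0.25
    asymmetry: float = 0.4
    smooth_seconds: float = 0.5
    delay_ms: float = 850.0
    gain1: float = 1.0
    gain2: float = -0.4
    gain3: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigError("duration and fs must be positive")
        if not 0.05 <= self.breath_rate <= 0.5:
            raise ConfigError(
                f"breath_rate must lie in [0.05, 0.5] Hz, got {self.breath_rate}"
            )
        if not 0 < self.asymmetry < 1:
            raise ConfigError(f"asymmetry must lie in (0, 1), got {self.asymmetry}")
        if self.smooth_seconds < 0 or self.smooth_seconds >= 0.5 / self.breath_rate:
            raise ConfigError(
                f"smoothing window {self.smooth_seconds} s must be shorter than "
                f"half a breath period ({0.5 / self.breath_rate:g} s)"
            )
        if not 0 <= self.delay_ms < self.duration * 250.0:
            raise ConfigError(
                f"delay {self.delay_ms} ms must be non-negative and below a "
                f"quarter of the duration ({self.duration * 250.0:g} ms)"
            )
        if self.gain3 <= 0:
            raise ConfigError(f"gain3 must be positive, got {self.gain3}")
        if self.gain1 == 0 and self.gain2 == 0:
            raise ConfigError("gain1 and gain2 cannot both be zero")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def period_s(self) -> float:
        return 1.0 / self.breath_rate


def _smooth_window(params: SimulationParams) -> int:
    """Moving-average width in samples, forced odd so it is centered."""
    k = int(round(params.smooth_seconds * params.fs))
    if k <= 1:
        return 1
    return k + 1 if k % 2 == 0 else k


def generate_rsp(params: SimulationParams) -> SignalTrace:
    """Asymmetric smoothed triangular respiration trace, z-scored.

    The rising (inspiratory) ramp occupies ``asymmetry`` of each cycle.
    Smoothing is a centered moving average evaluated on an extended time
    grid, so there is no edge distortion; the result is deterministic in
    the parameters.
    """
    n = params.n_samples
    k = _smooth_window(params)
    half = (k - 1) // 2
    t = (np.arange(-half, n + half)) / params.fs
    wave = sps.sawtooth(2 * np.pi * params.breath_rate * t, width=params.asymmetry)
    if k > 1:
        wave = np.convolve(wave, np.full(k, 1.0 / k), mode="valid")
    wave = (wave - wave.mean()) / wave.std(ddof=1)
    return SignalTrace(wave, params.fs, "RSP")


def generate_sinusoidal_rsp(params: SimulationParams) -> SignalTrace:
    """Pure sinusoid at the breath rate: the smooth limit of the waveform,
    used for closed-form lag checks."""
    t = np.arange(params.n_samples) / params.fs
    return SignalTrace(
        np.sin(2 * np.pi * params.breath_rate * t), params.fs, "RSP"
    )


def apply_delay(
    trace: SignalTrace,
    delay_ms: float,
    *,
    period_s: float | None = None,
    fill: str = "periodic",
) -> SignalTrace:
    """Shift a trace later in time by ``delay_ms``.

    The delay is rounded (half up) to an integer number of samples ``d``;
    ``out[i] = in[i - d]`` for ``i >= d``. The first ``d`` samples are
    filled by periodic extension: one cycle of length ``period_s`` wrapped
    around (the whole trace when no period is given), so no edge
    transient enters downstream lag estimation. ``fill="zero"`` pads with
    zeros instead.
    """
    fs = trace.sampling_rate
    n = len(trace)
    if delay_ms < 0:
        raise ConfigError(f"delay must be >= 0 ms, got {delay_ms}")
    d = int(math.floor(delay_ms * fs / 1000.0 + 0.5))
    if d > n // 4:
        raise ConfigError(
            f"delay of {d} samples exceeds a quarter of the trace ({n} samples)"
        )
    if d == 0:
        return trace.with_samples(trace.samples.copy())
    out = np.empty(n)
    out[d:] = trace.samples[: n - d]
    if fill == "zero":
        out[:d] = 0.0
    elif fill == "periodic":
        period = n if period_s is None else int(round(period_s * fs))
        if not 0 < period <= n:
            raise ConfigError(
                f"period of {period} samples must lie in (0, {n}]"
            )
        out[:d] = trace.samples[(np.arange(d) - d) % period]
    else:
        raise ConfigError(f"unknown fill mode {fill!r}")
    return trace.with_samples(out)


def simulate_hr(
    rsp: SignalTrace, params: SimulationParams
) -> tuple[SignalTrace, SignalTrace]:
    """Delayed and advanced HR traces from a respiration trace.

    The derivative in the gain2 term is taken on the *delayed* trace, so
    that the term advances the delayed signal back toward RSP. Gaussian
    noise of SD ``noise_sd`` (seeded) is added to the advanced trace only.
    """
    delayed = apply_delay(rsp, params.delay_ms, period_s=params.period_s)
    deriv = time_derivative(delayed)
    advanced = params.gain3 * (
        params.gain1 * delayed.samples + params.gain2 * deriv.samples
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        advanced = advanced + rng.normal(0.0, params.noise_sd, advanced.size)
    return (
        delayed.with_samples(delayed.samples, "HR_delayed"),
        delayed.with_samples(advanced, "HR_advanced"),
    )


def sinusoid_lag_oracle(
    gain1: float, gain2: float, omega: float, delay_s: float
) -> float:
    """Closed-form effective RSP->HR lag (seconds) for sinusoidal RSP.

    ``delay_s - atan2(gain2 * omega, gain1) / omega``: the delay minus
    the phase advance contributed by the derivative term.
    """
    if omega <= 0:
        raise ConfigError(f"omega must be positive, got {omega}")
    if gain1 == 0 and gain2 == 0:
        raise ConfigError("gain1 and gain2 cannot both be zero")
    return delay_s - math.atan2(gain2 * omega, gain1) / omega


def trajectory_area(x: SignalTrace, y: SignalTrace) -> float:
    """Shoelace area of the closed (x, y) trajectory.

    Plotting RSP against a phase-shifted HR traces a loop; the enclosed
    area (summed signed area of the polygon, absolute value) shrinks to
    ~0 as the effective lag approaches zero and the loop collapses to a
    line. Used to quantify trajectory closure.
    """
    xs, ys = x.samples, y.samples
    return float(
        0.5 * abs(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))
    )


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    """Copy of the parameters with a different noise seed."""
    return replace(params, seed=seed)
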