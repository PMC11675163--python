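"""Continuous linear models of HR from RSP, compared per subject by AICc.

Two nested ordinary-least-squares models are fitted to every subject's
filtered, z-scored traces, sample by sample over the whole segment:

    model 1:  HRm(t) = b0 + b1 * RSP(t)
    model 2:  HRm(t) = b0 + b1 * RSP(t) + b2 * dRSP/dt

The derivative term lets a linear model absorb the RSP->HR phase lag:
for a quasi-sinusoidal RSP, a weighted sum of the signal and its
derivative is a phase-shifted copy, so model 2 can align the prediction
with HR where model 1 cannot. Model comparison uses the corrected
Akaike criterion under a Gaussian likelihood,

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1),

with k counting the intercept, slopes and the noise variance (k = 3 and
4). Fits use every sample of the traces; residual autocorrelation is
acknowledged, so coefficient point estimates and AICc ranks are reported
but classical p-values are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, PairingError, RankError
from .signal_io import SignalTrace

CMODEL1 = "cmodel1"
CMODEL2 = "cmodel2"


@dataclass(frozen=True)
class ModelFit:
    """OLS fit of one model for one subject.

    ``k`` counts estimated parameters including the noise variance, so
    k = 3 for model 1 and k = 4 for model 2.
    """

    model_id: str
    b0: float
    b1: float
    b2: float | None
    rss: float
    r2: float
    n: int
    k: int


@dataclass(frozen=True)
class ModelComparison:
    subject_id: str
    aicc1: float
    aicc2: float
    winner: str

    @property
    def delta_aicc(self) -> float:
        """AICc(model 1) - AICc(model 2); positive favours model 2."""
        return self.aicc1 - self.aicc2


@dataclass(frozen=True)
class CohortModelSummary:
    n_subjects: int
    n_cmodel2_wins: int
    n_b1_positive: int
    n_b2_negative: int


def _ols(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares fit; returns (coefficients, rss, r2)."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise RankError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]})"
        )
    resid = y - design @ coef
    rss = float(resid @ resid)
    centered = y - y.mean()
    tss = float(centered @ centered)
    if tss == 0:
        raise RankError("response is constant; R^2 undefined")
    return coef, rss, 1.0 - rss / tss


def _check_lengths(*traces: SignalTrace, min_n: int = 10) -> int:
    n = len(traces[0])
    for t in traces[1:]:
        if len(t) != n:
            raise PairingError(f"regression traces differ in length: {n} vs {len(t)}")
    if n < min_n:
        raise PairingError(f"regression needs >= {min_n} samples, got {n}")
    return n


def fit_cmodel1(hr: SignalTrace, rsp: SignalTrace) -> ModelFit:
    """OLS of HR on an intercept and RSP."""
    n = _check_lengths(hr, rsp)
    design = np.column_stack([np.ones(n), rsp.samples])
    coef, rss, r2 = _ols(hr.samples, design)
    return ModelFit(CMODEL1, float(coef[0]), float(coef[1]), None, rss, r2, n, 3)


def fit_cmodel2(hr: SignalTrace, rsp: SignalTrace, drsp: SignalTrace) -> ModelFit:
    """OLS of HR on an intercept, RSP and dRSP/dt."""
    n = _check_lengths(hr, rsp, drsp)
    design = np.column_stack([np.ones(n), rsp.samples, drsp.samples])
    coef, rss, r2 = _ols(hr.samples, design)
    return ModelFit(
        CMODEL2, float(coef[0]), float(coef[1]), float(coef[2]), rss, r2, n, 4
    )


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected AIC under a Gaussian likelihood, constants dropped."""
    if n <= k + 1:
        raise ConfigError(f"AICc needs n > k + 1, got n={n}, k={k}")
    if rss <= 0:
        raise ConfigError(f"AICc needs rss > 0, got {rss}")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_models(
    fit1: ModelFit, fit2: ModelFit, subject_id: str = ""
) -> ModelComparison:
    """Declare the AICc winner between the two fits; ties go to model 1."""
    if fit1.n != fit2.n:
        raise PairingError(f"fits have different n: {fit1.n} vs {fit2.n}")
    if fit1.model_id != CMODEL1 or fit2.model_id != CMODEL2:
        raise PairingError(
            f"expected ({CMODEL1}, {CMODEL2}) fits, got "
            f"({fit1.model_id}, {fit2.model_id})"
        )
    a1 = aicc(fit1.rss, fit1.n, fit1.k)
    a2 = aicc(fit2.rss, fit2.n, fit2.k)
    winner = CMODEL2 if a2 < a1 else CMODEL1
    return ModelComparison(subject_id, a1, a2, winner)


def predict_hrm(
    fit: ModelFit, rsp: SignalTrace, drsp: SignalTrace | None = None
) -> SignalTrace:
    """Predicted HRm trace from a fitted model.

    Model 1 fits must be called without ``drsp``; model 2 fits require it.
    """
    if fit.model_id == CMODEL1:
        if drsp is not None:
            raise ConfigError("cmodel1 prediction takes no derivative trace")
        pred = fit.b0 + fit.b1 * rsp.samples
    elif fit.model_id == CMODEL2:
        if drsp is None:
            raise ConfigError("cmodel2 prediction requires the derivative trace")
        _check_lengths(rsp, drsp, min_n=2)
        pred = fit.b0 + fit.b1 * rsp.samples + fit.b2 * drsp.samples
    else:
        raise ConfigError(f"unknown model id {fit.model_id!r}")
    return rsp.with_samples(pred, "HRm")


def summarize_models(
    comparisons: Sequence[ModelComparison], fits2: Sequence[ModelFit]
) -> CohortModelSummary:
    """Cohort tallies: model-2 AICc wins, positive b1, negative b2.

    Slope tallies are taken from the model-2 fits, one per subject,
    aligned with ``comparisons``.
    """
    if not comparisons or len(comparisons) != len(fits2):
        raise PairingError(
            f"need one cmodel2 fit per comparison, got {len(comparisons)} "
            f"comparisons and {len(fits2)} fits"
        )
    for fit in fits2:
        if fit.model_id != CMODEL2:
            raise PairingError("slope tallies require cmodel2 fits")
    return CohortModelSummary(
        n_subjects=len(comparisons),
        n_cmodel2_wins=sum(c.winner == CMODEL2 for c in comparisons),
        n_b1_positive=sum(f.b1 > 0 for f in fits2),
        n_b2_negative=sum(f.b2 < 0 for f in fits2),
    )
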