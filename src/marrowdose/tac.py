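"""Time-activity-curve (TAC) models.

Sparse activity measurements of a source region (whole body, an organ, the
abdominal SPECT field of view, or a blood concentration series) are fitted
with mono- or bi-exponential washout models and integrated analytically from
injection (t = 0) to infinity to obtain time-integrated activities (TIA,
units of the samples times hours).

Conventions
-----------
* Times are hours post-injection; t = 0 is the injection.
* Measurements are effective (physical decay included, not decay-corrected),
  so the analytic integrals are effective time-integrated activities.
* Activities are Bq internally; blood series are concentrations in Bq/ml.

The mono-exponential fit is unweighted linear least squares on the
log-transformed values: exact for two points, deterministic, and standard
clinical practice for three-point whole-body series.  A weighted variant
(weights applied in log space) is available but off by default.

The bi-exponential fit is bounded non-linear least squares on the linear
scale, started from a small deterministic grid of half-life guesses, because
five-point bi-exponential fits are ill-conditioned and a single start is not
trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DomainError,
    FitFailureError,
    InsufficientDataError,
    NonIntegrableError,
    NonPhysicalKineticsError,
)

LN2 = math.log(2.0)

__all__ = [
    "ActivitySample",
    "MonoExpFit",
    "BiExpFit",
    "fit_monoexp",
    "fit_biexp",
    "integrate_to_infinity",
    "samples_from_arrays",
]


@dataclass(frozen=True)
class ActivitySample:
    """One measurement of a source region.

    Parameters
    ----------
    time : float
        Hours post-injection, strictly positive.
    value : float
        Activity (Bq) or activity concentration (Bq/ml), non-negative.
    kind : {"activity", "concentration"}
    """

    time: float
    value: float
    kind: Literal["activity", "concentration"] = "activity"

    def __post_init__(self):
        if not self.time > 0:
            raise DomainError(f"sample time must be > 0 h, got {self.time}")
        if self.value < 0:
            raise DomainError(f"sample value must be >= 0, got {self.value}")


def samples_from_arrays(
    times: Sequence[float],
    values: Sequence[float],
    kind: Literal["activity", "concentration"] = "activity",
) -> list[ActivitySample]:
    """Build a validated sample series from parallel arrays."""
    return [ActivitySample(float(t), float(v), kind) for t, v in zip(times, values)]


def _validate_series(samples: Sequence[ActivitySample]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([s.time for s in samples], dtype=float)
    a = np.asarray([s.value for s in samples], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DomainError("sample times must be strictly increasing")
    return t, a


@dataclass(frozen=True)
class MonoExpFit:
    """A(t) = amplitude_A0 * exp(-decay_lambda * t).

    ``half_life`` is ln(2)/decay_lambda; ``residual_norm`` is the Euclidean
    norm of the fit residuals (log space for the log-linear fitter).
    """

    amplitude_A0: float
    decay_lambda: float
    residual_norm: float = 0.0

    def __post_init__(self):
        if not self.decay_lambda > 0:
            raise NonPhysicalKineticsError(
                f"decay constant must be > 0, got {self.decay_lambda}",
                fitted_lambda=self.decay_lambda,
            )

    @property
    def half_life(self) -> float:
        return LN2 / self.decay_lambda

    def __call__(self, t) -> np.ndarray:
        return self.amplitude_A0 * np.exp(-self.decay_lambda * np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        return {
            "amplitude_A0": self.amplitude_A0,
            "decay_lambda": self.decay_lambda,
            "half_life": self.half_life,
            "residual_norm": self.residual_norm,
        }


@dataclass(frozen=True)
class BiExpFit:
    """A(t) = sum_i amplitudes[i] * exp(-decay_lambdas[i] * t), fast first.

    ``degenerate`` is set when one amplitude collapsed to (numerically) zero,
    i.e. the series is effectively mono-exponential.
    """

    amplitudes: tuple[float, float]
    decay_lambdas: tuple[float, float]
    residual_norm: float = 0.0
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self):
        if any(lam <= 0 for lam in self.decay_lambdas):
            raise NonPhysicalKineticsError(
                f"decay constants must be > 0, got {self.decay_lambdas}"
            )
        if self.decay_lambdas[0] < self.decay_lambdas[1]:
            raise DomainError("decay constants must be ordered fast to slow")
        if any(a < 0 for a in self.amplitudes):
            raise DomainError("amplitudes must be non-negative")

    @property
    def half_lives(self) -> tuple[float, float]:
        return (LN2 / self.decay_lambdas[0], LN2 / self.decay_lambdas[1])

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitudes[0] * np.exp(-self.decay_lambdas[0] * t) + self.amplitudes[
            1
        ] * np.exp(-self.decay_lambdas[1] * t)

    def to_dict(self) -> dict:
        return {
            "amplitudes": list(self.amplitudes),
            "decay_lambdas": list(self.decay_lambdas),
            "half_lives": list(self.half_lives),
            "residual_norm": self.residual_norm,
            "degenerate": self.degenerate,
        }


def fit_monoexp(
    samples: Sequence[ActivitySample],
    min_points: int = 3,
    weights: Sequence[float] | None = None,
) -> MonoExpFit:
    """Least-squares mono-exponential fit in log space.

    Ordinary (unweighted by default) least squares of ln(value) on time gives
    slope -lambda and intercept ln(A0); exact for two points.

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_points`` samples.
    NonPhysicalKineticsError
        The fitted decay constant is non-positive (series does not decay).
    DomainError
        Any sample value is zero (log undefined) or times not increasing.
    """
    if len(samples) < min_points:
        raise InsufficientDataError(
            f"mono-exponential fit needs >= {min_points} samples, got {len(samples)}"
        )
    t, a = _validate_series(samples)
    if np.any(a <= 0):
        raise DomainError("mono-exponential log fit requires strictly positive values")
    y = np.log(a)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape or np.any(w <= 0):
        raise DomainError("weights must be positive and match the sample count")
    # weighted linear LS: minimise sum w_i (y_i - (b0 + b1 t_i))^2
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    intercept, slope = beta
    lam = -slope
    # below ~1e-12/h (half-life ~ 10^11 h) the slope is floating-point noise
    if lam <= 1e-12:
        raise NonPhysicalKineticsError(
            f"fitted decay constant is non-positive ({lam:.4g}/h): series does not decay",
            fitted_lambda=float(lam),
        )
    resid = (y - X @ beta) * sw
    return MonoExpFit(
        amplitude_A0=float(math.exp(intercept)),
        decay_lambda=float(lam),
        residual_norm=float(np.linalg.norm(resid)),
    )


# deterministic start grid of (fast, slow) half-life guesses in hours
_BIEXP_START_HALF_LIVES = [
    (0.5, 20.0),
    (1.0, 30.0),
    (2.0, 50.0),
    (5.0, 80.0),
    (0.2, 10.0),
]
_DEGENERATE_AMPLITUDE_FRACTION = 1e-6


def fit_biexp(
    samples: Sequence[ActivitySample],
    early_cutoff_h: float = 2.0,
    late_cutoff_h: float = 24.0,
    max_nfev: int = 2000,
) -> BiExpFit:
    """Bounded non-linear least-squares bi-exponential fit on the linear scale.

    Requires at least four samples spanning an early phase (< ``early_cutoff_h``)
    and a late phase (>= ``late_cutoff_h``), the typical blood-sampling design.
    Multi-start over a fixed grid of half-life pairs; the best solution by
    residual norm wins.  A fit whose smaller amplitude is numerically zero is
    returned flagged ``degenerate`` rather than raised.
    """
    if len(samples) < 4:
        raise InsufficientDataError(
            f"bi-exponential fit needs >= 4 samples, got {len(samples)}"
        )
    t, a = _validate_series(samples)
    if not (np.any(t < early_cutoff_h) and np.any(t >= late_cutoff_h)):
        raise InsufficientDataError(
            "bi-exponential fit needs both an early (< "
            f"{early_cutoff_h} h) and a late (>= {late_cutoff_h} h) sample"
        )

    scale = float(np.max(a))
    if scale <= 0:
        raise DomainError("all-zero series cannot be fitted")
    an = a / scale

    def residuals(p):
        a1, a2, lam1, lam2 = p
        return a1 * np.exp(-lam1 * t) + a2 * np.exp(-lam2 * t) - an

    lo = np.array([0.0, 0.0, 1e-6, 1e-6])
    hi = np.array([np.inf, np.inf, 50.0, 50.0])
    best = None
    for hl_fast, hl_slow in _BIEXP_START_HALF_LIVES:
        p0 = np.array([0.7 * an[0], 0.3 * an[0], LN2 / hl_fast, LN2 / hl_slow])
        p0 = np.clip(p0, lo + 1e-9, None)
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi), max_nfev=max_nfev)
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError(
            "bi-exponential fit failed to converge from every start",
            best_residual=None if best is None else float(np.sqrt(2 * best.cost)),
        )

    a1, a2, lam1, lam2 = best.x
    # order fast-to-slow by decay constant
    if lam1 < lam2:
        a1, a2, lam1, lam2 = a2, a1, lam2, lam1
    total = a1 + a2
    degenerate = total > 0 and min(a1, a2) / total < _DEGENERATE_AMPLITUDE_FRACTION
    if degenerate and a1 / total < _DEGENERATE_AMPLITUDE_FRACTION:
        # fast component vanished: keep it at a harmless faster-than-slow rate
        lam1 = max(lam1, lam2)
    resid_norm = float(np.linalg.norm(residuals(best.x))) * scale
    return BiExpFit(
        amplitudes=(float(a1) * scale, float(a2) * scale),
        decay_lambdas=(float(lam1), float(lam2)),
        residual_norm=resid_norm,
        degenerate=bool(degenerate),
    )


def integrate_to_infinity(fit: MonoExpFit | BiExpFit) -> float:
    """Analytic time integral of the fitted curve over [0, inf).

    Mono-exponential: A0/lambda = A0 * T_half / ln 2.
    Bi-exponential:   sum_i amplitude_i / lambda_i.
    """
    if isinstance(fit, MonoExpFit):
        if fit.decay_lambda <= 0:
            raise NonIntegrableError("non-positive decay constant has no finite integral")
        return fit.amplitude_A0 / fit.decay_lambda
    if isinstance(fit, BiExpFit):
        if any(lam <= 0 for lam in fit.decay_lambdas):
            raise NonIntegrableError("non-positive decay constant has no finite integral")
        return sum(a / lam for a, lam in zip(fit.amplitudes, fit.decay_lambdas))
    raise TypeError(f"cannot integrate object of type {type(fit).__name__}")
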