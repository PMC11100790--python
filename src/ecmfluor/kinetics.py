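"""Pseudo-first-order binding kinetics of a reversible dye-substrate system.

When dye at concentration ``C`` (held in large excess over binding sites)
is added to a substrate, the field-of-view intensity approaches equilibrium
as a single exponential,

    I(t) = Imax * (1 - exp(-kobs * (t - t0))) + b        for t >= t0,
    I(t) = b                                             for t <  t0,

with observed rate ``kobs = kon * C + koff``.  Fitting a timelapse per
concentration and regressing ``kobs`` against ``C`` yields the association
rate ``kon`` (slope, M^-1 s^-1), the dissociation rate ``koff`` (intercept,
s^-1), and the apparent dissociation constant ``KD = koff / kon``.

The delay ``t0`` absorbs the arbitrary moment at which dye was added; the
model is clamped to the background ``b`` before it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "BindingTimelapse",
    "KineticsFit",
    "RateConstants",
    "NotIdentifiableError",
    "FitFailureError",
    "binding_model",
    "fit_binding_timelapse",
    "fit_rate_line",
    "dissociation_constant",
    "predict_kobs",
    "time_to_fraction",
]

KOBS_BOUNDS = (1e-7, 1.0)  # s^-1, physically plausible for hour-scale binding


class NotIdentifiableError(ValueError):
    """Raised when a trace carries no kinetic information (e.g. is flat)."""


class FitFailureError(RuntimeError):
    """Raised when the nonlinear fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class BindingTimelapse:
    """Mean field-of-view intensity versus time at one dye concentration."""

    times_s: np.ndarray
    intensities: np.ndarray
    concentration_M: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size < 8:
            raise ValueError("at least 8 samples are required")
        if np.any(t < 0) or not np.all(np.diff(t) > 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if self.concentration_M <= 0:
            raise ValueError("concentration must be positive")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class KineticsFit:
    """Per-timelapse saturation-model fit result."""

    imax: float
    kobs: float
    t0: float
    b: float
    imax_se: float
    kobs_se: float
    t0_se: float
    b_se: float
    residual_rms: float
    n: int
    kobs_ci95: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.kobs <= 0 or self.imax <= 0:
            raise ValueError("kobs and Imax must be positive")


@dataclass(frozen=True)
class RateConstants:
    """Association/dissociation rates and the derived dissociation constant.

    ``kd`` is stored redundantly and asserted to equal ``koff / kon``
    bit-for-bit; when the fitted intercept is nonpositive KD is undefined
    and ``kd_available`` is False.
    """

    kon: float  # M^-1 s^-1
    koff: float  # s^-1
    kd: float  # M
    kon_se: float
    koff_se: float
    kon_ci95: Tuple[float, float]
    koff_ci95: Tuple[float, float]
    kd_available: bool = True

    def __post_init__(self) -> None:
        if self.kon <= 0:
            raise ValueError("kon must be positive")
        if self.kd_available and self.kd != self.koff / self.kon:
            raise ValueError("stored KD must equal koff/kon exactly")


def binding_model(t, imax: float, kobs: float, t0: float, b: float):
    """Saturation model with the exponent clamped so ``I(t < t0) = b``."""
    dt = np.clip(np.asarray(t, dtype=float) - t0, 0.0, None)
    return imax * -np.expm1(-kobs * dt) + b


def _initial_guess(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    b0 = float(y.min())
    imax0 = float(y.max() - y.min())
    # log-linearized tail: ln(Imax0 + b0 - I) ~ const - kobs * t
    resid = imax0 + b0 - y
    usable = resid > 1e-3 * imax0
    kobs0 = 1.0 / max(t[-1] - t[0], 1.0)
    if usable.sum() >= 3:
        slope = np.polyfit(t[usable], np.log(resid[usable]), 1)[0]
        if slope < 0:
            kobs0 = -float(slope)
    kobs0 = float(np.clip(kobs0, KOBS_BOUNDS[0] * 10, KOBS_BOUNDS[1] / 10))
    above = np.nonzero(y > b0 + 0.05 * imax0)[0]
    t00 = float(t[above[0]]) if above.size else float(t[0])
    t00 = float(np.clip(t00, 0.0, t[-1] / 2))
    return imax0, kobs0, t00, b0


def fit_binding_timelapse(tl: BindingTimelapse) -> KineticsFit:
    """Nonlinear least-squares fit of ``(Imax, kobs, t0, b)`` to one timelapse.

    Deterministic multi-start: the rate guess from the log-linearized tail is
    tried at {0.3x, 1x, 3x}; the best (lowest residual RMS) converged fit is
    returned.  A flat trace raises ``NotIdentifiableError``; if no start
    converges a ``FitFailureError`` carrying diagnostics is raised.
    """
    t, y = tl.times_s, tl.intensities
    if np.ptp(y) < 1e-9 * max(abs(float(np.mean(y))), np.finfo(float).tiny):
        raise NotIdentifiableError("flat trace: intensity range < 1e-9 of mean")

    imax0, kobs0, t00, b0 = _initial_guess(t, y)
    lower = [1e-12, KOBS_BOUNDS[0], 0.0, -np.inf]
    upper = [np.inf, KOBS_BOUNDS[1], t[-1] / 2, np.inf]
    t00 = min(t00, t[-1] / 2)

    best = None
    failures = []
    for mult in (0.3, 1.0, 3.0):
        k_start = float(np.clip(mult * kobs0, KOBS_BOUNDS[0], KOBS_BOUNDS[1]))
        p0 = [max(imax0, 1e-9), k_start, t00, b0]
        try:
            popt, pcov = optimize.curve_fit(
                binding_model,
                t,
                y,
                p0=p0,
                bounds=(lower, upper),
                method="trf",
                x_scale="jac",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
            failures.append({"start": p0, "error": str(exc)})
            continue
        rms = float(np.sqrt(np.mean((binding_model(t, *popt) - y) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, popt, pcov)

    if best is None:
        raise FitFailureError(
            "binding fit did not converge from any start", {"failures": failures}
        )
    rms, popt, pcov = best

    n = t.size
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    se = np.where(np.isfinite(se), se, np.inf)
    tcrit = stats.t.ppf(0.975, max(n - 4, 1))
    kobs_ci = (float(popt[1] - tcrit * se[1]), float(popt[1] + tcrit * se[1]))
    return KineticsFit(
        imax=float(popt[0]),
        kobs=float(popt[1]),
        t0=float(popt[2]),
        b=float(popt[3]),
        imax_se=float(se[0]),
        kobs_se=float(se[1]),
        t0_se=float(se[2]),
        b_se=float(se[3]),
        residual_rms=rms,
        n=n,
        kobs_ci95=kobs_ci,
    )


def fit_rate_line(
    points: Sequence[Tuple[float, ...]],
) -> RateConstants:
    """Regress ``kobs`` against concentration: slope = kon, intercept = koff.

    ``points`` is a sequence of ``(concentration_M, kobs_per_s)`` or
    ``(concentration_M, kobs_per_s, weight)`` tuples.  With weights an
    inverse-variance-weighted least squares is used; otherwise ordinary
    least squares.  95% confidence intervals come from the t distribution
    on the regression standard errors.  A nonpositive intercept leaves KD
    undefined (``kd_available=False``) with a warning.
    """
    pts = [tuple(p) for p in points]
    if not pts:
        raise ValueError("no points given")
    conc = np.array([p[0] for p in pts], dtype=float)
    kobs = np.array([p[1] for p in pts], dtype=float)
    weights = None
    if any(len(p) > 2 for p in pts):
        weights = np.array([p[2] if len(p) > 2 else 1.0 for p in pts], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("at least 2 distinct concentrations are required")

    X = sm.add_constant(conc)
    model = sm.WLS(kobs, X, weights=weights) if weights is not None else sm.OLS(kobs, X)
    with warnings.catch_warnings():
        # a two-point fit has zero residual degrees of freedom; the line is
        # still exact, only the uncertainty columns degenerate to nan/inf
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit()
        koff, kon = (float(v) for v in res.params)
        koff_se, kon_se = (float(v) for v in res.bse)
        ci = np.asarray(res.conf_int(alpha=0.05), dtype=float)

    if kon <= 0:
        raise ValueError("fitted slope (kon) is nonpositive; no binding signal")
    kd_available = koff > 0
    if not kd_available:
        warnings.warn(
            "fitted intercept (koff) is nonpositive; KD undefined", RuntimeWarning
        )
    return RateConstants(
        kon=kon,
        koff=koff,
        kd=koff / kon if kd_available else math.nan,
        kon_se=kon_se,
        koff_se=koff_se,
        kon_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        koff_ci95=(float(ci[0, 0]), float(ci[0, 1])),
        kd_available=kd_available,
    )


def dissociation_constant(kon: float, koff: float) -> float:
    """``KD = koff / kon`` in molar."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    if koff < 0:
        raise ValueError("koff must be nonnegative")
    return koff / kon


def predict_kobs(rc: RateConstants, concentration_M: float) -> float:
    """Observed rate at a concentration: ``kon * C + koff``."""
    if concentration_M < 0:
        raise ValueError("concentration must be nonnegative")
    return rc.kon * concentration_M + rc.koff


def time_to_fraction(rc: RateConstants, concentration_M: float, fraction: float) -> float:
    """Delay-free time to reach a fraction of the equilibrium amplitude.

    ``t = -ln(1 - f) / kobs(C)``; e.g. ``f=0.5`` gives the half-rise time
    ``ln 2 / kobs``.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    return -math.log1p(-fraction) / predict_kobs(rc, concentration_M)
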