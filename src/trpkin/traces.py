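"""Kinetic-trace analysis: drift correction, Beer-Lambert conversions,
exponential decay fits, initial rates, and the radical quantum yield.

A trace is a time-stamped absorbance series at a probe wavelength (514 nm
for the neutral radical, 450 nm for the triplet). The analyses here convert
raw traces into physical quantities:

* a linear instrument drift (bounded at ~0.001 AU per 300 s) estimated on a
  light-off window and subtracted;
* absorbance -> concentration -> fractional radical population
  f = dA / (epsilon l [W48]_0);
* monoexponential decay constants (triplet lifetime tau_T, radical dark
  decay k_decay);
* initial formation rates and the radical quantum yield Phi_rad as the
  slope of radical formation rate versus excited-state formation rate
  across excitation powers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from lmfit.models import Model
from scipy import stats

from .errors import (
    BoundaryWarning,
    DataQualityWarning,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
)
from .photon import BeamSpec

#: Molar absorptivity of the neutral tryptophan radical at 514 nm, M^-1 cm^-1.
EPSILON_RADICAL_514 = 2200.0


@dataclass(frozen=True)
class KineticTrace:
    """Absorbance kinetic trace with probe and illumination metadata."""

    time_s: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float
    path_cm: float = 1.0
    label: str = ""
    light_on_s: float | None = None
    light_off_s: float | None = None
    beam: BeamSpec | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "absorbance", a)
        if t.shape != a.shape or t.ndim != 1:
            raise InvalidInputError("time and absorbance must be 1-d, same length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise InvalidInputError("trace contains non-finite values")
        if self.path_cm <= 0:
            raise InvalidInputError("path length must be > 0")

    def window(self, t0: float, t1: float) -> "KineticTrace":
        """Sub-trace with t0 <= t <= t1 (closed interval)."""
        mask = (self.time_s >= t0) & (self.time_s <= t1)
        return replace(self, time_s=self.time_s[mask], absorbance=self.absorbance[mask])

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class DecayFit:
    """Monoexponential fit A exp(-t/tau) (+ c), with standard errors."""

    amplitude: float
    tau_s: float
    offset: float
    stderr: dict[str, float]
    residual_rms: float
    window: tuple[float, float]

    @property
    def rate(self) -> float:
        return 1.0 / self.tau_s

    @property
    def rate_stderr(self) -> float:
        # first-order propagation of the tau standard error through 1/tau
        return self.stderr.get("tau_s", math.nan) / self.tau_s**2


@dataclass(frozen=True)
class YieldRegression:
    """Eq-1 regression: radical formation rate vs excited-state formation rate."""

    excited_rates: np.ndarray  # molecules s^-1
    radical_rates: np.ndarray  # molecules s^-1
    slope: float  # Phi_rad
    slope_stderr: float
    intercept: float  # 0.0 under the default through-origin policy
    through_origin: bool


def correct_drift(trace: KineticTrace, dark_window: tuple[float, float]) -> KineticTrace:
    """Subtract a linear baseline fitted on a light-off window.

    The drift line (slope and offset) is estimated by ordinary least squares
    on ``dark_window`` and subtracted from the entire trace; the input is
    left untouched.
    """
    sub = trace.window(*dark_window)
    if len(sub) < 10:
        raise InsufficientDataError(
            f"drift window {dark_window} holds {len(sub)} points; need >= 10"
        )
    slope, intercept = np.polyfit(sub.time_s, sub.absorbance, 1)
    corrected = trace.absorbance - (slope * trace.time_s + intercept)
    return replace(trace, absorbance=corrected)


def beer_lambert_conc(delta_abs: float, epsilon: float, path_cm: float) -> float:
    """Concentration (M) from an absorbance change: dA / (epsilon l)."""
    if epsilon <= 0 or path_cm <= 0:
        raise InvalidInputError("epsilon and path length must be > 0")
    return delta_abs / (epsilon * path_cm)


def radical_fraction(
    trace: KineticTrace,
    w48_total_M: float,
    epsilon_514: float = EPSILON_RADICAL_514,
    path_cm: float | None = None,
) -> np.ndarray:
    """Fractional radical population f(t) = dA(t) / (epsilon_514 l [W48]_0).

    Values outside [0, 1] are reported as-is with a data-quality warning
    (noise legitimately overshoots); nothing is clipped silently.
    """
    if w48_total_M <= 0:
        raise InvalidInputError("total W48 concentration must be > 0")
    path = trace.path_cm if path_cm is None else path_cm
    f = trace.absorbance / (epsilon_514 * path * w48_total_M)
    # routine noise dips slightly below zero around the baseline; only flag
    # physically meaningful violations
    bad = (f > 1.0) | (f < -0.05)
    if np.any(bad):
        warnings.warn(
            f"{bad.sum()} of {len(f)} fractional populations fall outside [0, 1] "
            f"(min {f.min():.3g}, max {f.max():.3g}); values reported unclipped",
            DataQualityWarning,
            stacklevel=2,
        )
    return f


def _monoexp(t, amplitude, tau, offset):
    return amplitude * np.exp(-t / tau) + offset


def fit_monoexponential(
    trace: KineticTrace,
    window: tuple[float, float] | None = None,
    with_offset: bool = False,
    tau_bounds: tuple[float, float] = (1e-6, 1e6),
) -> DecayFit:
    """Least-squares monoexponential decay fit over a window.

    The time origin is shifted to the window start, so ``amplitude`` is the
    signal at the start of the decay. Offsets are assumed pre-subtracted
    (the bench protocol removes the pre-light baseline); pass
    ``with_offset=True`` to float a constant.
    """
    sub = trace if window is None else trace.window(*window)
    if len(sub) < 10:
        raise InsufficientDataError(f"decay window holds {len(sub)} points; need >= 10")
    t = sub.time_s - sub.time_s[0]
    y = sub.absorbance
    if y[: max(3, len(y) // 10)].mean() < y[-max(3, len(y) // 10):].mean():
        warnings.warn(
            "window shows no decreasing trend; decay fit may be meaningless",
            DataQualityWarning,
            stacklevel=2,
        )

    model = Model(_monoexp)
    params = model.make_params(
        amplitude=max(float(y[0]), 1e-12),
        tau=max((t[-1] - t[0]) / 3.0, tau_bounds[0] * 10),
        offset=0.0,
    )
    params["tau"].min, params["tau"].max = tau_bounds
    params["offset"].vary = with_offset
    result = model.fit(y, params, t=t)
    if not result.success:
        raise FitFailureError(f"monoexponential fit failed: {result.message}")
    tau = float(result.params["tau"].value)
    if tau <= tau_bounds[0] * 1.001 or tau >= tau_bounds[1] * 0.999:
        warnings.warn(
            f"fitted tau = {tau:.3g} s sits on its bound {tau_bounds}",
            BoundaryWarning,
            stacklevel=2,
        )
    stderr = {
        "amplitude": float(result.params["amplitude"].stderr or math.nan),
        "tau_s": float(result.params["tau"].stderr or math.nan),
        "offset": float(result.params["offset"].stderr or 0.0),
    }
    win = (float(sub.time_s[0]), float(sub.time_s[-1]))
    return DecayFit(
        amplitude=float(result.params["amplitude"].value),
        tau_s=tau,
        offset=float(result.params["offset"].value),
        stderr=stderr,
        residual_rms=float(np.sqrt(np.mean(result.residual**2))),
        window=win,
    )


def initial_rate(
    trace: KineticTrace, window: tuple[float, float], model: str = "quadratic"
) -> tuple[float, float]:
    """Initial slope (AU s^-1) at the window start, with its standard error.

    Ordinary least squares on the window; the default fits a quadratic in
    time and reports the linear coefficient, i.e. the rate extrapolated to
    the window start. This removes most of the downward bias a straight-line
    slope picks up as radical formation slows over the window (for the
    canonical system a plain slope over 30 s runs ~30% low, the quadratic
    <5%). ``model="linear"`` gives the plain straight-line slope.
    """
    sub = trace.window(*window)
    if len(sub) < 5:
        raise InsufficientDataError(f"rate window holds {len(sub)} points; need >= 5")
    if model == "linear":
        res = stats.linregress(sub.time_s, sub.absorbance)
        return float(res.slope), float(res.stderr)
    if model != "quadratic":
        raise InvalidInputError(f"unknown initial-rate model {model!r}")
    t = sub.time_s - sub.time_s[0]
    X = np.column_stack([np.ones_like(t), t, t**2])
    coef, res_ss, *_ = np.linalg.lstsq(X, sub.absorbance, rcond=None)
    dof = max(len(t) - 3, 1)
    s2 = float(res_ss[0]) / dof if len(res_ss) else float(
        np.sum((sub.absorbance - X @ coef) ** 2)
    ) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(coef[1]), float(math.sqrt(cov[1, 1]))


def radical_quantum_yield(
    excited_rates: np.ndarray,
    radical_rates: np.ndarray,
    through_origin: bool = True,
) -> YieldRegression:
    """Radical quantum yield as the regression slope of formation rates.

    Both rates are molecule counts per second in the illuminated volume; the
    slope is dimensionless. The default regression is through the origin
    (zero excitation must give zero radical); the free-intercept mode is a
    diagnostic for offsets.
    """
    x = np.asarray(excited_rates, dtype=float)
    y = np.asarray(radical_rates, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InvalidInputError("need >= 2 paired rate points")
    if through_origin:
        sxx = float(np.dot(x, x))
        if sxx == 0.0:
            raise FitFailureError("all excited-state rates are zero")
        slope = float(np.dot(x, y)) / sxx
        resid = y - slope * x
        dof = max(len(x) - 1, 1)
        stderr = math.sqrt(float(np.dot(resid, resid)) / dof / sxx)
        intercept = 0.0
    else:
        if np.allclose(x, x[0]):
            raise FitFailureError("excited-state rates are degenerate")
        res = stats.linregress(x, y)
        slope, stderr, intercept = float(res.slope), float(res.stderr), float(res.intercept)
    return YieldRegression(
        excited_rates=x,
        radical_rates=y,
        slope=slope,
        slope_stderr=stderr,
        intercept=intercept,
        through_origin=through_origin,
    )
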