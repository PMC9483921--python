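"""Global least-squares fitting of the photocycle to multi-power radical
traces.

Six fractional-radical curves acquired at different excitation rate
constants are fit simultaneously: the photophysical constants (k_isc,
k_rad + k_ic, 1/tau_T) and the independently measured radical dark-decay
k_decay are held fixed, while the electron-transfer, deprotonation, back-ET
and cation-decay rate constants are optimized in log space.

The observable depends on the cation-branch constants only through the
branching probabilities p_deprot, p_back, p_x and on k_ET only through the
saturated triplet branching p_ET = k_ET/(k_ET + 1/tau_T); the overall scale
of the cation-branch rates and the magnitude of k_ET are therefore flat
directions of the objective. The fitter reports them as such via a profile
diagnostic rather than pretending the point values are precise. Point
estimates along the flat directions reflect the documented initialization
recipe (all cation rates started at a common 1e6 s^-1 scale, k_deprot set
from the measured initial-rate yield via Phi_isc, k_ET started at 1e6).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy import stats

from .errors import FitFailureError, InvalidInputError
from .scheme import (
    LightSchedule,
    RateConstants,
    derive_fixed_constants,
    qss_radical_timecourse,
    simulate,
)

FREE_PARAMS = ("k_ET", "k_deprot", "k_back", "k_decay_prime")
FIXED_PARAMS = ("k_isc", "k_rad_plus_ic", "inv_tau_T", "k_decay")
#: log-space bounds for free rates, s^-1
RATE_BOUNDS = (1e0, 1e10)
#: profile score below which a parameter is reported as a flat direction
FLAT_SCORE_THRESHOLD = 0.01


@dataclass(frozen=True)
class FractionalTrace:
    """One fractional-radical curve with its excitation rate constant."""

    time_s: np.ndarray
    fraction: np.ndarray
    k_excit: float
    light_on_s: float
    light_off_s: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fraction", f)
        if t.shape != f.shape or t.ndim != 1 or len(t) < 10:
            raise InvalidInputError("trace needs matched 1-d arrays, >= 10 points")
        if self.k_excit < 0:
            raise InvalidInputError("k_excit must be >= 0")

    @property
    def schedule(self) -> LightSchedule:
        return LightSchedule.single(self.light_on_s, self.light_off_s)


@dataclass(frozen=True)
class GlobalFitProblem:
    """Traces plus the fixed-constant set and free-parameter configuration."""

    traces: tuple[FractionalTrace, ...]
    fixed: dict[str, float]
    bounds: tuple[float, float] = RATE_BOUNDS
    initial: dict[str, float] | None = None
    #: subset of FREE_PARAMS actually optimized; the rest stay at their
    #: initial values (useful for reduced or diagnostic fits)
    vary: tuple[str, ...] = FREE_PARAMS

    def __post_init__(self) -> None:
        if len(self.traces) < 1:
            raise InvalidInputError("global fit needs >= 1 trace")
        if len(self.traces) < 2 and self.vary == FREE_PARAMS:
            raise InvalidInputError(
                "a single trace cannot constrain all four free parameters; "
                "pass >= 2 traces or restrict `vary`"
            )
        unknown = set(self.vary) - set(FREE_PARAMS)
        if unknown:
            raise InvalidInputError(f"unknown free parameters: {sorted(unknown)}")
        missing = set(FIXED_PARAMS) - set(self.fixed)
        if missing:
            raise InvalidInputError(f"fixed constants missing: {sorted(missing)}")
        overlap = set(self.fixed) & set(FREE_PARAMS)
        if overlap:
            raise InvalidInputError(f"free parameters listed as fixed: {sorted(overlap)}")

    def rates(self, free: dict[str, float], k_excit: float) -> RateConstants:
        return RateConstants(k_excit=k_excit, **self.fixed, **free)

    @property
    def phi_isc(self) -> float:
        return self.fixed["k_isc"] / (self.fixed["k_isc"] + self.fixed["k_rad_plus_ic"])


@dataclass(frozen=True)
class GlobalFitResult:
    """Estimates, uncertainties and diagnostics of a global fit."""

    estimates: dict[str, float]
    stderrs: dict[str, float]
    per_trace_rms: dict[str, float]
    objective: float
    converged: bool
    engine: str
    initial: dict[str, float]
    flat_params: tuple[str, ...] = ()
    flat_scores: dict[str, float] = field(default_factory=dict)
    #: covariance of the varied log10 parameters (order: varied FREE_PARAMS)
    covar_log10: np.ndarray | None = None

    def summary(self) -> str:
        lines = []
        for name in FREE_PARAMS:
            flag = "  [flat direction -- value reflects initialization]" \
                if name in self.flat_params else ""
            lines.append(
                f"{name:14s} = {self.estimates[name]:.3g} "
                f"+/- {self.stderrs[name]:.2g} s^-1{flag}"
            )
        return "\n".join(lines)


def _model_f_r(
    problem: GlobalFitProblem,
    free: dict[str, float],
    trace: FractionalTrace,
    engine: str,
) -> np.ndarray:
    rates = problem.rates(free, trace.k_excit)
    if engine == "reduced":
        return qss_radical_timecourse(rates, trace.schedule, trace.time_s, warn=False)
    if engine == "full_ode":
        return simulate(rates, trace.schedule, trace.time_s, method="bdf").f_R
    raise InvalidInputError(f"unknown engine {engine!r}")


def objective(
    problem: GlobalFitProblem, free: dict[str, float], engine: str = "reduced"
) -> float:
    """Summed squared residuals over all traces for a free-parameter set."""
    total = 0.0
    for trace in problem.traces:
        r = _model_f_r(problem, free, trace, engine) - trace.fraction
        total += float(np.dot(r, r))
    return total


def initial_rate_yield(problem: GlobalFitProblem, window_s: float = 5.0) -> float:
    """Quick Phi_rad estimate: per-trace initial slope of f_R regressed
    through the origin against k_excit."""
    slopes, kex = [], []
    for trace in problem.traces:
        mask = (trace.time_s >= trace.light_on_s) & (
            trace.time_s <= trace.light_on_s + window_s
        )
        if mask.sum() < 5:
            continue
        slopes.append(stats.linregress(trace.time_s[mask], trace.fraction[mask]).slope)
        kex.append(trace.k_excit)
    if len(slopes) < 2:
        raise FitFailureError("not enough traces for an initial-rate estimate")
    x, y = np.asarray(kex), np.asarray(slopes)
    return float(np.dot(x, y) / np.dot(x, x))


def problem_from_traces(
    traces,
    truth: dict,
    drift_window_margin_s: float = 0.2,
) -> GlobalFitProblem:
    """Assemble a GlobalFitProblem from generated kinetic traces + truth record.

    Applies the standard preprocessing: linear drift correction on the
    pre-illumination window, then Beer-Lambert conversion to fractional
    radical populations using the truth record's probe constants. Only
    acquisition metadata (not the free rate constants) is read from truth.
    """
    from .traces import correct_drift  # local import avoids a cycle

    scale = truth["epsilon_probe"] * truth["probe_path_cm"] * truth["conc_w48_M"]
    ftraces = []
    for trace, k_excit in zip(traces, truth["k_excit_per_trace"]):
        corrected = correct_drift(
            trace, (float(trace.time_s[0]), truth["light_on_s"] - drift_window_margin_s)
        )
        ftraces.append(
            FractionalTrace(
                time_s=trace.time_s,
                fraction=corrected.absorbance / scale,
                k_excit=k_excit,
                light_on_s=truth["light_on_s"],
                light_off_s=truth["light_off_s"],
                label=trace.label,
            )
        )
    fixed = {name: truth["rates"][name] for name in FIXED_PARAMS}
    return GlobalFitProblem(traces=tuple(ftraces), fixed=fixed)


def default_initial_guesses(problem: GlobalFitProblem) -> dict[str, float]:
    """Initialization recipe for the four free rate constants.

    k_ET, k_back and k_decay' start at a common 1e6 s^-1 scale (back-ET and
    forward ET cross the same donor-acceptor pair, so a shared magnitude is
    the natural prior; the non-productive cation channels split 50/50).
    k_deprot is then set so the one-pass branching yield matches the
    measured initial-rate yield divided by Phi_isc.
    """
    p_target = initial_rate_yield(problem) / problem.phi_isc
    p_target = min(max(p_target, 1e-4), 0.9)
    k_back0 = k_decay_prime0 = 1e6
    k_deprot0 = p_target / (1.0 - p_target) * (k_back0 + k_decay_prime0)
    return {
        "k_ET": 1e6,
        "k_deprot": k_deprot0,
        "k_back": k_back0,
        "k_decay_prime": k_decay_prime0,
    }


def _fit(
    problem: GlobalFitProblem,
    init: dict[str, float],
    engine: str,
    vary: dict[str, bool] | None = None,
) -> lmfit.minimizer.MinimizerResult:
    lo, hi = problem.bounds
    params = lmfit.Parameters()
    for name in FREE_PARAMS:
        base = name in problem.vary
        params.add(
            f"log10_{name}",
            value=math.log10(init[name]),
            min=math.log10(lo),
            max=math.log10(hi),
            vary=base if vary is None else (base and vary.get(name, True)),
        )

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        free = {name: 10.0 ** p[f"log10_{name}"].value for name in FREE_PARAMS}
        return np.concatenate(
            [
                _model_f_r(problem, free, trace, engine) - trace.fraction
                for trace in problem.traces
            ]
        )

    with warnings.catch_warnings():
        # flat directions give a singular covariance; lmfit's sqrt of the
        # negative/NaN diagonal is expected and handled downstream
        warnings.simplefilter("ignore", RuntimeWarning)
        return lmfit.minimize(residuals, params, method="least_squares")


def global_fit(
    problem: GlobalFitProblem,
    engine: str = "reduced",
    diagnose_flat: bool = True,
) -> GlobalFitResult:
    """Simultaneous fit of the photocycle to all traces.

    ``engine="reduced"`` (default) evaluates the QSS closed form, validated
    against the full stiff integration; ``engine="full_ode"`` integrates the
    six-species network at every evaluation (slow verification path).
    Uncertainties come from the Jacobian-based covariance at the optimum,
    propagated from log space; flat directions are flagged via the profile
    diagnostic and their point values must not be read as precise.
    """
    init = dict(problem.initial) if problem.initial else default_initial_guesses(problem)
    out = _fit(problem, init, engine)
    if not out.success:
        warnings.warn(
            f"optimizer did not report convergence: {out.message}; "
            "returning best-so-far estimates",
            UserWarning,
            stacklevel=2,
        )
    estimates, stderrs = {}, {}
    for name in FREE_PARAMS:
        p = out.params[f"log10_{name}"]
        k = 10.0 ** p.value
        estimates[name] = k
        stderrs[name] = (
            math.log(10.0) * k * p.stderr
            if p.stderr is not None and math.isfinite(p.stderr)
            else math.inf
        )
    free = dict(estimates)
    per_trace_rms = {}
    for trace in problem.traces:
        r = _model_f_r(problem, free, trace, engine) - trace.fraction
        per_trace_rms[trace.label or f"k_excit={trace.k_excit:g}"] = float(
            np.sqrt(np.mean(r**2))
        )
    result = GlobalFitResult(
        estimates=estimates,
        stderrs=stderrs,
        per_trace_rms=per_trace_rms,
        objective=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        engine=engine,
        initial=init,
        covar_log10=getattr(out, "covar", None),
    )
    if diagnose_flat:
        scores = {
            name: profile_flatness(problem, result, name, engine=engine, n_points=3)
            for name in problem.vary
        }
        flat = tuple(n for n, s in scores.items() if s < FLAT_SCORE_THRESHOLD)
        result = replace(result, flat_params=flat, flat_scores=scores)
    return result


def p_deprot_estimate(
    problem: GlobalFitProblem,
    result: GlobalFitResult,
    engine: str = "reduced",
) -> tuple[float, float]:
    """Deprotonation branching probability with a delta-method standard error.

    p_deprot = k_deprot / (k_deprot + k_back + k_decay') is the combination
    of the cation-branch rates the data actually constrain; its uncertainty
    stays finite even though the individual rates lie along flat directions.
    The covariance is built from a finite-difference model Jacobian at the
    optimum, pseudo-inverted within the identifiable subspace only, so the
    (formally infinite) flat-direction variance cannot leak into the
    combination.
    """
    e = result.estimates
    total = e["k_deprot"] + e["k_back"] + e["k_decay_prime"]
    p = e["k_deprot"] / total

    def model_vec(free: dict[str, float]) -> np.ndarray:
        return np.concatenate(
            [_model_f_r(problem, free, trace, engine) for trace in problem.traces]
        )

    f0 = model_vec(e)
    h = 1e-4  # log10 step
    cols = []
    for name in FREE_PARAMS:
        bumped = dict(e)
        bumped[name] = e[name] * 10.0**h
        cols.append((model_vec(bumped) - f0) / h)
    J = np.column_stack(cols)  # d model / d log10 k
    jtj = J.T @ J
    w, V = np.linalg.eigh(jtj)
    keep = w > 1e-10 * w.max()
    n_obs = len(f0)
    s2 = result.objective / max(n_obs - int(keep.sum()), 1)
    cov = (V[:, keep] / w[keep]) @ V[:, keep].T * s2
    grads = {
        "k_ET": 0.0,
        "k_deprot": 1.0 - p,
        "k_back": -e["k_back"] / total,
        "k_decay_prime": -e["k_decay_prime"] / total,
    }
    g = np.array([grads[name] for name in FREE_PARAMS])  # d log10 p / d log10 k
    var_log10 = float(g @ cov @ g)
    return p, p * math.log(10.0) * math.sqrt(max(var_log10, 0.0))


def profile_flatness(
    problem: GlobalFitProblem,
    result: GlobalFitResult,
    param: str,
    span_decades: float = 1.0,
    n_points: int = 5,
    engine: str = "reduced",
) -> float:
    """Profile-likelihood flatness score for one free parameter.

    The parameter is clamped on a log grid spanning +/- ``span_decades``
    around its estimate while the others are re-optimized from the fit
    optimum; the score is max |objective change| / optimum objective. A
    score near zero means the data do not constrain the parameter
    (unidentifiable); compare against ``FLAT_SCORE_THRESHOLD``.
    """
    if param not in FREE_PARAMS:
        raise InvalidInputError(f"unknown free parameter {param!r}")
    obj0 = objective(problem, result.estimates, engine)
    if obj0 == 0.0:
        obj0 = np.finfo(float).tiny
    worst = 0.0
    grid = np.linspace(-span_decades, span_decades, n_points)
    for delta in grid:
        if delta == 0.0:
            continue
        init = dict(result.estimates)
        init[param] = result.estimates[param] * 10.0**delta
        out = _fit(problem, init, engine, vary={param: False})
        worst = max(worst, abs(float(np.sum(out.residual**2)) - obj0))
    return worst / obj0


def sensitivity_phi_isc(
    problem: GlobalFitProblem,
    phi_values: tuple[float, ...],
    tau_fluo_ns: float = 3.0,
    engine: str = "reduced",
) -> dict[float, GlobalFitResult]:
    """Refit with the singlet-manifold constants re-derived per Phi_isc.

    Returns estimates side by side so the stability of k_deprot and
    k_decay' under the triplet-yield assumption can be inspected.
    """
    results: dict[float, GlobalFitResult] = {}
    for phi in phi_values:
        if not 0.0 < phi <= 1.0:
            raise InvalidInputError(f"phi_isc must lie in (0, 1], got {phi}")
        _, k_isc, k_rad_plus_ic = derive_fixed_constants(tau_fluo_ns, phi)
        fixed = dict(problem.fixed, k_isc=k_isc, k_rad_plus_ic=k_rad_plus_ic)
        sub = replace(problem, fixed=fixed)
        results[phi] = global_fit(sub, engine=engine, diagnose_flat=False)
    return results
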