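"""Global photocycle fitting: recovery, engines, identifiability."""

import numpy as np
import pytest

from trpkin import synthetic as syn
from trpkin.errors import InvalidInputError
from trpkin.fitting import (
    GlobalFitProblem,
    global_fit,
    objective,
    p_deprot_estimate,
    profile_flatness,
    sensitivity_phi_isc,
)

from conftest import build_problem

P_DEPROT_TRUE = 3e5 / (3e5 + 2e6 + 7e5)


def coarse_problem(seed, noise=2e-4, dt=0.5, drift=0.001 / 300.0):
    traces, truth = syn.gen_radical_traces(
        syn.RadicalTraceSpec(
            seed=seed, noise_sd_AU=noise, dt_s=dt, drift_slope_AU_per_s=drift
        )
    )
    return build_problem(traces, truth), truth


def test_noiseless_fit_reproduces_generator_curves():
    traces, truth = syn.gen_radical_traces(
        syn.RadicalTraceSpec(seed=0, noise_sd_AU=0.0, drift_slope_AU_per_s=0.0, dt_s=1.0)
    )
    problem = build_problem(traces, truth)
    result = global_fit(problem, diagnose_flat=False)
    assert result.converged
    assert max(result.per_trace_rms.values()) <= 1e-5


def test_engine_equivalence_on_noisy_data(radical_problem, true_free):
    """QSS-reduced and full-ODE objectives agree to 0.1% at the bench scale."""
    o_reduced = objective(radical_problem, true_free, "reduced")
    o_full = objective(radical_problem, true_free, "full_ode")
    assert o_reduced == pytest.approx(o_full, rel=1e-3)


def test_recovery_of_identifiable_combination(radical_problem, radical_fit):
    p, _ = p_deprot_estimate(radical_problem, radical_fit)
    assert p == pytest.approx(P_DEPROT_TRUE, rel=0.10)


def test_k_et_is_a_flat_direction(radical_fit):
    """p_ET saturates at 1, so the data cannot constrain k_ET."""
    assert "k_ET" in radical_fit.flat_params
    assert radical_fit.flat_scores["k_ET"] < 1e-6


def test_single_free_parameter_is_identifiable():
    traces, truth = syn.gen_radical_traces(
        syn.RadicalTraceSpec(seed=3, powers_mW=(0.80, 0.30), dt_s=1.0)
    )
    problem = build_problem(traces, truth)
    problem = GlobalFitProblem(
        traces=problem.traces,
        fixed=problem.fixed,
        vary=("k_deprot",),
        initial={"k_ET": 6e6, "k_deprot": 1e5, "k_back": 2e6, "k_decay_prime": 7e5},
    )
    result = global_fit(problem)
    assert result.estimates["k_deprot"] == pytest.approx(3e5, rel=0.1)
    assert result.flat_scores["k_deprot"] > 1.0


def test_replicate_recovery_and_coverage():
    """50-replicate study: p_deprot bias < 5% and ~nominal SE coverage.

    Drift-free generation isolates the calibration of the fitter itself:
    drift-correction residuals add a correlated per-trace tilt that the
    white-noise standard error deliberately does not model (the drift stage
    has its own round-trip tests).
    """
    from trpkin.fitting import FIXED_PARAMS, FractionalTrace

    estimates, hits = [], 0
    for seed in range(100, 150):
        traces, truth = syn.gen_radical_traces(
            syn.RadicalTraceSpec(seed=seed, dt_s=0.5, drift_slope_AU_per_s=0.0)
        )
        scale = truth["epsilon_probe"] * truth["probe_path_cm"] * truth["conc_w48_M"]
        problem = GlobalFitProblem(
            traces=tuple(
                FractionalTrace(
                    t.time_s,
                    t.absorbance / scale,
                    k,
                    truth["light_on_s"],
                    truth["light_off_s"],
                    t.label,
                )
                for t, k in zip(traces, truth["k_excit_per_trace"])
            ),
            fixed={n: truth["rates"][n] for n in FIXED_PARAMS},
        )
        result = global_fit(problem, diagnose_flat=False)
        p, se = p_deprot_estimate(problem, result)
        estimates.append(p)
        if np.isfinite(se) and abs(p - P_DEPROT_TRUE) <= se:
            hits += 1
    bias = abs(np.mean(estimates) - P_DEPROT_TRUE) / P_DEPROT_TRUE
    assert bias < 0.05
    assert 0.5 <= hits / 50 <= 0.95


def test_corrupting_fixed_k_decay_worsens_fit(radical_problem, radical_fit):
    corrupted = GlobalFitProblem(
        traces=radical_problem.traces,
        fixed={**radical_problem.fixed, "k_decay": radical_problem.fixed["k_decay"] * 10},
    )
    bad = global_fit(corrupted, diagnose_flat=False)
    assert bad.objective > 2.0 * radical_fit.objective


def test_sensitivity_phi_isc(radical_problem):
    """Refits at Phi_isc 0.2 and 0.3 leave k_deprot compatible and the
    one-pass yield essentially unchanged."""
    results = sensitivity_phi_isc(radical_problem, (0.2, 0.3))
    e2, e3 = results[0.2].estimates, results[0.3].estimates
    s2, s3 = results[0.2].stderrs, results[0.3].stderrs
    spread = max(s for s in (s2["k_deprot"], s3["k_deprot"]) if np.isfinite(s)) \
        if any(np.isfinite(s) for s in (s2["k_deprot"], s3["k_deprot"])) else np.inf
    assert abs(e2["k_deprot"] - e3["k_deprot"]) <= max(spread, 0.5 * e3["k_deprot"])
    def one_pass(phi, e):
        return phi * e["k_deprot"] / (e["k_deprot"] + e["k_back"] + e["k_decay_prime"])
    assert one_pass(0.2, e2) == pytest.approx(one_pass(0.3, e3), rel=0.05)


def test_sensitivity_rejects_zero_phi(radical_problem):
    with pytest.raises(InvalidInputError):
        sensitivity_phi_isc(radical_problem, (0.0,))


def test_problem_validation(radical_problem):
    with pytest.raises(InvalidInputError):
        GlobalFitProblem(traces=radical_problem.traces[:1], fixed=radical_problem.fixed)
    with pytest.raises(InvalidInputError):
        GlobalFitProblem(
            traces=radical_problem.traces, fixed={"k_isc": 1.0}
        )
    with pytest.raises(InvalidInputError):
        GlobalFitProblem(
            traces=radical_problem.traces,
            fixed={**radical_problem.fixed, "k_ET": 1.0},
        )


def test_profile_flatness_rejects_unknown_param(radical_problem, radical_fit):
    with pytest.raises(InvalidInputError):
        profile_flatness(radical_problem, radical_fit, "k_isc")
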