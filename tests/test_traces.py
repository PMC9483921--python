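"""Trace analysis: drift correction, conversions, decay fits, yields."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trpkin.errors import (
    DataQualityWarning,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
)
from trpkin.scheme import LightSchedule, azurin_rates, qss_reduce, simulate
from trpkin.traces import (
    KineticTrace,
    beer_lambert_conc,
    correct_drift,
    fit_monoexponential,
    initial_rate,
    radical_fraction,
    radical_quantum_yield,
)

SCALE = 2200.0 * 1.0 * 75e-6  # AU per unit radical fraction at the bench


def make_trace(t, a, **kw):
    kw.setdefault("wavelength_nm", 514.0)
    return KineticTrace(time_s=t, absorbance=a, **kw)


@pytest.fixture(scope="module")
def clean_curve_a():
    """Noiseless curve-A absorbance trace: 230 s dark, 330 s light, 300 s dark."""
    t = np.arange(0.0, 860.0001, 0.1)
    sched = LightSchedule.single(230.0, 560.0)
    tc = simulate(azurin_rates(0.044), sched, t, method="expm")
    return make_trace(t, tc.f_R * SCALE, light_on_s=230.0, light_off_s=560.0)


class TestCorrectDrift:
    def test_pure_ramp_removed(self):
        t = np.arange(0.0, 300.0, 0.1)
        trace = make_trace(t, 3.3e-6 * t + 0.01)
        out = correct_drift(trace, (0.0, 299.9))
        assert np.max(np.abs(out.absorbance)) < 1e-12

    def test_drift_free_trace_unchanged(self, clean_curve_a):
        out = correct_drift(clean_curve_a, (0.0, 229.0))
        assert np.max(np.abs(out.absorbance - clean_curve_a.absorbance)) < 1e-12

    def test_input_untouched(self, clean_curve_a):
        before = clean_curve_a.absorbance.copy()
        correct_drift(clean_curve_a, (0.0, 229.0))
        assert np.array_equal(clean_curve_a.absorbance, before)

    def test_short_window_rejected(self, clean_curve_a):
        with pytest.raises(InsufficientDataError):
            correct_drift(clean_curve_a, (0.0, 0.5))

    @given(slope=st.floats(-3.3e-6, 3.3e-6))
    def test_ramp_roundtrip(self, slope, clean_curve_a):
        """Adding then removing any drift within the stated bound is identity."""
        ramped = make_trace(
            clean_curve_a.time_s,
            clean_curve_a.absorbance + slope * clean_curve_a.time_s,
        )
        out = correct_drift(ramped, (0.0, 229.0))
        rms = np.sqrt(np.mean((out.absorbance - clean_curve_a.absorbance) ** 2))
        assert rms <= 1e-5


@pytest.mark.parametrize(
    "delta_abs, expected_M",
    [(0.165, 7.5e-5), (0.0, 0.0), (0.00165, 7.5e-7)],
)
def test_beer_lambert_conc(delta_abs, expected_M):
    assert beer_lambert_conc(delta_abs, 2200.0, 1.0) == pytest.approx(
        expected_M, rel=1e-12
    )


def test_beer_lambert_rejects_nonpositive():
    with pytest.raises(InvalidInputError):
        beer_lambert_conc(0.1, 0.0, 1.0)


class TestRadicalFraction:
    def test_zero_and_scaling(self):
        t = np.arange(10.0)
        assert np.all(radical_fraction(make_trace(t, np.zeros(10)), 75e-6) == 0.0)
        f = radical_fraction(make_trace(t, np.full(10, 0.00165)), 75e-6)
        assert f == pytest.approx(0.010, rel=1e-12)

    def test_roundtrip_is_exact_inverse(self, clean_curve_a):
        f = radical_fraction(clean_curve_a, 75e-6)
        back = f * SCALE
        assert np.max(np.abs(back - clean_curve_a.absorbance)) <= 1e-12

    def test_overshoot_flagged_not_clipped(self):
        t = np.arange(10.0)
        trace = make_trace(t, np.full(10, 0.2))
        with pytest.warns(DataQualityWarning):
            f = radical_fraction(trace, 75e-6)
        assert f.max() > 1.0  # reported unclipped


class TestMonoexponential:
    @pytest.mark.parametrize("tau", [0.1, 0.53, 10.0, 100.0])
    def test_noiseless_recovery(self, tau):
        t = np.arange(0.0, 10.0 * tau, tau / 20.0)
        trace = make_trace(t, 0.01 * np.exp(-t / tau))
        fit = fit_monoexponential(trace)
        assert fit.tau_s == pytest.approx(tau, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.01, rel=1e-6)

    def test_offset_mode(self):
        t = np.arange(0.0, 5.0, 0.05)
        trace = make_trace(t, 0.01 * np.exp(-t / 0.5) + 0.002)
        fit = fit_monoexponential(trace, with_offset=True)
        assert fit.tau_s == pytest.approx(0.5, rel=1e-6)
        assert fit.offset == pytest.approx(0.002, rel=1e-4)

    def test_short_window_rejected(self):
        t = np.arange(0.0, 0.5, 0.1)
        with pytest.raises(InsufficientDataError):
            fit_monoexponential(make_trace(t, np.exp(-t)))

    def test_estimator_calibration(self):
        """Across 100 noise replicates the tau estimator is unbiased (<1%)
        and its spread matches the reported standard error (factor 2)."""
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 5.0, 0.1)
        signal = 0.0087 * np.exp(-t / 0.53)
        taus, errs = [], []
        for _ in range(100):
            trace = make_trace(t, signal + rng.normal(0.0, 2e-4, len(t)))
            fit = fit_monoexponential(trace)
            taus.append(fit.tau_s)
            errs.append(fit.stderr["tau_s"])
        bias = abs(np.mean(taus) - 0.53) / 0.53
        assert bias < 0.01
        spread_ratio = np.std(taus) / np.mean(errs)
        assert 0.5 < spread_ratio < 2.0


class TestInitialRate:
    def test_exact_line(self):
        t = np.arange(0.0, 30.0, 0.1)
        for model in ("linear", "quadratic"):
            slope, _ = initial_rate(make_trace(t, 1e-5 * t), (0.0, 30.0), model=model)
            assert slope == pytest.approx(1e-5, rel=1e-9)

    def test_flat_trace(self):
        t = np.arange(0.0, 30.0, 0.1)
        slope, _ = initial_rate(make_trace(t, np.zeros(len(t))), (0.0, 30.0))
        assert slope == pytest.approx(0.0, abs=1e-15)

    def test_curve_a_early_rate_matches_reduced_model(self, clean_curve_a):
        """Default 30 s window recovers the closed-form initial rate to 5%."""
        slope, _ = initial_rate(clean_curve_a, (230.0, 260.0))
        q = qss_reduce(azurin_rates(0.044))
        assert slope == pytest.approx(q.k_GR * SCALE, rel=0.05)

    def test_too_few_points(self, clean_curve_a):
        with pytest.raises(InsufficientDataError):
            initial_rate(clean_curve_a, (230.0, 230.2))


class TestRadicalQuantumYield:
    def test_zero_radical(self):
        reg = radical_quantum_yield(np.array([1e14, 2e14]), np.zeros(2))
        assert reg.slope == 0.0

    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]) * 1e14
        reg = radical_quantum_yield(x, 0.030 * x)
        assert reg.slope == pytest.approx(0.030, rel=1e-12)
        assert reg.slope_stderr == pytest.approx(0.0, abs=1e-15)

    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_under_common_rescaling(self, scale):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = np.array([0.03, 0.055, 0.13, 0.22])
        base = radical_quantum_yield(x, y).slope
        assert radical_quantum_yield(x * scale, y * scale).slope == pytest.approx(
            base, rel=1e-9
        )

    def test_free_intercept_mode(self):
        x = np.array([1.0, 2.0, 3.0])
        reg = radical_quantum_yield(x, 0.1 * x + 0.05, through_origin=False)
        assert reg.slope == pytest.approx(0.1, rel=1e-9)
        assert reg.intercept == pytest.approx(0.05, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitFailureError):
            radical_quantum_yield(np.zeros(3), np.ones(3))
        with pytest.raises(InvalidInputError):
            radical_quantum_yield(np.array([1.0]), np.array([1.0]))
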