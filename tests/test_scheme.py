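"""Photocycle network: simulation, conservation, QSS reduction, yields."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trpkin.errors import InvalidInputError, QSSValidityWarning
from trpkin.scheme import (
    LightSchedule,
    RateConstants,
    azurin_rates,
    derive_fixed_constants,
    one_pass_radical_yield,
    qss_radical_timecourse,
    qss_reduce,
    round_sig,
    simulate,
    steady_state_triplet,
)

CURVE_A = 0.044


def test_derive_fixed_constants_canonical():
    k_fluo, k_isc, k_rad_ic = derive_fixed_constants(3.0, 0.3)
    assert round_sig(k_fluo, 2) == 3.3e8
    assert round_sig(k_isc, 2) == 9.9e7
    assert round_sig(k_rad_ic, 2) == 2.3e8


def test_derive_fixed_constants_limits_and_exact_mode():
    k_fluo, k_isc, k_rad_ic = derive_fixed_constants(3.0, 0.0)
    assert k_isc == 0.0 and k_rad_ic == k_fluo
    _, k_isc, k_rad_ic = derive_fixed_constants(3.0, 1.0)
    assert k_rad_ic == 0.0
    k_fluo_exact, _, _ = derive_fixed_constants(3.0, 0.3, sig_figs=None)
    assert k_fluo_exact == pytest.approx(1.0 / 3.0e-9, rel=1e-12)


def test_rate_constants_reject_negative():
    with pytest.raises(InvalidInputError):
        azurin_rates(k_ET=-1.0)


def test_no_light_keeps_ground_state():
    rates = azurin_rates(0.0)
    tc = simulate(rates, LightSchedule.single(0.0, 10.0), np.linspace(0, 20, 21))
    assert np.allclose(tc["G"], 1.0, atol=1e-9)
    assert np.allclose(tc.fractions[:, 1:], 0.0, atol=1e-9)


@pytest.fixture(scope="module")
def curve_a_run():
    rates = azurin_rates(CURVE_A)
    sched = LightSchedule.single(0.0, 330.0)
    t = np.arange(0.0, 630.0001, 0.1)
    return rates, sched, t, simulate(rates, sched, t, method="bdf")


def test_stiff_integration_conserves_population(curve_a_run):
    _, _, _, tc = curve_a_run
    assert tc.conservation_defect() <= 1e-6
    assert np.all(tc.fractions >= -1e-12)


def test_full_ode_matches_qss_closed_form(curve_a_run):
    """Stiff integration and the QSS reduction agree on f_R to <= 1e-4."""
    rates, sched, t, tc = curve_a_run
    f_qss = qss_radical_timecourse(rates, sched, t)
    mask = t >= 5.0
    assert np.max(np.abs(tc.f_R[mask] - f_qss[mask])) <= 1e-4


def test_exact_propagator_matches_bdf(curve_a_run):
    rates, sched, t, tc = curve_a_run
    tc2 = simulate(rates, sched, t, method="expm")
    assert np.max(np.abs(tc.fractions - tc2.fractions)) <= 1e-6


def test_light_off_decay_is_exponential_with_k_decay(curve_a_run):
    """After light-off the radical decays monoexponentially at k_decay."""
    rates, sched, t, _ = curve_a_run
    tc = simulate(rates, sched, t, method="expm")
    dark = t >= 335.0
    k = -np.polyfit(t[dark], np.log(tc.f_R[dark]), 1)[0]
    assert k == pytest.approx(rates.k_decay, rel=1e-6)


def test_photoproduct_monotone_and_radical_bounded(curve_a_run):
    rates, _, _, tc = curve_a_run
    assert np.all(np.diff(tc["X"]) >= -1e-12)
    q = qss_reduce(rates)
    assert tc.f_R.max() <= q.k_GR / q.k_RX + 1e-9


@given(
    logs=st.lists(st.floats(-2.0, 8.0), min_size=8, max_size=8),
    k_excit=st.floats(0.0, 0.05),
)
def test_conservation_over_random_rates(logs, k_excit):
    """Sum of populations stays 1 within 1e-6 for arbitrary rate sets."""
    ks = [10.0**v for v in logs]
    rates = RateConstants(k_excit, *ks)
    t = np.linspace(0.0, 10.0, 11)
    tc = simulate(rates, LightSchedule.single(0.0, 6.0), t, method="bdf")
    assert tc.conservation_defect() <= 1e-6


def test_qss_reduce_canonical_branching():
    q = qss_reduce(azurin_rates(CURVE_A))
    assert q.p_ET == pytest.approx(1.0, abs=1e-5)
    assert q.p_deprot == pytest.approx(0.100, abs=1e-12)
    assert q.p_back + q.p_deprot + q.p_x == pytest.approx(1.0, rel=1e-12)


def test_qss_reduce_limiting_cases():
    q = qss_reduce(azurin_rates(CURVE_A, k_back=0.0, k_decay_prime=0.0))
    assert q.p_deprot == 1.0
    with pytest.warns(QSSValidityWarning):  # no acceptor: triplet pools up
        q = qss_reduce(azurin_rates(CURVE_A, k_ET=0.0))
    assert q.k_GR == 0.0


def test_qss_warns_when_pumping_is_fast():
    with pytest.warns(QSSValidityWarning):
        qss_reduce(azurin_rates(0.1, k_ET=0.0))


def test_one_pass_radical_yield():
    assert one_pass_radical_yield(azurin_rates(CURVE_A)) == pytest.approx(0.030, abs=1e-5)
    zero_isc = azurin_rates(CURVE_A)
    zero_isc = RateConstants(
        **{**zero_isc.__dict__, "k_isc": 0.0, "k_rad_plus_ic": zero_isc.k_fluo}
    )
    assert one_pass_radical_yield(zero_isc) == 0.0
    saturated = azurin_rates(CURVE_A, k_ET=1e12, k_back=0.0, k_decay_prime=0.0)
    assert one_pass_radical_yield(saturated) == pytest.approx(
        saturated.phi_isc, rel=1e-6
    )


@pytest.mark.parametrize(
    "k_excit, phi, tau, expected",
    [(0.044, 0.3, 0.53, 6.95e-3), (0.0, 0.3, 0.53, 0.0), (1e9, 1.0, 1e9, 1.0)],
)
def test_steady_state_triplet(k_excit, phi, tau, expected):
    assert steady_state_triplet(k_excit, phi, tau) == pytest.approx(expected, abs=1e-5)


def test_schedule_validation():
    with pytest.raises(InvalidInputError):
        LightSchedule(((10.0, 5.0),))
    with pytest.raises(InvalidInputError):
        LightSchedule(((0.0, 5.0), (4.0, 8.0)))
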