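"""Synthetic bench data with declared ground truth.

Every input the analysis pipeline consumes can be generated here:
photocycle-governed 514 nm radical traces at the six bench excitation
powers, 450 nm triplet on/off traces, two-band emission spectra against a
reference fluorophore, and toy Calpha trajectories with prescribed
per-residue fluctuation amplitudes. Each generator returns the data
together with a machine-readable truth record holding every parameter it
used; downstream tests read truth from that record only.

Defaults emulate the photolysis bench: 0.1 s sampling, Gaussian instrument
noise of 2e-4 AU, a linear baseline drift at the stated bound of 0.001 AU
per 300 s, incident powers of 0.80/0.63/0.54/0.38/0.30/0.10 mW on a
0.64 cm^2 beam, 75 uM protein probed over 1 cm at 514 nm, and the canonical
photocycle rate constants. Identical specs (including the mandatory seed)
produce identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import emission as em
from .errors import InvalidInputError
from .photon import BeamSpec, ChromophoreOptics, EPSILON_W48_280, excitation_rate, photon_flux
from .scheme import LightSchedule, RateConstants, azurin_rates, simulate, steady_state_triplet
from .structure import Trajectory
from .traces import EPSILON_RADICAL_514, KineticTrace

#: Bench incident powers (mW) for curves A-F.
CURVE_POWERS_MW = (0.80, 0.63, 0.54, 0.38, 0.30, 0.10)
CURVE_LABELS = ("A", "B", "C", "D", "E", "F")

_DRIFT_BOUND = 0.001 / 300.0  # AU/s, stated instrument bound


def _rates_record(rates: RateConstants) -> dict:
    rec = asdict(rates)
    rec["phi_isc"] = rates.phi_isc
    rec["tau_T_s"] = rates.tau_T
    return rec


@dataclass(frozen=True)
class RadicalTraceSpec:
    """Scenario for 514 nm radical growth/decay traces at several powers."""

    rates: RateConstants = field(default_factory=azurin_rates)
    powers_mW: tuple[float, ...] = CURVE_POWERS_MW
    wavelength_nm: float = 280.0
    beam_area_cm2: float = 0.64
    epsilon_excitation: float = EPSILON_W48_280
    conc_w48_M: float = 75e-6
    epsilon_probe: float = EPSILON_RADICAL_514
    probe_path_cm: float = 1.0
    dt_s: float = 0.1
    pre_light_s: float = 230.0
    light_s: float = 330.0
    dark_s: float = 300.0
    noise_sd_AU: float = 2e-4
    drift_slope_AU_per_s: float = _DRIFT_BOUND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_AU < 0 or self.dt_s <= 0:
            raise InvalidInputError("noise sd must be >= 0 and dt > 0")


def gen_radical_traces(spec: RadicalTraceSpec) -> tuple[list[KineticTrace], dict]:
    """Radical kinetic traces for each power, plus the truth record.

    For each power the excitation rate constant is computed from the photon
    flux and the W48 cross-section, the full six-species photocycle is
    integrated exactly, and the radical fraction is converted to absorbance
    via Beer-Lambert. Gaussian noise and the linear drift are then added.
    """
    rng = np.random.default_rng(spec.seed)
    optics = ChromophoreOptics(epsilon=spec.epsilon_excitation)
    t_on = spec.pre_light_s
    t_off = spec.pre_light_s + spec.light_s
    t_end = t_off + spec.dark_s
    t = np.arange(0.0, t_end + spec.dt_s / 2, spec.dt_s)
    schedule = LightSchedule.single(t_on, t_off)
    scale = spec.epsilon_probe * spec.probe_path_cm * spec.conc_w48_M

    traces: list[KineticTrace] = []
    k_excits: list[float] = []
    for label, power in zip(CURVE_LABELS, spec.powers_mW):
        beam = BeamSpec(spec.wavelength_nm, power, spec.beam_area_cm2)
        k_excit = excitation_rate(photon_flux(beam), optics)
        k_excits.append(k_excit)
        tc = simulate(spec.rates.with_k_excit(k_excit), schedule, t, method="expm")
        absorbance = tc.f_R * scale
        absorbance = absorbance + spec.drift_slope_AU_per_s * t
        if spec.noise_sd_AU > 0:
            absorbance = absorbance + rng.normal(0.0, spec.noise_sd_AU, len(t))
        traces.append(
            KineticTrace(
                time_s=t,
                absorbance=absorbance,
                wavelength_nm=514.0,
                path_cm=spec.probe_path_cm,
                label=label,
                light_on_s=t_on,
                light_off_s=t_off,
                beam=beam,
            )
        )
    truth = {
        "rates": _rates_record(spec.rates),
        "k_excit_per_trace": k_excits,
        "powers_mW": list(spec.powers_mW),
        "labels": list(CURVE_LABELS[: len(spec.powers_mW)]),
        "conc_w48_M": spec.conc_w48_M,
        "epsilon_probe": spec.epsilon_probe,
        "probe_path_cm": spec.probe_path_cm,
        "epsilon_excitation": spec.epsilon_excitation,
        "beam_area_cm2": spec.beam_area_cm2,
        "wavelength_nm": spec.wavelength_nm,
        "light_on_s": t_on,
        "light_off_s": t_off,
        "dt_s": spec.dt_s,
        "noise_sd_AU": spec.noise_sd_AU,
        "drift_slope_AU_per_s": spec.drift_slope_AU_per_s,
        "seed": spec.seed,
    }
    return traces, truth


@dataclass(frozen=True)
class TripletTraceSpec:
    """Scenario for a 450 nm triplet on/off trace (no electron acceptor)."""

    tau_T_s: float = 0.53
    phi_isc: float = 0.3
    power_mW: float = 1.1
    wavelength_nm: float = 280.0
    beam_area_cm2: float = 0.64
    epsilon_excitation: float = EPSILON_W48_280
    conc_M: float = 250e-6
    epsilon_triplet_450: float = 5000.0  # free instrument-scale parameter
    probe_path_cm: float = 1.0
    dt_s: float = 0.1
    pre_light_s: float = 5.0
    light_s: float = 30.0
    dark_s: float = 5.0
    noise_sd_AU: float = 2e-4
    seed: int = 0


def gen_triplet_trace(spec: TripletTraceSpec) -> tuple[KineticTrace, dict]:
    """Triplet absorbance trace: rise to the steady-state plateau while the
    light is on, monoexponential dark decay with tau_T after light-off."""
    rng = np.random.default_rng(spec.seed)
    beam = BeamSpec(spec.wavelength_nm, spec.power_mW, spec.beam_area_cm2)
    k_excit = excitation_rate(
        photon_flux(beam), ChromophoreOptics(epsilon=spec.epsilon_excitation)
    )
    t_on = spec.pre_light_s
    t_off = spec.pre_light_s + spec.light_s
    t = np.arange(0.0, t_off + spec.dark_s + spec.dt_s / 2, spec.dt_s)
    f_ss = steady_state_triplet(k_excit, spec.phi_isc, spec.tau_T_s)
    # two-state ground<->triplet relaxation rate while pumped
    k_relax = k_excit * spec.phi_isc + 1.0 / spec.tau_T_s
    f_T = np.zeros_like(t)
    on = (t >= t_on) & (t < t_off)
    f_T[on] = f_ss * (1.0 - np.exp(-k_relax * (t[on] - t_on)))
    f_at_off = f_ss * (1.0 - np.exp(-k_relax * spec.light_s))
    dark = t >= t_off
    f_T[dark] = f_at_off * np.exp(-(t[dark] - t_off) / spec.tau_T_s)
    absorbance = f_T * spec.epsilon_triplet_450 * spec.probe_path_cm * spec.conc_M
    if spec.noise_sd_AU > 0:
        absorbance = absorbance + rng.normal(0.0, spec.noise_sd_AU, len(t))
    trace = KineticTrace(
        time_s=t,
        absorbance=absorbance,
        wavelength_nm=450.0,
        path_cm=spec.probe_path_cm,
        label="triplet",
        light_on_s=t_on,
        light_off_s=t_off,
        beam=beam,
    )
    truth = {
        "tau_T_s": spec.tau_T_s,
        "phi_isc": spec.phi_isc,
        "k_excit": k_excit,
        "plateau_fraction": f_ss,
        "epsilon_triplet_450": spec.epsilon_triplet_450,
        "conc_M": spec.conc_M,
        "light_on_s": t_on,
        "light_off_s": t_off,
        "noise_sd_AU": spec.noise_sd_AU,
        "seed": spec.seed,
    }
    return trace, truth


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


@dataclass(frozen=True)
class EmissionSpec:
    """Scenario for a sample/reference emission-spectrum pair.

    Band areas are constructed so that the relative quantum-yield procedure,
    run with the declared absorbances and the ``saturating`` absorbed-light
    convention, returns exactly the requested true yields.
    """

    phi_fluo_true: float = 0.21
    phi_phos_true: float = 0.015
    phi_ref: float = em.PHI_FLUO_NATA
    absorbance_sample: float = 0.10
    absorbance_reference: float = 0.08
    emitter_fraction: float = 1.0
    reference_band_area: float = 1e6
    grid_step_nm: float = 1.0
    lo_nm: float = 275.0
    hi_nm: float = 535.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phi_fluo_true <= 0 and self.phi_phos_true <= 0:
            raise InvalidInputError("at least one true yield must be > 0")


def gen_emission_spectra(
    spec: EmissionSpec,
) -> tuple[em.EmissionSpectrum, em.EmissionSpectrum, dict]:
    """Sample and reference spectra with constructed true yields.

    The sample is a fluorescence Gaussian centred at 308 nm plus a
    three-component vibronic phosphorescence band confined to >= 400 nm; the
    reference is a broad single band. Component scales are solved from the
    band-overlap matrix so the requested band areas hold exactly on the
    synthesis grid.
    """
    wl = np.arange(spec.lo_nm, spec.hi_nm + spec.grid_step_nm / 2, spec.grid_step_nm)
    ref_shape = _gauss(wl, 360.0, 25.0)
    fluo_shape = _gauss(wl, 308.0, 13.0)
    phos_shape = (
        0.6 * _gauss(wl, 413.0, 8.0)
        + 0.48 * _gauss(wl, 440.0, 10.0)
        + 0.30 * _gauss(wl, 470.0, 12.0)
    )
    phos_shape = np.where(wl >= em.PHOS_BAND[0], phos_shape, 0.0)

    def band(y: np.ndarray, lo: float, hi: float) -> float:
        s = em.EmissionSpectrum(wavelength_nm=wl, intensity=np.abs(y) + 0.0)
        return em.integrate_band(s, lo, hi)

    ref_scale = spec.reference_band_area / band(ref_shape, *em.REFERENCE_BAND)
    reference = em.EmissionSpectrum(
        wavelength_nm=wl,
        intensity=ref_shape * ref_scale,
        absorbance_at_ex=spec.absorbance_reference,
        emitter_fraction=1.0,
        label="reference",
    )

    alpha_s = 1.0 - 10.0 ** (-spec.absorbance_sample)
    alpha_r = 1.0 - 10.0 ** (-spec.absorbance_reference)
    norm = spec.phi_ref * alpha_r / spec.reference_band_area / (
        alpha_s * spec.emitter_fraction
    )
    target_fluo = spec.phi_fluo_true / norm
    target_phos = spec.phi_phos_true / norm
    overlap = np.array(
        [
            [band(fluo_shape, *em.FLUO_BAND), band(phos_shape, *em.FLUO_BAND)],
            [band(fluo_shape, *em.PHOS_BAND), band(phos_shape, *em.PHOS_BAND)],
        ]
    )
    if spec.phi_phos_true == 0:
        s_fluo = target_fluo / overlap[0, 0]
        s_phos = 0.0
    else:
        s_fluo, s_phos = np.linalg.solve(overlap, [target_fluo, target_phos])
    sample = em.EmissionSpectrum(
        wavelength_nm=wl,
        intensity=s_fluo * fluo_shape + s_phos * phos_shape,
        absorbance_at_ex=spec.absorbance_sample,
        emitter_fraction=spec.emitter_fraction,
        label="sample",
    )
    truth = {
        "phi_fluo": spec.phi_fluo_true,
        "phi_phos": spec.phi_phos_true,
        "phi_ref": spec.phi_ref,
        "absorbance_sample": spec.absorbance_sample,
        "absorbance_reference": spec.absorbance_reference,
        "emitter_fraction": spec.emitter_fraction,
        "absorption_convention": "saturating",
        "seed": spec.seed,
    }
    return sample, reference, truth


@dataclass(frozen=True)
class TrajectorySpec:
    """Scenario for a toy Calpha trajectory with prescribed fluctuations."""

    n_residues: int = 64
    n_frames: int = 200
    baseline_amp_A: float = 0.5
    loop_residues: tuple[int, ...] = ()
    loop_amp_A: float = 1.5
    global_motion: bool = True
    max_translation_A: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.n_residues < 4:
            raise InvalidInputError("need >= 2 frames and >= 4 residues")

    def amplitudes(self) -> np.ndarray:
        amp = np.full(self.n_residues, self.baseline_amp_A)
        for r in self.loop_residues:
            amp[r - 1] = self.loop_amp_A  # residue ids are 1-based
        return amp


def gen_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, dict]:
    """Trajectory of atoms jittering about a rigid helical scaffold.

    Per-residue isotropic Gaussian jitter with per-axis sd amp/sqrt(3), so
    the expected RMSF equals the prescribed amplitude. Optional random rigid
    rotation/translation of every frame exercises the superposition step.
    """
    rng = np.random.default_rng(spec.seed)
    theta = np.arange(spec.n_residues) * (2.0 * np.pi / 3.6)
    scaffold = np.column_stack(
        [10.0 * np.cos(theta), 10.0 * np.sin(theta), 1.5 * theta]
    )
    amp = spec.amplitudes()
    sd = amp / np.sqrt(3.0)
    coords = scaffold[None, :, :] + rng.normal(
        0.0, 1.0, (spec.n_frames, spec.n_residues, 3)
    ) * sd[None, :, None]
    if spec.global_motion:
        rots = Rotation.random(spec.n_frames, rng)
        shifts = rng.uniform(-spec.max_translation_A, spec.max_translation_A, (spec.n_frames, 3))
        for i in range(spec.n_frames):
            coords[i] = coords[i] @ rots[i].as_matrix().T + shifts[i]
    residue_ids = np.arange(1, spec.n_residues + 1)
    truth = {
        "amplitudes_A": amp.tolist(),
        "residue_ids": residue_ids.tolist(),
        "n_frames": spec.n_frames,
        "global_motion": spec.global_motion,
        "seed": spec.seed,
    }
    return Trajectory(coords=coords, residue_ids=residue_ids), truth
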