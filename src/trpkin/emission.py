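"""Relative fluorescence and phosphorescence quantum yields.

Yields are measured against a reference fluorophore of known fluorescence
quantum yield (NATA, Phi_fluo = 0.13) by the standard normalise-and-
integrate procedure: band-integrated emission is divided by the fraction of
excitation light absorbed by the emitter, and the same quantity for the
reference calibrates the scale. Fluorescence is integrated over 275-400 nm,
vibronic phosphorescence over 400-535 nm, and the reference over 300-500 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyBandError, InvalidInputError
from .photon import absorbed_fraction

#: Fluorescence quantum yield of the NATA reference at pH 7.2.
PHI_FLUO_NATA = 0.13

FLUO_BAND = (275.0, 400.0)
PHOS_BAND = (400.0, 535.0)
REFERENCE_BAND = (300.0, 500.0)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Emission spectrum with the metadata the yield procedure needs.

    ``absorbance_at_ex`` is the solution absorbance at the excitation
    wavelength over the excitation path; ``emitter_fraction`` is the share
    of that absorption attributable to the emitter (1 for a pure solution).
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float = 270.0
    absorbance_at_ex: float = 0.0
    emitter_fraction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", inten)
        if wl.shape != inten.shape or wl.ndim != 1 or len(wl) < 2:
            raise InvalidInputError("spectrum needs matched 1-d arrays, >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise InvalidInputError("intensities must be >= 0")
        if not 0.0 <= self.emitter_fraction <= 1.0:
            raise InvalidInputError("emitter_fraction must lie in [0, 1]")


def integrate_band(spectrum: EmissionSpectrum, lo_nm: float, hi_nm: float) -> float:
    """Trapezoidal integral of intensity over [lo, hi] nm, endpoints included.

    Band edges falling between grid points are included by linear
    interpolation, so adjacent bands tile the full-range integral exactly.
    """
    wl, inten = spectrum.wavelength_nm, spectrum.intensity
    if hi_nm <= lo_nm:
        raise InvalidInputError(f"empty band [{lo_nm}, {hi_nm}]")
    lo = max(lo_nm, wl[0])
    hi = min(hi_nm, wl[-1])
    if hi <= lo:
        raise EmptyBandError(
            f"band [{lo_nm}, {hi_nm}] nm does not overlap support "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    inner = (wl > lo) & (wl < hi)
    grid = np.concatenate(([lo], wl[inner], [hi]))
    vals = np.concatenate(
        ([np.interp(lo, wl, inten)], inten[inner], [np.interp(hi, wl, inten)])
    )
    return float(np.trapezoid(vals, grid))


def relative_quantum_yields(
    sample: EmissionSpectrum,
    reference: EmissionSpectrum,
    phi_ref: float = PHI_FLUO_NATA,
    fluo_band: tuple[float, float] = FLUO_BAND,
    phos_band: tuple[float, float] = PHOS_BAND,
    reference_band: tuple[float, float] = REFERENCE_BAND,
    absorption: str = "saturating",
) -> tuple[float, float]:
    """Fluorescence and phosphorescence quantum yields of the sample.

    Phi_band = phi_ref * [I_band / (alpha_s f_s)] / [I_ref / alpha_r]

    where alpha is the fraction of excitation light absorbed (1 - 10^-A by
    default; ``absorption="linear"`` selects the thin-sample ln10 A form)
    and f_s the emitter's share of the sample absorption. Band edges are
    closed intervals, so the shared 400 nm point belongs to both bands.
    """
    alpha_s = absorbed_fraction(sample.absorbance_at_ex, absorption)
    alpha_r = absorbed_fraction(reference.absorbance_at_ex, absorption)
    if alpha_s * sample.emitter_fraction <= 0 or alpha_r <= 0:
        raise InvalidInputError("absorbed fractions must be > 0")
    i_ref = integrate_band(reference, *reference_band)
    if i_ref <= 0:
        raise InvalidInputError("reference band integral is zero")
    norm = phi_ref * alpha_r / i_ref / (alpha_s * sample.emitter_fraction)
    phi_fluo = norm * integrate_band(sample, *fluo_band)
    phi_phos = norm * integrate_band(sample, *phos_band)
    return phi_fluo, phi_phos
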