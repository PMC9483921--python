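"""Distance-decay electron-tunneling estimates and excited-state redox
arithmetic.

The maximum (activationless) rate for electron tunneling through protein
medium follows the empirical square-barrier relation

    k_max = k0 exp{-beta (R - R0)}

with prefactor k0 = 1e13 s^-1 at van der Waals contact R0 = 3 A and a
distance-decay constant beta ~ 1.1 A^-1 from Ru-azurin photochemistry. The
donor-acceptor separation R is composed by the caller from through-bond /
through-space segment lengths (structure parsing is out of scope).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidInputError


@dataclass(frozen=True)
class TunnelingGeometry:
    """Donor-acceptor geometry and decay parameters for the tunneling estimate."""

    segments_A: tuple[float, ...]
    beta_per_A: float = 1.1
    contact_offset_A: float = 3.0
    prefactor_per_s: float = 1e13

    def __post_init__(self) -> None:
        if not self.segments_A:
            raise InvalidInputError("at least one distance segment is required")
        if any(s < 0 for s in self.segments_A):
            raise InvalidInputError("segment lengths must be >= 0")
        if self.beta_per_A < 0 or self.contact_offset_A < 0 or self.prefactor_per_s <= 0:
            raise InvalidInputError("beta, offset must be >= 0; prefactor > 0")

    @property
    def separation_A(self) -> float:
        return compose_distance(self.segments_A)


def compose_distance(segments_A: Sequence[float] | Iterable[float]) -> float:
    """Total donor-acceptor separation as the sum of segment lengths (A)."""
    segs = list(segments_A)
    if not segs:
        raise InvalidInputError("no distance segments given")
    if any(s < 0 for s in segs):
        raise InvalidInputError("segment lengths must be >= 0")
    return float(sum(segs))


def max_et_rate(geom: TunnelingGeometry) -> float:
    """Maximum electron-tunneling rate k0 exp{-beta (R - R0)}, s^-1.

    For separations inside van der Waals contact (R < R0) the rate is capped
    at the prefactor with a warning. The full-precision value is returned;
    any rounding to the conventional one significant figure is left to
    display code.
    """
    r = geom.separation_A
    if r < geom.contact_offset_A:
        warnings.warn(
            f"separation {r} A is inside contact ({geom.contact_offset_A} A); "
            "rate capped at the prefactor",
            UserWarning,
            stacklevel=2,
        )
        return geom.prefactor_per_s
    return geom.prefactor_per_s * math.exp(-geom.beta_per_A * (r - geom.contact_offset_A))


def excited_state_potential(ground_couple_V: float, e00_eV: float) -> float:
    """Excited-state reduction potential of a photo-oxidant, one-electron
    convention: E(ox/red*) = E(ox/red) - E00."""
    return ground_couple_V - e00_eV
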