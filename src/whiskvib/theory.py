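"""Vortex-shedding frequency model for a whisker in uniform flow.

A bluff body of stream-wise diameter ``d`` in flow of speed ``U`` sheds
vortices at a frequency ``f = St * U / d``, where the Strouhal number ``St``
depends on the Reynolds number ``Re = U * d / nu``.  For circular cylinders
the classical empirical fits are

    St = 0.212 - 4.5 / Re     (laminar wake,   50 <= Re <= 150)
    St = 0.212 - 2.7 / Re     (turbulent wake, 300 <= Re <= 2000)

with an irregular transition in between; here the two fits are blended
linearly over 150 < Re < 300 so the map is total and continuous.  The fit
constants are configurable via :class:`StrouhalFit`.

Whiskers are flattened in cross-section, so the stream-wise diameter -- and
hence the predicted frequency -- depends on the angle of attack: at 0 deg the
thin edge faces the flow (small ``d``, high ``f``), at 90 deg the broad face
does (large ``d``, low ``f``).  Undulated whiskers additionally vary in width
between crests and troughs, which this module expresses as a frequency
interval from the maximum and minimum local widths.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FlowConditions",
    "StrouhalFit",
    "SheddingPrediction",
    "ReynoldsRangeError",
    "reynolds",
    "strouhal",
    "shedding_frequency",
    "undulated_frequency_range",
    "percent_difference",
]


class ReynoldsRangeError(ValueError):
    """Reynolds number outside the validity window of the empirical fits."""


@dataclass(frozen=True)
class FlowConditions:
    """Free-stream conditions of the flume.

    Defaults are the study conditions: 0.5 m/s in fresh water at ~20 C
    (kinematic viscosity 1.0e-6 m^2/s).
    """

    U: float = 0.5  # m/s
    nu: float = 1.0e-6  # m^2/s
    medium: str = "fresh water"

    def __post_init__(self) -> None:
        if self.U <= 0:
            raise ValueError(f"flow speed must be positive, got {self.U}")
        if self.nu <= 0:
            raise ValueError(f"kinematic viscosity must be positive, got {self.nu}")


@dataclass(frozen=True)
class StrouhalFit:
    """Empirical St(Re) fit constants and regime windows for a circular cylinder."""

    st_inf: float = 0.212
    laminar_coeff: float = 4.5
    turbulent_coeff: float = 2.7
    laminar_range: tuple[float, float] = (50.0, 150.0)
    turbulent_range: tuple[float, float] = (300.0, 2000.0)

    def laminar(self, Re: float) -> float:
        return self.st_inf - self.laminar_coeff / Re

    def turbulent(self, Re: float) -> float:
        return self.st_inf - self.turbulent_coeff / Re


DEFAULT_FIT = StrouhalFit()


@dataclass(frozen=True)
class SheddingPrediction:
    Re: float
    St: float
    f: float  # Hz
    regime: str  # laminar_fit | transition_blend | turbulent_fit


def reynolds(flow: FlowConditions, d: float) -> float:
    """Reynolds number Re = U * d / nu for stream-wise diameter ``d`` (m)."""
    if d <= 0:
        raise ValueError(f"stream-wise diameter must be positive, got {d}")
    return flow.U * d / flow.nu


def strouhal(Re: float, fit: StrouhalFit = DEFAULT_FIT) -> tuple[float, str]:
    """Strouhal number and regime label for Reynolds number ``Re``.

    Raises :class:`ReynoldsRangeError` outside [laminar lower, turbulent upper].
    """
    lam_lo, lam_hi = fit.laminar_range
    turb_lo, turb_hi = fit.turbulent_range
    if Re < lam_lo or Re > turb_hi:
        raise ReynoldsRangeError(
            f"Re = {Re:g} outside the empirical validity range [{lam_lo:g}, {turb_hi:g}]"
        )
    if Re <= lam_hi:
        return fit.laminar(Re), "laminar_fit"
    if Re >= turb_lo:
        return fit.turbulent(Re), "turbulent_fit"
    # transition: linear blend of the two branch fits, continuous at both ends
    w = (Re - lam_hi) / (turb_lo - lam_hi)
    return (1.0 - w) * fit.laminar(Re) + w * fit.turbulent(Re), "transition_blend"


def shedding_frequency(
    flow: FlowConditions, d: float, fit: StrouhalFit = DEFAULT_FIT
) -> SheddingPrediction:
    """Predicted shedding frequency f = St(Re) * U / d for diameter ``d`` (m)."""
    Re = reynolds(flow, d)
    St, regime = strouhal(Re, fit)
    return SheddingPrediction(Re=Re, St=St, f=St * flow.U / d, regime=regime)


def undulated_frequency_range(
    flow: FlowConditions,
    d_max: float,
    d_min: float,
    fit: StrouhalFit = DEFAULT_FIT,
) -> tuple[float, float, float]:
    """Frequency interval for an undulated whisker from its crest/trough widths.

    Returns ``(f_low, f_high, f_mid)``: the prediction at the widest section,
    at the narrowest section, and their midpoint (the group-comparable scalar).
    """
    if d_min <= 0 or d_max < d_min:
        raise ValueError(f"need d_max >= d_min > 0, got d_max={d_max}, d_min={d_min}")
    f_low = shedding_frequency(flow, d_max, fit).f
    f_high = shedding_frequency(flow, d_min, fit).f
    return f_low, f_high, 0.5 * (f_low + f_high)


def percent_difference(measured_f: float, theoretical_f: float) -> float:
    """Percent difference 100 * |measured - theoretical| / measured.

    Asymmetric by convention: the measured value is the denominator.
    """
    if measured_f <= 0:
        raise ValueError(f"measured frequency must be positive, got {measured_f}")
    return 100.0 * abs(measured_f - theoretical_f) / measured_f
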