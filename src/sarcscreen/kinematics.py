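"""Chair-rise (sit-to-stand) kinematics.

The rising phase of a sit-to-stand transition — from seat-off to full hip and
knee extension — is bounded by two video frames selected by the operator on a
high-speed recording (nominally 240 fps).  From the frame pair and the femur
length (the vertical distance travelled by the greater trochanter) this module
derives rising time, mean vertical velocity, and body-mass-relative vertical
power via a validated linear regression:

    power (W/kg) = 2.773 - 6.228 * t + 18.224 * d

with ``t`` the rising time in seconds and ``d`` the femur length in meters.
Frame selection itself is manual and therefore an *input* here, never a
computation.  All lengths are stored internally in meters; tape measurements
in centimeters are converted at ingest (see :mod:`sarcscreen.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "POWER_INTERCEPT",
    "POWER_COEF_TIME",
    "POWER_COEF_FEMUR",
    "SitToStandTrial",
    "InvalidTrialError",
    "MeasurementWarning",
    "rising_time",
    "vertical_velocity",
    "vertical_power",
    "trial_power",
]

#: Coefficients of the vertical-power regression (W/kg; t in s, d in m).
POWER_INTERCEPT = 2.773
POWER_COEF_TIME = -6.228
POWER_COEF_FEMUR = 18.224

# Sanity bounds for tape measurements (meters).  Violations are warnings, not
# errors: the most common cause is centimeters passed where meters are
# expected, which inflates computed power past any physiological value.
_FEMUR_BOUNDS_M = (0.2, 0.7)
_CALF_BOUNDS_M = (0.15, 0.6)


class InvalidTrialError(ValueError):
    """Raised when a trial cannot represent a physical chair rise."""


class MeasurementWarning(UserWarning):
    """A measurement is outside its plausible range (likely a unit error)."""


@dataclass(frozen=True)
class SitToStandTrial:
    """One filmed chair rise.

    Parameters
    ----------
    start_frame, end_frame
        Frame indices bounding the rising phase (onset of pelvis forward
        motion to full hip/knee extension).  ``end_frame`` must exceed
        ``start_frame``.
    fps
        Recording frame rate, frames per second (nominally 240).
    femur_length_m
        Greater trochanter to lateral femoral condyle distance, meters.
    calf_circumference_m
        Largest calf circumference of the non-dominant leg, meters.
    body_mass_kg
        Optional; power is reported relative to body mass, so it is not
        needed for the index test itself.
    """

    start_frame: int
    end_frame: int
    fps: float
    femur_length_m: float
    calf_circumference_m: float
    body_mass_kg: float | None = None

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise InvalidTrialError(
                f"end_frame ({self.end_frame}) must be greater than "
                f"start_frame ({self.start_frame}): zero- or negative-"
                "duration rising phase"
            )
        if self.fps <= 0:
            raise InvalidTrialError(f"fps must be positive, got {self.fps}")
        lo, hi = _FEMUR_BOUNDS_M
        if not lo <= self.femur_length_m <= hi:
            warnings.warn(
                f"femur_length_m={self.femur_length_m} outside [{lo}, {hi}] m"
                " — check units (centimeters passed as meters?)",
                MeasurementWarning,
                stacklevel=2,
            )
        lo, hi = _CALF_BOUNDS_M
        if not lo <= self.calf_circumference_m <= hi:
            warnings.warn(
                f"calf_circumference_m={self.calf_circumference_m} outside "
                f"[{lo}, {hi}] m — check units",
                MeasurementWarning,
                stacklevel=2,
            )


def rising_time(trial: SitToStandTrial) -> float:
    """Rising-phase duration in seconds: ``(end - start) / fps``.

    Kept at full float precision; no rounding to frame resolution.
    """
    return (trial.end_frame - trial.start_frame) / trial.fps


def vertical_velocity(trial: SitToStandTrial) -> float:
    """Mean vertical velocity (m/s) of the rise: femur length over rising time."""
    return trial.femur_length_m / rising_time(trial)


def vertical_power(rising_time_s: float, femur_length_m: float) -> float:
    """Body-mass-relative vertical power (W/kg) from the linear regression.

    Strictly decreasing in rising time and increasing in femur length.  A
    negative value (a very slow rise) is returned as-is with a warning —
    clamping would silently hide data errors.
    """
    if rising_time_s <= 0:
        raise InvalidTrialError(f"rising time must be positive, got {rising_time_s}")
    if femur_length_m <= 0:
        raise InvalidTrialError(f"femur length must be positive, got {femur_length_m}")
    power = (
        POWER_INTERCEPT
        + POWER_COEF_TIME * rising_time_s
        + POWER_COEF_FEMUR * femur_length_m
    )
    if power < 0:
        warnings.warn(
            f"computed vertical power is negative ({power:.3f} W/kg); the rise "
            f"took {rising_time_s:.3f} s — verify the selected frames",
            MeasurementWarning,
            stacklevel=2,
        )
    return power


def trial_power(trial: SitToStandTrial) -> float:
    """Vertical power (W/kg) for a trial: convenience over :func:`vertical_power`."""
    return vertical_power(rising_time(trial), trial.femur_length_m)
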