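"""Visuo-motor unit conversions for the head-fixed wheel task.

In the task, turning the steering wheel translates the on-screen Gabor
patch: 1 mm of wheel movement moves the stimulus 4 visual degrees, and the
reward threshold of 8.75 mm corresponds to 35 visual degrees.  Expressed in
wheel rotation, 17.2 wheel degrees (0.3 rad) equal those same 35 visual
degrees, so 1 wheel degree is roughly 2 visual degrees.  These constants
link wheel kinematics to the retinal consequences of the movement, in
particular the effective temporal frequency the moving grating imposes on
the retina.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ConversionConstants",
    "mm_to_visual_deg",
    "wheel_deg_to_visual_deg",
    "visual_angle",
    "stimulus_height_for_angle",
    "temporal_frequency",
    "luminance_log",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Fixed geometry of the wheel-stimulus coupling.

    Attributes
    ----------
    gain_mm:
        Visual degrees of stimulus displacement per mm of wheel movement.
    wheel_deg_for_35_visual_deg:
        Wheel degrees that displace the stimulus by 35 visual degrees.
    wheel_rad_for_35_visual_deg:
        Same displacement expressed in radians of wheel rotation.
    """

    gain_mm: float = 4.0
    wheel_deg_for_35_visual_deg: float = 17.2
    wheel_rad_for_35_visual_deg: float = 0.3
    visual_deg_per_wheel_deg: float = field(init=False)

    def __post_init__(self) -> None:
        if self.gain_mm <= 0 or self.wheel_deg_for_35_visual_deg <= 0:
            raise ValueError("conversion constants must be positive")
        object.__setattr__(
            self, "visual_deg_per_wheel_deg", 35.0 / self.wheel_deg_for_35_visual_deg
        )


DEFAULT_CONSTANTS = ConversionConstants()


def mm_to_visual_deg(x_mm: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Convert linear wheel displacement (mm) to visual degrees of stimulus motion."""
    return x_mm * constants.gain_mm


def wheel_deg_to_visual_deg(
    w_deg: float, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert wheel rotation (wheel degrees) to visual degrees of stimulus motion."""
    return w_deg * constants.visual_deg_per_wheel_deg


def visual_angle(h_cm: float, d_cm: float) -> float:
    """Visual angle (degrees) subtended by an object of height ``h_cm`` at distance ``d_cm``.

    phi = 2 * arctan(h / (2 d)).
    """
    if d_cm <= 0:
        raise ValueError("viewing distance must be positive")
    if h_cm < 0:
        raise ValueError("height must be non-negative")
    return math.degrees(2.0 * math.atan(h_cm / (2.0 * d_cm)))


def stimulus_height_for_angle(phi_deg: float, d_cm: float) -> float:
    """Physical height (cm) subtending ``phi_deg`` at distance ``d_cm``; inverse of
    :func:`visual_angle`."""
    if d_cm <= 0:
        raise ValueError("viewing distance must be positive")
    if not 0 <= phi_deg < 180:
        raise ValueError("visual angle must lie in [0, 180) degrees")
    return 2.0 * d_cm * math.tan(math.radians(phi_deg) / 2.0)


def temporal_frequency(
    wheel_speed_deg_s: float,
    spatial_frequency_cpd: float = 0.10,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> float:
    """Effective temporal frequency (Hz) of the grating during wheel movement.

    The wheel speed is first converted to visual-stimulus speed (visual
    deg/s); the number of grating cycles sweeping a retinal point per second
    is then that speed times the spatial frequency (cycles per visual
    degree) — equivalently, speed divided by the spatial period in degrees
    per cycle.
    """
    if spatial_frequency_cpd <= 0:
        raise ValueError("spatial frequency must be positive")
    visual_speed = wheel_deg_to_visual_deg(wheel_speed_deg_s, constants)
    return visual_speed * spatial_frequency_cpd


def luminance_log(luminance_cd_m2: float) -> float:
    """Base-10 log of screen luminance (log cd/m^2), the photometric scale on
    which contrast-sensitivity conditions are expressed."""
    if luminance_cd_m2 <= 0:
        raise ValueError("luminance must be positive")
    return math.log10(luminance_cd_m2)
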