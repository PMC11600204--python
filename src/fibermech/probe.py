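"""Euler-Bernoulli cantilever model of the sensing probe.

The sensing probe is a hollow quartz capillary clamped at one end.  The
fiber sample rests on it a distance ``l`` from the clamp (``l < L_p``) and
pulls sideways; the tip deflection ``x`` is read off camera frames in whole
pixels.  For small deflections the probe acts as a linear spring, so a
single stiffness ``k`` converts pixel counts to force.

All quantities are SI internally (m, N, Pa).  Presentation layers convert
to um / uN / kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ProbeSpec",
    "ProbeCalibration",
    "moment_of_inertia",
    "stiffness",
    "force_from_deflection",
    "quantize_deflection",
    "rescale_resolution",
    "resolution_after_rescale",
    "probe_preset",
    "PROBE_PRESETS",
]

#: Elastic modulus of fused quartz, Pa.  A literature value; configurable
#: per probe because drawn capillaries vary.
QUARTZ_MODULUS = 72e9


@dataclass(frozen=True)
class ProbeSpec:
    """Geometry and material of one sensing cantilever.

    Parameters
    ----------
    outer_diameter, inner_diameter:
        Capillary cross-section, m.  ``inner_diameter`` may be 0 (solid rod)
        but must be strictly smaller than ``outer_diameter``.
    probe_length:
        Free length from the clamp to the tip, m.
    mount_position:
        Distance from the clamp at which the sample rests, m; must lie
        strictly inside the free length.
    pixel_size:
        Physical size of one camera pixel in the bending plane, m/px.
    """

    outer_diameter: float
    inner_diameter: float
    probe_length: float
    mount_position: float
    pixel_size: float
    material_modulus: float = QUARTZ_MODULUS

    def __post_init__(self) -> None:
        if not 0.0 <= self.inner_diameter < self.outer_diameter:
            raise ValueError(
                "need 0 <= inner_diameter < outer_diameter, got "
                f"{self.inner_diameter!r} / {self.outer_diameter!r}"
            )
        if not 0.0 < self.mount_position < self.probe_length:
            raise ValueError(
                "mount_position must lie strictly between the clamp and the tip"
            )
        if self.material_modulus <= 0.0:
            raise ValueError("material_modulus must be positive")
        if self.pixel_size <= 0.0:
            raise ValueError("pixel_size must be positive")

    @property
    def calibration(self) -> "ProbeCalibration":
        return calibrate(self)


@dataclass(frozen=True)
class ProbeCalibration:
    """Derived constants of a probe: inertia, stiffness, pixel resolution."""

    inertia: float  # m^4
    stiffness: float  # N/m
    force_per_pixel: float  # N per pixel of tip deflection


def moment_of_inertia(spec: ProbeSpec) -> float:
    """Second moment of area of the annular cross section, m^4.

    I_z = pi/64 * (D_p^4 - d_p^4).
    """
    return math.pi / 64.0 * (spec.outer_diameter**4 - spec.inner_diameter**4)


def stiffness(spec: ProbeSpec) -> float:
    """Tip-referred spring stiffness of the probe, N/m (magnitude).

    For a cantilever clamped at 0 and loaded by a point force at ``l``, the
    tip deflection is x = F l^2 (3 L_p - l) / (6 E I_z), hence

        k = F / x = 6 E I_z / (l^2 (3 L_p - l)).

    We store the magnitude; deflection toward the moving probe is taken as
    positive, so a positive stretching force gives a positive deflection.
    """
    iz = moment_of_inertia(spec)
    l = spec.mount_position
    return 6.0 * spec.material_modulus * iz / (l**2 * (3.0 * spec.probe_length - l))


def calibrate(spec: ProbeSpec) -> ProbeCalibration:
    k = stiffness(spec)
    return ProbeCalibration(
        inertia=moment_of_inertia(spec),
        stiffness=k,
        force_per_pixel=k * spec.pixel_size,
    )


def force_from_deflection(spec: ProbeSpec, tip_deflection_pixels: int) -> float:
    """Force (N) from an integer pixel count of tip deflection.

    The camera readout is quantized: only whole-pixel deflections are
    observable, so the force is an integral multiple of
    ``stiffness * pixel_size``.
    """
    n = tip_deflection_pixels
    if n != int(n) or n < 0:
        raise ValueError(f"pixel count must be a non-negative integer, got {n!r}")
    return stiffness(spec) * spec.pixel_size * int(n)


def quantize_deflection(deflection_m: float, pixel_size: float) -> int:
    """Signed whole-pixel readout of a physical deflection.

    Convention: floor of the magnitude (a deflection smaller than one pixel
    reads as zero), sign preserved.
    """
    return int(math.copysign(math.floor(abs(deflection_m) / pixel_size), deflection_m))


def rescale_resolution(force_per_pixel: float, length_scale: float) -> float:
    """Per-pixel force resolution after scaling the probe length.

    Scaling both ``L_p`` and ``l`` by ``length_scale`` (same load-position
    ratio, same cross section) scales the tip stiffness — and hence the
    force per pixel — by ``length_scale**-3``.  Halving the probe turns a
    0.11 uN/px probe into a 0.88 uN/px probe; doubling it does the reverse.
    """
    if length_scale <= 0.0:
        raise ValueError("length_scale must be positive")
    return force_per_pixel * length_scale**-3


def resolution_after_rescale(spec: ProbeSpec, length_scale: float) -> float:
    """Force per pixel (N/px) of ``spec`` with its lengths scaled."""
    return rescale_resolution(calibrate(spec).force_per_pixel, length_scale)


def rescaled(spec: ProbeSpec, length_scale: float) -> ProbeSpec:
    """A copy of ``spec`` with ``L_p`` and ``l`` scaled by ``length_scale``."""
    if length_scale <= 0.0:
        raise ValueError("length_scale must be positive")
    return replace(
        spec,
        probe_length=spec.probe_length * length_scale,
        mount_position=spec.mount_position * length_scale,
    )


# Bundled presets.  The short probe is the stiff, CF-capable viscoelasticity
# probe (~0.88 uN/px); the long probe is its doubled-length variant used for
# contractile-force sensitivity (~0.11 uN/px).  Outer/inner diameters are the
# documented 0.3 / 0.1 mm quartz capillary; lengths are fixture values chosen
# so the short probe lands on 0.88 uN/px with a ~1.1 um camera pixel.
_SHORT = ProbeSpec(
    outer_diameter=0.3e-3,
    inner_diameter=0.1e-3,
    probe_length=50e-3,
    mount_position=45e-3,
    pixel_size=1.1028e-6,
)
PROBE_PRESETS: dict[str, ProbeSpec] = {
    "short": _SHORT,
    "long": rescaled(_SHORT, 2.0),
}


def probe_preset(name: str) -> ProbeSpec:
    try:
        return PROBE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown probe preset {name!r}; valid: {sorted(PROBE_PRESETS)}"
        ) from None
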