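"""Coordinate systems for perimeter screens and headset angular space.

Two device profiles ship built in: ``efa`` (a desktop eye-tracking perimeter
viewed at 400 mm, angular scale 1.0) and ``svft`` (a head-mounted display
viewed at 44 mm whose optics render one retinal degree as 1.54 device
degrees, stereoscopic field of view 90 deg).  Positions are expressed in
signed degrees of visual angle on a flat 2-D plane (no spherical correction);
positive x is temporal for the right eye, positive y is up.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from .errors import InvalidProfileError, OutOfFieldError

__all__ = [
    "AngularPosition",
    "ScreenPoint",
    "DeviceProfile",
    "EFA",
    "SVFT",
    "get_profile",
    "load_profiles",
    "screen_offset_to_retinal_deg",
    "retinal_deg_to_screen_offset",
    "efa_to_svft",
    "svft_to_efa",
    "angular_distance",
]


@dataclass(frozen=True)
class AngularPosition:
    """A point in the visual field, in signed degrees of visual angle."""

    x_deg: float
    y_deg: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_deg) and math.isfinite(self.y_deg)):
            raise ValueError("angular position must be finite")

    @property
    def eccentricity(self) -> float:
        """Radial distance from fixation, in degrees."""
        return math.hypot(self.x_deg, self.y_deg)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x_deg, self.y_deg)


@dataclass(frozen=True)
class DeviceProfile:
    """Display geometry of one device.

    ``angular_scale`` converts retinal degrees to device degrees; ``fov_deg``
    is the full (diameter) field of view usable for display targets.
    """

    name: str
    viewing_distance_mm: float
    angular_scale: float
    fov_deg: float

    def __post_init__(self) -> None:
        if self.viewing_distance_mm <= 0:
            raise InvalidProfileError(
                f"profile {self.name!r}: viewing_distance_mm must be > 0"
            )
        if self.angular_scale <= 0:
            raise InvalidProfileError(f"profile {self.name!r}: angular_scale must be > 0")
        if self.fov_deg <= 0:
            raise InvalidProfileError(f"profile {self.name!r}: fov_deg must be > 0")


@dataclass(frozen=True)
class ScreenPoint:
    """A point on a device's physical screen, in mm from screen centre."""

    x_mm: float
    y_mm: float
    device: DeviceProfile

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_mm) and math.isfinite(self.y_mm)):
            raise ValueError("screen point must be finite")


def load_profiles() -> dict[str, DeviceProfile]:
    """Load the bundled device-profile registry."""
    raw = resources.files("vistrain.data").joinpath("devices.json").read_text()
    return {
        entry["name"]: DeviceProfile(
            name=entry["name"],
            viewing_distance_mm=entry["viewing_distance_mm"],
            angular_scale=entry["angular_scale"],
            fov_deg=entry["fov_deg"],
        )
        for entry in json.loads(raw)
    }


_PROFILES = load_profiles()
EFA: DeviceProfile = _PROFILES["efa"]
SVFT: DeviceProfile = _PROFILES["svft"]


def get_profile(name: str) -> DeviceProfile:
    """Look up a built-in device profile by name."""
    try:
        return _PROFILES[name.lower()]
    except KeyError:
        raise InvalidProfileError(f"unknown device profile {name!r}") from None


def screen_offset_to_retinal_deg(s_mm: float, d_mm: float) -> float:
    """Visual angle (degrees) subtended by an offset ``s_mm`` viewed at ``d_mm``.

    Returns ``2*atan(s/(2d))`` in degrees; an odd, strictly increasing
    function of the offset.
    """
    if d_mm <= 0:
        raise InvalidProfileError("viewing distance must be > 0")
    return math.degrees(2.0 * math.atan2(s_mm, 2.0 * d_mm))


def retinal_deg_to_screen_offset(deg: float, d_mm: float) -> float:
    """Inverse of :func:`screen_offset_to_retinal_deg`."""
    if d_mm <= 0:
        raise InvalidProfileError("viewing distance must be > 0")
    return 2.0 * d_mm * math.tan(math.radians(deg) / 2.0)


def efa_to_svft(p: ScreenPoint) -> AngularPosition:
    """Convert a perimeter screen point to headset display degrees.

    Each axis is converted independently: the mm offset is turned into
    retinal degrees via the subtended-angle formula at the perimeter's
    viewing distance, then multiplied by the headset's angular scale (1.54).

    Raises :class:`OutOfFieldError` when the result exceeds the headset's
    half field of view; the error carries the radially clipped coordinate.
    """
    if p.device.name != EFA.name:
        raise InvalidProfileError(
            f"efa_to_svft expects a point on the {EFA.name!r} display, got {p.device.name!r}"
        )
    x = screen_offset_to_retinal_deg(p.x_mm, p.device.viewing_distance_mm) * SVFT.angular_scale
    y = screen_offset_to_retinal_deg(p.y_mm, p.device.viewing_distance_mm) * SVFT.angular_scale
    half = SVFT.fov_deg / 2.0
    r = math.hypot(x, y)
    if r > half:
        scale = half / r
        raise OutOfFieldError(
            f"({x:.3f}, {y:.3f}) deg exceeds the {SVFT.name} half field of view ({half} deg)",
            clipped=(x * scale, y * scale),
        )
    return AngularPosition(x, y)


def svft_to_efa(a: AngularPosition) -> ScreenPoint:
    """Exact inverse of :func:`efa_to_svft` (headset degrees -> perimeter mm)."""
    half = SVFT.fov_deg / 2.0
    if a.eccentricity > half + 1e-12:
        raise OutOfFieldError(
            f"{a} exceeds the {SVFT.name} half field of view ({half} deg)",
            clipped=(a.x_deg * half / a.eccentricity, a.y_deg * half / a.eccentricity),
        )
    d = EFA.viewing_distance_mm
    x = retinal_deg_to_screen_offset(a.x_deg / SVFT.angular_scale, d)
    y = retinal_deg_to_screen_offset(a.y_deg / SVFT.angular_scale, d)
    return ScreenPoint(x, y, EFA)


def angular_distance(a: AngularPosition, b: AngularPosition) -> float:
    """Euclidean distance between two field positions, in degrees."""
    return math.hypot(a.x_deg - b.x_deg, a.y_deg - b.y_deg)
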