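"""Source and detector models with the signed-angle convention.

Both optics are modelled at the phantom surface.  The source is a
collimated beam whose 0.610 mm spot (200 um facet imaged at magnification
3.05) is projected obliquely; the detector is a 0.55 mm surface spot plus
an acceptance cone standing in for the collection lens.

Sign convention (angles in the x-z plane, degrees):

* positive theta_s tilts the source beam toward the detector (+x);
* positive theta_d tilts the detector axis toward the source, so accepted
  photons leave the surface travelling upward with a +x component;
* negative angles tilt source and detector away from each other.

Angle changes never move the spot centres: the source spot stays at
x = -d/2 and the detector spot at x = +d/2 for source-detector distance d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kernel import PhotonState, TerminalEvent
from .scene import GeometryError

__all__ = [
    "SourceConfig",
    "DetectorConfig",
    "source_detector_pair",
    "launch",
    "detect",
]

SOURCE_FACET_DIAMETER = 0.2  # mm
SOURCE_MAGNIFICATION = 3.05
DETECTOR_SPOT_DIAMETER = 0.55  # mm
DETECTOR_LENS_DIAMETER = 10.9  # mm (metadata; lens is not ray-traced)
DETECTOR_FIBRE_DIAMETER = 0.2  # mm (metadata)
DETECTOR_MAGNIFICATION = 2.76  # (metadata)


@dataclass(frozen=True)
class SourceConfig:
    """Collimated source spot on the phantom surface."""

    theta_s: float  # signed degrees
    spot_center: tuple[float, float] = (0.0, 0.0)  # (x, y) on the surface, mm
    facet_diameter: float = SOURCE_FACET_DIAMETER
    magnification: float = SOURCE_MAGNIFICATION
    wavelength: int = 940

    def __post_init__(self) -> None:
        if abs(self.theta_s) >= 90.0:
            raise GeometryError("source angle must satisfy |theta_s| < 90 deg")

    @property
    def spot_diameter(self) -> float:
        """Beam diameter imaged onto the phantom (0.610 mm nominal)."""
        return self.facet_diameter * self.magnification

    @property
    def direction(self) -> np.ndarray:
        """Beam axis (unit vector, +z into the phantom)."""
        th = math.radians(self.theta_s)
        return np.array([math.sin(th), 0.0, math.cos(th)])


@dataclass(frozen=True)
class DetectorConfig:
    """Detector spot plus acceptance cone at the phantom surface."""

    theta_d: float  # signed degrees
    spot_center: tuple[float, float] = (0.0, 0.0)
    spot_diameter: float = DETECTOR_SPOT_DIAMETER
    acceptance_half_angle: float = 30.0  # degrees, in air
    lens_diameter: float = DETECTOR_LENS_DIAMETER
    fibre_diameter: float = DETECTOR_FIBRE_DIAMETER
    magnification: float = DETECTOR_MAGNIFICATION

    def __post_init__(self) -> None:
        if abs(self.theta_d) >= 90.0:
            raise GeometryError("detector angle must satisfy |theta_d| < 90 deg")
        if not (0.0 < self.acceptance_half_angle < 90.0):
            raise GeometryError("acceptance half-angle must lie in (0, 90) deg")

    @property
    def axis(self) -> np.ndarray:
        """Direction of accepted photons leaving the surface (unit vector)."""
        th = math.radians(self.theta_d)
        return np.array([math.sin(th), 0.0, -math.cos(th)])


def source_detector_pair(
    distance: float,
    theta_s: float,
    theta_d: float,
    wavelength: int = 940,
    acceptance_half_angle: float = 30.0,
    mirror: bool = False,
) -> tuple[SourceConfig, DetectorConfig]:
    """Standard geometry: spots at -d/2 and +d/2 on the x axis.

    ``mirror=True`` reflects the whole arrangement about the x = 0 plane
    (source on +x pointing toward -x); by symmetry of the scene this must
    give statistically identical results and is used as a sign-convention
    smoke test.
    """
    if distance <= 0:
        raise GeometryError("source-detector distance must be positive")
    s = -1.0 if mirror else 1.0
    src = SourceConfig(
        theta_s=s * theta_s, spot_center=(-s * distance / 2.0, 0.0),
        wavelength=wavelength,
    )
    det = DetectorConfig(
        theta_d=s * theta_d, spot_center=(s * distance / 2.0, 0.0),
        acceptance_half_angle=acceptance_half_angle,
    )
    return src, det


def launch(source: SourceConfig, rng: np.random.Generator) -> PhotonState:
    """Sample one photon at the surface spot (before the entry interface).

    Position is uniform over the collimated beam cross-section, projected
    onto the surface: the circular footprint becomes an ellipse with major
    axis (spot diameter)/cos(theta_s) along x under oblique incidence.
    The returned packet carries the beam direction in air; specular loss
    at the phantom surface is applied by the standard interface event in
    the transport kernel.
    """
    th = math.radians(source.theta_s)
    r = 0.5 * source.spot_diameter * math.sqrt(rng.random())
    ang = 2.0 * math.pi * rng.random()
    x = source.spot_center[0] + r * math.cos(ang) / math.cos(th)
    y = source.spot_center[1] + r * math.sin(ang)
    return PhotonState(
        position=np.array([x, y, 0.0]),
        direction=source.direction,
        weight=1.0,
        current_material="air",
    )


def detect(event: TerminalEvent, det: DetectorConfig):
    """Weight accepted by the detector from one surface-exit event.

    Accepts iff the exit position lies in the detector spot ellipse (the
    0.55 mm disc projected at theta_d) and the exit direction lies within
    the acceptance cone about the detector axis.  Returns the accepted
    weight, or None on rejection.
    """
    if event.kind != "escaped" and event.kind != "detected":
        return None
    if event.exit_position is None or event.exit_direction is None:
        return None
    th = math.radians(det.theta_d)
    ax = 0.5 * det.spot_diameter / math.cos(th if abs(th) < math.pi / 2 else 0.0)
    ax = abs(ax)
    by = 0.5 * det.spot_diameter
    rx = (event.exit_position[0] - det.spot_center[0]) / ax
    ry = (event.exit_position[1] - det.spot_center[1]) / by
    if rx * rx + ry * ry > 1.0:
        return None
    u = np.asarray(event.exit_direction, dtype=float)
    cosang = float(np.dot(u, det.axis))
    if cosang < math.cos(math.radians(det.acceptance_half_angle)):
        return None
    return event.weight
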