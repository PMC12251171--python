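"""Materials, optical properties and the layered measurement scene.

The simulated scene reproduces a laboratory reflectance-PPG setup: a
homogeneous cylindrical skin phantom (radius 25 mm, height 50 mm) whose
polished top surface carries, from bottom to top, a thin air gap, 1 mm
microscope slides, and a vertical opaque barrier (0.5 mm thick) centred
between the source and detector spots to suppress direct optical
cross-talk.  The phantom is the only scattering medium; glass and air are
traversed with Lambert-Beer attenuation only, and the barrier is a perfect
absorber.

Coordinate convention
---------------------
Origin at the phantom surface midpoint between the source and detector
spots; +z points *into* the phantom; +x points from the source spot toward
the detector spot; all lengths in mm.  The superstructure (gap, slides,
barrier) therefore lives at z < 0 and the phantom occupies
0 <= z <= height within the cylinder radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "OpticalProperties",
    "Material",
    "Scene",
    "SceneConfig",
    "phantom_properties",
    "glass_properties",
    "derive_mu_s",
    "build_scene",
    "material_at",
    "WAVELENGTHS",
    "AMBIENT",
    "AIR_GAP",
    "GLASS",
    "PHANTOM",
    "BARRIER",
    "MATERIAL_NAMES",
    "UnsupportedWavelengthError",
    "GeometryError",
]

WAVELENGTHS = (520, 637, 940)

# integer material codes shared with the transport kernel and voxel grid
AMBIENT = 0
AIR_GAP = 1
GLASS = 2
PHANTOM = 3
BARRIER = 4

MATERIAL_NAMES = {
    AMBIENT: "ambient",
    AIR_GAP: "air",
    GLASS: "glass",
    PHANTOM: "phantom",
    BARRIER: "barrier",
}


class UnsupportedWavelengthError(ValueError):
    """Raised for wavelengths outside the characterised set {520, 637, 940} nm."""


class GeometryError(ValueError):
    """Raised for geometrically inconsistent scene configurations."""


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one material at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient [1/mm].
    mu_s_reduced : float
        Reduced scattering coefficient mu_s' = mu_s (1 - g) [1/mm].
    g : float
        Scattering anisotropy (mean cosine of the single-scattering angle).
    n : float
        Refractive index.
    """

    mu_a: float
    mu_s_reduced: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_reduced < 0:
            raise ValueError("mu_a and mu_s_reduced must be non-negative")
        if not (-1.0 < self.g < 1.0):
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g) [1/mm]."""
        return derive_mu_s(self)


@dataclass(frozen=True)
class Material:
    name: str
    properties: OpticalProperties
    scattering: bool = False
    perfect_absorber: bool = False


# Characterised optical parameters of the epoxy-resin porcine-skin phantom
# and the microscope slides at the three sensor wavelengths.
_PHANTOM_TABLE = {
    520: OpticalProperties(mu_a=0.093, mu_s_reduced=1.719, g=0.550, n=1.561),
    637: OpticalProperties(mu_a=0.019, mu_s_reduced=1.376, g=0.550, n=1.552),
    940: OpticalProperties(mu_a=0.016, mu_s_reduced=0.793, g=0.550, n=1.543),
}

_GLASS_MU_A = {520: 0.004, 637: 0.005, 940: 0.029}
_GLASS_N = 1.520

_AIR = OpticalProperties(mu_a=0.0, mu_s_reduced=0.0, g=0.0, n=1.000)


def phantom_properties(wavelength: int) -> OpticalProperties:
    """Phantom optical properties at a characterised wavelength [nm]."""
    try:
        return _PHANTOM_TABLE[int(wavelength)]
    except (KeyError, TypeError) as err:
        raise UnsupportedWavelengthError(
            f"no phantom characterisation at {wavelength} nm; "
            f"supported: {sorted(_PHANTOM_TABLE)}"
        ) from err


def glass_properties(wavelength: int) -> OpticalProperties:
    """Microscope-slide glass properties at a characterised wavelength [nm]."""
    try:
        mu_a = _GLASS_MU_A[int(wavelength)]
    except (KeyError, TypeError) as err:
        raise UnsupportedWavelengthError(
            f"no glass characterisation at {wavelength} nm; "
            f"supported: {sorted(_GLASS_MU_A)}"
        ) from err
    return OpticalProperties(mu_a=mu_a, mu_s_reduced=0.0, g=0.0, n=_GLASS_N)


def air_properties() -> OpticalProperties:
    return _AIR


def derive_mu_s(props: OpticalProperties) -> float:
    """Scattering coefficient from the similarity relation mu_s' = mu_s (1-g)."""
    if props.g >= 1.0:
        raise ValueError("degenerate anisotropy g = 1: mu_s undefined")
    return props.mu_s_reduced / (1.0 - props.g)


@dataclass(frozen=True)
class SceneConfig:
    """Geometric configuration of the measurement scene (all lengths mm)."""

    phantom_radius: float = 25.0
    phantom_height: float = 50.0
    slide_thickness: float = 1.0
    air_gap_thickness: float = 0.02
    barrier_thickness: float = 0.5
    barrier_height: float = 5.0
    voxel_edge: float = 0.1
    # drop gap/slides/barrier entirely (bare half-space phantom, used for
    # homogeneous-medium sanity checks)
    bare_phantom: bool = False
    # lateral half-extent of the voxel grid; defaults to the phantom radius
    voxel_half_extent: float = 25.0


@dataclass
class Scene:
    """Composite scene: analytic phantom half-cylinder + voxelized superstructure.

    The voxel grid covers the region above the phantom surface (z < 0) that
    contains the air gap, slides and barrier; below the surface the phantom
    is represented analytically as a homogeneous cylinder.
    """

    config: SceneConfig
    wavelength: int
    materials: dict[int, Material]
    voxel_grid: np.ndarray = field(repr=False)  # uint8 [nx, ny, nz]
    voxel_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    voxel_edge: float = 0.1

    @property
    def phantom(self) -> Material:
        return self.materials[PHANTOM]

    @property
    def glass(self) -> Material:
        return self.materials[GLASS]

    def summary(self) -> dict:
        """JSON-serialisable provenance summary of the scene."""
        counts = np.bincount(self.voxel_grid.ravel(), minlength=5)
        return {
            "wavelength_nm": self.wavelength,
            "config": asdict(self.config),
            "voxel_shape": list(self.voxel_grid.shape),
            "voxel_origin_mm": list(self.voxel_origin),
            "voxel_edge_mm": self.voxel_edge,
            "voxel_counts": {MATERIAL_NAMES[i]: int(c) for i, c in enumerate(counts)},
            "materials": {
                MATERIAL_NAMES[i]: asdict(m.properties)
                for i, m in self.materials.items()
            },
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def _material_above_analytic(
    x: float,
    y: float,
    z: float,
    gap: float,
    slide: float,
    barrier_half: float,
    barrier_height: float,
    radius: float,
) -> int:
    """Material identity above the phantom surface (z < 0), closed form.

    Mirrors the voxelization rules; the transport kernel uses the same
    logic (re-stated in compiled code) and a test pins the agreement.
    """
    if x * x + y * y > radius * radius:
        return AMBIENT
    if abs(x) <= barrier_half and z >= -barrier_height:
        return BARRIER
    if z >= -gap:
        return AIR_GAP
    if z >= -(gap + slide):
        return GLASS
    return AMBIENT


def build_scene(config: SceneConfig, wavelength: int) -> Scene:
    """Construct the scene for one wavelength.

    Raises
    ------
    GeometryError
        If the voxel edge cannot resolve the 0.5 mm barrier.
    UnsupportedWavelengthError
        For wavelengths outside the characterised set.
    """
    if config.voxel_edge <= 0:
        raise GeometryError("voxel_edge must be positive")
    if not config.bare_phantom and config.voxel_edge > config.barrier_thickness:
        raise GeometryError(
            f"voxel_edge {config.voxel_edge} mm exceeds barrier thickness "
            f"{config.barrier_thickness} mm; barrier would not be representable"
        )
    if config.air_gap_thickness < 0 or config.slide_thickness < 0:
        raise GeometryError("layer thicknesses must be non-negative")

    phantom = Material(
        "phantom", phantom_properties(wavelength), scattering=True
    )
    glass = Material("glass", glass_properties(wavelength))
    air = Material("air", _AIR)
    ambient = Material("ambient", _AIR)
    # barrier optical properties are irrelevant (weight is zeroed on entry)
    barrier = Material("barrier", _AIR, perfect_absorber=True)
    materials = {
        AMBIENT: ambient,
        AIR_GAP: air,
        GLASS: glass,
        PHANTOM: phantom,
        BARRIER: barrier,
    }

    edge = config.voxel_edge
    half = config.voxel_half_extent
    if config.bare_phantom:
        top = edge  # single token layer of ambient
    else:
        top = config.air_gap_thickness + config.slide_thickness
        top = max(top, config.barrier_height)
    nx = ny = max(1, int(np.ceil(2.0 * half / edge)))
    nz = max(1, int(np.ceil(top / edge)))

    # voxel (i, j, k) spans x in [x0 + i*edge, ...), z in [-k*edge - edge, -k*edge)
    # with k = 0 the layer touching the surface; store material at voxel centres.
    x0 = -0.5 * nx * edge
    y0 = -0.5 * ny * edge
    xc = x0 + (np.arange(nx) + 0.5) * edge
    yc = y0 + (np.arange(ny) + 0.5) * edge
    zc = -((np.arange(nz) + 0.5) * edge)

    grid = np.full((nx, ny, nz), AMBIENT, dtype=np.uint8)
    if not config.bare_phantom:
        X = xc[:, None, None]
        Y = yc[None, :, None]
        Z = zc[None, None, :]
        inside_r = (X * X + Y * Y) <= config.phantom_radius**2
        bh = 0.5 * config.barrier_thickness
        in_barrier = (np.abs(X) <= bh) & (Z >= -config.barrier_height) & inside_r
        in_gap = (Z >= -config.air_gap_thickness) & inside_r & ~in_barrier
        in_glass = (
            (Z < -config.air_gap_thickness)
            & (Z >= -(config.air_gap_thickness + config.slide_thickness))
            & inside_r
            & ~in_barrier
        )
        grid[np.broadcast_to(in_gap, grid.shape)] = AIR_GAP
        grid[np.broadcast_to(in_glass, grid.shape)] = GLASS
        grid[np.broadcast_to(in_barrier, grid.shape)] = BARRIER

    return Scene(
        config=config,
        wavelength=wavelength,
        materials=materials,
        voxel_grid=grid,
        voxel_origin=(x0, y0, 0.0),
        voxel_edge=edge,
    )


def material_at(scene: Scene, position) -> Material:
    """Material at a point (mm). Deterministic; out-of-bounds maps to ambient.

    Below the surface plane the analytic phantom cylinder takes precedence;
    above it the voxel grid is consulted.
    """
    x, y, z = (float(v) for v in position)
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        raise ValueError("position must be finite")
    cfg = scene.config
    if z >= 0.0:
        if (
            z <= cfg.phantom_height
            and x * x + y * y <= cfg.phantom_radius**2
        ):
            return scene.materials[PHANTOM]
        return scene.materials[AMBIENT]
    x0, y0, _ = scene.voxel_origin
    edge = scene.voxel_edge
    i = int(np.floor((x - x0) / edge))
    j = int(np.floor((y - y0) / edge))
    k = int(np.floor(-z / edge))
    nx, ny, nz = scene.voxel_grid.shape
    if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
        return scene.materials[int(scene.voxel_grid[i, j, k])]
    return scene.materials[AMBIENT]
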