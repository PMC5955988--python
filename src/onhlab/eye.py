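"""Geometric eye model for Maxwellian-view stimulation.

The globe is modelled as a spheroid with the optical axis along z: semi-axis
``axial_length/2`` axially and ``transverse_diameter/2`` in both transverse
directions.  The visual stimulus is a cone of straight rays of a given
half-angle cast from a point on the optical axis toward the posterior pole.
Refraction by the ocular media is not modelled; instead the cone apex is
placed, by default, at the posterior nodal point of the schematic rat eye
(~3 mm behind the anterior corneal pole), which is the standard first-order
mapping between stimulus visual angle and retinal extent.

The illuminated retinal area is the surface area of the posterior cap swept
by the ray cone, obtained by triangulating the ray-to-shell intersection
points over the cone's angular domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EyeGeometry",
    "axial_length_from_wrapped",
    "illuminated_area",
    "retinal_luminance_scale",
]


@dataclass(frozen=True)
class EyeGeometry:
    """Spheroidal eye with an on-axis Maxwellian stimulus cone.

    Parameters
    ----------
    axial_length_mm:
        Pole-to-pole length of the globe along the optical axis (mm).
    transverse_diameter_mm:
        Equatorial diameter of the globe (mm).
    apex_offset_mm:
        Distance of the cone apex from the anterior pole along the optical
        axis (mm).  Default 3.0 mm: the posterior nodal point of the
        schematic rat eye, the effective divergence point of a stimulus
        focused at the pupil plane once corneal/lenticular refraction is
        folded in.
    half_angle_deg:
        Half-angle of the stimulus cone (degrees), in (0, 90].
    """

    axial_length_mm: float
    transverse_diameter_mm: float
    apex_offset_mm: float = 3.0
    half_angle_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.axial_length_mm <= 0 or self.transverse_diameter_mm <= 0:
            raise ValueError("eye dimensions must be positive")
        if self.apex_offset_mm <= 0:
            raise ValueError("apex offset must be positive")
        if not 0.0 < self.half_angle_deg <= 90.0:
            raise ValueError("half-angle must lie in (0, 90] degrees")

    @property
    def semi_axis_axial_mm(self) -> float:
        return self.axial_length_mm / 2.0

    @property
    def semi_axis_transverse_mm(self) -> float:
        return self.transverse_diameter_mm / 2.0

    @property
    def apex_z_mm(self) -> float:
        """Apex position on the optical axis (anterior pole at +a)."""
        return self.semi_axis_axial_mm - self.apex_offset_mm


def axial_length_from_wrapped(distance_mm: float) -> float:
    """Axial eye length from a wrapped anterior-segment B-scan measure.

    In a swept-source B-scan wrapped around the zero-delay line, the corneal
    apex appears at half the eye's optical length from the image top edge;
    the axial length is therefore twice the measured top-edge-to-apex
    distance.
    """
    if not np.isfinite(distance_mm) or distance_mm <= 0:
        raise ValueError("wrapped-scan distance must be positive and finite")
    return 2.0 * distance_mm


def _ray_hits(geometry: EyeGeometry, alpha: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Intersection of cone rays with the posterior spheroid shell.

    ``alpha`` is the polar angle from the posterior-pointing axis (-z) and
    ``phi`` the azimuth.  Broadcasts ``alpha``/``phi``; returns points with
    shape ``broadcast + (3,)``.
    """
    a = geometry.semi_axis_axial_mm
    b = geometry.semi_axis_transverse_mm
    zp = geometry.apex_z_mm
    if (zp / a) ** 2 >= 1.0:
        raise ValueError("cone apex lies outside the spheroid")

    alpha, phi = np.broadcast_arrays(alpha, phi)
    # direction: posterior along -z
    dx = np.sin(alpha) * np.cos(phi)
    dy = np.sin(alpha) * np.sin(phi)
    dz = -np.cos(alpha)
    # quadratic for |origin + t d| on the spheroid, origin = (0, 0, zp)
    qa = (dx**2 + dy**2) / b**2 + dz**2 / a**2
    qb = 2.0 * zp * dz / a**2
    qc = zp**2 / a**2 - 1.0
    t = (-qb + np.sqrt(qb**2 - 4.0 * qa * qc)) / (2.0 * qa)
    return np.stack([t * dx, t * dy, zp + t * dz], axis=-1)


def illuminated_area(geometry: EyeGeometry, n_polar: int = 512, n_azimuth: int = 256) -> float:
    """Illuminated posterior surface area (mm^2) of the stimulus cone.

    Rays are cast on an (alpha, phi) grid over the cone, intersected with
    the spheroid, and the resulting curvilinear quad mesh is triangulated;
    the area is the summed triangle area.  The default mesh is converged
    well below 0.5% (halving the mesh changes the result by <0.2%).
    """
    theta = np.deg2rad(geometry.half_angle_deg)
    alpha = np.linspace(0.0, theta, n_polar + 1)
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth + 1)
    pts = _ray_hits(geometry, alpha[:, None], phi[None, :])

    p00 = pts[:-1, :-1]
    p10 = pts[1:, :-1]
    p01 = pts[:-1, 1:]
    p11 = pts[1:, 1:]
    # two triangles per quad
    area = 0.5 * (
        np.linalg.norm(np.cross(p10 - p00, p01 - p00), axis=-1)
        + np.linalg.norm(np.cross(p10 - p11, p01 - p11), axis=-1)
    )
    return float(area.sum())


def retinal_luminance_scale(area_baseline_mm2: float, area_elevated_mm2: float) -> float:
    """Relative retinal irradiance when the same flux spreads over a new area.

    Under constant total stimulus energy, retinal luminance scales inversely
    with the illuminated area; the returned factor is baseline/elevated.
    """
    if area_baseline_mm2 <= 0 or area_elevated_mm2 <= 0:
        raise ValueError("areas must be positive")
    return area_baseline_mm2 / area_elevated_mm2
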