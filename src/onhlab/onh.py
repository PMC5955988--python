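"""ONH-depression morphometry and circular-scan layer thickness.

The depression statistic follows the study definition: surface elevation is
sampled radially from the ONH centre, averaged over rays in a narrow
annulus at 150 µm (ONH boundary, h_i) and at 500 µm (peripheral reference,
h_o), and reported as D = h_o - h_i — positive for a posteriorly bowed
(depressed) ONH.  Sign is a declared convention of this package.

Layer thicknesses are measured on a circular scan (default Ø 1 mm, 3000
samples) resampled from the registered volume; samples under large vessel
shadows are excluded before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .oct import (
    ElevationMap,
    OCTVolume,
    SurfaceMap,
    register_bscans,
    segment_band_boundary,
    segment_surfaces,
    surface_to_elevation,
)

__all__ = [
    "RadialProfileSet",
    "DepressionResult",
    "ThicknessResult",
    "detect_onh_center",
    "radial_profiles",
    "onh_depression",
    "vessel_shadow_mask",
    "circular_scan_thickness",
    "depression_from_volume",
]


@dataclass
class RadialProfileSet:
    """Elevation sampled along rays sharing one radius grid (all µm)."""

    center_um: tuple[float, float]
    angles_rad: np.ndarray  # (n_rays,)
    radii_um: np.ndarray  # (n_r,) strictly increasing, >= 0
    elevation_um: np.ndarray  # (n_rays, n_r)
    valid: np.ndarray  # (n_rays, n_r)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_um, float)
        if r.ndim != 1 or np.any(np.diff(r) <= 0) or r[0] < 0:
            raise ValueError("radius grid must be strictly increasing and start >= 0")


@dataclass(frozen=True)
class DepressionResult:
    """ONH depression D = h_o - h_i (µm), with the annulus means it came from."""

    depression_um: float
    h_inner_um: float
    h_outer_um: float
    n_rays_used: int


@dataclass(frozen=True)
class ThicknessResult:
    """Circular-scan mean thicknesses (µm) and the vessel-excluded fraction."""

    nfl_gcl_um: float
    gcc_um: float
    total_um: float
    vessel_fraction: float


def detect_onh_center(
    elevation: ElevationMap,
    provided_um: tuple[float, float] | None = None,
    disc_radius_um: float = 150.0,
    min_pit_depth_um: float = 10.0,
) -> tuple[float, float]:
    """ONH centre in µm: manual pass-through or deepest-pit auto-detection.

    Manual mode mirrors the study (the operator picks the convergence point
    of the major vessels): a provided centre is bounds-checked and returned.
    Auto mode minimises the mean elevation over a disc of
    ``disc_radius_um`` and refuses maps with no discernible pit.
    """
    ny, nx = elevation.height_um.shape
    sp = elevation.lateral_spacing_um
    if provided_um is not None:
        x, y = provided_um
        if not (0 <= x <= (nx - 1) * sp and 0 <= y <= (ny - 1) * sp):
            raise ValueError(f"provided centre {provided_um} lies outside the map")
        return (float(x), float(y))

    r_px = max(1, int(round(disc_radius_um / sp)))
    yy, xx = np.ogrid[-r_px : r_px + 1, -r_px : r_px + 1]
    disc = (xx**2 + yy**2) <= r_px**2
    h = np.where(elevation.valid, elevation.height_um, 0.0)
    num = ndimage.convolve(h, disc.astype(float), mode="nearest")
    den = ndimage.convolve(elevation.valid.astype(float), disc.astype(float), mode="nearest")
    mean = np.where(den > 0.5 * disc.sum(), num / np.maximum(den, 1e-9), np.inf)
    iy, ix = np.unravel_index(np.argmin(mean), mean.shape)
    ref = float(np.median(elevation.height_um[elevation.valid]))
    if ref - mean[iy, ix] < min_pit_depth_um:
        raise ValueError("no pit detected (map is flat at the disc scale)")
    return (float(ix * sp), float(iy * sp))


def radial_profiles(
    elevation: ElevationMap,
    center_um: tuple[float, float],
    n_rays: int = 360,
    r_max_um: float = 520.0,
    dr_um: float | None = None,
) -> RadialProfileSet:
    """Bilinear radial resampling of the elevation map around the centre.

    Rays are equally spaced over the full circle; samples interpolated from
    any invalid pixel, or falling outside the map, are masked.
    """
    if n_rays < 8:
        raise ValueError("n_rays must be >= 8 (ray quorum undefined below that)")
    if r_max_um < 500.0:
        raise ValueError("r_max must reach the 500 µm reference radius")
    sp = elevation.lateral_spacing_um
    if dr_um is None:
        dr_um = sp / 2.0
    radii = np.arange(0.0, r_max_um + dr_um / 2.0, dr_um)
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)

    cx, cy = center_um
    xs = (cx + np.cos(angles)[:, None] * radii[None, :]) / sp
    ys = (cy + np.sin(angles)[:, None] * radii[None, :]) / sp
    coords = np.stack([ys, xs])  # map axes are (y=b_scan, x=a_scan)

    h = np.where(elevation.valid, elevation.height_um, 0.0)
    samples = ndimage.map_coordinates(h, coords, order=1, mode="constant", cval=0.0)
    vmask = ndimage.map_coordinates(
        elevation.valid.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    ny, nx = elevation.height_um.shape
    inside = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
    valid = (vmask > 0.999) & inside  # every contributing pixel valid

    if not inside.all():
        import warnings

        warnings.warn(
            "centre lies closer than r_max to the map border; rays truncated",
            stacklevel=2,
        )
    if not valid.any():
        raise ValueError("all radial samples are masked")
    return RadialProfileSet(
        center_um=(float(cx), float(cy)),
        angles_rad=angles,
        radii_um=radii,
        elevation_um=samples,
        valid=valid,
    )


def onh_depression(
    profiles: RadialProfileSet,
    r_inner_um: float = 150.0,
    r_outer_um: float = 500.0,
    annulus_halfwidth_um: float = 10.0,
    ray_quorum: float = 0.75,
) -> DepressionResult:
    """Averaged elevation difference between the 150 µm and 500 µm annuli.

    A ray contributes only if it has valid samples inside both annuli; if
    fewer than ``ray_quorum`` of the rays survive, the metric refuses and
    names the masked rays.
    """
    r = profiles.radii_um
    if r[-1] < r_outer_um - annulus_halfwidth_um:
        raise ValueError("radius grid does not cover the outer reference")

    def ring_mean(r0: float) -> tuple[np.ndarray, np.ndarray]:
        ring = np.abs(r - r0) <= annulus_halfwidth_um
        if not ring.any():
            raise ValueError(f"no radial samples inside the {r0:.0f} µm annulus")
        v = profiles.valid[:, ring]
        e = profiles.elevation_um[:, ring]
        ok = v.any(axis=1)
        means = np.where(
            ok, (e * v).sum(axis=1) / np.maximum(v.sum(axis=1), 1), np.nan
        )
        return means, ok

    hi, ok_i = ring_mean(r_inner_um)
    ho, ok_o = ring_mean(r_outer_um)
    use = ok_i & ok_o
    n_rays = len(profiles.angles_rad)
    if use.sum() < ray_quorum * n_rays:
        bad = np.flatnonzero(~use)
        raise ValueError(
            f"ray quorum failed: {use.sum()}/{n_rays} rays valid at both radii; "
            f"masked rays: {bad[:20].tolist()}{'...' if len(bad) > 20 else ''}"
        )
    h_i = float(hi[use].mean())
    h_o = float(ho[use].mean())
    return DepressionResult(
        depression_um=h_o - h_i,
        h_inner_um=h_i,
        h_outer_um=h_o,
        n_rays_used=int(use.sum()),
    )


def depression_from_volume(
    volume: OCTVolume,
    center_um: tuple[float, float] | None = None,
    n_rays: int = 360,
) -> DepressionResult:
    """Full measurement chain: register, segment, elevate, locate, measure.

    Convenience wrapper running the whole ONH-depression pipeline on a raw
    (possibly motion-corrupted) volume; the centre is auto-detected unless
    provided.
    """
    registered, _ = register_bscans(volume)
    ilm, _ = segment_surfaces(registered)
    elevation = surface_to_elevation(ilm, registered)
    center = detect_onh_center(elevation, provided_um=center_um)
    return onh_depression(radial_profiles(elevation, center, n_rays=n_rays))


def vessel_shadow_mask(
    volume: OCTVolume,
    ilm: SurfaceMap,
    quantile: float = 0.15,
    dilate_px: int = 3,
    depth_range_um: tuple[float, float] = (10.0, 160.0),
) -> np.ndarray:
    """En-face mask of large vessel shadows from the sub-ILM projection.

    The mean intensity between ``depth_range_um`` below the ILM is
    projected en face; pixels darker than the given quantile are flagged
    and the mask dilated to cover the shadow penumbra.  The quantile cut is
    capped at 0.6x the median projection so that a vessel-free map flags
    nothing (shadows attenuate several-fold; speckle does not).
    """
    nb, na, nz = volume.shape
    z0 = depth_range_um[0] / volume.axial_spacing_um
    z1 = depth_range_um[1] / volume.axial_spacing_um
    zz = np.arange(nz)
    band = (zz >= (ilm.depth_px[..., None] + z0)) & (zz <= (ilm.depth_px[..., None] + z1))
    proj = (volume.data * band).sum(axis=-1) / np.maximum(band.sum(axis=-1), 1)
    ref = proj[ilm.valid] if ilm.valid.any() else proj
    thr = min(float(np.quantile(ref, quantile)), 0.6 * float(np.median(ref)))
    mask = proj < thr
    if dilate_px > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate_px)
    return mask


def circular_scan_thickness(
    volume: OCTVolume,
    center_um: tuple[float, float],
    radius_um: float = 500.0,
    n_samples: int = 3000,
    band_windows_um: tuple[tuple[float, float], tuple[float, float]] = (
        (15.0, 65.0),
        (55.0, 105.0),
    ),
    vessel_mask: np.ndarray | None = None,
    vessel_quantile: float = 0.15,
    max_excluded: float = 0.5,
) -> ThicknessResult:
    """Layer thicknesses on a circular scan around the ONH centre.

    The volume is resampled by bilinear interpolation on ``n_samples``
    points of the circle, the ILM/RPE and the two inner band boundaries
    (searched inside ``band_windows_um`` below the ILM, with bright-to-dark
    polarity) are segmented on the resulting circular B-scan, and
    boundary-to-boundary distances are averaged over samples not excluded
    by the vessel mask.
    """
    nb, na, nz = volume.shape
    sp = volume.lateral_spacing_um
    cx, cy = center_um
    for x, y in ((cx - radius_um, cy), (cx + radius_um, cy), (cx, cy - radius_um), (cx, cy + radius_um)):
        if not (0 <= x <= (na - 1) * sp and 0 <= y <= (nb - 1) * sp):
            raise ValueError("scan circle extends beyond the volume footprint")

    theta = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    xs = (cx + radius_um * np.cos(theta)) / sp
    ys = (cy + radius_um * np.sin(theta)) / sp

    zz = np.arange(nz, dtype=float)
    coords = np.stack(
        [
            np.broadcast_to(ys[:, None], (n_samples, nz)),
            np.broadcast_to(xs[:, None], (n_samples, nz)),
            np.broadcast_to(zz[None, :], (n_samples, nz)),
        ]
    )
    circ = ndimage.map_coordinates(volume.data, coords, order=1, mode="nearest")
    circ_vol = OCTVolume(
        circ[None, ...], volume.lateral_spacing_um, volume.axial_spacing_um
    )

    ilm_c, rpe_c = segment_surfaces(circ_vol)
    ax = volume.axial_spacing_um
    inner1 = segment_band_boundary(
        circ_vol,
        polarity=-1,
        z_min=ilm_c.depth_px + band_windows_um[0][0] / ax,
        z_max=ilm_c.depth_px + band_windows_um[0][1] / ax,
    )
    inner2 = segment_band_boundary(
        circ_vol,
        polarity=-1,
        z_min=ilm_c.depth_px + band_windows_um[1][0] / ax,
        z_max=ilm_c.depth_px + band_windows_um[1][1] / ax,
    )

    if vessel_mask is None:
        ilm_full, _ = segment_surfaces(volume)
        vessel_mask = vessel_shadow_mask(volume, ilm_full, quantile=vessel_quantile)
    excluded = ndimage.map_coordinates(
        vessel_mask.astype(float), np.stack([ys, xs]), order=1, mode="nearest"
    ) > 0.01
    keep = ilm_c.valid[0] & rpe_c.valid[0] & ~excluded
    frac_excluded = float(excluded.mean())
    if keep.sum() < (1.0 - max_excluded) * n_samples:
        raise ValueError("insufficient unmasked samples on the scan circle")

    ilm_d = ilm_c.depth_px[0]
    nfl = (inner1.depth_px[0] - ilm_d) * ax
    gcc = (inner2.depth_px[0] - ilm_d) * ax
    tot = (rpe_c.depth_px[0] - ilm_d) * ax
    return ThicknessResult(
        nfl_gcl_um=float(nfl[keep].mean()),
        gcc_um=float(gcc[keep].mean()),
        total_um=float(tot[keep].mean()),
        vessel_fraction=frac_excluded,
    )
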