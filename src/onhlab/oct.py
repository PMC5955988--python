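"""OCT volume handling: B-scan registration and surface segmentation.

Coordinate convention (used package-wide): volumes are indexed
``(b_scan, a_scan, depth)``; the depth axis increases posteriorly with
index origin 0; surface elevation is anterior-positive.  Axial and lateral
pixel spacings are carried in µm/px.

Registration estimates per-B-scan axial motion by sub-pixel
cross-correlation of consecutive mean A-line profiles; the cumulative shift
sequence is linearly detrended so registration cannot introduce a global
tilt.  Surfaces are segmented as minimum-cost continuous paths through an
axial-gradient (ILM) or intensity (RPE) image with a per-A-scan jump bound,
followed by parabolic sub-pixel refinement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "OCTVolume",
    "SurfaceMap",
    "ElevationMap",
    "RegistrationResult",
    "register_bscans",
    "segment_surfaces",
    "segment_band_boundary",
    "surface_to_elevation",
]


@dataclass
class OCTVolume:
    """Intensity volume of shape (n_bscans, n_ascans, n_depth)."""

    data: np.ndarray
    lateral_spacing_um: float
    axial_spacing_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D (b_scan, a_scan, depth)")
        if self.lateral_spacing_um <= 0 or self.axial_spacing_um <= 0:
            raise ValueError("pixel spacings must be positive")
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    # -- I/O ---------------------------------------------------------------
    def save_tiff(self, path) -> None:
        """Multi-page TIFF, one page per B-scan; spacing in the description."""
        meta = {
            "lateral_spacing_um": self.lateral_spacing_um,
            "axial_spacing_um": self.axial_spacing_um,
        }
        tifffile.imwrite(path, self.data, description=json.dumps(meta))

    @classmethod
    def load_tiff(cls, path) -> "OCTVolume":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = json.loads(tf.pages[0].tags["ImageDescription"].value)
        return cls(data, meta["lateral_spacing_um"], meta["axial_spacing_um"])

    def save_hdf5(self, path, ground_truth=None) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            d = h5.create_dataset("volume", data=self.data, compression="gzip")
            d.attrs["lateral_spacing_um"] = self.lateral_spacing_um
            d.attrs["axial_spacing_um"] = self.axial_spacing_um
            if ground_truth is not None:
                if ground_truth.surface_um is not None:
                    h5.create_dataset("ground_truth/surface", data=ground_truth.surface_um)
                if ground_truth.shifts_px is not None:
                    h5.create_dataset("ground_truth/shifts", data=ground_truth.shifts_px)

    @classmethod
    def load_hdf5(cls, path) -> "OCTVolume":
        import h5py

        with h5py.File(path, "r") as h5:
            d = h5["volume"]
            return cls(
                d[...], float(d.attrs["lateral_spacing_um"]), float(d.attrs["axial_spacing_um"])
            )


@dataclass
class SurfaceMap:
    """Per-(b_scan, a_scan) boundary depth in (sub-)pixels with a valid mask."""

    depth_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.depth_px = np.asarray(self.depth_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depth_px.shape != self.valid.shape or self.depth_px.ndim != 2:
            raise ValueError("depth and mask must be matching 2-D arrays")


@dataclass
class ElevationMap:
    """Per-(x, y) surface height in µm, anterior-positive."""

    height_um: np.ndarray
    valid: np.ndarray
    lateral_spacing_um: float

    def __post_init__(self) -> None:
        self.height_um = np.asarray(self.height_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.height_um.shape != self.valid.shape or self.height_um.ndim != 2:
            raise ValueError("height and mask must be matching 2-D arrays")
        if self.lateral_spacing_um <= 0:
            raise ValueError("lateral spacing must be positive")
        if not np.all(np.isfinite(self.height_um[self.valid])):
            raise ValueError("heights must be finite on valid pixels")

    def save_tiff(self, path) -> None:
        """32-bit float TIFF plus a JSON sidecar with spacing and mask stats."""
        path = Path(path)
        out = self.height_um.astype(np.float32).copy()
        out[~self.valid] = np.nan
        tifffile.imwrite(path, out)
        sidecar = {
            "lateral_spacing_um": self.lateral_spacing_um,
            "n_valid": int(self.valid.sum()),
            "n_total": int(self.valid.size),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load_tiff(cls, path) -> "ElevationMap":
        path = Path(path)
        h = tifffile.imread(path).astype(float)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        valid = np.isfinite(h)
        h[~valid] = 0.0
        return cls(h, valid, sidecar["lateral_spacing_um"])


@dataclass
class RegistrationResult:
    """Estimated (detrended, cumulative) axial shifts and per-B-scan flags."""

    shifts_px: np.ndarray
    flagged: np.ndarray
    pair_confidence: np.ndarray


def _pair_confidence(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    c = np.correlate(a, b, mode="full")
    return float(c.max() / denom)


def register_bscans(
    volume: OCTVolume,
    upsample: int = 100,
    min_confidence: float = 0.3,
) -> tuple[OCTVolume, RegistrationResult]:
    """Compensate per-B-scan axial motion by sub-pixel profile correlation.

    Consecutive B-scans are reduced to mean A-line profiles and their
    relative axial displacement estimated by Fourier-upsampled
    cross-correlation.  Pairs whose normalized correlation peak falls below
    ``min_confidence`` contribute no shift and mark their B-scan as flagged
    (it remains unshifted).  Cumulative shifts are linearly detrended so a
    genuine large-scale tilt is not removed, then each B-scan is resampled
    axially by the negated shift.
    """
    n_b = volume.shape[0]
    if n_b < 2:
        raise ValueError("insufficient B-scans for registration (need >= 2)")

    profiles = volume.data.mean(axis=1)  # (n_bscans, n_depth)
    # demean and band-limit: the sub-pixel Fourier correlator is unbiased
    # only for band-limited profiles, and raw profiles carry step edges
    profiles = ndimage.gaussian_filter1d(
        profiles - profiles.mean(axis=1, keepdims=True), 1.0, axis=1
    )
    pair = np.zeros(n_b)
    conf = np.ones(n_b)
    flagged = np.zeros(n_b, dtype=bool)
    for i in range(1, n_b):
        ref, mov = profiles[i - 1], profiles[i]
        conf[i] = _pair_confidence(ref, mov)
        if conf[i] < min_confidence:
            flagged[i] = True
            continue
        shift, _, _ = phase_cross_correlation(
            ref, mov, upsample_factor=upsample, normalization=None
        )
        pair[i] = float(shift[0])

    cum = np.cumsum(pair)
    idx = np.arange(n_b)
    slope, intercept = np.polyfit(idx, cum, 1)
    est = cum - (slope * idx + intercept)

    # apply the negated shifts to all B-scans at once with an exact
    # (Fourier phase-ramp) axial resampling; flagged B-scans stay unshifted
    applied = np.where(flagged, 0.0, est)
    n_z = volume.shape[-1]
    freqs = np.fft.rfftfreq(n_z).astype(np.float32)
    phase = np.exp(-2j * np.pi * freqs[None, :] * applied[:, None].astype(np.float32))
    spec = np.fft.rfft(volume.data, axis=-1)
    out = np.fft.irfft(spec * phase[:, None, :], n=n_z, axis=-1).astype(np.float32)
    reg = OCTVolume(
        np.clip(out, 0.0, None), volume.lateral_spacing_um, volume.axial_spacing_um
    )
    return reg, RegistrationResult(shifts_px=-est, flagged=flagged, pair_confidence=conf)


def _min_cost_paths(cost: np.ndarray, max_jump_px: int) -> np.ndarray:
    """Minimum-cost depth path per B-scan across A-scans (vectorised DP).

    ``cost`` has shape (n_bscans, n_ascans, n_depth); the path may move at
    most ``max_jump_px`` depth pixels between neighbouring A-scans.  Uses a
    forward + backward pass; the optimal path through each A-scan column is
    the depth minimising forward + backward - local cost.
    """
    n_b, n_a, n_z = cost.shape
    size = 2 * max_jump_px + 1
    fwd = np.empty_like(cost)
    bwd = np.empty_like(cost)
    fwd[:, 0] = cost[:, 0]
    for i in range(1, n_a):
        fwd[:, i] = cost[:, i] + ndimage.minimum_filter1d(fwd[:, i - 1], size, axis=-1)
    bwd[:, -1] = cost[:, -1]
    for i in range(n_a - 2, -1, -1):
        bwd[:, i] = cost[:, i] + ndimage.minimum_filter1d(bwd[:, i + 1], size, axis=-1)
    total = fwd + bwd - cost
    return np.argmin(total, axis=-1)


def _parabolic_refine(score: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Sub-pixel vertex of the parabola through score at path-1, path, path+1."""
    n_z = score.shape[-1]
    p = np.clip(path, 1, n_z - 2)
    ii, jj = np.meshgrid(
        np.arange(score.shape[0]), np.arange(score.shape[1]), indexing="ij"
    )
    s0 = score[ii, jj, p - 1]
    s1 = score[ii, jj, p]
    s2 = score[ii, jj, p + 1]
    denom = s0 - 2.0 * s1 + s2
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (s0 - s2) / denom, 0.0)
    return p + np.clip(delta, -0.5, 0.5)


def segment_band_boundary(
    volume: OCTVolume,
    polarity: int = 1,
    z_min: np.ndarray | float | None = None,
    z_max: np.ndarray | float | None = None,
    max_jump_px: int = 2,
    smooth_axial_px: float = 1.5,
    smooth_lateral_px: float = 1.0,
    smooth_bscan_px: float = 1.0,
    use_log: bool = True,
) -> SurfaceMap:
    """Continuous boundary at a dark-to-bright (+1) or bright-to-dark (-1) step.

    The generic path operator behind ILM and inner-band segmentation: the
    axial intensity gradient (optionally of the log image, which makes
    multiplicative speckle additive) is turned into a cost image, restricted
    to an optional per-A-scan depth window, and traversed by the
    continuity-constrained minimum-cost path.
    """
    vol = volume.data
    img = np.log(vol + 1e-3) if use_log else vol
    img = ndimage.gaussian_filter(
        img, sigma=(smooth_bscan_px, smooth_lateral_px, smooth_axial_px), mode="nearest"
    )
    grad = np.gradient(img, axis=-1) * np.float32(polarity)
    cost = -grad
    big = np.float32(float(np.abs(cost).max()) * 4.0 + 1.0)
    n_z = vol.shape[-1]
    zz = np.arange(n_z, dtype=np.float32)
    if z_min is not None:
        zmin = np.asarray(z_min, dtype=np.float32)[..., None] if np.ndim(z_min) else z_min
        cost = np.where(zz >= zmin, cost, big)
    if z_max is not None:
        zmax = np.asarray(z_max, dtype=np.float32)[..., None] if np.ndim(z_max) else z_max
        cost = np.where(zz <= zmax, cost, big)
    path = _min_cost_paths(cost, max_jump_px)
    # +0.5: voxel i spans [i, i+1), so a gradient peak at sample index p
    # marks a geometric boundary at depth p + 0.5
    depth = _parabolic_refine(grad, path) + 0.5
    valid = np.ones(depth.shape, dtype=bool)
    return SurfaceMap(depth_px=depth, valid=valid)


def segment_surfaces(
    volume: OCTVolume,
    noise_floor_k: float = 6.0,
    max_jump_px: int = 2,
    rpe_margin_um: float = 40.0,
) -> tuple[SurfaceMap, SurfaceMap]:
    """Segment the ILM and the RPE of a registered volume.

    The ILM is the minimum-cost dark-to-bright gradient path; the RPE is the
    dark-to-bright entry edge of the brightest band, constrained to lie
    below the ILM by a margin.  Both use the gradient of the log image, so
    multiplicative shadowing (vessels) does not move the boundaries.
    A-scans whose maximum gradient does not exceed ``noise_floor_k`` robust
    noise sigmas are masked invalid rather than guessed.
    """
    vol = volume.data
    img = ndimage.gaussian_filter(
        np.log(vol + 1e-3), sigma=(1.0, 1.0, 1.5), mode="nearest"
    )
    grad = np.gradient(img, axis=-1)

    # robust noise scale of the gradient field
    sigma = float(np.median(np.abs(grad))) / 0.6745
    peak = grad.max(axis=-1)
    valid = peak > noise_floor_k * max(sigma, 1e-12)

    cost = -grad
    path = _min_cost_paths(cost, max_jump_px)
    ilm_depth = _parabolic_refine(grad, path) + 0.5
    ilm = SurfaceMap(depth_px=ilm_depth, valid=valid)

    # RPE: the only remaining dark-to-bright step below the inner retina
    margin_px = np.float32(rpe_margin_um / volume.axial_spacing_um)
    n_z = vol.shape[-1]
    zz = np.arange(n_z, dtype=np.float32)
    big = np.float32(float(np.abs(grad).max()) * 4.0 + 1.0)
    rpe_floor = (ilm_depth + margin_px)[..., None].astype(np.float32)
    rpe_cost = np.where(zz >= rpe_floor, cost, big)
    rpe_path = _min_cost_paths(rpe_cost, max_jump_px)
    rpe_depth = _parabolic_refine(grad, rpe_path) + 0.5
    rpe_valid = valid & (rpe_depth >= ilm_depth)
    rpe = SurfaceMap(depth_px=rpe_depth, valid=rpe_valid)
    return ilm, rpe


def surface_to_elevation(
    surface: SurfaceMap,
    volume: OCTVolume,
    reference_depth_px: float | None = None,
) -> ElevationMap:
    """Convert boundary depths to anterior-positive heights in µm.

    ``height = (reference_depth - depth) * axial_spacing``.  The default
    reference is the median valid depth, which makes the map invariant to a
    uniform axial translation of the whole volume.
    """
    if not surface.valid.any():
        raise ValueError("surface has no valid pixels")
    if reference_depth_px is None:
        reference_depth_px = float(np.median(surface.depth_px[surface.valid]))
    height = (reference_depth_px - surface.depth_px) * volume.axial_spacing_um
    height = np.where(surface.valid, height, 0.0)
    return ElevationMap(
        height_um=height,
        valid=surface.valid.copy(),
        lateral_spacing_um=volume.lateral_spacing_um,
    )
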