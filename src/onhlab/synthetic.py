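"""Synthetic phantoms with programmed ground truth.

Every analysis stage in this package is exercised against data generated
here: layered-retina OCT volumes with an ONH pit, axial motion jitter,
vessel shadows and speckle; scotopic flash-ERG traces with a/b lobes and an
oscillatory-potential packet; Poisson axon fields with a programmed
degenerating fraction; and a full simulated study crossing subjects, eyes,
weeks and loop procedures with programmed cell means.

Defaults emulate the study conditions: a 256 x 256 x 512 volume at
8 µm lateral / 2 µm axial spacing standing in for the instrument's
1000 x 1000 acquisition over ~2 mm^2, a 1 s ERG record with a 500 ms
pre-stimulus period, and an optic nerve of ~0.22 mm^2 cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .axons import AxonField, EllipseBoundary
from .erg import ERGTrace
from .oct import OCTVolume

__all__ = [
    "PhantomParams",
    "ERGParams",
    "AxonFieldParams",
    "StudyDesign",
    "StudyDataset",
    "GroundTruth",
    "pit_profile",
    "analytic_depression",
    "pit_depth_for_target",
    "generate_oct_phantom",
    "generate_erg_trace",
    "generate_axon_field",
    "generate_study_dataset",
    "write_study_tsv",
    "read_study_tsv",
]

# intensity levels (arbitrary units) of the phantom bands, anterior to posterior
_LEVELS = {
    "vitreous": 0.05,
    "nfl_gcl": 1.0,
    "gcc_remainder": 0.75,
    "outer_retina": 0.5,
    "rpe": 1.25,
    "choroid": 0.12,
}
_RPE_THICKNESS_UM = 16.0
_VESSEL_ATTENUATION = 0.25

DEPRESSION_R_INNER_UM = 150.0
DEPRESSION_R_OUTER_UM = 500.0


def pit_profile(family: str) -> Callable[[np.ndarray, float], np.ndarray]:
    """Radial pit profile p(r; sigma) in [0, 1], 1 at the centre, 0 far away."""
    if family == "gaussian":
        return lambda r, s: np.exp(-np.asarray(r, float) ** 2 / (2.0 * s**2))
    if family == "tanh-crater":
        # flat floor of radius ~sigma with a tanh wall of width sigma/3
        return lambda r, s: 0.5 * (1.0 - np.tanh((np.asarray(r, float) - s) / (s / 3.0)))
    raise ValueError(f"unknown pit profile family: {family!r}")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, optics and noise of the volumetric ONH phantom."""

    n_bscans: int = 256
    n_ascans: int = 256
    n_depth: int = 512
    lateral_spacing_um: float = 8.0
    axial_spacing_um: float = 2.0
    # NFL+GCL, GCC remainder, outer retina (ILM->RPE = sum)
    layer_thicknesses_um: tuple[float, float, float] = (40.0, 40.0, 120.0)
    pit_depth_um: float = 100.0
    pit_sigma_um: float = 200.0
    pit_family: str = "gaussian"
    tilt_um_per_mm: tuple[float, float] = (0.0, 0.0)
    jitter_sigma_px: float = 5.0
    jitter_shifts_px: Optional[np.ndarray] = None
    speckle_contrast: float = 0.35
    additive_noise: float = 0.01
    # ((x0, y0), (x1, y1), width) in µm, en-face coordinates
    vessels: tuple[tuple[tuple[float, float], tuple[float, float], float], ...] = ()
    surface_reference_px: float = 160.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if min(self.n_bscans, self.n_ascans, self.n_depth) < 2:
            raise ValueError("volume shape too small")
        if self.lateral_spacing_um <= 0 or self.axial_spacing_um <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.pit_depth_um < 0:
            raise ValueError("pit depth must be >= 0")
        if self.pit_sigma_um <= 0:
            raise ValueError("pit radial scale must be positive")
        if any(t <= 0 for t in self.layer_thicknesses_um):
            raise ValueError("layer thicknesses must be positive")
        if self.jitter_sigma_px < 0 or self.speckle_contrast < 0:
            raise ValueError("noise parameters must be >= 0")
        pit_profile(self.pit_family)  # validates the family name
        field_um = min(self.n_ascans, self.n_bscans) * self.lateral_spacing_um
        if 4.0 * self.pit_sigma_um > field_um:
            raise ValueError("pit diameter exceeds the lateral field of view")
        if self.jitter_shifts_px is not None and len(self.jitter_shifts_px) != self.n_bscans:
            raise ValueError("jitter shift sequence length must equal n_bscans")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.n_ascans * self.lateral_spacing_um, self.n_bscans * self.lateral_spacing_um)


@dataclass
class GroundTruth:
    """Programmed truth recorded alongside each generated artefact."""

    surface_um: Optional[np.ndarray] = None  # unshifted analytic ILM height
    shifts_px: Optional[np.ndarray] = None  # applied per-B-scan axial shifts
    d_true_um: Optional[float] = None  # metric depression of the analytic surface
    center_um: Optional[tuple[float, float]] = None
    layer_thicknesses_um: Optional[tuple[float, float, float]] = None
    erg_features: Optional[dict[str, float]] = None
    axon_expected_total: Optional[float] = None
    degenerating_fraction: Optional[float] = None


def analytic_depression(params: PhantomParams) -> float:
    """Metric depression of the analytic surface at the 150/500 µm scheme.

    The pit is radially symmetric and tilt averages out over a full circle
    of rays, so the scheme reduces to the closed-form profile difference.
    """
    p = pit_profile(params.pit_family)
    s = params.pit_sigma_um
    return float(
        params.pit_depth_um
        * (p(DEPRESSION_R_INNER_UM, s) - p(DEPRESSION_R_OUTER_UM, s))
    )


def pit_depth_for_target(
    target_depression_um: float, sigma_um: float = 200.0, family: str = "gaussian"
) -> float:
    """Pit depth whose 150/500 µm metric depression equals the target."""
    p = pit_profile(family)
    scale = float(p(DEPRESSION_R_INNER_UM, sigma_um) - p(DEPRESSION_R_OUTER_UM, sigma_um))
    if scale <= 0:
        raise ValueError("pit profile has no contrast between 150 and 500 µm")
    return target_depression_um / scale


def _analytic_surface(params: PhantomParams) -> tuple[np.ndarray, tuple[float, float]]:
    """Anterior-positive surface height h(x, y) in µm and the pit centre."""
    x = np.arange(params.n_ascans) * params.lateral_spacing_um
    y = np.arange(params.n_bscans) * params.lateral_spacing_um
    cx, cy = x.mean(), y.mean()
    xx, yy = np.meshgrid(x - cx, y - cy)  # (n_bscans, n_ascans)
    r = np.hypot(xx, yy)
    p = pit_profile(params.pit_family)
    h = (
        params.tilt_um_per_mm[0] * xx / 1000.0
        + params.tilt_um_per_mm[1] * yy / 1000.0
        - params.pit_depth_um * p(r, params.pit_sigma_um)
    )
    return h, (cx, cy)


def _vessel_mask(params: PhantomParams) -> np.ndarray:
    """En-face boolean mask of vessel shadow footprints."""
    mask = np.zeros((params.n_bscans, params.n_ascans), dtype=bool)
    if not params.vessels:
        return mask
    x = np.arange(params.n_ascans) * params.lateral_spacing_um
    y = np.arange(params.n_bscans) * params.lateral_spacing_um
    xx, yy = np.meshgrid(x, y)
    for (x0, y0), (x1, y1), width in params.vessels:
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        if L2 == 0:
            d = np.hypot(xx - x0, yy - y0)
        else:
            t = np.clip(((xx - x0) * dx + (yy - y0) * dy) / L2, 0.0, 1.0)
            d = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
        mask |= d <= width / 2.0
    return mask


def _jitter_sequence(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    if params.jitter_shifts_px is not None:
        return np.asarray(params.jitter_shifts_px, dtype=float)
    n = params.n_bscans
    if params.jitter_sigma_px == 0:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    walk = ndimage.gaussian_filter1d(walk, 3.0, mode="nearest")
    idx = np.arange(n)
    slope, intercept = np.polyfit(idx, walk, 1)
    walk = walk - (slope * idx + intercept)  # drift would masquerade as tilt
    sd = walk.std()
    return walk * (params.jitter_sigma_px / sd) if sd > 0 else walk


def generate_oct_phantom(params: PhantomParams) -> tuple[OCTVolume, GroundTruth]:
    """Render a layered ONH phantom volume with programmed ground truth.

    The volume holds a bright ILM edge at the analytic surface, banded
    retinal layers, an RPE band, optional vessel shadows, multiplicative
    gamma speckle and a small additive noise floor; each B-scan is rendered
    at its jittered axial position (the geometry is shifted before
    rasterisation, so the applied shifts are exact).
    """
    rng = np.random.default_rng(params.seed)
    h, center = _analytic_surface(params)
    shifts = _jitter_sequence(params, rng)

    t1, t2, t3 = params.layer_thicknesses_um
    ax = params.axial_spacing_um
    z_ilm = (
        params.surface_reference_px
        - h / ax
        + shifts[:, None]
    ).astype(np.float32)

    # band boundaries in depth px, anterior to posterior
    offsets_px = np.array(
        [0.0, t1 / ax, (t1 + t2) / ax, (t1 + t2 + t3) / ax,
         (t1 + t2 + t3 + _RPE_THICKNESS_UM) / ax],
        dtype=np.float32,
    )
    n_z = params.n_depth
    if float(z_ilm.min()) < 2 or float(z_ilm.max() + offsets_px[-1]) > n_z - 2:
        raise ValueError("retina does not fit in the depth range; adjust reference or shape")

    zz = np.arange(n_z, dtype=np.float32)
    levels = list(_LEVELS.values())
    # render as cumulative level steps: each boundary adds (level - previous)
    # times the sub-pixel fraction of the voxel lying at/below it
    vol = np.full(
        (params.n_bscans, params.n_ascans, n_z), np.float32(levels[0]), dtype=np.float32
    )
    for off, prev, lv in zip(offsets_px, levels[:-1], levels[1:]):
        frac = np.clip(zz + np.float32(1.0) - (z_ilm[..., None] + off), 0.0, 1.0)
        frac *= np.float32(lv - prev)
        vol += frac

    vmask = _vessel_mask(params)
    if vmask.any():
        # attenuate everything from just below the ILM downward
        below = np.clip(zz - (z_ilm[..., None] + np.float32(2.0)), 0.0, 1.0)
        factor = 1.0 - (1.0 - _VESSEL_ATTENUATION) * below * vmask[..., None]
        vol *= factor.astype(np.float32)

    if params.speckle_contrast > 0:
        k = 1.0 / params.speckle_contrast**2
        vol *= rng.standard_gamma(k, size=vol.shape, dtype=np.float32) / np.float32(k)
    if params.additive_noise > 0:
        vol += params.additive_noise * rng.standard_normal(size=vol.shape, dtype=np.float32)
    np.clip(vol, 0.0, None, out=vol)

    volume = OCTVolume(vol, params.lateral_spacing_um, params.axial_spacing_um)
    truth = GroundTruth(
        surface_um=h,
        shifts_px=shifts,
        d_true_um=analytic_depression(params),
        center_um=center,
        layer_thicknesses_um=params.layer_thicknesses_um,
    )
    return volume, truth


# --------------------------------------------------------------------------
# ERG traces


@dataclass(frozen=True)
class ERGParams:
    """Waveform model of a scotopic flash ERG record.

    The noiseless waveform is baseline - A_a * lobe(t - t_a) + A_b *
    lobe(t - t_b) + OP packet, with Gaussian lobes gated to zero before
    flash onset; the packet is an in-band (75-300 Hz) sinusoid under a
    cosine-tapered window.
    """

    sampling_hz: float = 2000.0
    record_ms: float = 1000.0
    pre_stimulus_ms: float = 500.0
    baseline_uv: float = 0.0
    a_amplitude_uv: float = 200.0
    a_latency_ms: float = 15.0
    a_width_ms: float = 6.0
    b_amplitude_uv: float = 600.0
    b_latency_ms: float = 55.0
    b_width_ms: float = 20.0
    op_amplitude_uv: float = 20.0
    op_frequency_hz: float = 120.0
    op_window_ms: tuple[float, float] = (20.0, 60.0)
    noise_sigma_uv: float = 15.0
    flash_duration_ms: float = 7.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0 or self.record_ms <= 0 or self.pre_stimulus_ms < 0:
            raise ValueError("invalid timing parameters")
        if self.record_ms < self.pre_stimulus_ms + 100.0:
            raise ValueError("record must extend >= 100 ms past the pre-stimulus period")
        if self.a_amplitude_uv < 0 or self.b_amplitude_uv < 0 or self.op_amplitude_uv < 0:
            raise ValueError("amplitudes must be >= 0")
        if not self.a_latency_ms < self.b_latency_ms:
            raise ValueError("a-wave latency must precede b-wave latency")
        if self.op_amplitude_uv > 0 and not 75.0 <= self.op_frequency_hz <= 300.0:
            raise ValueError("OP packet frequency must lie in the 75-300 Hz band")
        if self.noise_sigma_uv < 0:
            raise ValueError("noise sigma must be >= 0")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _erg_components(params: ERGParams, t_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(a/b-wave compound, OP packet) of the noiseless waveform."""
    gate = _smoothstep(t_ms / 5.0)  # responses cannot precede the flash
    lobe_a = np.exp(-((t_ms - params.a_latency_ms) ** 2) / (2.0 * params.a_width_ms**2))
    lobe_b = np.exp(-((t_ms - params.b_latency_ms) ** 2) / (2.0 * params.b_width_ms**2))
    ab = gate * (-params.a_amplitude_uv * lobe_a + params.b_amplitude_uv * lobe_b)

    w0, w1 = params.op_window_ms
    ramp = min(5.0, (w1 - w0) / 4.0)
    win = _smoothstep((t_ms - w0) / ramp) * _smoothstep((w1 - t_ms) / ramp)
    packet = (
        params.op_amplitude_uv
        * win
        * np.sin(2.0 * np.pi * params.op_frequency_hz * (t_ms - w0) / 1000.0)
    )
    return ab, gate * packet


def generate_erg_trace(params: ERGParams) -> tuple[ERGTrace, GroundTruth]:
    """Simulate one flash-ERG record and its true feature values.

    True a/b amplitudes and implicit times apply the peak-to-peak feature
    definitions to the noiseless waveform; the true OP RMS is the 20-70 ms
    RMS of the noiseless packet (which lies entirely in the 75-300 Hz band).
    """
    dt_ms = 1000.0 / params.sampling_hz
    n = int(round(params.record_ms / dt_ms))
    t_ms = (np.arange(n) * dt_ms) - params.pre_stimulus_ms
    ab, packet = _erg_components(params, t_ms)
    clean = params.baseline_uv + ab + packet

    rng = np.random.default_rng(params.seed)
    noise = (
        rng.normal(0.0, params.noise_sigma_uv, size=n) if params.noise_sigma_uv > 0 else 0.0
    )
    trace = ERGTrace(t_ms, clean + noise)

    base = params.baseline_uv
    a_win = (t_ms >= 5.0) & (t_ms <= 40.0)
    ia = int(np.flatnonzero(a_win)[np.argmin(clean[a_win])])
    a_amp = max(0.0, base - float(clean[ia]))
    b_win = (np.arange(n) > ia) & (t_ms <= 150.0)
    ib = int(np.flatnonzero(b_win)[np.argmax(clean[b_win])])
    b_amp = max(0.0, float(clean[ib]) - float(clean[ia]))
    sel = (t_ms >= 20.0) & (t_ms <= 70.0)
    op_rms = float(np.sqrt(np.mean(packet[sel] ** 2)))

    truth = GroundTruth(
        erg_features={
            "a_amplitude_uv": a_amp,
            "a_implicit_time_ms": float(t_ms[ia]) if a_amp > 0 else 0.0,
            "b_amplitude_uv": b_amp,
            "b_implicit_time_ms": float(t_ms[ib]) if b_amp > 0 else 0.0,
            "op_rms_uv": op_rms,
        }
    )
    return trace, truth


# --------------------------------------------------------------------------
# Axon fields


@dataclass(frozen=True)
class AxonFieldParams:
    """Homogeneous Poisson axon field inside an elliptical nerve section."""

    semi_axes_mm: tuple[float, float] = (0.28, 0.25)
    density_per_mm2: float = 384_000.0
    degenerating_fraction: float = 0.033
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.semi_axes_mm[0] <= 0 or self.semi_axes_mm[1] <= 0:
            raise ValueError("semi-axes must be positive")
        if self.density_per_mm2 < 0:
            raise ValueError("density must be >= 0")
        if not 0.0 <= self.degenerating_fraction <= 1.0:
            raise ValueError("degenerating fraction must lie in [0, 1]")


def generate_axon_field(params: AxonFieldParams) -> AxonField:
    """Sample a Poisson point process in the ellipse with Bernoulli labels."""
    rng = np.random.default_rng(params.seed)
    boundary = EllipseBoundary(*params.semi_axes_mm)
    n = rng.poisson(params.density_per_mm2 * boundary.area_mm2)
    # uniform in the unit disc, scaled to the ellipse
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    th = rng.uniform(0.0, 2.0 * np.pi, n)
    xy = np.column_stack(
        [params.semi_axes_mm[0] * r * np.cos(th), params.semi_axes_mm[1] * r * np.sin(th)]
    )
    deg = rng.uniform(size=n) < params.degenerating_fraction
    return AxonField(xy_mm=xy, degenerating=deg, boundary=boundary)


# --------------------------------------------------------------------------
# Full study simulation

_ENDPOINTS = ("onh_depression_um", "erg_a_uv", "erg_b_uv", "erg_op_rms_uv", "iop_mmhg")


def _per_week(values, weeks) -> dict:
    values = tuple(values)
    if len(values) == 1:
        values = values * len(weeks)
    if len(values) != len(weeks):
        raise ValueError("per-week value count must be 1 or match the weeks")
    return dict(zip(weeks, values))


@dataclass(frozen=True)
class StudyDesign:
    """Effect model of the simulated chronic intermittent-IOP study.

    Cell means follow the study's printed group means: loop-on ONH
    depression of 89.3 µm at week 1 rising by 131%/140% at weeks 5/9
    against pre/post values near 21 µm, a ~4x loop-on ERG amplitude
    enhancement declining over weeks, and the measured IOP profile.
    Endpoint values are cell mean + between-subject effect + residual.
    """

    n_subjects: int = 6
    weeks: tuple[int, ...] = (1, 5, 9)
    procedures: tuple[str, ...] = ("pre", "loop", "post")
    eyes: tuple[str, ...] = ("treated", "untreated")
    depression_means_um: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=lambda: {
            "treated": {"pre": (21.4,), "loop": (89.3, 206.3, 214.3), "post": (20.3,)},
            "untreated": {"pre": (21.0,), "loop": (21.0,), "post": (21.0,)},
        }
    )
    erg_loop_multiplier: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"treated": (4.0, 3.5, 3.0), "untreated": (1.0,)}
    )
    erg_baseline_uv: Mapping[str, float] = field(
        default_factory=lambda: {"erg_a_uv": 200.0, "erg_b_uv": 800.0, "erg_op_rms_uv": 30.0}
    )
    iop_mmhg: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "treated": {"pre": 12.5, "loop": 34.7, "post": 11.2},
            "untreated": {"pre": 12.6, "loop": 12.4, "post": 11.9},
        }
    )
    # endpoint -> (between-subject SD, residual SD)
    noise_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "onh_depression_um": (16.0, 20.0),
            "erg_a_uv": (15.0, 20.0),
            "erg_b_uv": (45.0, 60.0),
            "erg_op_rms_uv": (3.0, 4.0),
            "iop_mmhg": (0.5, 0.8),
        }
    )
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects (statistics undefined below that)")
        for eye in self.eyes:
            for proc in self.procedures:
                _per_week(self.depression_means_um[eye][proc], self.weeks)
                self.iop_mmhg[eye][proc]
            _per_week(self.erg_loop_multiplier[eye], self.weeks)

    def cell_mean(self, endpoint: str, eye: str, week: int, procedure: str) -> float:
        """Programmed population mean of one (endpoint, eye, week, procedure) cell."""
        if endpoint == "onh_depression_um":
            return float(_per_week(self.depression_means_um[eye][procedure], self.weeks)[week])
        if endpoint == "iop_mmhg":
            return float(self.iop_mmhg[eye][procedure])
        if endpoint in self.erg_baseline_uv:
            base = self.erg_baseline_uv[endpoint]
            if procedure == "loop":
                return base * float(_per_week(self.erg_loop_multiplier[eye], self.weeks)[week])
            return float(base)
        raise KeyError(f"unknown endpoint {endpoint!r}")


@dataclass
class StudyDataset:
    """Simulated study: tidy endpoint table plus lazy raw-data constructors.

    ``endpoints`` is the long-format table (subject, eye, week, procedure,
    endpoint, value).  Raw OCT volumes and ERG traces for any cell are
    materialised on demand with the cell's endpoint values programmed in,
    rather than stored (a full study is ~100 volumes).
    """

    design: StudyDesign
    endpoints: pd.DataFrame

    def cell_value(self, subject: str, eye: str, week: int, procedure: str, endpoint: str) -> float:
        t = self.endpoints
        sel = (
            (t.subject == subject)
            & (t.eye == eye)
            & (t.week == week)
            & (t.procedure == procedure)
            & (t.endpoint == endpoint)
        )
        v = t.loc[sel, "value"]
        if len(v) != 1:
            raise KeyError("cell not found (or not unique)")
        return float(v.iloc[0])

    def realize_oct(
        self, subject: str, eye: str, week: int, procedure: str, **overrides
    ) -> tuple[OCTVolume, GroundTruth]:
        """Phantom volume whose metric-true depression equals the cell value."""
        d_cell = max(0.0, self.cell_value(subject, eye, week, procedure, "onh_depression_um"))
        params = PhantomParams(
            pit_depth_um=pit_depth_for_target(d_cell),
            seed=_cell_seed(self.design.seed, subject, eye, week, procedure, 0),
            **overrides,
        )
        return generate_oct_phantom(params)

    def realize_erg(
        self, subject: str, eye: str, week: int, procedure: str, n_traces: int = 5, **overrides
    ) -> tuple[list[ERGTrace], GroundTruth]:
        """Five repeat ERG traces whose noiseless features match the cell values."""
        a = max(0.0, self.cell_value(subject, eye, week, procedure, "erg_a_uv"))
        b = max(0.0, self.cell_value(subject, eye, week, procedure, "erg_b_uv"))
        op = max(0.0, self.cell_value(subject, eye, week, procedure, "erg_op_rms_uv"))
        base = ERGParams(
            a_amplitude_uv=a,
            b_amplitude_uv=max(0.0, b - a),
            op_amplitude_uv=op * np.sqrt(2.0),
            **overrides,
        )
        traces = []
        truth = None
        for k in range(n_traces):
            p = replace(
                base, seed=_cell_seed(self.design.seed, subject, eye, week, procedure, k + 1)
            )
            tr, truth = generate_erg_trace(p)
            traces.append(tr)
        return traces, truth


def _cell_seed(base_seed, subject, eye, week, procedure, k) -> int:
    import zlib

    tag = zlib.crc32(f"{subject}|{eye}|{week}|{procedure}|{k}".encode())
    ss = np.random.SeedSequence(
        [0 if base_seed is None else int(base_seed)], spawn_key=(tag,)
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_study_dataset(design: StudyDesign) -> StudyDataset:
    """Draw the full study's endpoint values from the programmed effect model."""
    rng = np.random.default_rng(design.seed)
    subjects = [f"S{i + 1}" for i in range(design.n_subjects)]
    rows = []
    subj_fx = {
        (s, ep): rng.normal(0.0, design.noise_sd[ep][0])
        for s in subjects
        for ep in _ENDPOINTS
    }
    for s in subjects:
        for eye in design.eyes:
            for week in design.weeks:
                for proc in design.procedures:
                    for ep in _ENDPOINTS:
                        mean = design.cell_mean(ep, eye, week, proc)
                        value = mean + subj_fx[(s, ep)] + rng.normal(
                            0.0, design.noise_sd[ep][1]
                        )
                        rows.append(
                            {
                                "subject": s,
                                "eye": eye,
                                "week": week,
                                "procedure": proc,
                                "endpoint": ep,
                                "value": value,
                            }
                        )
    return StudyDataset(design=design, endpoints=pd.DataFrame(rows))


def write_study_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_study_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
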