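"""Flash-ERG feature extraction: a/b-waves and oscillatory potentials.

Conventions: time is in ms with flash onset at t = 0 and negative times
forming the pre-stimulus baseline period; voltage is in µV.  The a-wave
amplitude is the drop from the pre-stimulus baseline to the first negative
peak; the b-wave amplitude is measured from the a-wave trough to the
following positive peak; implicit times run from flash onset to each peak.
Oscillatory potentials are isolated with a zero-phase 75-300 Hz Fourier
band-pass and summarised as the RMS over 20-70 ms post-flash.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

__all__ = [
    "ERGTrace",
    "ERGFeatures",
    "average_traces",
    "ab_wave_metrics",
    "oscillatory_potentials",
    "extract_features",
]


@dataclass
class ERGTrace:
    """Uniformly sampled ERG voltage record."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uv = np.asarray(self.voltage_uv, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.voltage_uv.shape:
            raise ValueError("time and voltage must be matching 1-D arrays")
        if len(self.time_ms) < 3:
            raise ValueError("trace too short")
        dt = np.diff(self.time_ms)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValueError("time grid must be uniform and increasing")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def sampling_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ms": self.time_ms, "voltage_uv": self.voltage_uv}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "ERGTrace":
        df = pd.read_csv(path)
        return cls(df["time_ms"].to_numpy(), df["voltage_uv"].to_numpy())


@dataclass(frozen=True)
class ERGFeatures:
    a_amplitude_uv: float
    a_implicit_time_ms: float
    b_amplitude_uv: float
    b_implicit_time_ms: float
    op_rms_uv: float


def average_traces(traces: Sequence[ERGTrace] | Iterable[ERGTrace]) -> ERGTrace:
    """Pointwise mean of repeated acquisitions sharing one time grid."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    t0 = traces[0].time_ms
    for tr in traces[1:]:
        if tr.time_ms.shape != t0.shape or not np.allclose(tr.time_ms, t0):
            raise ValueError("traces have mismatched time grids")
    v = np.mean([tr.voltage_uv for tr in traces], axis=0)
    return ERGTrace(t0.copy(), v)


def ab_wave_metrics(
    trace: ERGTrace,
    a_window_ms: tuple[float, float] = (5.0, 40.0),
    b_window_end_ms: float = 150.0,
    prominence_samples: int = 2,
    noise_guard_sd: float = 3.0,
) -> dict[str, float]:
    """Baseline-referenced a/b-wave amplitudes and implicit times.

    The baseline is the mean pre-stimulus voltage.  The a-peak is the first
    local minimum inside ``a_window_ms`` that dips below baseline by more
    than ``noise_guard_sd`` pre-stimulus noise SDs (local over
    ±``prominence_samples`` samples); both guards stop shallow noise dips
    early in the window from masquerading as the a-wave.  The b-peak is the
    maximum voltage after the a-peak up to ``b_window_end_ms``.
    """
    t, v = trace.time_ms, trace.voltage_uv
    pre = t < 0
    if not pre.any():
        raise ValueError("trace has no pre-stimulus segment")
    baseline = float(v[pre].mean())
    floor = baseline - noise_guard_sd * float(v[pre].std())

    in_a = (t >= a_window_ms[0]) & (t <= a_window_ms[1])
    idx_a = np.flatnonzero(in_a)
    if len(idx_a) < 2 * prominence_samples + 1:
        raise ValueError("a-wave search window contains too few samples")
    minima = argrelextrema(v, np.less_equal, order=prominence_samples)[0]
    minima = minima[np.isin(minima, idx_a)]
    minima = minima[v[minima] < min(baseline, floor)]
    if len(minima) == 0:
        raise ValueError("a-wave not found (no sub-baseline minimum in window)")
    # "first negative peak": earliest local minimum whose depth is within
    # noise tolerance of the deepest point in the window, so noise dips on
    # the descending flank are not mistaken for the trough
    depth_tol = noise_guard_sd * float(v[pre].std())
    window_min = float(v[idx_a].min())
    deep = minima[v[minima] <= window_min + depth_tol]
    ia = int(deep[0]) if len(deep) else int(minima[0])
    # plateaus from less_equal: take the centre of a run of equal values
    run = minima[(minima >= ia) & (v[minima] == v[ia])]
    run = run[np.r_[True, np.diff(run) == 1].cumprod().astype(bool)]
    ia = int(run[len(run) // 2])

    in_b = (np.arange(len(t)) > ia) & (t <= b_window_end_ms)
    if not in_b.any():
        raise ValueError("b-wave window empty")
    ib = int(np.flatnonzero(in_b)[np.argmax(v[in_b])])

    return {
        "baseline_uv": baseline,
        "a_amplitude_uv": baseline - float(v[ia]),
        "a_implicit_time_ms": float(t[ia]),
        "b_amplitude_uv": float(v[ib]) - float(v[ia]),
        "b_implicit_time_ms": float(t[ib]),
    }


def oscillatory_potentials(
    trace: ERGTrace,
    band_hz: tuple[float, float] = (75.0, 300.0),
    transition_hz: float = 5.0,
    rms_window_ms: tuple[float, float] = (20.0, 70.0),
) -> tuple[ERGTrace, float]:
    """Zero-phase band-pass isolation of the OPs and their windowed RMS.

    The filter has unity gain inside ``band_hz``, zero outside, and a
    raised-cosine transition of ``transition_hz`` at each edge, applied in
    the frequency domain (hence exactly zero-phase).  The RMS is taken over
    samples with ``rms_window_ms[0] <= t <= rms_window_ms[1]``.
    """
    fs = trace.sampling_hz
    if fs <= 2 * band_hz[1]:
        raise ValueError(
            f"sampling rate {fs:.0f} Hz too low to represent the {band_hz[1]:.0f} Hz band edge"
        )
    n = len(trace.voltage_uv)
    freqs = np.fft.rfftfreq(n, d=trace.dt_ms / 1000.0)
    lo, hi = band_hz
    tw = transition_hz
    gain = np.zeros_like(freqs)
    gain[(freqs >= lo) & (freqs <= hi)] = 1.0
    rise = (freqs > lo - tw) & (freqs < lo)
    gain[rise] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[rise]) / tw))
    fall = (freqs > hi) & (freqs < hi + tw)
    gain[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - hi) / tw))

    filtered = np.fft.irfft(np.fft.rfft(trace.voltage_uv) * gain, n=n)
    out = ERGTrace(trace.time_ms.copy(), filtered)
    sel = (trace.time_ms >= rms_window_ms[0]) & (trace.time_ms <= rms_window_ms[1])
    if not sel.any():
        raise ValueError("RMS window contains no samples")
    rms = float(np.sqrt(np.mean(filtered[sel] ** 2)))
    return out, rms


def extract_features(
    traces: Sequence[ERGTrace],
    a_window_ms: tuple[float, float] = (5.0, 40.0),
    b_window_end_ms: float = 150.0,
) -> ERGFeatures:
    """Average repeated traces, then extract all a/b/OP features of the mean."""
    mean = average_traces(traces)
    ab = ab_wave_metrics(mean, a_window_ms=a_window_ms, b_window_end_ms=b_window_end_ms)
    _, rms = oscillatory_potentials(mean)
    return ERGFeatures(
        a_amplitude_uv=ab["a_amplitude_uv"],
        a_implicit_time_ms=ab["a_implicit_time_ms"],
        b_amplitude_uv=ab["b_amplitude_uv"],
        b_implicit_time_ms=ab["b_implicit_time_ms"],
        op_rms_uv=rms,
    )
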