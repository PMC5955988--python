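"""Grid-sampling stereology of optic-nerve axon cross-sections.

A labelled point field (axon centroids classified as normal or degenerating
inside a nerve boundary) is sampled with a fixed square-grid overlay: a
systematic-random subset of fully interior cells covering a target fraction
(default 20%) of the nerve cross-sectional area is counted, and the totals
follow as density x area.  Labels are inputs — no image-based detection or
morphological classification is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EllipseBoundary",
    "AxonField",
    "GridSample",
    "AxonEstimate",
    "grid_sample_counts",
    "estimate_totals",
    "compare_groups",
    "read_axon_table",
    "write_axon_table",
]


@dataclass(frozen=True)
class EllipseBoundary:
    """Elliptical nerve cross-section boundary (all lengths in mm)."""

    semi_axis_x_mm: float
    semi_axis_y_mm: float
    center_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.semi_axis_x_mm <= 0 or self.semi_axis_y_mm <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.semi_axis_x_mm * self.semi_axis_y_mm)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.center_mm
        return (
            cx - self.semi_axis_x_mm,
            cy - self.semi_axis_y_mm,
            cx + self.semi_axis_x_mm,
            cy + self.semi_axis_y_mm,
        )

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        cx, cy = self.center_mm
        return ((xy[..., 0] - cx) / self.semi_axis_x_mm) ** 2 + (
            (xy[..., 1] - cy) / self.semi_axis_y_mm
        ) ** 2 <= 1.0


class PolygonBoundary:
    """Polygonal nerve boundary backed by shapely (convex or not)."""

    def __init__(self, exterior_xy_mm: Sequence[tuple[float, float]]):
        from shapely.geometry import Polygon

        self._poly = Polygon(exterior_xy_mm)
        if self._poly.area <= 0:
            raise ValueError("polygon must enclose a positive area")

    @property
    def area_mm2(self) -> float:
        return float(self._poly.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return tuple(self._poly.bounds)  # type: ignore[return-value]

    def contains(self, xy: np.ndarray) -> np.ndarray:
        from shapely import covers, points

        xy = np.asarray(xy, dtype=float)
        return covers(self._poly, points(xy.reshape(-1, 2))).reshape(xy.shape[:-1])


@dataclass
class AxonField:
    """Axon centroids with degeneration labels inside a nerve boundary."""

    xy_mm: np.ndarray  # (n, 2)
    degenerating: np.ndarray  # (n,) bool
    boundary: EllipseBoundary | PolygonBoundary

    def __post_init__(self) -> None:
        self.xy_mm = np.asarray(self.xy_mm, dtype=float).reshape(-1, 2)
        self.degenerating = np.asarray(self.degenerating, dtype=bool).reshape(-1)
        if len(self.xy_mm) != len(self.degenerating):
            raise ValueError("centroid and label lengths differ")
        if len(self.xy_mm) and not bool(np.all(self.boundary.contains(self.xy_mm))):
            raise ValueError("all centroids must lie inside the nerve boundary")

    @property
    def area_mm2(self) -> float:
        return self.boundary.area_mm2

    def __len__(self) -> int:
        return len(self.xy_mm)


@dataclass
class GridSample:
    """Counts in a systematic-random subset of fully interior grid cells."""

    cell_size_mm: float
    origin_mm: tuple[float, float]
    cell_indices: np.ndarray  # (m, 2) int (col, row) of selected cells
    counts_normal: np.ndarray  # (m,)
    counts_degenerating: np.ndarray  # (m,)
    n_interior_cells: int

    @property
    def sampled_area_mm2(self) -> float:
        return len(self.cell_indices) * self.cell_size_mm**2

    @property
    def total_count(self) -> int:
        return int(self.counts_normal.sum() + self.counts_degenerating.sum())


@dataclass
class AxonEstimate:
    """Density/total estimates expanded from a grid sample."""

    density_per_mm2: float
    total_axons: float
    percent_degenerating: Optional[float]  # None when nothing was counted
    total_non_degenerated: float
    sampled_fraction: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def grid_sample_counts(
    axon_field: AxonField,
    target_fraction: float = 0.20,
    cell_size_mm: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> GridSample:
    """Overlay a fixed grid and count axons in a systematic-random cell subset.

    The grid is anchored at the boundary's bounding-box corner.  Only cells
    fully interior to the boundary are eligible; a systematic-random subset
    (random start, regular stride through the row-major cell order) is
    selected so the summed cell area is within one cell of
    ``target_fraction`` x nerve area.  Cells are half-open (points on a
    shared edge belong to the cell owning the left/bottom edge).
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in (0, 1]")
    if cell_size_mm <= 0:
        raise ValueError("cell size must be positive")
    rng = np.random.default_rng(seed)

    x0, y0, x1, y1 = axon_field.boundary.bounds
    s = cell_size_mm
    nx = int(np.ceil((x1 - x0) / s))
    ny = int(np.ceil((y1 - y0) / s))
    if nx < 1 or ny < 1:
        raise ValueError("grid cell larger than the nerve bounding box")

    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx = x0 + ix * s
    cy = y0 + iy * s
    corners = np.stack(
        [
            np.stack([cx, cy], axis=-1),
            np.stack([cx + s, cy], axis=-1),
            np.stack([cx, cy + s], axis=-1),
            np.stack([cx + s, cy + s], axis=-1),
        ]
    )
    interior = np.all(
        [axon_field.boundary.contains(corners[k]) for k in range(4)], axis=0
    )
    interior_idx = np.argwhere(interior)  # row-major over (ix, iy)
    n_interior = len(interior_idx)
    if n_interior == 0:
        raise ValueError("no grid cell lies fully inside the nerve boundary")

    n_target = int(round(target_fraction * axon_field.area_mm2 / s**2))
    n_sel = max(1, min(n_target, n_interior))
    stride = n_interior / n_sel
    start = rng.uniform(0.0, stride)
    sel = np.unique(np.floor(start + stride * np.arange(n_sel)).astype(int))
    sel = sel[sel < n_interior]
    chosen = interior_idx[sel]

    # half-open cell membership of every centroid
    counts_n = np.zeros(len(chosen), dtype=int)
    counts_d = np.zeros(len(chosen), dtype=int)
    if len(axon_field):
        cell_of_pt = np.floor((axon_field.xy_mm - np.array([x0, y0])) / s).astype(int)
        key_pt = cell_of_pt[:, 0] * ny + cell_of_pt[:, 1]
        key_cell = chosen[:, 0] * ny + chosen[:, 1]
        order = np.argsort(key_cell)
        pos = np.searchsorted(key_cell[order], key_pt)
        inside = (pos < len(key_cell)) & (
            key_cell[order][np.clip(pos, 0, len(key_cell) - 1)] == key_pt
        )
        for sub, counts in ((~axon_field.degenerating, counts_n), (axon_field.degenerating, counts_d)):
            hit = inside & sub
            np.add.at(counts, order[pos[hit]], 1)

    return GridSample(
        cell_size_mm=s,
        origin_mm=(x0, y0),
        cell_indices=chosen,
        counts_normal=counts_n,
        counts_degenerating=counts_d,
        n_interior_cells=n_interior,
    )


def estimate_totals(sample: GridSample, axon_field: AxonField) -> AxonEstimate:
    """Expand grid-sample counts to whole-nerve totals.

    Density is the summed count over the summed sampled area; the total axon
    number is the product of that mean density and the nerve cross-sectional
    area.  The degenerating percentage is the labelled fraction of sampled
    counts; it is flagged as undefined (None) when nothing was counted.
    """
    area_sampled = sample.sampled_area_mm2
    if area_sampled <= 0:
        raise ValueError("sampled area must be positive")
    nerve_area = axon_field.area_mm2
    n_tot = sample.total_count
    n_deg = int(sample.counts_degenerating.sum())
    density = n_tot / area_sampled
    flags: list[str] = []
    if n_tot == 0:
        pct = None
        flags.append("no axons sampled; percent degenerating undefined")
    else:
        pct = 100.0 * n_deg / n_tot
    density_normal = sample.counts_normal.sum() / area_sampled
    return AxonEstimate(
        density_per_mm2=density,
        total_axons=density * nerve_area,
        percent_degenerating=pct,
        total_non_degenerated=density_normal * nerve_area,
        sampled_fraction=area_sampled / nerve_area,
        flags=tuple(flags),
    )


def compare_groups(
    treated_total: float,
    untreated_total: float,
    treated_pct_degenerating: float,
    untreated_pct_degenerating: float,
) -> dict[str, float]:
    """Between-eye report: relative axon loss (%) and degeneration ratio.

    ``relative_loss_pct`` is the treated-eye deficit as a percentage of the
    untreated total; ``degeneration_ratio`` is treated/untreated percent
    degenerating.
    """
    if untreated_total <= 0 or untreated_pct_degenerating <= 0:
        raise ValueError("untreated reference values must be positive")
    return {
        "relative_loss_pct": 100.0 * (untreated_total - treated_total) / untreated_total,
        "degeneration_ratio": treated_pct_degenerating / untreated_pct_degenerating,
    }


def read_axon_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TSV centroid table (columns x_mm, y_mm, label)."""
    df = pd.read_csv(path, sep="\t")
    xy = df[["x_mm", "y_mm"]].to_numpy(float)
    deg = df["label"].astype(str).str.strip().str.lower().eq("degenerating").to_numpy()
    return xy, deg


def write_axon_table(path, axon_field: AxonField) -> None:
    labels = np.where(axon_field.degenerating, "degenerating", "normal")
    pd.DataFrame(
        {"x_mm": axon_field.xy_mm[:, 0], "y_mm": axon_field.xy_mm[:, 1], "label": labels}
    ).to_csv(path, sep="\t", index=False)
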