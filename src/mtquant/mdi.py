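"""Microtubule Distribution Index (MDI).

The MDI quantifies how tubulin intensity is distributed between the cell
center and the periphery.  From a manually chosen central point, straight
line profiles are cast at a fixed angular interval to the cell boundary.
For each line the mean intensity of the inner part (adjacent to the
center, default the inner 10% of the line length) and of the outer part
(adjacent to the boundary, default the outer 40%) are measured, and their
ratio R = I_o / I_i computed.  The MDI of a cell is the average of all
defined per-line ratios: a low MDI indicates a centralized (aster-like)
microtubule network, a high MDI a dispersed one.

Numerical conventions:

* intensities are sampled along each line at ~1-pixel arc spacing with
  bilinear interpolation;
* lines are cast at angles k * angle_interval_deg (counterclockwise from
  +x), k = 0 .. floor(360/interval) - 1, ending at the FIRST intersection
  of the ray with the boundary polygon (so profiles stay inside the cell
  even for concave outlines);
* a line whose inner aggregate intensity is exactly zero has an undefined
  ratio and is excluded from the average (an error is raised only if every
  line is undefined).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString

from .datatypes import CellGeometry, CellImage

Segment = tuple[tuple[float, float], tuple[float, float]]


@dataclass
class MDIConfig:
    """Parameters of the MDI measurement."""

    angle_interval_deg: float = 3.0
    inner_fraction: float = 0.10
    outer_fraction: float = 0.40
    aggregate: str = "mean"  # "mean" or "max" per-segment intensity statistic

    def __post_init__(self) -> None:
        if not self.angle_interval_deg > 0:
            raise ValueError("angle_interval_deg must be positive")
        if not 0 < self.inner_fraction < 1:
            raise ValueError("inner_fraction must be in (0, 1)")
        if not 0 < self.outer_fraction < 1:
            raise ValueError("outer_fraction must be in (0, 1)")
        if self.inner_fraction + self.outer_fraction > 1:
            raise ValueError("inner_fraction + outer_fraction must be <= 1")
        if self.aggregate not in ("mean", "max"):
            raise ValueError("aggregate must be 'mean' or 'max'")

    @property
    def n_lines(self) -> int:
        return int(math.floor(360.0 / self.angle_interval_deg))


@dataclass
class MDIResult:
    """Per-cell MDI with per-line ratios (NaN marks undefined lines)."""

    per_line_R: np.ndarray
    mdi: float
    n_lines: int


def radial_lines(geometry: CellGeometry, config: MDIConfig | None = None) -> list[Segment]:
    """Cast one line per angle from the center to the first boundary crossing.

    Returns a list of ((x0, y0), (x1, y1)) segments in pixel coordinates,
    one per angle k * angle_interval_deg.
    """
    config = config or MDIConfig()
    cx, cy = geometry.center_px
    boundary = geometry.polygon.exterior
    # Any ray from an interior point must cross the boundary within this reach.
    minx, miny, maxx, maxy = geometry.polygon.bounds
    reach = 2.0 * max(maxx - minx, maxy - miny) + 1.0

    segments: list[Segment] = []
    for k in range(config.n_lines):
        theta = math.radians(k * config.angle_interval_deg)
        dx, dy = math.cos(theta), math.sin(theta)
        ray = LineString([(cx, cy), (cx + reach * dx, cy + reach * dy)])
        inter = ray.intersection(boundary)
        if inter.is_empty:
            raise ValueError(
                f"ray at {k * config.angle_interval_deg:g} deg does not hit the "
                "boundary (is the center inside the polygon?)"
            )
        # Gather all crossing coordinates; take the nearest beyond the center.
        geoms = getattr(inter, "geoms", [inter])
        best: tuple[float, float] | None = None
        best_t = math.inf
        for g in geoms:
            for x, y in np.asarray(g.coords):
                t = (x - cx) * dx + (y - cy) * dy
                if 1e-9 < t < best_t:
                    best_t = t
                    best = (float(x), float(y))
        if best is None:
            raise ValueError(
                f"ray at {k * config.angle_interval_deg:g} deg yields no boundary "
                "crossing with positive length"
            )
        segments.append(((cx, cy), best))
    return segments


def _sample_line(image: CellImage, segment: Segment) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample intensities along a segment at ~1-pixel spacing (bilinear)."""
    (x0, y0), (x1, y1) = segment
    length = math.hypot(x1 - x0, y1 - y0)
    if length <= 0:
        raise ValueError("segment has zero length")
    n = max(2, int(math.ceil(length - 1e-9)) + 1)
    t = np.linspace(0.0, 1.0, n)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    values = map_coordinates(image.data, [ys, xs], order=1, mode="nearest")
    return values, t * length, length


def line_ratio(image: CellImage, segment: Segment, config: MDIConfig | None = None) -> float | None:
    """Outer/inner intensity ratio R = I_o / I_i along one line profile.

    Returns ``None`` when the inner aggregate intensity is zero (undefined
    ratio, excluded from the per-cell average).
    """
    config = config or MDIConfig()
    values, arc, length = _sample_line(image, segment)
    inner = values[arc <= config.inner_fraction * length + 1e-9]
    outer = values[arc >= (1.0 - config.outer_fraction) * length - 1e-9]
    agg = np.mean if config.aggregate == "mean" else np.max
    i_inner = float(agg(inner))
    i_outer = float(agg(outer))
    if i_inner == 0.0:
        return None
    return i_outer / i_inner


def compute_mdi(
    image: CellImage, geometry: CellGeometry, config: MDIConfig | None = None
) -> MDIResult:
    """Per-cell MDI: the mean of all defined per-line ratios R = I_o / I_i."""
    config = config or MDIConfig()
    segments = radial_lines(geometry, config)
    per_line = np.full(len(segments), np.nan)
    for i, seg in enumerate(segments):
        r = line_ratio(image, seg, config)
        if r is not None:
            per_line[i] = r
    defined = per_line[np.isfinite(per_line)]
    if defined.size == 0:
        raise ValueError("MDI undefined (empty inner intensities on every line)")
    return MDIResult(per_line_R=per_line, mdi=float(defined.mean()), n_lines=len(segments))
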