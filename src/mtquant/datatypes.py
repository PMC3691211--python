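"""Core data containers shared across the quantification pipeline.

Coordinate conventions (fixed package-wide):

* pixel coordinates are 0-based with the pixel-center convention,
  ``x`` = column index, ``y`` = row index;
* physical units are micrometres (µm) and minutes everywhere in outputs;
* angles are measured counterclockwise from the +x axis in image
  coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from functools import cached_property

import numpy as np
from shapely.geometry import Point, Polygon


class Phase(IntEnum):
    """Dynamic-instability phase of a microtubule tip."""

    GROWTH = 0
    SHRINKAGE = 1
    PAUSE = 2


def path_length(polyline: np.ndarray) -> float:
    """Total length of a polyline given as an (N, 2) vertex array."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("polyline must be an (N>=2, 2) array")
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass
class CellImage:
    """A single- or two-channel 2D fluorescence image with physical pixel size.

    ``data`` is the primary channel (e.g. total tubulin); ``channel2`` an
    optional registered second channel (e.g. acetylated tubulin).
    """

    data: np.ndarray
    pixel_size_um: float
    channel2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {self.data.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.channel2 is not None:
            self.channel2 = np.asarray(self.channel2, dtype=float)
            if self.channel2.shape != self.data.shape:
                raise ValueError(
                    f"channel2 shape {self.channel2.shape} does not match "
                    f"primary channel {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class CellGeometry:
    """Manually selected cell geometry: a central point plus boundary polygon.

    The center is the point of highest tubulin concentration near the cell
    middle; the boundary outlines the cell border.  Both are in pixel
    coordinates (x, y).
    """

    center_px: tuple[float, float]
    boundary_px: np.ndarray

    def __post_init__(self) -> None:
        self.center_px = (float(self.center_px[0]), float(self.center_px[1]))
        self.boundary_px = np.asarray(self.boundary_px, dtype=float)
        if self.boundary_px.ndim != 2 or self.boundary_px.shape[1] != 2:
            raise ValueError("boundary_px must be an (N, 2) array of vertices")
        if len(self.boundary_px) < 3:
            raise ValueError("boundary polygon needs at least 3 vertices")
        poly = Polygon(self.boundary_px)
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("boundary polygon must be simple (non-self-intersecting)")
        if not poly.contains(Point(*self.center_px)):
            raise ValueError("center must lie strictly inside the boundary polygon")

    @cached_property
    def polygon(self) -> Polygon:
        return Polygon(self.boundary_px)


@dataclass
class Track:
    """An ordered sequence of (frame, x, y) tip or comet positions.

    Frames must be strictly increasing.  ``frame_interval_s`` is the time
    between consecutive frame numbers; ``pixel_size_um`` converts pixel
    displacements to µm.
    """

    track_id: int | str
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if not (len(self.frames) == len(self.x_px) == len(self.y_px)):
            raise ValueError("frames, x_px and y_px must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 samples")
        d = np.diff(self.frames)
        if np.any(d <= 0):
            raise ValueError(
                f"track {self.track_id!r}: frames must be strictly increasing "
                "(duplicate or unsorted frames)"
            )
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def positions_um(self) -> np.ndarray:
        """(N, 2) array of positions in µm."""
        return np.column_stack([self.x_px, self.y_px]) * self.pixel_size_um


@dataclass
class EMFilament:
    """A microtubule polyline from an EM image plus bound gold particles.

    Coordinates are in µm.  ``length_um`` is validated against the polyline
    path length (tolerance 1e-6) or filled in when omitted.
    """

    filament_id: int | str
    polyline_um: np.ndarray
    particles_um: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    length_um: float | None = None

    def __post_init__(self) -> None:
        self.polyline_um = np.asarray(self.polyline_um, dtype=float)
        self.particles_um = np.asarray(self.particles_um, dtype=float).reshape(-1, 2)
        plen = path_length(self.polyline_um)
        if self.length_um is None:
            self.length_um = plen
        elif abs(self.length_um - plen) > 1e-6:
            raise ValueError(
                f"filament {self.filament_id!r}: length_um={self.length_um} "
                f"disagrees with polyline path length {plen}"
            )

    @property
    def n_particles(self) -> int:
        return len(self.particles_um)
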