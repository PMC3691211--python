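"""Comet origin classification and dynamic-instability parameter extraction.

Phase segmentation follows a static-displacement rule: a tip that moves
less than 0.3 µm between consecutive frames is in pause; larger
displacements are growth or shrinkage according to their sign, which is
the projection of the displacement onto the direction away from a
per-track reference point (a minus-end proxy, e.g. the nucleation site).

Catastrophe frequency is the number of transitions from growth (or
pause) to shrinkage per minute of time spent in growth + pause; rescue
frequency is the number of transitions from shrinkage (or pause) to
growth per minute of time in shrinkage + pause.  An alternative
per-total-time denominator is available via ``denominator="total"``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import Phase, Track


@dataclass
class PhaseSegmentation:
    """Per-interval phase labels and speeds of one (gap-free) track."""

    labels: np.ndarray  # Phase codes, length n_samples - 1
    speeds_um_min: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.speeds_um_min = np.asarray(self.speeds_um_min, dtype=float)
        if self.labels.shape != self.speeds_um_min.shape:
            raise ValueError("labels and speeds must have equal length")


@dataclass
class DynamicsSummary:
    """Pooled dynamic-instability parameters of a set of tracks.

    Percentages are fractions of total observed time and sum to 100
    exactly.  Frequencies are ``None`` when the corresponding at-risk
    exposure time is zero (undefined, not zero).  Speeds are NaN when no
    interval of the matching phase was observed.
    """

    pct_growth: float
    pct_shrink: float
    pct_pause: float
    mean_growth_speed_um_min: float
    mean_shrink_speed_um_min: float
    catastrophe_freq_per_min: float | None
    rescue_freq_per_min: float | None
    n_tracks: int
    total_time_min: float


@dataclass
class OriginCall:
    """Origin classification of one comet track."""

    track_id: int | str
    origin: str  # "centrosomal" | "non_centrosomal" | "excluded"
    start_distance_um: float
    n_frames: int


def split_on_gaps(track: Track) -> list[Track]:
    """Split a track at skipped frames into gap-free sub-tracks.

    The static-displacement rule is a per-frame rule, so intervals
    spanning missing frames are not interpretable; each contiguous run of
    frames becomes an independent track (runs shorter than 2 samples are
    dropped).
    """
    breaks = np.where(np.diff(track.frames) != 1)[0] + 1
    pieces = []
    for part in np.split(np.arange(track.n_frames), breaks):
        if len(part) >= 2:
            pieces.append(
                Track(
                    track_id=track.track_id,
                    frames=track.frames[part],
                    x_px=track.x_px[part],
                    y_px=track.y_px[part],
                    frame_interval_s=track.frame_interval_s,
                    pixel_size_um=track.pixel_size_um,
                )
            )
    return pieces


def segment_phases(
    track: Track,
    static_threshold_um: float = 0.3,
    direction_ref: tuple[float, float] | None = None,
) -> PhaseSegmentation:
    """Label each consecutive-frame interval as growth, shrinkage or pause.

    ``direction_ref`` (pixel coordinates) defines the growth sign:
    displacement away from the reference is growth.  Tracks with frame
    gaps must be split with :func:`split_on_gaps` first.
    """
    if direction_ref is None:
        raise ValueError("direction_ref is required: the growth sign is undefined without it")
    if not static_threshold_um > 0:
        raise ValueError("static_threshold_um must be positive")
    if np.any(np.diff(track.frames) != 1):
        raise ValueError(
            f"track {track.track_id!r} contains frame gaps; split with split_on_gaps first"
        )
    pos = track.positions_um
    ref = np.asarray(direction_ref, dtype=float) * track.pixel_size_um
    disp = np.diff(pos, axis=0)
    dist = np.hypot(disp[:, 0], disp[:, 1])
    away = pos[:-1] - ref
    norm = np.hypot(away[:, 0], away[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norm[:, None] > 0, away / np.where(norm[:, None] > 0, norm[:, None], 1.0), 0.0)
    proj = np.sum(disp * unit, axis=1)
    # At the reference point itself the outward direction degenerates: count as outward.
    sign = np.where((proj >= 0) | (norm == 0), 1.0, -1.0)

    labels = np.full(len(dist), int(Phase.PAUSE), dtype=np.int8)
    moving = dist >= static_threshold_um
    labels[moving & (sign > 0)] = int(Phase.GROWTH)
    labels[moving & (sign < 0)] = int(Phase.SHRINKAGE)
    speeds = dist / (track.frame_interval_s / 60.0)
    return PhaseSegmentation(labels=labels, speeds_um_min=speeds, frame_interval_s=track.frame_interval_s)


def summarize_dynamics(
    segmentations: list[PhaseSegmentation],
    denominator: str = "at_risk",
) -> DynamicsSummary:
    """Pool phase segmentations into dynamic-instability parameters.

    denominator="at_risk" (default): catastrophes per minute of
    growth+pause time and rescues per minute of shrinkage+pause time.
    denominator="total": both frequencies per minute of total time.
    """
    if not segmentations:
        raise ValueError("need at least one segmentation")
    if denominator not in ("at_risk", "total"):
        raise ValueError("denominator must be 'at_risk' or 'total'")

    t_growth = t_shrink = t_pause = 0.0
    n_cat = n_res = 0
    growth_speed_sum = shrink_speed_sum = 0.0
    n_growth = n_shrink = 0
    for seg in segmentations:
        dt_min = seg.frame_interval_s / 60.0
        lab = seg.labels
        t_growth += np.sum(lab == Phase.GROWTH) * dt_min
        t_shrink += np.sum(lab == Phase.SHRINKAGE) * dt_min
        t_pause += np.sum(lab == Phase.PAUSE) * dt_min
        a, b = lab[:-1], lab[1:]
        n_cat += int(np.sum((b == Phase.SHRINKAGE) & (a != Phase.SHRINKAGE)))
        n_res += int(np.sum((b == Phase.GROWTH) & (a != Phase.GROWTH)))
        g = lab == Phase.GROWTH
        s = lab == Phase.SHRINKAGE
        growth_speed_sum += float(np.sum(seg.speeds_um_min[g]))
        shrink_speed_sum += float(np.sum(seg.speeds_um_min[s]))
        n_growth += int(np.sum(g))
        n_shrink += int(np.sum(s))

    total = t_growth + t_shrink + t_pause
    pct_growth = 100.0 * t_growth / total
    pct_shrink = 100.0 * t_shrink / total
    pct_pause = 100.0 - pct_growth - pct_shrink  # exact complement

    if denominator == "at_risk":
        cat_exposure = t_growth + t_pause
        res_exposure = t_shrink + t_pause
    else:
        cat_exposure = res_exposure = total
    cat_freq = n_cat / cat_exposure if cat_exposure > 0 else None
    res_freq = n_res / res_exposure if res_exposure > 0 else None

    return DynamicsSummary(
        pct_growth=pct_growth,
        pct_shrink=pct_shrink,
        pct_pause=pct_pause,
        mean_growth_speed_um_min=growth_speed_sum / n_growth if n_growth else math.nan,
        mean_shrink_speed_um_min=shrink_speed_sum / n_shrink if n_shrink else math.nan,
        catastrophe_freq_per_min=cat_freq,
        rescue_freq_per_min=res_freq,
        n_tracks=len(segmentations),
        total_time_min=total,
    )


def classify_comet_origin(
    track: Track,
    centrosome_px: tuple[float, float],
    centrosomal_radius_um: float = 2.0,
    min_frames: int = 4,
    ambiguity_factor: float = 2.0,
) -> OriginCall:
    """Classify a comet track as centrosomal, non-centrosomal or excluded.

    Tracks followed for fewer than ``min_frames`` frames are excluded.  A
    track is centrosomal when it starts within ``centrosomal_radius_um``
    of the centrosome and its initial velocity points away from it;
    non-centrosomal when it starts beyond ``centrosomal_radius_um *
    ambiguity_factor``.  Starts inside the ambiguity band (or inside the
    radius but moving inward) are excluded as ambiguous.
    """
    if not centrosomal_radius_um > 0:
        raise ValueError("centrosomal_radius_um must be positive")
    if ambiguity_factor < 1:
        raise ValueError("ambiguity_factor must be >= 1")
    pos = track.positions_um
    c = np.asarray(centrosome_px, dtype=float) * track.pixel_size_um
    start_dist = float(np.hypot(*(pos[0] - c)))

    if track.n_frames < min_frames:
        origin = "excluded"
    elif start_dist <= centrosomal_radius_um:
        v0 = pos[1] - pos[0]
        outward = float(np.dot(v0, pos[0] - c)) >= 0 or start_dist == 0
        origin = "centrosomal" if outward else "excluded"
    elif start_dist >= centrosomal_radius_um * ambiguity_factor:
        origin = "non_centrosomal"
    else:
        origin = "excluded"
    return OriginCall(
        track_id=track.track_id,
        origin=origin,
        start_distance_um=start_dist,
        n_frames=track.n_frames,
    )


def detect_time_zero(
    intensity_trace,
    baseline_frames: int = 10,
    threshold_factor: float = 8.0,
    rel_floor: float = 0.01,
) -> int | None:
    """First frame where summed fluorescence bursts above baseline.

    The baseline is the median of the first ``baseline_frames`` values;
    its robust deviation is 1.4826 x the median absolute deviation,
    floored at ``rel_floor`` times the absolute baseline so that a flat
    trace never triggers.  Returns the first frame whose value exceeds
    baseline + threshold_factor x deviation, or ``None`` when no frame
    qualifies (no burst detected).
    """
    trace = list(intensity_trace)
    if len(trace) < 5:
        raise ValueError("trace must have at least 5 frames")
    if np.ndim(trace[0]) == 0:
        frames = list(range(len(trace)))
        values = np.asarray(trace, dtype=float)
    else:
        frames = [int(f) for f, _ in trace]
        values = np.asarray([v for _, v in trace], dtype=float)
    if baseline_frames < 2 or baseline_frames > len(values):
        raise ValueError("baseline_frames must be in [2, len(trace)]")
    base = values[:baseline_frames]
    b = float(np.median(base))
    sigma = 1.4826 * float(np.median(np.abs(base - b)))
    sigma_eff = max(sigma, rel_floor * abs(b), 1e-12)
    threshold = b + threshold_factor * sigma_eff
    hits = np.where(values > threshold)[0]
    if len(hits) == 0:
        return None
    return frames[int(hits[0])]
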