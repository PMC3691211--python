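"""Synthetic ground-truth generators for every quantification stage.

These generators produce images, tracks and EM annotations with known
ground truth so that each analysis stage can be validated without any
experimental data:

* :func:`make_filament_image` renders aster-like or dispersed microtubule
  images (1-pixel polylines of unit amplitude, Gaussian PSF blur, optional
  noise) with a per-segment ground-truth record, optionally with a second
  channel marking acetylated (pre-existing) filaments;
* :func:`simulate_di_track` simulates a microtubule tip undergoing dynamic
  instability as a continuous-time three-state process (growth,
  shrinkage, pause) sampled at the frame interval with localization
  jitter, recording the true state history;
* :func:`simulate_comets` produces plus-end comet tracks with known
  centrosomal / non-centrosomal origin labels;
* :func:`make_em_filaments` produces filament polylines with gold
  particles placed by a Poisson process of known intensity;
* :func:`make_particle_field` renders fields of disjoint fluorescent spots
  for the nucleation-assay counter;
* :func:`simulate_washout_trace` emulates the whole-field fluorescence
  trace around the first comet burst after drug washout.

All generators are deterministic given their seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from .datatypes import CellGeometry, CellImage, EMFilament, Phase, Track, path_length

_PLACEMENT_CAP = 10_000  # rejection-sampling attempts before "no placement area"


@dataclass
class ImageSpec:
    """Rendering parameters of a synthetic fluorescence image.

    Defaults mirror a confocal acquisition at 0.1 µm/pixel.  Filaments are
    rendered as anti-aliased 1-pixel polylines of unit amplitude, then
    convolved with a Gaussian PSF of ``psf_sigma_px``.
    """

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.1
    psf_sigma_px: float = 1.0
    background_level: float = 0.0
    noise_model: str = "none"  # none | gaussian | poisson
    noise_param: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 32 or self.height_px < 32:
            raise ValueError("image must be at least 32x32 pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.psf_sigma_px < 0 or self.noise_param < 0 or self.background_level < 0:
            raise ValueError("psf_sigma_px, background_level and noise_param must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be one of none|gaussian|poisson")


@dataclass
class FilamentGroundTruth:
    """Per-segment ground truth of a rendered filament image."""

    segments: list[np.ndarray]  # each (2, 2): endpoint pixel coordinates (x, y)
    lengths_um: list[float]
    is_acetylated: list[bool]
    pixel_size_um: float
    centrosome_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (len(self.segments) == len(self.lengths_um) == len(self.is_acetylated)):
            raise ValueError("ground-truth lists must have equal length")
        for seg, length in zip(self.segments, self.lengths_um):
            if abs(path_length(seg) * self.pixel_size_um - length) > 1e-6:
                raise ValueError("lengths_um disagrees with polyline path length")

    @property
    def n_filaments(self) -> int:
        return len(self.segments)

    @property
    def total_length_um(self) -> float:
        return float(sum(self.lengths_um))


def _render_segments(
    segments: list[np.ndarray], spec: ImageSpec, rng: np.random.Generator
) -> np.ndarray:
    from skimage.draw import line_aa

    canvas = np.zeros((spec.height_px, spec.width_px), dtype=float)
    for seg in segments:
        (x0, y0), (x1, y1) = seg.astype(int)
        rr, cc, val = line_aa(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < spec.height_px) & (cc >= 0) & (cc < spec.width_px)
        rr, cc, val = rr[keep], cc[keep], val[keep]
        # Overlaps saturate at unit amplitude rather than summing.
        canvas[rr, cc] = np.maximum(canvas[rr, cc], val)
    if spec.psf_sigma_px > 0:
        canvas = gaussian_filter(canvas, spec.psf_sigma_px)
    canvas = canvas + spec.background_level
    if spec.noise_model == "gaussian" and spec.noise_param > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_param, canvas.shape)
    elif spec.noise_model == "poisson" and spec.noise_param > 0:
        # noise_param acts as photons per intensity unit.
        canvas = rng.poisson(np.clip(canvas, 0, None) * spec.noise_param) / spec.noise_param
    return canvas


def make_filament_image(
    spec: ImageSpec,
    n_filaments: int,
    length_range_um: tuple[float, float],
    layout: str = "dispersed",
    acetyl_fraction: float = 0.0,
    centrosome_px: tuple[float, float] | None = None,
    region: CellGeometry | None = None,
    min_separation_px: float = 0.0,
    two_channel: bool | None = None,
) -> tuple[CellImage, FilamentGroundTruth]:
    """Render a synthetic microtubule image plus its ground truth.

    layout="aster": straight segments emanate radially from the centrosome
    (default image center).  layout="dispersed": segment midpoints are
    uniform over the placement region with uniform random orientation.
    ``min_separation_px`` > 0 enforces non-overlapping placement by
    rejection sampling (only meaningful for the dispersed layout).
    Segments marked acetylated are additionally rendered into channel 2.
    """
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    lo, hi = length_range_um
    if not (0 < lo <= hi):
        raise ValueError("length_range_um must be a positive interval")
    if layout not in ("aster", "dispersed"):
        raise ValueError("layout must be 'aster' or 'dispersed'")

    rng = np.random.default_rng(spec.seed)
    lengths_um = rng.uniform(lo, hi, size=n_filaments)
    acetyl = rng.random(n_filaments) < acetyl_fraction

    margin = 2.0
    if region is not None:
        poly = region.polygon
    else:
        poly = None

    def inside(x: float, y: float) -> bool:
        if not (margin <= x <= spec.width_px - 1 - margin):
            return False
        if not (margin <= y <= spec.height_px - 1 - margin):
            return False
        if poly is not None and not poly.contains(Point(x, y)):
            return False
        return True

    if layout == "aster":
        if centrosome_px is None:
            centrosome_px = ((spec.width_px - 1) / 2.0, (spec.height_px - 1) / 2.0)
        cx, cy = round(centrosome_px[0]), round(centrosome_px[1])
        if n_filaments > 0 and not inside(cx, cy):
            raise ValueError("no placement area: centrosome outside the placement region")
        centrosome_px = (float(cx), float(cy))

    segments: list[np.ndarray] = []
    placed: list[LineString] = []
    for i in range(n_filaments):
        len_px = lengths_um[i] / spec.pixel_size_um
        ok = False
        for _ in range(_PLACEMENT_CAP):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            dx, dy = math.cos(theta), math.sin(theta)
            if layout == "aster":
                x0, y0 = centrosome_px  # type: ignore[misc]
                x1, y1 = x0 + len_px * dx, y0 + len_px * dy
            else:
                mx = rng.uniform(margin, spec.width_px - 1 - margin)
                my = rng.uniform(margin, spec.height_px - 1 - margin)
                x0, y0 = mx - 0.5 * len_px * dx, my - 0.5 * len_px * dy
                x1, y1 = mx + 0.5 * len_px * dx, my + 0.5 * len_px * dy
            seg = np.array([[round(x0), round(y0)], [round(x1), round(y1)]], dtype=float)
            if np.array_equal(seg[0], seg[1]):
                continue
            if not (inside(*seg[0]) and inside(*seg[1])):
                continue
            if layout == "dispersed" and min_separation_px > 0:
                ls = LineString(seg)
                if any(ls.distance(other) < min_separation_px for other in placed):
                    continue
                placed.append(ls)
            segments.append(seg)
            lengths_um[i] = path_length(seg) * spec.pixel_size_um
            ok = True
            break
        if not ok:
            raise RuntimeError("no placement area: rejection sampling exhausted")

    data = _render_segments(segments, spec, rng)
    if two_channel is None:
        two_channel = acetyl_fraction > 0
    channel2 = None
    if two_channel:
        acetyl_segments = [s for s, a in zip(segments, acetyl) if a]
        channel2 = _render_segments(acetyl_segments, spec, rng)

    truth = FilamentGroundTruth(
        segments=segments,
        lengths_um=[float(v) for v in lengths_um[: len(segments)]],
        is_acetylated=[bool(a) for a in acetyl],
        pixel_size_um=spec.pixel_size_um,
        centrosome_px=centrosome_px if layout == "aster" else None,
    )
    return CellImage(data, spec.pixel_size_um, channel2=channel2), truth


# ---------------------------------------------------------------------------
# Dynamic instability simulation
# ---------------------------------------------------------------------------


@dataclass
class DynamicsParams:
    """Parameters of the three-state dynamic-instability simulator.

    Growth and shrinkage speeds are in µm/min; catastrophe (growth ->
    shrinkage) and rescue (shrinkage -> growth) are exponential rates per
    minute.  At each transition event a pause is interposed with
    probability ``p_pause`` before the target state is entered; pauses end
    after an exponential dwell with rate ``pause_exit_rate_per_min``.
    Sampled positions carry isotropic Gaussian localization jitter of
    ``jitter_sigma_um``, well below the 0.3 µm/frame static threshold so
    it does not by itself flip phase classifications.
    """

    v_growth_um_min: float = 12.0
    v_shrink_um_min: float = 18.0
    k_catastrophe_per_min: float = 2.0
    k_rescue_per_min: float = 1.0
    p_pause: float = 0.0
    pause_exit_rate_per_min: float = 1.0
    frame_interval_s: float = 3.0
    n_frames: int = 40
    jitter_sigma_um: float = 0.05
    pixel_size_um: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_growth_um_min < 0 or self.v_shrink_um_min < 0:
            raise ValueError("speeds must be >= 0")
        if self.k_catastrophe_per_min < 0 or self.k_rescue_per_min < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.p_pause <= 1:
            raise ValueError("p_pause must be in [0, 1]")
        if not self.pause_exit_rate_per_min > 0:
            raise ValueError("pause_exit_rate_per_min must be positive")
        if self.n_frames < 4:
            raise ValueError("n_frames must be >= 4")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")


@dataclass
class SimulatedTrack:
    """A simulated tip track with its exact state history.

    ``events`` is the piecewise-constant state history as (phase,
    duration_min) pairs covering the whole observation; ``true_states``
    holds the instantaneous phase at each sampled frame.
    ``direction_ref_px`` is a minus-end proxy suitable as the
    ``direction_ref`` of phase segmentation.
    """

    track: Track
    true_states: np.ndarray
    events: list[tuple[Phase, float]]
    params: DynamicsParams
    direction_ref_px: tuple[float, float]


def simulate_di_track(params: DynamicsParams) -> SimulatedTrack:
    """Simulate one microtubule tip track along a single axis."""
    rng = np.random.default_rng(params.seed)
    dt_min = params.frame_interval_s / 60.0
    total_min = (params.n_frames - 1) * dt_min

    k_cat = params.k_catastrophe_per_min
    k_res = params.k_rescue_per_min
    k_pe = params.pause_exit_rate_per_min

    states: list[Phase] = []
    durations: list[float] = []
    t = 0.0
    state = Phase.GROWTH
    pause_target = Phase.SHRINKAGE
    while t < total_min:
        if state is Phase.GROWTH:
            rate = k_cat
            target = Phase.SHRINKAGE
        elif state is Phase.SHRINKAGE:
            rate = k_res
            target = Phase.GROWTH
        else:
            rate = k_pe
            target = pause_target
        dwell = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        states.append(state)
        durations.append(min(dwell, total_min - t))
        t += dwell
        if t >= total_min:
            break
        if state is not Phase.PAUSE and params.p_pause > 0 and rng.random() < params.p_pause:
            pause_target = target
            state = Phase.PAUSE
        else:
            state = target

    seg_state = np.array([int(s) for s in states])
    seg_dur = np.asarray(durations)
    speed = np.array([params.v_growth_um_min, -params.v_shrink_um_min, 0.0])
    seg_v = speed[seg_state]
    bounds = np.concatenate([[0.0], np.cumsum(seg_dur)])
    pos_start = np.concatenate([[0.0], np.cumsum(seg_v * seg_dur)])

    t_frames = np.arange(params.n_frames) * dt_min
    idx = np.clip(np.searchsorted(bounds, t_frames, side="right") - 1, 0, len(seg_dur) - 1)
    pos = pos_start[idx] + seg_v[idx] * (t_frames - bounds[idx])
    true_states = seg_state[idx]

    x_um = 5.0 + pos + rng.normal(0.0, params.jitter_sigma_um, params.n_frames)
    y_um = 5.0 + rng.normal(0.0, params.jitter_sigma_um, params.n_frames)
    track = Track(
        track_id=params.seed,
        frames=np.arange(params.n_frames),
        x_px=x_um / params.pixel_size_um,
        y_px=y_um / params.pixel_size_um,
        frame_interval_s=params.frame_interval_s,
        pixel_size_um=params.pixel_size_um,
    )
    ref = (-1e6, 5.0 / params.pixel_size_um)  # far behind the minus end on the growth axis
    return SimulatedTrack(
        track=track,
        true_states=true_states,
        events=[(Phase(int(s)), float(d)) for s, d in zip(seg_state, seg_dur)],
        params=params,
        direction_ref_px=ref,
    )


def true_frequencies(sim: SimulatedTrack | list[SimulatedTrack]) -> tuple[float, float]:
    """Exact (catastrophe, rescue) frequencies from simulated state histories.

    Events per minute of at-risk time: transitions into shrinkage divided by
    time in growth+pause, and transitions into growth divided by time in
    shrinkage+pause.
    """
    sims = sim if isinstance(sim, list) else [sim]
    n_cat = n_res = 0
    t_g = t_s = t_p = 0.0
    for s in sims:
        phases = [e[0] for e in s.events]
        durs = [e[1] for e in s.events]
        for ph, d in zip(phases, durs):
            if ph is Phase.GROWTH:
                t_g += d
            elif ph is Phase.SHRINKAGE:
                t_s += d
            else:
                t_p += d
        for a, b in zip(phases[:-1], phases[1:]):
            if b is Phase.SHRINKAGE and a in (Phase.GROWTH, Phase.PAUSE):
                n_cat += 1
            elif b is Phase.GROWTH and a in (Phase.SHRINKAGE, Phase.PAUSE):
                n_res += 1
    f_cat = n_cat / (t_g + t_p) if t_g + t_p > 0 else math.nan
    f_res = n_res / (t_s + t_p) if t_s + t_p > 0 else math.nan
    return f_cat, f_res


# ---------------------------------------------------------------------------
# Comet tracks with known origin
# ---------------------------------------------------------------------------


def simulate_comets(
    n_centrosomal: int,
    n_noncentrosomal: int,
    centrosome_px: tuple[float, float],
    geometry: CellGeometry,
    speed_um_min: float = 15.0,
    pixel_size_um: float = 0.1,
    frame_interval_s: float = 5.0,
    n_frames: int = 8,
    start_radius_um: float = 0.5,
    exclusion_radius_um: float = 6.0,
    jitter_sigma_um: float = 0.02,
    seed: int = 0,
) -> list[tuple[Track, str]]:
    """Generate labeled comet tracks inside a cell boundary.

    Centrosomal comets start within ``start_radius_um`` of the centrosome
    and move radially outward; non-centrosomal comets start at uniform
    positions at least ``exclusion_radius_um`` from the centrosome and move
    in a uniform random direction.  All samples stay inside the boundary
    polygon (placements that would exit are rejected and re-drawn).
    """
    if n_centrosomal < 0 or n_noncentrosomal < 0:
        raise ValueError("comet counts must be >= 0")
    if not speed_um_min > 0:
        raise ValueError("speed_um_min must be positive")
    poly = geometry.polygon
    c = np.asarray(centrosome_px, dtype=float)
    if not poly.contains(Point(*c)):
        raise ValueError("centrosome must lie inside the cell boundary")

    rng = np.random.default_rng(seed)
    step_px = speed_um_min * (frame_interval_s / 60.0) / pixel_size_um
    start_radius_px = start_radius_um / pixel_size_um
    exclusion_px = exclusion_radius_um / pixel_size_um

    def path_inside(start: np.ndarray, direction: np.ndarray) -> np.ndarray | None:
        t = np.arange(n_frames)[:, None]
        pts = start[None, :] + t * step_px * direction[None, :]
        if all(poly.contains(Point(*p)) for p in pts):
            return pts
        return None

    tracks: list[tuple[Track, str]] = []
    specs = [("centrosomal", n_centrosomal), ("non_centrosomal", n_noncentrosomal)]
    tid = 0
    for label, count in specs:
        for _ in range(count):
            pts = None
            for _ in range(_PLACEMENT_CAP):
                if label == "centrosomal":
                    r = start_radius_px * math.sqrt(rng.uniform())
                    phi = rng.uniform(0, 2 * math.pi)
                    start = c + r * np.array([math.cos(phi), math.sin(phi)])
                    out = start - c
                    norm = np.hypot(*out)
                    if norm < 1e-9:
                        ang = rng.uniform(0, 2 * math.pi)
                        direction = np.array([math.cos(ang), math.sin(ang)])
                    else:
                        direction = out / norm
                else:
                    minx, miny, maxx, maxy = poly.bounds
                    start = np.array(
                        [rng.uniform(minx, maxx), rng.uniform(miny, maxy)]
                    )
                    if not poly.contains(Point(*start)):
                        continue
                    if np.hypot(*(start - c)) < exclusion_px:
                        continue
                    ang = rng.uniform(0, 2 * math.pi)
                    direction = np.array([math.cos(ang), math.sin(ang)])
                pts = path_inside(start, direction)
                if pts is not None:
                    break
            if pts is None:
                raise RuntimeError("no placement area: could not fit comet track")
            jitter = rng.normal(0.0, jitter_sigma_um / pixel_size_um, pts.shape)
            pts = pts + jitter
            tracks.append(
                (
                    Track(
                        track_id=tid,
                        frames=np.arange(n_frames),
                        x_px=pts[:, 0],
                        y_px=pts[:, 1],
                        frame_interval_s=frame_interval_s,
                        pixel_size_um=pixel_size_um,
                    ),
                    label,
                )
            )
            tid += 1
    return tracks


# ---------------------------------------------------------------------------
# Immuno-EM filaments
# ---------------------------------------------------------------------------


def make_em_filaments(
    n: int,
    length_dist=("uniform", 0.5, 8.0),
    density_fn=lambda length_um: 2.0,
    capture_distance_um: float = 0.025,
    seed: int = 0,
) -> list[EMFilament]:
    """Straight filaments with gold particles placed by a Poisson process.

    ``length_dist`` is either a callable ``f(rng) -> length`` or a tuple
    ("uniform", lo, hi) / ("exponential", mean).  ``density_fn`` maps
    filament length (µm) to the expected particle count per µm.  Particles
    sit within ``capture_distance_um`` laterally of the polyline (gold
    radius plus antibody reach).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)

    def draw_length() -> float:
        if callable(length_dist):
            return float(length_dist(rng))
        kind = length_dist[0]
        if kind == "uniform":
            return float(rng.uniform(length_dist[1], length_dist[2]))
        if kind == "exponential":
            return float(rng.exponential(length_dist[1]))
        raise ValueError(f"unknown length distribution {kind!r}")

    filaments: list[EMFilament] = []
    for i in range(n):
        length = max(draw_length(), 1e-3)
        theta = rng.uniform(0, 2 * math.pi)
        origin = rng.uniform(0.0, 50.0, size=2)
        d = np.array([math.cos(theta), math.sin(theta)])
        normal = np.array([-d[1], d[0]])
        polyline = np.vstack([origin, origin + length * d])
        lam = max(density_fn(length), 0.0) * length
        n_particles = rng.poisson(lam)
        arc = rng.uniform(0.0, length, size=n_particles)
        lateral = rng.uniform(-capture_distance_um, capture_distance_um, size=n_particles)
        particles = origin + arc[:, None] * d[None, :] + lateral[:, None] * normal[None, :]
        filaments.append(EMFilament(filament_id=i, polyline_um=polyline, particles_um=particles))
    return filaments


# ---------------------------------------------------------------------------
# Nucleation-assay spot fields
# ---------------------------------------------------------------------------


def make_particle_field(
    spec: ImageSpec,
    n_particles: int,
    radius_px_range: tuple[float, float] = (2.0, 4.0),
    amplitude_range: tuple[float, float] = (50.0, 100.0),
    min_separation_px: float = 3.0,
) -> tuple[CellImage, list[dict]]:
    """Render a field of disjoint disc-shaped spots with known centers."""
    from skimage.draw import disk as draw_disk

    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros((spec.height_px, spec.width_px), dtype=float)
    truth: list[dict] = []
    for _ in range(n_particles):
        ok = False
        for _ in range(_PLACEMENT_CAP):
            r = rng.uniform(*radius_px_range)
            cx = rng.uniform(r + 2, spec.width_px - 3 - r)
            cy = rng.uniform(r + 2, spec.height_px - 3 - r)
            if any(
                math.hypot(cx - t["x_px"], cy - t["y_px"]) < r + t["radius_px"] + min_separation_px
                for t in truth
            ):
                continue
            amp = rng.uniform(*amplitude_range)
            rr, cc = draw_disk((cy, cx), r, shape=canvas.shape)
            canvas[rr, cc] = np.maximum(canvas[rr, cc], amp)
            truth.append({"x_px": cx, "y_px": cy, "radius_px": r, "amplitude": amp})
            ok = True
            break
        if not ok:
            raise RuntimeError("no placement area: field too crowded")
    if spec.psf_sigma_px > 0:
        canvas = gaussian_filter(canvas, spec.psf_sigma_px)
    canvas = canvas + spec.background_level
    if spec.noise_model == "gaussian" and spec.noise_param > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_param, canvas.shape)
    elif spec.noise_model == "poisson" and spec.noise_param > 0:
        canvas = rng.poisson(np.clip(canvas, 0, None) * spec.noise_param) / spec.noise_param
    return CellImage(canvas, spec.pixel_size_um), truth


# ---------------------------------------------------------------------------
# Washout fluorescence trace
# ---------------------------------------------------------------------------


def simulate_washout_trace(
    n_frames: int = 60,
    onset_frame: int = 20,
    baseline: float = 100.0,
    burst_height: float = 50.0,
    growth_per_frame: float = 10.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Summed-fluorescence trace with a nucleation burst at a known frame."""
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    values = np.full(n_frames, baseline, dtype=float)
    after = frames >= onset_frame
    values[after] += burst_height + growth_per_frame * (frames[after] - onset_frame)
    if noise_sigma > 0:
        values += rng.normal(0.0, noise_sigma, n_frames)
    return list(zip(frames.tolist(), values.tolist()))
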