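"""Readers and writers shared by all pipeline stages.

Images are grayscale TIFF (1-2 channels) with the pixel size taken from
the resolution tags (ImageJ-style, unit µm) or a config override.
Tracks, ROIs and EM annotations travel as plain CSV with the column
conventions documented in each function.  Every CSV written by the CLI
carries a commented metadata header (version, config hash, seed, and the
verbatim parameters of the run).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CellGeometry, CellImage, EMFilament, Track

_MICRON_UNITS = {"um", "micron", "microns", "micrometer", "µm"}


def write_image(path, image: CellImage) -> None:
    """Write a CellImage as an ImageJ-style TIFF with µm pixel size."""
    res = (1.0 / image.pixel_size_um, 1.0 / image.pixel_size_um)
    if image.channel2 is not None:
        arr = np.stack([image.data, image.channel2]).astype(np.float32)
        tifffile.imwrite(
            path, arr, imagej=True, resolution=res, metadata={"unit": "um", "axes": "CYX"}
        )
    else:
        tifffile.imwrite(
            path,
            image.data.astype(np.float32),
            imagej=True,
            resolution=res,
            metadata={"unit": "um"},
        )


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    meta = tif.imagej_metadata or {}
    unit = str(meta.get("unit", "")).lower()
    if unit not in _MICRON_UNITS:
        return None
    return den / num


def read_image(path, pixel_size_um: float | None = None, max_project: bool = False) -> CellImage:
    """Read a grayscale TIFF (1-2 channels, optional z-stack) as CellImage.

    The pixel size comes from the TIFF resolution tags (ImageJ unit µm)
    unless overridden.  A multi-plane stack is reduced by per-pixel
    maximum projection when ``max_project`` is set; a 3D array with a
    leading axis of 2 is otherwise interpreted as two channels.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tags(tif)
    if pixel_size_um is None:
        raise ValueError(f"pixel size unknown for {path}: no µm resolution tags and no override")

    if arr.ndim == 2:
        return CellImage(arr, pixel_size_um)
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[0]:
            raise ValueError(f"RGB(A) image of shape {arr.shape} is not supported")
        if max_project:
            return CellImage(arr.max(axis=0), pixel_size_um)
        if arr.shape[0] == 2:
            return CellImage(arr[0], pixel_size_um, channel2=arr[1])
        raise ValueError(
            f"image of shape {arr.shape} has more than 2 channels/planes; "
            "use max_project for z-stacks"
        )
    raise ValueError(f"unsupported image dimensionality: shape {arr.shape}")


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------


def read_tracks(path, frame_interval_s: float, pixel_size_um: float) -> list[Track]:
    """Read tracks from CSV with columns track_id, frame, x_px, y_px.

    Rows are grouped by track id and sorted by frame; a duplicate
    (track_id, frame) pair raises an error naming the offending row.
    Single-sample groups are dropped (a track needs >= 2 samples).
    """
    df = pd.read_csv(path, comment="#")
    required = {"track_id", "frame", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["track_id", "frame"], keep="first")
    if dup.any():
        row = int(np.where(dup)[0][0]) + 2  # 1-based, after the header line
        raise ValueError(f"{path}: duplicate (track_id, frame) at row {row}")
    tracks = []
    for tid, group in df.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        if len(group) < 2:
            continue
        tracks.append(
            Track(
                track_id=tid,
                frames=group["frame"].to_numpy(),
                x_px=group["x_px"].to_numpy(),
                y_px=group["y_px"].to_numpy(),
                frame_interval_s=frame_interval_s,
                pixel_size_um=pixel_size_um,
            )
        )
    return tracks


def write_tracks(path, tracks: list[Track], labels: dict | None = None) -> None:
    """Write tracks as CSV (track_id, frame, x_px, y_px [, label])."""
    rows = []
    for t in tracks:
        for f, x, y in zip(t.frames, t.x_px, t.y_px):
            row = {"track_id": t.track_id, "frame": int(f), "x_px": x, "y_px": y}
            if labels is not None:
                row["label"] = labels.get(t.track_id, "")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------


def read_roi_csv(path) -> CellGeometry:
    """Read a cell geometry CSV with columns kind, x_px, y_px.

    Exactly one row with kind="center" and >= 3 rows with kind="vertex"
    (in boundary order) are required.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("kind", "x_px", "y_px"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    centers = df[df["kind"] == "center"]
    verts = df[df["kind"] == "vertex"]
    if len(centers) != 1:
        raise ValueError(f"{path}: expected exactly one center row, found {len(centers)}")
    return CellGeometry(
        center_px=(float(centers["x_px"].iloc[0]), float(centers["y_px"].iloc[0])),
        boundary_px=verts[["x_px", "y_px"]].to_numpy(),
    )


def write_roi_csv(path, geometry: CellGeometry) -> None:
    rows = [{"kind": "center", "x_px": geometry.center_px[0], "y_px": geometry.center_px[1]}]
    rows += [{"kind": "vertex", "x_px": x, "y_px": y} for x, y in geometry.boundary_px]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EM annotations
# ---------------------------------------------------------------------------


def write_em_annotations(polyline_path, particle_path, filaments: list[EMFilament]) -> None:
    """Write EM filaments as a polyline CSV plus a particle CSV."""
    poly_rows = []
    part_rows = []
    for f in filaments:
        for i, (x, y) in enumerate(f.polyline_um):
            poly_rows.append(
                {"filament_id": f.filament_id, "vertex_index": i, "x_um": x, "y_um": y}
            )
        for x, y in f.particles_um:
            part_rows.append({"filament_id": f.filament_id, "x_um": x, "y_um": y})
    pd.DataFrame(poly_rows).to_csv(polyline_path, index=False)
    pd.DataFrame(part_rows, columns=["filament_id", "x_um", "y_um"]).to_csv(
        particle_path, index=False
    )


def read_em_annotations(polyline_path, particle_path) -> list[EMFilament]:
    """Read EM filaments from a polyline CSV plus a particle CSV."""
    poly = pd.read_csv(polyline_path, comment="#")
    parts = pd.read_csv(particle_path, comment="#")
    filaments = []
    for fid, group in poly.groupby("filament_id", sort=True):
        group = group.sort_values("vertex_index")
        p = parts[parts["filament_id"] == fid][["x_um", "y_um"]].to_numpy()
        filaments.append(
            EMFilament(
                filament_id=fid,
                polyline_um=group[["x_um", "y_um"]].to_numpy(),
                particles_um=p.reshape(-1, 2),
            )
        )
    return filaments


# ---------------------------------------------------------------------------
# Run metadata
# ---------------------------------------------------------------------------


def metadata_header(params: dict) -> list[str]:
    """Commented metadata lines: version, config hash, verbatim parameters."""
    from . import __version__

    blob = json.dumps(params, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
    lines = [f"# mtquant_version: {__version__}", f"# config_hash: {digest}"]
    lines += [f"# {key}: {params[key]}" for key in sorted(params)]
    return lines


def write_csv_with_metadata(path, df: pd.DataFrame, params: dict) -> None:
    """Write a DataFrame as CSV preceded by a commented metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in metadata_header(params):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
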