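"""Filament counting and measurement in fluorescence images.

Pipeline: a Hessian-based tubularity filter sharpens curvilinear
structures (and suppresses blob-like regions such as the centrosome
core), the response is binarized and thinned to 1-pixel skeletons,
8-connected skeleton components are counted and measured, and an
optional per-image size threshold removes overlapping microtubules that
would otherwise be counted as single objects.  A second (acetylated
tubulin) channel is used to call de novo formed microtubules: only
objects without any sign of acetylation along their skeleton are counted
as truly de novo.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, skeletonize

from .datatypes import CellImage


@dataclass
class FilamentObject:
    """One skeletonized filament: pixel set, path length and intensity."""

    id: int
    pixels: np.ndarray  # (n, 2) row, col skeleton coordinates
    path_length_um: float
    mean_intensity: float
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col


@dataclass
class FilamentSet:
    """Skeletonized filament objects of one image."""

    objects: list[FilamentObject]
    pixel_size_um: float
    image_shape: tuple[int, int]
    size_threshold_um: float | None = None

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def total_length_um(self) -> float:
        return float(sum(o.path_length_um for o in self.objects))


@dataclass
class DeNovoCallConfig:
    """Rule for calling de novo (non-acetylated) microtubules.

    An object is de novo iff no skeleton pixel, dilated by
    ``overlap_dilation_px`` to tolerate channel-registration jitter, has
    acetyl-channel intensity above ``acetyl_threshold``.
    """

    acetyl_threshold: float = 0.0
    overlap_dilation_px: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.acetyl_threshold):
            raise ValueError("acetyl_threshold must be finite")
        if self.overlap_dilation_px < 0:
            raise ValueError("overlap_dilation_px must be >= 0")


def enhance_tubular(image: CellImage, scale_px: float) -> CellImage:
    """Hessian ridge (tubularity) response for bright curvilinear structures.

    Returns the gamma-normalized magnitude of the most negative Hessian
    eigenvalue at the given scale, clipped at zero.  Line-like structures
    produce strong responses; flat or blob-interior regions (such as the
    centrosome core) are comparatively suppressed.
    """
    if scale_px < 0.5:
        raise ValueError("scale_px must be >= 0.5")
    h = hessian_matrix(
        image.data, sigma=scale_px, mode="nearest", order="rc",
        use_gaussian_derivatives=True,
    )
    eigvals = hessian_matrix_eigvals(h)  # sorted descending; [-1] most negative
    response = np.clip(-eigvals[-1], 0.0, None) * scale_px**2
    return CellImage(response, image.pixel_size_um, channel2=image.channel2)


def _component_length_px(coords: np.ndarray) -> float:
    """Skeleton path length of one component in pixel units.

    Sum of the edge lengths (1 for axial, sqrt(2) for diagonal steps) of
    the minimum spanning tree of the 8-neighbor pixel graph; single-pixel
    components count one pixel of footprint.
    """
    n = len(coords)
    if n == 1:
        return 1.0
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(1.5)))
    if len(pairs) == 0:
        return 1.0
    d = np.hypot(*(coords[pairs[:, 0]] - coords[pairs[:, 1]]).T)
    graph = coo_matrix((d, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    return float(minimum_spanning_tree(graph).sum())


def skeletonize_and_count(
    enhanced: CellImage,
    binarize_threshold: float | None = None,
    size_threshold_um: float | None = None,
    min_size_um: float = 0.0,
) -> FilamentSet:
    """Binarize, thin to 1-pixel skeletons, label and measure components.

    ``binarize_threshold`` defaults to Otsu's threshold on the enhanced
    image.  ``size_threshold_um`` is an upper bound that removes objects
    longer than the threshold (overlapping microtubules erroneously merged
    into one object); ``min_size_um`` is a lower bound that discards
    specks.  An empty binary mask yields an empty FilamentSet.
    """
    img = enhanced.data
    if binarize_threshold is None:
        binarize_threshold = float(threshold_otsu(img)) if img.max() > img.min() else np.inf
    mask = img > binarize_threshold
    objects: list[FilamentObject] = []
    if mask.any():
        skel = skeletonize(mask)
        labels = label_components(skel, connectivity=2)
        next_id = 1
        for region in regionprops(labels, intensity_image=img):
            coords = region.coords
            length_um = _component_length_px(coords) * enhanced.pixel_size_um
            if size_threshold_um is not None and length_um > size_threshold_um:
                continue
            if length_um < min_size_um:
                continue
            objects.append(
                FilamentObject(
                    id=next_id,
                    pixels=coords,
                    path_length_um=length_um,
                    mean_intensity=float(region.intensity_mean),
                    bbox=tuple(region.bbox),
                )
            )
            next_id += 1
    return FilamentSet(
        objects=objects,
        pixel_size_um=enhanced.pixel_size_um,
        image_shape=img.shape,
        size_threshold_um=size_threshold_um,
    )


def call_de_novo(
    filaments: FilamentSet,
    acetyl_channel: CellImage | np.ndarray,
    config: DeNovoCallConfig | None = None,
) -> tuple[int, list[bool]]:
    """Count de novo microtubules: objects without any acetylation signal.

    Returns ``(n_de_novo, per-object de novo flags)``; flags align with
    ``filaments.objects``.
    """
    config = config or DeNovoCallConfig()
    acetyl = acetyl_channel.data if isinstance(acetyl_channel, CellImage) else np.asarray(acetyl_channel)
    if acetyl.shape != tuple(filaments.image_shape):
        raise ValueError(
            f"acetyl channel shape {acetyl.shape} does not match image shape "
            f"{tuple(filaments.image_shape)}"
        )
    selem = disk(config.overlap_dilation_px) if config.overlap_dilation_px > 0 else None
    flags: list[bool] = []
    for obj in filaments.objects:
        mask = np.zeros(acetyl.shape, dtype=bool)
        mask[obj.pixels[:, 0], obj.pixels[:, 1]] = True
        if selem is not None:
            mask = dilation(mask, selem)
        flags.append(not bool(np.any(acetyl[mask] > config.acetyl_threshold)))
    return int(sum(flags)), flags


def aster_area(
    image: CellImage,
    roi,
    mode: str = "roi",
    window_px: int = 64,
) -> float:
    """Area of a microtubule aster in µm².

    mode="roi": ``roi`` is an (N, 2) polygon of (x, y) vertices outlining
    the manually selected aster; returns the polygon area times the pixel
    area.  mode="seeded": ``roi`` is an (x, y) seed point; the threshold is
    Otsu computed on a local window of half-width ``window_px`` around the
    seed and the area of the connected above-threshold region containing
    the seed is returned (an automation convenience beyond manual
    selection).
    """
    px2 = image.pixel_size_um**2
    if mode == "roi":
        verts = np.asarray(roi, dtype=float)
        if verts.ndim != 2 or len(verts) < 3:
            raise ValueError("roi polygon needs at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("degenerate roi polygon")
        return float(poly.area) * px2
    if mode == "seeded":
        x, y = int(round(roi[0])), int(round(roi[1]))
        h, w = image.shape
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError("seed point outside image")
        window = image.data[
            max(0, y - window_px) : y + window_px + 1,
            max(0, x - window_px) : x + window_px + 1,
        ]
        if window.max() == window.min():
            return 0.0
        thr = threshold_otsu(window)
        mask = image.data > thr
        labels = label_components(mask, connectivity=2)
        lab = labels[y, x]
        if lab == 0:
            return 0.0
        return float(np.sum(labels == lab)) * px2
    raise ValueError("mode must be 'roi' or 'seeded'")
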