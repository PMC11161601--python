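"""Organoid, nucleus, and cell segmentation for mid z-section confocal planes.

Pipeline: organoid masks by Otsu thresholding of the combined keratin
(K8 + K14) signal; nuclei from the DAPI channel by a two-class intensity
model (k-means, k=2) with seeded splitting of touching nuclei; cells by a
watershed seeded on the nuclei over a multi-scale Hessian ridge-enhancement
elevation of the keratin signal. Outer/inner layer classification is purely
geometric: a cell is *outer* iff it touches the 1-px boundary band of its
organoid mask (i.e. is in contact with the surrounding matrix).

Thresholds are always computed from the image, so segmentation is invariant
to a positive global intensity gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation as skseg
from skimage.feature import peak_local_max
from sklearn.cluster import KMeans

from .image import MultichannelImage

logger = logging.getLogger(__name__)

__all__ = [
    "OrganoidMask",
    "CellLabelMap",
    "segment_organoid",
    "detect_nuclei",
    "segment_cells",
    "classify_layers",
]

STRUCT_8 = np.ones((3, 3), dtype=bool)  # 8-connectivity everywhere


def _drop_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndi.label(mask, structure=STRUCT_8)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


@dataclass
class OrganoidMask:
    """One connected organoid: binary mask plus boundary geometry."""

    mask: np.ndarray
    contour: np.ndarray  # ordered subpixel (row, col) boundary points, closed
    centroid: tuple[float, float]
    equivalent_radius_um: float
    pixel_size_um: float

    @property
    def boundary_band(self) -> np.ndarray:
        """1-px-wide inner boundary band (pixels in contact with the matrix)."""
        return self.mask & ~ndi.binary_erosion(self.mask, structure=STRUCT_8)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class CellLabelMap:
    """Cell and nucleus label grids with a one-to-one correspondence.

    Label 0 is background; cell label ``i`` contains exactly nucleus label
    ``i``. Cell regions partition the organoid mask.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    pixel_size_um: float
    dropped_nuclei: list[int] = field(default_factory=list)

    @property
    def labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.cell_labels) if v != 0]


def segment_organoid(
    img: MultichannelImage,
    smooth_sigma_px: float = 2.0,
    min_area_px: int = 500,
) -> list[OrganoidMask]:
    """Segment organoids by Otsu thresholding the combined K8+K14 signal.

    Returns one :class:`OrganoidMask` per 8-connected foreground component
    of at least ``min_area_px`` pixels, holes filled. A blank image yields
    an empty list.
    """
    img.require("K8", "K14")
    combined = img["K8"] + img["K14"]
    smoothed = ndi.gaussian_filter(combined, smooth_sigma_px)
    if np.ptp(smoothed) == 0:
        return []
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    fg = ndi.binary_fill_holes(fg)
    fg = _drop_small_components(fg, min_area_px)
    if not fg.any():
        return []
    labels, n = ndi.label(fg, structure=STRUCT_8)
    masks = []
    for lab in range(1, n + 1):
        mask = labels == lab
        contours = measure.find_contours(mask.astype(float), 0.5)
        contour = max(contours, key=len)
        cy, cx = ndi.center_of_mass(mask)
        r_eq = np.sqrt(mask.sum() / np.pi) * img.pixel_size_um
        masks.append(
            OrganoidMask(
                mask=mask,
                contour=contour,
                centroid=(float(cy), float(cx)),
                equivalent_radius_um=float(r_eq),
                pixel_size_um=img.pixel_size_um,
            )
        )
    return masks


def detect_nuclei(
    dapi: np.ndarray,
    organoid: OrganoidMask,
    smooth_sigma_px: float = 1.5,
    min_area_px: int = 20,
    min_seed_distance_px: int = 4,
) -> np.ndarray:
    """Label nuclei inside one organoid from the DAPI channel.

    Pixels within the organoid mask are split into nucleus vs non-nucleus
    intensity classes by k-means (k=2) on the smoothed DAPI signal; touching
    nuclei are separated by a watershed seeded on smoothed-intensity maxima.
    """
    dapi = np.asarray(dapi, dtype=float)
    smoothed = ndi.gaussian_filter(dapi, smooth_sigma_px)
    inside = smoothed[organoid.mask]
    if inside.size == 0 or np.ptp(inside) == 0:
        return np.zeros(dapi.shape, dtype=int)
    km = KMeans(n_clusters=2, n_init=3, random_state=0).fit(inside.reshape(-1, 1))
    hi_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    nuc_mask = np.zeros(dapi.shape, dtype=bool)
    nuc_mask[organoid.mask] = km.labels_ == hi_cluster
    nuc_mask = _drop_small_components(nuc_mask, min_area_px)
    if not nuc_mask.any():
        return np.zeros(dapi.shape, dtype=int)
    # seeded split of touching nuclei on smoothed-intensity maxima
    peaks = peak_local_max(
        smoothed,
        labels=nuc_mask,
        min_distance=min_seed_distance_px,
        exclude_border=False,
    )
    if len(peaks) == 0:
        labels, _ = ndi.label(nuc_mask, structure=STRUCT_8)
        return labels
    markers = np.zeros(dapi.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = skseg.watershed(-smoothed, markers=markers, mask=nuc_mask)
    # merge any watershed fragments below the area floor into neighbors
    labels = _absorb_small_labels(labels, min_area_px)
    return labels


def _absorb_small_labels(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Merge labels smaller than min_area into their largest touching neighbor."""
    out = labels.copy()
    for lab, count in zip(*np.unique(out, return_counts=True)):
        if lab == 0 or count >= min_area:
            continue
        region = out == lab
        ring = ndi.binary_dilation(region, structure=STRUCT_8) & ~region
        neighbors = out[ring]
        neighbors = neighbors[neighbors > 0]
        out[region] = np.bincount(neighbors).argmax() if neighbors.size else 0
    return _relabel_sequential(out)


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals != 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out


def segment_cells(
    nuclei: np.ndarray,
    img: MultichannelImage,
    organoid: OrganoidMask,
    hessian_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0),
    compactness: float = 0.05,
) -> CellLabelMap:
    """Watershed cell segmentation seeded on nuclei.

    The elevation surface is a multi-scale Hessian ridge enhancement (Sato
    tubeness, maximum over ``hessian_sigmas``) of the combined K8+K14 signal,
    so cell–cell membranes act as watershed ridges. Cell regions partition
    the organoid mask; nuclei falling outside the mask are dropped with a
    warning.
    """
    img.require("K8", "K14")
    nuclei = np.asarray(nuclei)
    if nuclei.max() == 0:
        raise ValueError("segment_cells requires at least one nucleus")
    markers = nuclei.copy()
    dropped = []
    for lab in np.unique(nuclei):
        if lab == 0:
            continue
        region = nuclei == lab
        if not (region & organoid.mask).any():
            markers[region] = 0
            dropped.append(int(lab))
    if dropped:
        logger.warning("dropped %d nuclei outside the organoid mask: %s", len(dropped), dropped)
    if markers.max() == 0:
        raise ValueError("all nuclei fall outside the organoid mask")
    markers[~organoid.mask] = 0

    membrane = img["K8"] + img["K14"]
    scale = membrane.max()
    elevation = filters.sato(
        membrane / scale if scale > 0 else membrane,
        sigmas=hessian_sigmas,
        black_ridges=False,
    )
    # small compactness resolves flat elevation plateaus (e.g. just inside
    # the mask boundary) by geodesic proximity to the seeding nucleus
    cells = skseg.watershed(
        elevation, markers=markers, mask=organoid.mask, compactness=compactness
    )
    # one-nucleus-per-cell bijection: restrict nuclei to their cell regions
    nuc_out = np.where((markers > 0) & (cells == markers), markers, 0)
    return CellLabelMap(
        cell_labels=cells,
        nucleus_labels=nuc_out,
        pixel_size_um=img.pixel_size_um,
        dropped_nuclei=dropped,
    )


def classify_layers(cells: CellLabelMap, organoid: OrganoidMask) -> dict[int, str]:
    """Outer/inner classification: outer iff the cell touches the organoid
    boundary band (is in contact with the surrounding collagen)."""
    band = organoid.boundary_band
    out: dict[int, str] = {}
    for lab in cells.labels:
        touches = bool((band & (cells.cell_labels == lab)).any())
        out[lab] = "outer" if touches else "inner"
    return out
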