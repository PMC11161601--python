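"""Per-cell Yap nuclear/cytoplasmic ratio and cell classifications.

The ratio is (nuclear mean - background) / (cytoplasmic mean - background)
on the Yap channel, with the background estimated as the median intensity
outside a dilated organoid mask. Cells whose cytoplasmic mean does not
exceed the background have an undefined ratio: they are flagged invalid and
excluded from group summaries, never silently given a number.

Classifications:

* K14 Hi/Lo — a cell is Hi iff its mean K14 intensity over the cell region
  strictly exceeds the mean of those means over the outer-layer cells of the
  same image (ties -> Lo).
* role — inner cells are ``none``; outer cells are ``rim`` unless both
  elongated (major/minor axis ratio >= ``e_min``) and protrusive (farthest
  point >= ``p_min_um`` beyond the organoid's convex body outline), in which
  case they are ``leader``. These thresholds are a reproducible surrogate
  for the field's manual leader selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import MultiPoint, Point
from skimage import measure, morphology

from .image import MultichannelImage
from .segmentation import STRUCT_8, CellLabelMap, OrganoidMask

logger = logging.getLogger(__name__)

__all__ = [
    "CellRecord",
    "estimate_background",
    "nuc_cyto_ratio",
    "build_cell_records",
    "classify_k14",
    "classify_role",
    "measure_cell_length",
    "quantify_cells",
]


@dataclass
class CellRecord:
    """One segmented cell and its intensity/geometry summaries."""

    cell_id: int
    layer: str  # outer | inner
    nuc_mean: float
    cyto_mean: float
    background: float
    nuc_cyto_ratio: float  # NaN when undefined
    valid: bool  # cyto_mean > background
    k14_mean: float
    k14_class: str = ""  # Hi | Lo | "" before classification
    role: str = "none"  # rim | leader | none
    elongation: float = 1.0
    protrusion_um: float = 0.0
    length_um: float = float("nan")

    def __post_init__(self) -> None:
        if self.role == "leader" and self.layer != "outer":
            raise ValueError("a leader cell must lie in the outer layer")


def estimate_background(
    channel: np.ndarray,
    organoids: OrganoidMask | list[OrganoidMask],
    dilate_px: int = 10,
) -> float:
    """Median intensity outside all (dilated) organoid masks."""
    if isinstance(organoids, OrganoidMask):
        organoids = [organoids]
    channel = np.asarray(channel, dtype=float)
    excluded = np.zeros(channel.shape, dtype=bool)
    for org in organoids:
        excluded |= ndi.binary_dilation(org.mask, structure=STRUCT_8, iterations=dilate_px)
    outside = channel[~excluded]
    if outside.size == 0:
        raise ValueError(
            "organoid fills the frame: no background pixels; pass an explicit background value"
        )
    return float(np.median(outside))


def nuc_cyto_ratio(nuc_mean: float, cyto_mean: float, background: float) -> float:
    """Background-subtracted nuclear over cytoplasmic mean; NaN if undefined."""
    if cyto_mean <= background:
        return float("nan")
    return (nuc_mean - background) / (cyto_mean - background)


def build_cell_records(
    img: MultichannelImage,
    cells: CellLabelMap,
    layers: dict[int, str],
    background: float,
    yap_channel: str = "Yap",
    k14_channel: str = "K14",
) -> list[CellRecord]:
    """Assemble per-cell intensity summaries from the label maps."""
    img.require(yap_channel, k14_channel)
    yap = img[yap_channel]
    k14 = img[k14_channel]
    records = []
    for lab in cells.labels:
        cell = cells.cell_labels == lab
        nuc = cells.nucleus_labels == lab
        cyto = cell & ~nuc
        if not nuc.any() or not cyto.any():
            logger.warning("cell %d lacks a nucleus or cytoplasm region; skipped", lab)
            continue
        nuc_mean = float(yap[nuc].mean())
        cyto_mean = float(yap[cyto].mean())
        ratio = nuc_cyto_ratio(nuc_mean, cyto_mean, background)
        records.append(
            CellRecord(
                cell_id=lab,
                layer=layers[lab],
                nuc_mean=nuc_mean,
                cyto_mean=cyto_mean,
                background=background,
                nuc_cyto_ratio=ratio,
                valid=bool(cyto_mean > background),
                k14_mean=float(k14[cell].mean()),
            )
        )
    return records


def classify_k14(records: list[CellRecord]) -> None:
    """Assign Hi/Lo in place: Hi iff k14_mean strictly exceeds the mean
    k14_mean of the outer-layer cells of this image."""
    outer = [r.k14_mean for r in records if r.layer == "outer"]
    if len(outer) < 2:
        warnings.warn("fewer than 2 outer cells; K14 classification skipped", stacklevel=2)
        return
    threshold = float(np.mean(outer))
    for r in records:
        r.k14_class = "Hi" if r.k14_mean > threshold else "Lo"


def _body_hull(organoid: OrganoidMask, opening_um: float):
    """Convex outline of the organoid body, protrusions stripped by a
    morphological opening of radius ``opening_um``."""
    radius_px = max(1, int(round(opening_um / organoid.pixel_size_um)))
    body = morphology.opening(organoid.mask, morphology.disk(radius_px))
    if not body.any():
        body = organoid.mask
    pts = np.argwhere(body)
    return MultiPoint([tuple(p) for p in pts[:, ::-1]]).convex_hull  # (x=col, y=row)


def classify_role(
    records: list[CellRecord],
    cells: CellLabelMap,
    organoid: OrganoidMask,
    e_min: float = 2.0,
    p_min_um: float = 5.0,
    body_opening_um: float = 5.0,
) -> None:
    """Assign rim/leader/none in place (see module docstring for criteria)."""
    hull = _body_hull(organoid, body_opening_um)
    px = organoid.pixel_size_um
    for r in records:
        if r.layer != "outer":
            r.role = "none"
            continue
        region = cells.cell_labels == r.cell_id
        props = measure.regionprops(region.astype(int))[0]
        minor = props.axis_minor_length
        r.elongation = float(props.axis_major_length / minor) if minor > 0 else float("inf")
        boundary = region & ~ndi.binary_erosion(region, structure=STRUCT_8)
        pts = np.argwhere(boundary)
        dists = [Point(c, rr).distance(hull) for rr, c in pts]  # 0 inside hull
        r.protrusion_um = float(max(dists, default=0.0)) * px
        r.role = (
            "leader" if (r.elongation >= e_min and r.protrusion_um >= p_min_um) else "rim"
        )


def _skeleton_path_length_px(region: np.ndarray) -> float:
    """Geodesic length (px) of the longest path on the region's skeleton,
    approximated by a double-sweep shortest-path search."""
    skel = morphology.skeletonize(region)
    pts = np.argwhere(skel)
    if len(pts) <= 1:
        return 1.0
    index = {tuple(p): i for i, p in enumerate(pts)}
    rows_i, cols_i, w = [], [], []
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    rows_i.append(i)
                    cols_i.append(j)
                    w.append(np.hypot(dr, dc))
    n = len(pts)
    graph = coo_matrix((w, (rows_i, cols_i)), shape=(n, n))
    d0 = dijkstra(graph, directed=False, indices=0)
    far = int(np.argmax(np.where(np.isfinite(d0), d0, -1)))
    d1 = dijkstra(graph, directed=False, indices=far)
    d1 = np.where(np.isfinite(d1), d1, -1)
    return float(d1.max()) + 1.0  # + 1 px: half a pixel at each end


def measure_cell_length(region: np.ndarray, pixel_size_um: float) -> float:
    """Length of a cell in µm: longest geodesic path of the region skeleton."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty cell region")
    if region.sum() == 1:
        return pixel_size_um
    return _skeleton_path_length_px(region) * pixel_size_um


def quantify_cells(
    img: MultichannelImage,
    cells: CellLabelMap,
    organoid: OrganoidMask,
    background: float | None = None,
    yap_channel: str = "Yap",
    k14_channel: str = "K14",
    e_min: float = 2.0,
    p_min_um: float = 5.0,
    measure_lengths: bool = False,
) -> list[CellRecord]:
    """Full per-cell quantification: layers, background, ratios, K14, roles."""
    from .segmentation import classify_layers

    layers = classify_layers(cells, organoid)
    if background is None:
        background = estimate_background(img[yap_channel], organoid)
    records = build_cell_records(
        img, cells, layers, background, yap_channel=yap_channel, k14_channel=k14_channel
    )
    classify_k14(records)
    classify_role(records, cells, organoid, e_min=e_min, p_min_um=p_min_um)
    if measure_lengths:
        for r in records:
            r.length_um = measure_cell_length(
                cells.cell_labels == r.cell_id, cells.pixel_size_um
            )
    return records
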