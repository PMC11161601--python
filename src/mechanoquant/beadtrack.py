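"""Drift-corrected bead displacement toward an organoid.

Stage drift is estimated by subpixel phase correlation of consecutive
frames and accumulated against frame 0. Beads are detected per frame as
smoothed local maxima with center-of-mass subpixel refinement, then linked
frame-to-frame by a mutual-nearest-neighbor rule with a maximum step, all in
drift-corrected coordinates. A track missing any frame is incomplete.

Selection follows the geometric inclusion rules used for organoid pulling
assays: a bead is included iff its track is complete, its initial distance
to the organoid border is at most one organoid diameter (mixed organoids)
or radius (luminal organoids), and it is not within that selection distance
of two organoids at once. Displacement toward the organoid is the initial
minus the final distance to the border (positive = net motion toward the
organoid body), reported in µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .image import ImageStack
from .segmentation import OrganoidMask

logger = logging.getLogger(__name__)

__all__ = [
    "DriftModel",
    "BeadTrack",
    "estimate_drift",
    "apply_drift_correction",
    "detect_and_link",
    "select_beads",
    "displacement_toward_organoid",
]


@dataclass
class DriftModel:
    """Cumulative xy translation per frame, zero at the reference frame."""

    offsets_px: np.ndarray  # (n_frames, 2) cumulative (row, col)
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.offsets_px = np.asarray(self.offsets_px, dtype=float)
        if not np.allclose(self.offsets_px[self.reference_frame], 0):
            raise ValueError("offset at the reference frame must be (0, 0)")


@dataclass
class BeadTrack:
    bead_id: int
    positions_px: np.ndarray  # (n_frames, 2) raw (row, col); NaN if missing
    corrected_px: np.ndarray  # drift-corrected positions
    complete: bool
    included: bool = False
    ambiguous_frames: list[int] = field(default_factory=list)
    initial_distance_um: float = float("nan")
    final_distance_um: float = float("nan")
    displacement_um: float = float("nan")


def estimate_drift(
    stack: ImageStack, upsample_factor: int = 20, mode: str = "reference"
) -> DriftModel:
    """Per-frame cumulative translation by subpixel phase correlation.

    ``mode='reference'`` (default) registers every frame directly against
    frame 0, avoiding the random-walk error accumulation of chaining
    consecutive pairs; ``mode='consecutive'`` estimates frame-to-frame steps
    and accumulates them (robust when the scene decorrelates from frame 0
    over long movies). Featureless frames give zero offsets with a warning.
    """
    if mode not in ("reference", "consecutive"):
        raise ValueError("mode must be 'reference' or 'consecutive'")
    frames = stack.frames
    offsets = np.zeros((stack.n_frames, 2))
    for t in range(1, stack.n_frames):
        a = frames[0] if mode == "reference" else frames[t - 1]
        b = frames[t]
        if a.std() == 0 or b.std() == 0:
            logger.warning("featureless frame at t=%d; assuming zero drift step", t)
            delta = np.zeros(2)
        else:
            shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample_factor)
            delta = -np.asarray(shift)  # shift maps b onto a; drift moved content by -shift
        offsets[t] = delta if mode == "reference" else offsets[t - 1] + delta
    return DriftModel(offsets_px=offsets, reference_frame=0)


def apply_drift_correction(stack: ImageStack, drift: DriftModel) -> ImageStack:
    """Translate every frame back by its cumulative offset (spline shift)."""
    corrected = np.stack(
        [
            ndi.shift(stack.frames[t], -drift.offsets_px[t], order=3, mode="nearest")
            for t in range(stack.n_frames)
        ]
    )
    return ImageStack(
        frames=corrected,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_min=stack.frame_interval_min,
    )


def _detect_spots(
    frame: np.ndarray, sigma_px: float, threshold_rel: float, refine_radius: int = 2
) -> np.ndarray:
    """Bandpass (difference-of-Gaussians) local maxima with center-of-mass
    subpixel refinement. The bandpass suppresses background structure that
    is broader than the bead point-spread function."""
    smoothed = ndi.gaussian_filter(frame, sigma_px) - ndi.gaussian_filter(frame, 4 * sigma_px)
    # robust scale: a percentile instead of the max, so one bright spot
    # (e.g. two overlapping beads) cannot mask the rest
    scale = np.percentile(smoothed, 99.9)
    if scale <= 0:
        return np.empty((0, 2))
    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(2 * sigma_px)),
        threshold_abs=threshold_rel * scale,
        exclude_border=False,
    )
    refined = []
    bg = 0.0
    for r, c in peaks:
        r0, r1 = max(0, r - refine_radius), min(frame.shape[0], r + refine_radius + 1)
        c0, c1 = max(0, c - refine_radius), min(frame.shape[1], c + refine_radius + 1)
        win = np.clip(smoothed[r0:r1, c0:c1] - bg, 0, None)
        total = win.sum()
        if total == 0:
            refined.append((float(r), float(c)))
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        refined.append((float((win * yy).sum() / total), float((win * xx).sum() / total)))
    return np.asarray(refined).reshape(-1, 2)


def detect_and_link(
    stack: ImageStack,
    drift: DriftModel,
    max_step_px: float | None = None,
    spot_sigma_px: float = 1.5,
    threshold_rel: float = 0.5,
) -> list[BeadTrack]:
    """Detect beads per frame and link them across frames.

    Linking is mutual-nearest-neighbor in drift-corrected coordinates with a
    maximum step of ``max_step_px`` (default: 10 px). Ambiguous links —
    detections with a competing candidate closer than the accepted partner —
    are flagged on the track. Tracks missing any frame have
    ``complete=False``.
    """
    if max_step_px is None:
        max_step_px = 10.0
    n_frames = stack.n_frames
    # work on drift-corrected frames and remove the static scene (temporal
    # low percentile): beads move between frames, gel texture does not
    corrected = apply_drift_correction(stack, drift).frames
    static = np.percentile(corrected, 10, axis=0)
    detections = []
    for t in range(n_frames):
        spots = _detect_spots(corrected[t] - static, spot_sigma_px, threshold_rel)
        detections.append(spots)  # already in corrected coordinates
    if len(detections[0]) == 0:
        return []

    n0 = len(detections[0])
    positions = np.full((n0, n_frames, 2), np.nan)
    positions[:, 0, :] = detections[0]
    active = {i: i for i in range(n0)}  # detection index in previous frame -> bead id
    ambiguous: dict[int, list[int]] = {i: [] for i in range(n0)}
    for t in range(1, n_frames):
        prev_pts = np.array(
            [positions[bid, t - 1] for bid in active.values()]
        ).reshape(-1, 2)
        cur = detections[t]
        new_active: dict[int, int] = {}
        if len(cur) and len(prev_pts):
            tree_prev = cKDTree(prev_pts)
            tree_cur = cKDTree(cur)
            d_pc, nn_pc = tree_cur.query(prev_pts, distance_upper_bound=max_step_px)
            d_cp, nn_cp = tree_prev.query(cur, distance_upper_bound=max_step_px)
            bead_ids = list(active.values())
            for i, bid in enumerate(bead_ids):
                j = nn_pc[i]
                if j < len(cur) and nn_cp[j] == i:  # mutual nearest
                    positions[bid, t] = cur[j]
                    new_active[j] = bid
                    # a competing previous point nearly as close => ambiguous
                    near = tree_prev.query_ball_point(cur[j], max_step_px)
                    if len(near) > 1:
                        ambiguous[bid].append(t)
        active = new_active
        if not active:
            break

    tracks = []
    for bid in range(n0):
        pos = positions[bid]
        complete = bool(np.all(np.isfinite(pos)))
        tracks.append(
            BeadTrack(
                bead_id=bid,
                positions_px=pos + drift.offsets_px,  # raw = corrected + drift
                corrected_px=pos,
                complete=complete,
                ambiguous_frames=ambiguous.get(bid, []),
            )
        )
    return tracks


def _border_polygon(organoid: OrganoidMask) -> Polygon:
    contour = np.asarray(organoid.contour)
    return Polygon(contour[:, ::-1])  # (x=col, y=row)


def _distance_to_border_um(pos_rc, poly: Polygon, pixel_size_um: float) -> float:
    p = Point(pos_rc[1], pos_rc[0])
    return float(p.distance(poly.exterior)) * pixel_size_um


def select_beads(
    tracks: list[BeadTrack],
    organoids: OrganoidMask | list[OrganoidMask],
    mode: str = "diameter",
    pixel_size_um: float | None = None,
) -> list[BeadTrack]:
    """Apply the inclusion rules in place and return the tracks.

    ``mode='diameter'`` (mixed organoids) includes beads starting within one
    organoid diameter of the border; ``mode='radius'`` (luminal organoids)
    within one radius. Beads within the selection distance of two organoids
    at once, or with incomplete tracks, are excluded.
    """
    if mode not in ("diameter", "radius"):
        raise ValueError("mode must be 'diameter' or 'radius'")
    if isinstance(organoids, OrganoidMask):
        organoids = [organoids]
    if not organoids:
        raise ValueError("at least one organoid is required")
    px = pixel_size_um or organoids[0].pixel_size_um
    polys = [_border_polygon(o) for o in organoids]
    limits = [
        (2 if mode == "diameter" else 1) * o.equivalent_radius_um for o in organoids
    ]
    for tr in tracks:
        if not tr.complete:
            tr.included = False
            continue
        d0 = [_distance_to_border_um(tr.corrected_px[0], p, px) for p in polys]
        within = [d <= lim for d, lim in zip(d0, limits)]
        tr.included = sum(within) == 1
        nearest = int(np.argmin(d0))
        tr.initial_distance_um = d0[nearest]
    return tracks


def displacement_toward_organoid(
    track: BeadTrack,
    organoid: OrganoidMask,
    pixel_size_um: float | None = None,
    path_integrated: bool = False,
) -> float:
    """Signed displacement toward the organoid border in µm.

    Default: initial minus final drift-corrected distance to the border.
    ``path_integrated=True`` instead accumulates only the inward per-frame
    steps (decreases in border distance), ignoring outward excursions.
    """
    px = pixel_size_um or organoid.pixel_size_um
    poly = _border_polygon(organoid)
    d = np.array(
        [_distance_to_border_um(p, poly, px) for p in track.corrected_px if np.all(np.isfinite(p))]
    )
    if len(d) < 2:
        raise ValueError("track needs at least two finite positions")
    steps = -np.diff(d)
    disp = float(steps[steps > 0].sum()) if path_integrated else float(d[0] - d[-1])
    track.initial_distance_um = float(d[0])
    track.final_distance_um = float(d[-1])
    track.displacement_um = disp
    return disp
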