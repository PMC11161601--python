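"""Synthetic organoid/fiber/bead/border generators with exact ground truth.

Every generator draws from ``numpy.random.default_rng(seed)`` and is
bit-deterministic for a fixed spec. The images emulate only the statistics
the analysis modules consume (intensity ratios, axial angle distributions,
radial kinematics, polygon geometry), not confocal appearance: nuclei are
filled discs, cytoplasm Voronoi-like annuli, fibers stamped rectangles.

Angle convention: degrees, counterclockwise from the image x-axis (columns),
with the mathematical y-axis pointing up (i.e. against the row index),
wrapped to [-90, 90) — axial data. Coordinates are 0-based (row, col);
subpixel positions are real-valued (row, col). Lengths in ground truth are
always in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from .image import ImageStack, MultichannelImage

__all__ = [
    "SyntheticOrganoidSpec",
    "SyntheticFiberSpec",
    "SyntheticBeadSpec",
    "GroundTruth",
    "gen_organoid_image",
    "gen_fiber_field",
    "gen_bead_timelapse",
    "gen_border_mask",
    "gen_strand_polylines",
    "merge_organoid_images",
    "wrap_axial_deg",
]


def wrap_axial_deg(theta_deg):
    """Wrap axial angles (period 180°) into [-90, 90)."""
    return (np.asarray(theta_deg, dtype=float) + 90.0) % 180.0 - 90.0


@dataclass
class GroundTruth:
    """Ground truth sidecar for one generated object.

    Only the fields relevant to the generator that produced it are set.
    """

    cells: dict[int, dict[str, Any]] = field(default_factory=dict)
    organoid: dict[str, Any] = field(default_factory=dict)
    fiber_angles_deg: np.ndarray | None = None
    fiber_angle_map: np.ndarray | None = None  # NaN off-fiber
    beads: dict[int, dict[str, Any]] = field(default_factory=dict)
    drift_px: np.ndarray | None = None  # cumulative (n_frames, 2) (row, col)
    border: dict[str, Any] = field(default_factory=dict)
    strands: dict[int, dict[str, Any]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# organoid
# ---------------------------------------------------------------------------

DEFAULT_YAP_RATIOS = {"rim": 2.0, "inner": 1.0, "leader": 3.0}


@dataclass
class SyntheticOrganoidSpec:
    organoid_radius_um: float = 50.0
    cell_radius_um: float = 7.0
    n_rim_cells: int = 16
    yap_ratio_by_role: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_YAP_RATIOS)
    )
    k14_hi_fraction: float = 0.5
    background_level: float = 10.0
    noise_sd: float = 0.0
    pixel_size_um: float = 1.0
    seed: int = 0
    # rendering extras (not part of the biological parameterization)
    n_leader_cells: int = 0
    leader_protrusion_um: float = 15.0
    image_shape_px: tuple[int, int] | None = None
    center_px: tuple[float, float] | None = None
    margin_um: float = 20.0
    yap_cyto_signal: float = 60.0
    k14_hi_signal: float = 170.0
    k14_lo_signal: float = 40.0
    k8_signal: float = 120.0
    dapi_signal: float = 200.0

    def __post_init__(self) -> None:
        if not (self.organoid_radius_um > self.cell_radius_um > 0):
            raise ValueError("require organoid_radius_um > cell_radius_um > 0")
        if not 0.0 <= self.k14_hi_fraction <= 1.0:
            raise ValueError("k14_hi_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_rim_cells < 3:
            raise ValueError("need at least 3 rim cells to close the ring")
        if self.n_leader_cells > self.n_rim_cells:
            raise ValueError("n_leader_cells cannot exceed n_rim_cells")
        for role, ratio in self.yap_ratio_by_role.items():
            if ratio <= 0:
                raise ValueError(f"yap ratio for role {role!r} must be positive")


def _hex_pack_points(max_radius: float, spacing: float) -> np.ndarray:
    """Hexagonally packed (row, col) offsets within a disk of max_radius."""
    pts = []
    dy = spacing * np.sqrt(3) / 2
    n_rows = int(np.ceil(max_radius / dy)) + 1
    for i in range(-n_rows, n_rows + 1):
        y = i * dy
        x0 = (spacing / 2) if (i % 2) else 0.0
        n_cols = int(np.ceil(max_radius / spacing)) + 1
        for j in range(-n_cols, n_cols + 1):
            x = x0 + j * spacing
            if np.hypot(x, y) <= max_radius:
                pts.append((y, x))
    if not pts:
        pts = [(0.0, 0.0)]
    return np.asarray(pts, dtype=float)


def gen_organoid_image(
    spec: SyntheticOrganoidSpec,
) -> tuple[MultichannelImage, GroundTruth]:
    """Render a packed-cell organoid disk with a single-cell outer rim.

    Channels: DAPI (nuclei), K8 (all cells), K14 (bimodal per cell),
    Yap (per-cell nuclear/cytoplasmic contrast set by the role's true ratio).
    Before noise, each cell's background-subtracted nuclear mean over
    cytoplasmic mean equals its ground-truth ratio exactly.
    """
    px = spec.pixel_size_um
    R = spec.organoid_radius_um / px
    rc = spec.cell_radius_um / px
    extent = spec.organoid_radius_um + (
        spec.leader_protrusion_um if spec.n_leader_cells else 0.0
    )
    if spec.image_shape_px is None:
        half = int(np.ceil((extent + spec.margin_um) / px))
        shape = (2 * half + 1, 2 * half + 1)
    else:
        shape = tuple(spec.image_shape_px)
    center = (
        np.array(spec.center_px, dtype=float)
        if spec.center_px is not None
        else np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    )
    max_extent_px = extent / px
    if (
        center[0] - max_extent_px < 0
        or center[1] - max_extent_px < 0
        or center[0] + max_extent_px > shape[0] - 1
        or center[1] + max_extent_px > shape[1] - 1
    ):
        raise ValueError(
            f"organoid (extent {extent:.1f} µm) does not fit in frame "
            f"{shape} at {px} µm/px; enlarge image_shape_px"
        )

    rng = np.random.default_rng(spec.seed)

    # --- cell seed points: one rim ring + hex-packed interior
    phase = rng.uniform(0, 2 * np.pi)
    ring_angles = phase + 2 * np.pi * np.arange(spec.n_rim_cells) / spec.n_rim_cells
    ring_r = R - rc
    rim_seeds = np.stack(
        [center[0] - ring_r * np.sin(ring_angles), center[1] + ring_r * np.cos(ring_angles)],
        axis=1,
    )
    inner_max = R - 2.2 * rc
    if inner_max > 0.5 * rc:
        inner = _hex_pack_points(inner_max, 2.0 * rc) + center
        jitter = rng.uniform(-0.15 * rc, 0.15 * rc, size=inner.shape)
        inner = inner + jitter
    else:
        inner = np.empty((0, 2))
    seeds = np.vstack([rim_seeds, inner])
    n_cells = len(seeds)
    layers = ["outer"] * spec.n_rim_cells + ["inner"] * len(inner)

    # leaders: evenly spaced subset of the rim ring, pushed outward
    leader_ids = set(
        np.linspace(0, spec.n_rim_cells, spec.n_leader_cells, endpoint=False).astype(int)
    ) if spec.n_leader_cells else set()
    roles = []
    for i in range(n_cells):
        if layers[i] == "inner":
            roles.append("none")
        elif i in leader_ids:
            roles.append("leader")
        else:
            roles.append("rim")

    # --- Voronoi-like cell regions within the organoid disk; leader seeds
    # are excluded from the tessellation and rendered as radial bars below,
    # so a leader's whole region is genuinely elongated
    rows, cols = np.indices(shape)
    rr = rows - center[0]
    cc = cols - center[1]
    in_disk = rr**2 + cc**2 <= R**2
    from scipy.spatial import cKDTree

    non_leader = [i for i in range(n_cells) if i not in leader_ids]
    _, nearest = cKDTree(seeds[non_leader]).query(
        np.stack([rows[in_disk], cols[in_disk]], axis=1)
    )
    cell_labels = np.zeros(shape, dtype=int)
    cell_labels[in_disk] = np.asarray(non_leader)[nearest] + 1

    # leader cells: radial bar from inside the rim to beyond the disk edge
    prot_len = spec.leader_protrusion_um / px
    for i in sorted(leader_ids):
        ang = ring_angles[i]
        u = np.array([-np.sin(ang), np.cos(ang)])  # outward radial (row, col)
        v = np.array([np.cos(ang), np.sin(ang)])  # tangential
        base = center + (R - 2.0 * rc) * u
        tip = center + (R + prot_len) * u
        hw = 0.45 * rc
        corners = np.array(
            [base + hw * v, base - hw * v, tip - hw * v, tip + hw * v]
        )
        pr, pc = draw_polygon(corners[:, 0], corners[:, 1], shape=shape)
        cell_labels[pr, pc] = i + 1

    # --- nuclei: filled discs at the seed points
    nucleus_labels = np.zeros(shape, dtype=int)
    nuc_r = 0.45 * rc
    for i, (sr, sc) in enumerate(seeds):
        disc = (rows - sr) ** 2 + (cols - sc) ** 2 <= nuc_r**2
        nucleus_labels[disc & (cell_labels == i + 1)] = i + 1

    # --- per-cell K14 class: exact Hi count among outer cells
    n_outer = spec.n_rim_cells
    n_hi = int(round(spec.k14_hi_fraction * n_outer))
    hi_ids = set(rng.choice(n_outer, size=n_hi, replace=False).tolist())
    k14_class = [
        ("Hi" if i in hi_ids else "Lo") if layers[i] == "outer" else "Lo"
        for i in range(n_cells)
    ]

    # --- channels
    bg = spec.background_level
    dapi = np.full(shape, bg, dtype=float)
    dapi[nucleus_labels > 0] = bg + spec.dapi_signal
    k8 = np.full(shape, bg, dtype=float)
    k8[cell_labels > 0] = bg + spec.k8_signal
    k14 = np.full(shape, bg, dtype=float)
    yap = np.full(shape, bg, dtype=float)
    truth = GroundTruth()
    for i in range(n_cells):
        cell = cell_labels == i + 1
        nuc = nucleus_labels == i + 1
        cyto = cell & ~nuc
        k14_sig = spec.k14_hi_signal if k14_class[i] == "Hi" else spec.k14_lo_signal
        k14[cell] = bg + k14_sig
        # inner cells have role "none"; their ratio is keyed as "inner"
        role_key = roles[i] if roles[i] != "none" else "inner"
        ratio = spec.yap_ratio_by_role.get(role_key, DEFAULT_YAP_RATIOS.get(role_key, 1.0))
        yap[cyto] = bg + spec.yap_cyto_signal
        yap[nuc] = bg + ratio * spec.yap_cyto_signal
        truth.cells[i + 1] = {
            "center": tuple(seeds[i]),
            "layer": layers[i],
            "role": roles[i],
            "true_ratio": ratio,
            "k14_class": k14_class[i],
            "k14_signal": k14_sig,
        }

    channels = {"DAPI": dapi, "K8": k8, "K14": k14, "Yap": yap}
    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0, spec.noise_sd, size=shape), 0, None
            )

    truth.organoid = {
        "center": tuple(center),
        "radius_um": spec.organoid_radius_um,
        "mask": cell_labels > 0,
        "cell_labels": cell_labels,
        "nucleus_labels": nucleus_labels,
        "n_rim_cells": spec.n_rim_cells,
        "n_cells": n_cells,
    }
    return MultichannelImage(channels=channels, pixel_size_um=px), truth


def merge_organoid_images(
    a: tuple[MultichannelImage, GroundTruth], b: tuple[MultichannelImage, GroundTruth]
) -> tuple[MultichannelImage, GroundTruth]:
    """Composite two organoid renderings into one frame (pixelwise maximum).

    Both must share shape, channels, and pixel size. Ground-truth cell ids of
    the second organoid are offset past those of the first.
    """
    (img_a, gt_a), (img_b, gt_b) = a, b
    if img_a.shape != img_b.shape or img_a.pixel_size_um != img_b.pixel_size_um:
        raise ValueError("images must share shape and pixel size")
    channels = {
        name: np.maximum(img_a[name], img_b[name]) for name in img_a.channels
    }
    merged = GroundTruth()
    merged.cells.update(gt_a.cells)
    offset = max(gt_a.cells, default=0)
    for cid, rec in gt_b.cells.items():
        merged.cells[cid + offset] = rec
    merged.organoid = {"organoids": [gt_a.organoid, gt_b.organoid]}
    return MultichannelImage(channels=channels, pixel_size_um=img_a.pixel_size_um), merged


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------


@dataclass
class SyntheticFiberSpec:
    mu_deg: float = 0.0
    kappa: float = 2.0
    n_fibers: int = 5000
    fiber_length_um: float = 15.0
    fiber_width_px: float = 2.0
    pixel_size_um: float = 0.5
    seed: int = 0
    image_shape_px: tuple[int, int] = (512, 512)
    fiber_intensity: float = 150.0
    background_level: float = 5.0
    noise_sd: float = 0.0
    # optional organoid exclusion zone / radial mode
    organoid_center_px: tuple[float, float] | None = None
    organoid_radius_um: float | None = None
    orientation_mode: str = "vonmises"  # or "radial"

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not -90.0 <= self.mu_deg < 90.0:
            raise ValueError("mu_deg must lie in [-90, 90)")
        if self.orientation_mode not in ("vonmises", "radial"):
            raise ValueError("orientation_mode must be 'vonmises' or 'radial'")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")


def gen_fiber_field(spec: SyntheticFiberSpec) -> tuple[MultichannelImage, GroundTruth]:
    """Stamp straight fibers whose axial angles follow a von Mises law.

    Angles are drawn on the doubled angle 2θ ~ vonMises(2µ, κ) and wrapped to
    [-90, 90), so the expected nematic order parameter of the stamped sample
    is the Bessel ratio I1(κ)/I0(κ). In ``radial`` mode each fiber instead
    points along the radius from ``organoid_center_px``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape_px)
    px = spec.pixel_size_um
    half_len = 0.5 * spec.fiber_length_um / px
    hw = 0.5 * spec.fiber_width_px

    centers = np.empty((spec.n_fibers, 2))
    n_placed = 0
    excl_r = (
        spec.organoid_radius_um / px if spec.organoid_radius_um is not None else None
    )
    oc = (
        np.array(spec.organoid_center_px, dtype=float)
        if spec.organoid_center_px is not None
        else np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    )
    while n_placed < spec.n_fibers:
        cand = rng.uniform([0, 0], [shape[0] - 1, shape[1] - 1], size=(spec.n_fibers, 2))
        if excl_r is not None:
            keep = np.hypot(cand[:, 0] - oc[0], cand[:, 1] - oc[1]) > excl_r + half_len
            cand = cand[keep]
        take = min(len(cand), spec.n_fibers - n_placed)
        centers[n_placed : n_placed + take] = cand[:take]
        n_placed += take

    if spec.orientation_mode == "radial":
        theta = wrap_axial_deg(
            np.degrees(np.arctan2(-(centers[:, 0] - oc[0]), centers[:, 1] - oc[1]))
        )
    else:
        theta = wrap_axial_deg(
            np.degrees(rng.vonmises(np.radians(2 * spec.mu_deg), spec.kappa, spec.n_fibers) / 2.0)
        )

    img = np.full(shape, spec.background_level, dtype=float)
    angle_map = np.full(shape, np.nan)
    th = np.radians(theta)
    # axis direction in (row, col): row decreases as mathematical y increases
    u = np.stack([-np.sin(th), np.cos(th)], axis=1)
    v = np.stack([np.cos(th), np.sin(th)], axis=1)
    for i in range(spec.n_fibers):
        c = centers[i]
        p0 = c - half_len * u[i]
        p1 = c + half_len * u[i]
        corners = np.array(
            [p0 + hw * v[i], p0 - hw * v[i], p1 - hw * v[i], p1 + hw * v[i]]
        )
        pr, pc = draw_polygon(corners[:, 0], corners[:, 1], shape=shape)
        img[pr, pc] = spec.background_level + spec.fiber_intensity
        angle_map[pr, pc] = theta[i]
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0, spec.noise_sd, size=shape), 0, None)

    truth = GroundTruth(fiber_angles_deg=theta, fiber_angle_map=angle_map)
    truth.organoid = {"center": tuple(oc), "radius_um": spec.organoid_radius_um}
    return MultichannelImage(channels={"collagen": img}, pixel_size_um=px), truth


# ---------------------------------------------------------------------------
# beads
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBeadSpec:
    n_beads: int = 20
    radial_speed_um_per_frame: float = 2.0
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (row, col) px / frame
    n_frames: int = 10
    organoid_center_px: tuple[float, float] | None = None
    organoid_radius_um: float = 40.0
    seed: int = 0
    pixel_size_um: float = 1.0
    image_shape_px: tuple[int, int] = (256, 256)
    bead_sigma_px: float = 1.3
    bead_intensity: float = 200.0
    background_level: float = 10.0
    noise_sd: float = 0.0
    texture_amplitude: float = 25.0
    start_margin_px: float = 12.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")


def _render_spots(shape, positions, sigma, amplitude):
    img = np.zeros(shape)
    half = int(np.ceil(4 * sigma))
    for r, c in positions:
        if not (-half <= r < shape[0] + half and -half <= c < shape[1] + half):
            continue
        r0, r1 = max(0, int(r) - half), min(shape[0], int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(shape[1], int(c) + half + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2)
        )
    return img


def gen_bead_timelapse(spec: SyntheticBeadSpec) -> tuple[ImageStack, GroundTruth]:
    """Time-lapse of beads advected radially toward an organoid, plus drift.

    The whole field of view (beads and a static speckle texture standing in
    for the gel) is translated by the cumulative stage drift, so the drift
    is recoverable by image registration. Ground truth stores drifted and
    drift-free positions per bead and the cumulative drift per frame; beads
    that leave the frame in any frame are flagged, never dropped.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape_px)
    px = spec.pixel_size_um
    R = spec.organoid_radius_um / px
    oc = (
        np.array(spec.organoid_center_px, dtype=float)
        if spec.organoid_center_px is not None
        else np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    )
    r_max = min(shape) / 2.0 - spec.start_margin_px
    if r_max <= R + 2:
        raise ValueError("no room outside the organoid for beads; enlarge frame")
    # start positions uniform-in-area in the annulus outside the organoid
    rad = np.sqrt(rng.uniform((R + 3) ** 2, r_max**2, spec.n_beads))
    ang = rng.uniform(0, 2 * np.pi, spec.n_beads)
    starts = oc + np.stack([-rad * np.sin(ang), rad * np.cos(ang)], axis=1)

    speed_px = spec.radial_speed_um_per_frame / px
    t = np.arange(spec.n_frames)
    cum_drift = np.outer(t, np.asarray(spec.drift_per_frame, dtype=float))

    # drift-free radial advection; beads stop at the organoid border
    vec = starts - oc
    dist0 = np.hypot(vec[:, 0], vec[:, 1])
    unit = vec / dist0[:, None]
    dist_t = np.maximum(dist0[:, None] - speed_px * t[None, :], R)  # (n_beads, T)
    pos_free = oc + dist_t[..., None] * unit[:, None, :]
    pos_drifted = pos_free + cum_drift[None, :, :]

    # static speckle texture (gel background, broad so it cannot be confused
    # with bead point sources), translated with the drift; generated on a
    # padded canvas so drifting never wraps content across the frame edge
    pad = int(np.ceil(np.abs(cum_drift).max())) + 4
    big = ndi.gaussian_filter(rng.normal(0, 1, (shape[0] + 2 * pad, shape[1] + 2 * pad)), 5.0)
    big = spec.texture_amplitude * big / max(big.std(), 1e-12)

    frames = np.empty((spec.n_frames,) + shape)
    for k in range(spec.n_frames):
        tex = ndi.shift(big, cum_drift[k], order=3, mode="nearest")[
            pad : pad + shape[0], pad : pad + shape[1]
        ]
        beads = _render_spots(shape, pos_drifted[:, k, :], spec.bead_sigma_px, spec.bead_intensity)
        frame = spec.background_level + tex + beads
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0, spec.noise_sd, shape)
        frames[k] = np.clip(frame, 0, None)

    truth = GroundTruth(drift_px=cum_drift)
    in_frame = (
        (pos_drifted[..., 0] >= 0)
        & (pos_drifted[..., 0] <= shape[0] - 1)
        & (pos_drifted[..., 1] >= 0)
        & (pos_drifted[..., 1] <= shape[1] - 1)
    )
    for i in range(spec.n_beads):
        truth.beads[i] = {
            "positions_drifted": pos_drifted[i],
            "positions_driftfree": pos_free[i],
            "left_frame": bool(~in_frame[i].all()),
            "true_displacement_um": float((dist0[i] - dist_t[i, -1]) * px),
        }
    truth.organoid = {"center": tuple(oc), "radius_um": spec.organoid_radius_um}
    return ImageStack(frames=frames, pixel_size_um=px), truth


# ---------------------------------------------------------------------------
# border masks and strands
# ---------------------------------------------------------------------------


def gen_border_mask(
    n_protrusions: int,
    depth_um: float,
    base_radius_um: float,
    pixel_size_um: float = 0.5,
    n_vertices: int = 720,
    margin_px: int = 10,
) -> tuple[np.ndarray, GroundTruth]:
    """Star-like polygonal tumor-border mask with exact perimeter truth.

    The boundary radius is ``base + depth*(1+cos(n·φ))/2``: valleys sit at the
    base radius and each of the ``n_protrusions`` lobes reaches ``depth_um``
    beyond it. Truth stores the exact polygon perimeter and the perimeter of
    its convex hull (both µm) from the continuous vertex polygon.
    """
    if depth_um < 0:
        raise ValueError("depth_um must be >= 0")
    if depth_um >= base_radius_um:
        raise ValueError("degenerate shape: depth_um must be < base_radius_um")
    phi = 2 * np.pi * np.arange(n_vertices) / n_vertices
    if n_protrusions == 0:
        r_um = np.full(n_vertices, base_radius_um)
    else:
        r_um = base_radius_um + depth_um * 0.5 * (1 + np.cos(n_protrusions * phi))
    x = r_um * np.cos(phi)
    y = r_um * np.sin(phi)

    seg = np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0]))
    perimeter_um = float(seg.sum())
    from scipy.spatial import ConvexHull

    hull = ConvexHull(np.stack([x, y], axis=1))
    hv = hull.points[hull.vertices]
    hull_perimeter_um = float(
        np.hypot(np.diff(hv[:, 0], append=hv[0, 0]), np.diff(hv[:, 1], append=hv[0, 1])).sum()
    )

    half = int(np.ceil((base_radius_um + depth_um) / pixel_size_um)) + margin_px
    shape = (2 * half + 1, 2 * half + 1)
    rows = half - y / pixel_size_um
    cols = half + x / pixel_size_um
    mask = np.zeros(shape, dtype=bool)
    pr, pc = draw_polygon(rows, cols, shape=shape)
    mask[pr, pc] = True

    truth = GroundTruth()
    truth.border = {
        "perimeter_um": perimeter_um,
        "hull_perimeter_um": hull_perimeter_um,
        "index": perimeter_um / hull_perimeter_um,
        "vertices_um": np.stack([x, y], axis=1),
        "center_px": (float(half), float(half)),
    }
    return mask, truth


def gen_strand_polylines(
    lengths_um, pixel_size_um: float = 0.5, seed: int = 0, n_segments: int = 6
) -> tuple[dict[int, np.ndarray], GroundTruth]:
    """Random gently-bending polylines with exact arc lengths.

    Returns (row, col) vertex arrays in pixel units, one per strand, and a
    truth entry per strand id with its exact length in µm.
    """
    rng = np.random.default_rng(seed)
    strands: dict[int, np.ndarray] = {}
    truth = GroundTruth()
    for sid, L in enumerate(np.atleast_1d(np.asarray(lengths_um, dtype=float)), start=1):
        seg = (L / pixel_size_um) / n_segments
        heading = rng.uniform(0, 2 * np.pi)
        pos = rng.uniform(50, 200, size=2)
        verts = [pos.copy()]
        for _ in range(n_segments):
            heading += rng.uniform(-0.25, 0.25)
            pos = pos + seg * np.array([-np.sin(heading), np.cos(heading)])
            verts.append(pos.copy())
        strands[sid] = np.asarray(verts)
        truth.strands[sid] = {"length_um": float(L)}
    return strands, truth
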