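"""Collagen fiber orientation and the 2D nematic scalar order parameter.

Local orientation and coherency come from the structure tensor (smoothed
outer product of Gaussian-derivative gradients), the standard reimplementation
of OrientationJ-style orientation analysis. Per-pixel orientation θ is the
fiber axis — the eigenvector of the *smaller* structure-tensor eigenvalue —
in degrees counterclockwise from the image x-axis, wrapped to [-90, 90);
coherency is (λmax − λmin)/(λmax + λmin) ∈ [0, 1].

The alignment statistic is the liquid-crystal scalar order parameter. From
an orientation sample {θi} the second-order tensor

    Q = [[<cos 2θ>,  <sin 2θ>],
         [<sin 2θ>, -<cos 2θ>]]

has eigenvalues λ1,2 = ±S with S = sqrt(<cos 2θ>² + <sin 2θ>²): S = 0 for a
uniform axial distribution, S = 1 for perfect alignment. ⟨·⟩ are (optionally
weighted) averages over all orientation measurements. Rim analysis measures
S in 30 × 50 µm rectangles anchored on the organoid boundary with the long
axis along the outward normal and distance zero at the cell–matrix interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .segmentation import OrganoidMask
from .synthgen import wrap_axial_deg

__all__ = [
    "OrientationField",
    "OrderParameterResult",
    "RimROI",
    "RimOrderProfile",
    "structure_tensor_orientation",
    "order_parameter",
    "order_tensor",
    "field_order_parameter",
    "extract_rim_rois",
    "rim_order_profile",
    "bessel_ratio",
    "invert_order_parameter",
]


@dataclass
class OrientationField:
    """Per-pixel fiber-axis angle and coherency; ``valid`` marks pixels whose
    gradient energy clears the floor (θ is meaningless elsewhere)."""

    theta_deg: np.ndarray
    coherency: np.ndarray
    valid: np.ndarray
    pixel_size_um: float


@dataclass
class OrderParameterResult:
    S: float
    n_angles: int
    lambda1: float  # +S
    lambda2: float  # -S
    mean_cos2: float
    mean_sin2: float

    @property
    def mean_axis_deg(self) -> float:
        """Mean fiber axis (axial mean of the sample), degrees in [-90, 90)."""
        return float(
            wrap_axial_deg(np.degrees(np.arctan2(self.mean_sin2, self.mean_cos2)) / 2.0)
        )


def structure_tensor_orientation(
    img: np.ndarray,
    sigma_grad: float = 1.0,
    sigma_window: float = 4.0,
    energy_floor_rel: float = 1e-6,
) -> OrientationField:
    """Per-pixel fiber orientation and coherency from the structure tensor.

    Gradients are Gaussian derivatives at scale ``sigma_grad``; the tensor
    products are smoothed with a Gaussian window ``sigma_window``. Pixels
    whose gradient energy (tensor trace) falls below ``energy_floor_rel``
    times the image maximum energy are marked invalid with coherency 0.
    """
    img = np.asarray(img, dtype=float)
    gr = ndi.gaussian_filter(img, sigma_grad, order=(1, 0))  # d/d(row)
    gc = ndi.gaussian_filter(img, sigma_grad, order=(0, 1))  # d/d(col)
    # mathematical frame: x = col, y = -row
    gx, gy = gc, -gr
    jxx = ndi.gaussian_filter(gx * gx, sigma_window)
    jxy = ndi.gaussian_filter(gx * gy, sigma_window)
    jyy = ndi.gaussian_filter(gy * gy, sigma_window)
    energy = jxx + jyy
    max_energy = energy.max()
    valid = energy > energy_floor_rel * max_energy if max_energy > 0 else np.zeros_like(energy, bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(
            energy > 0, np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2) / energy, 0.0
        )
    coherency = np.clip(coherency, 0.0, 1.0)
    # dominant gradient direction, then fiber axis = +90° rotation
    phi = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    theta = wrap_axial_deg(phi + 90.0)
    theta = np.where(valid, theta, np.nan)
    return OrientationField(theta_deg=theta, coherency=coherency, valid=valid, pixel_size_um=1.0)


def order_tensor(angles_deg, weights=None) -> np.ndarray:
    """The 2×2 second-order orientation tensor Q built from (weighted)
    averages of cos 2θ and sin 2θ."""
    c2, s2, _ = _mean_resultant(angles_deg, weights)
    return np.array([[c2, s2], [s2, -c2]])


def _mean_resultant(angles_deg, weights):
    angles = np.asarray(angles_deg, dtype=float).ravel()
    if angles.size == 0:
        raise ValueError("order parameter requires at least one angle")
    if np.any(~np.isfinite(angles)):
        raise ValueError("angles must be finite (no NaN/inf)")
    two_theta = np.radians(2.0 * angles)
    if weights is None:
        c2 = float(np.mean(np.cos(two_theta)))
        s2 = float(np.mean(np.sin(two_theta)))
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != angles.shape:
            raise ValueError("weights must match angles in length")
        if np.any(w < 0) or np.any(~np.isfinite(w)):
            raise ValueError("weights must be finite and nonnegative")
        total = w.sum()
        if total == 0:
            raise ValueError("weights must not all be zero")
        c2 = float(np.sum(w * np.cos(two_theta)) / total)
        s2 = float(np.sum(w * np.sin(two_theta)) / total)
    return c2, s2, angles.size


def order_parameter(angles_deg, weights=None) -> OrderParameterResult:
    """Scalar nematic order parameter S = sqrt(<cos 2θ>² + <sin 2θ>²).

    Equals the magnitude of either eigenvalue of the orientation tensor Q;
    both are reported as ±S. Rotation-invariant and 180°-periodic in θ.
    """
    c2, s2, n = _mean_resultant(angles_deg, weights)
    S = float(np.hypot(c2, s2))
    return OrderParameterResult(
        S=S, n_angles=n, lambda1=S, lambda2=-S, mean_cos2=c2, mean_sin2=s2
    )


def field_order_parameter(
    field: OrientationField,
    mask: np.ndarray | None = None,
    weight_by_coherency: bool = True,
    coherency_power: float = 2.0,
) -> OrderParameterResult:
    """Order parameter pooled over the valid pixels of an orientation field.

    Weights are coherency**``coherency_power`` (power 1 reproduces plain
    coherency weighting; higher powers suppress partially coherent pixels at
    fiber crossings and tips). ``mask`` optionally restricts the pixels.
    """
    sel = field.valid if mask is None else (field.valid & mask)
    if not sel.any():
        raise ValueError("no valid pixels selected")
    weights = field.coherency[sel] ** coherency_power if weight_by_coherency else None
    return order_parameter(field.theta_deg[sel], weights)


@dataclass
class RimROI:
    """A 30 × 50 µm rectangle anchored on the organoid boundary, long axis
    along the outward normal, distance zero at the cell–matrix interface."""

    anchor: tuple[float, float]  # (row, col) on the boundary contour
    normal: tuple[float, float]  # outward unit vector (row, col)
    width_um: float = 30.0  # tangential extent
    length_um: float = 50.0  # normal extent

    @property
    def normal_axis_deg(self) -> float:
        """Axial angle of the normal direction, degrees in [-90, 90)."""
        dr, dc = self.normal
        return float(wrap_axial_deg(np.degrees(np.arctan2(-dr, dc))))


def extract_rim_rois(
    organoid: OrganoidMask,
    spacing_um: float,
    width_um: float = 30.0,
    length_um: float = 50.0,
) -> list[RimROI]:
    """Anchor ROIs every ``spacing_um`` of arclength along the boundary.

    The outward normal at each anchor comes from the local contour tangent,
    oriented away from the organoid centroid. A contour shorter than the
    spacing yields a single ROI.
    """
    contour = np.asarray(organoid.contour, dtype=float)
    px = organoid.pixel_size_um
    seg = np.hypot(*np.diff(contour, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)]) * px
    total = arclen[-1]
    if total <= 0:
        raise ValueError("degenerate boundary contour")
    n_rois = max(1, int(total // spacing_um))
    targets = np.arange(n_rois) * spacing_um
    rois = []
    centroid = np.asarray(organoid.centroid)
    for s in targets:
        i = int(np.searchsorted(arclen, s, side="right") - 1)
        i = min(i, len(contour) - 2)
        frac = (s - arclen[i]) / max(arclen[i + 1] - arclen[i], 1e-12)
        anchor = contour[i] + frac * (contour[i + 1] - contour[i])
        # tangent from a centered window; wide enough to average out the
        # half-pixel jitter of marching-squares contours
        j0, j1 = max(0, i - 6), min(len(contour) - 1, i + 7)
        tangent = contour[j1] - contour[j0]
        norm = np.hypot(*tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        normal = np.array([-tangent[1], tangent[0]])
        if np.dot(normal, anchor - centroid) < 0:
            normal = -normal
        rois.append(
            RimROI(
                anchor=(float(anchor[0]), float(anchor[1])),
                normal=(float(normal[0]), float(normal[1])),
                width_um=width_um,
                length_um=length_um,
            )
        )
    return rois


@dataclass
class RimOrderProfile:
    per_roi: list[OrderParameterResult | None]
    pooled: OrderParameterResult | None
    mean_angle_vs_normal_deg: list[float]  # NaN where the ROI is empty


def rim_order_profile(
    field: OrientationField,
    rois: list[RimROI],
    pixel_size_um: float,
    max_distance_um: float = 50.0,
    weight_by_coherency: bool = True,
    coherency_power: float = 2.0,
) -> RimOrderProfile:
    """Order parameter per rim ROI and pooled across ROIs.

    Pixels enter a ROI when valid, within ``width_um/2`` of the anchor along
    the tangent, and at 0..``max_distance_um`` from the interface along the
    outward normal. Angles are weighted by coherency unless disabled. A ROI
    with no valid pixels reports ``None`` (missing), never S = 0.
    """
    shape = field.theta_deg.shape
    per_roi: list[OrderParameterResult | None] = []
    angle_vs_normal: list[float] = []
    pooled_angles: list[np.ndarray] = []
    pooled_weights: list[np.ndarray] = []
    for roi in rois:
        max_d_px = min(roi.length_um, max_distance_um) / pixel_size_um
        half_w_px = 0.5 * roi.width_um / pixel_size_um
        anchor = np.asarray(roi.anchor)
        n = np.asarray(roi.normal)
        tvec = np.array([-n[1], n[0]])
        reach = int(np.ceil(max_d_px + half_w_px)) + 1
        r0 = max(0, int(anchor[0]) - reach)
        r1 = min(shape[0], int(anchor[0]) + reach + 1)
        c0 = max(0, int(anchor[1]) - reach)
        c1 = min(shape[1], int(anchor[1]) + reach + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dr = rr - anchor[0]
        dc = cc - anchor[1]
        d = dr * n[0] + dc * n[1]
        t = dr * tvec[0] + dc * tvec[1]
        sel = (d >= 0) & (d <= max_d_px) & (np.abs(t) <= half_w_px)
        sel &= field.valid[r0:r1, c0:c1]
        if not sel.any():
            per_roi.append(None)
            angle_vs_normal.append(float("nan"))
            continue
        angles = field.theta_deg[r0:r1, c0:c1][sel]
        weights = (
            field.coherency[r0:r1, c0:c1][sel] ** coherency_power
            if weight_by_coherency
            else None
        )
        if weights is not None and weights.sum() == 0:
            per_roi.append(None)
            angle_vs_normal.append(float("nan"))
            continue
        res = order_parameter(angles, weights)
        per_roi.append(res)
        delta = wrap_axial_deg(res.mean_axis_deg - roi.normal_axis_deg)
        angle_vs_normal.append(float(abs(delta)))
        pooled_angles.append(np.asarray(angles))
        pooled_weights.append(
            np.asarray(weights) if weights is not None else np.ones(len(angles))
        )
    pooled = (
        order_parameter(np.concatenate(pooled_angles), np.concatenate(pooled_weights))
        if pooled_angles
        else None
    )
    return RimOrderProfile(
        per_roi=per_roi, pooled=pooled, mean_angle_vs_normal_deg=angle_vs_normal
    )


def bessel_ratio(kappa: float) -> float:
    """I1(κ)/I0(κ) — the expected order parameter of a von Mises axial
    sample with concentration κ (on the doubled angle)."""
    return float(i1e(kappa) / i0e(kappa))


def invert_order_parameter(S: float, kappa_max: float = 1e8) -> float:
    """Concentration κ̂ solving I1(κ)/I0(κ) = S (von Mises axial model)."""
    if not 0.0 <= S < 1.0:
        raise ValueError("S must lie in [0, 1) for a finite concentration")
    if S == 0.0:
        return 0.0
    return float(brentq(lambda k: bessel_ratio(k) - S, 0.0, kappa_max, xtol=1e-10))
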