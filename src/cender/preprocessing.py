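"""Automatic pre-processing: head extraction and the intrinsic worm frame.

From the maximum-intensity projection of a volume, the head is segmented as
the largest connected foreground region (median blur -> greyscale closing
with a dilation footprint slightly larger than the erosion footprint ->
global Otsu threshold -> connected components).  The intrinsic coordinate
system is then built from the head: bright points of interest define an
intensity-weighted center of mass O, the anterior-posterior axis is the
longest chord of the head region through O, the ventral-dorsal axis is the
perpendicular chord, and the anterior (resp. ventral) side is the half with
more points of interest.  The worm crawls on its side, so these two in-plane
axes capture its body plan; strongly self-occluding postures (head twisting,
omega-turn contact) surface as segmentation failures rather than guesses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)


@dataclass
class HeadContour:
    head_contour: np.ndarray  # (n, 2) ordered (x, y) contour points
    body_contours: list[np.ndarray]
    head_mask: np.ndarray  # binary (H, W)
    head_bbox: tuple[int, int, int, int]  # (x, y, w, h)


@dataclass
class WormFrame:
    """Intrinsic head coordinate system: origin O (center of mass of bright
    points), unit A-P and V-D axes (anterior and ventral positive), and the
    four contour endpoints."""

    origin: np.ndarray  # (2,)
    ap_axis: np.ndarray  # (2,) unit, anterior positive
    vd_axis: np.ndarray  # (2,) unit, ventral positive
    pa: np.ndarray = None
    pp: np.ndarray = None
    pv: np.ndarray = None
    pd: np.ndarray = None
    moments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.ap_axis = np.asarray(self.ap_axis, dtype=float)
        self.vd_axis = np.asarray(self.vd_axis, dtype=float)
        if not np.isclose(np.linalg.norm(self.ap_axis), 1.0, atol=1e-6):
            raise ValueError("ap_axis must be unit length")
        if not np.isclose(np.linalg.norm(self.vd_axis), 1.0, atol=1e-6):
            raise ValueError("vd_axis must be unit length")
        if abs(float(self.ap_axis @ self.vd_axis)) > 1e-6:
            raise ValueError("axes must be orthogonal")


def max_intensity_projection(volume) -> np.ndarray:
    """Per-pixel maximum across the Z axis of a (Z, H, W) stack."""
    stack = volume.red if hasattr(volume, "red") else np.asarray(volume)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (Z, H, W) stack")
    return stack.max(axis=0)


def segment_head(
    mip: np.ndarray,
    median_size: int = 5,
    dilation_radius: int = 5,
    erosion_radius: int = 4,
    threshold: str = "otsu",
) -> HeadContour:
    """Segment the head as the largest-area connected foreground component
    of the blurred, closed, thresholded projection image.  The dilation
    footprint is slightly larger than the erosion footprint so nearby nuclei
    connect into one head region."""
    img = np.asarray(mip, dtype=np.float64)
    if img.max() == img.min():
        raise ValueError("constant image: nothing to segment")
    smooth = ndimage.median_filter(img, size=median_size)
    closed = ndimage.grey_erosion(
        ndimage.grey_dilation(smooth, footprint=morphology.disk(dilation_radius)),
        footprint=morphology.disk(erosion_radius),
    )
    if threshold == "otsu":
        level = threshold_otsu(closed)
    elif threshold == "adaptive-mean":
        level = ndimage.uniform_filter(closed, size=51)
    else:
        raise ValueError(f"unknown threshold mode {threshold!r}")
    binary = closed > level
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no foreground component found")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(areas)[::-1] + 1
    head_mask = labels == order[0]

    def contour_of(mask):
        cs = measure.find_contours(mask.astype(float), 0.5)
        if not cs:
            return np.zeros((0, 2))
        c = max(cs, key=len)
        return c[:, ::-1]  # (row, col) -> (x, y)

    ys, xs = np.nonzero(head_mask)
    bbox = (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))
    body = [contour_of(labels == lab) for lab in order[1:]]
    return HeadContour(
        head_contour=contour_of(head_mask),
        body_contours=body,
        head_mask=head_mask,
        head_bbox=bbox,
    )


def _chord(mask: np.ndarray, origin: np.ndarray, direction: np.ndarray, step: float = 0.5):
    """March from ``origin`` along +-direction while inside the mask; returns
    (length, endpoint_plus, endpoint_minus)."""
    h, w = mask.shape

    def march(d):
        t = 0.0
        while True:
            nt = t + step
            p = origin + nt * d
            xi, yi = int(round(p[0])), int(round(p[1]))
            if not (0 <= xi < w and 0 <= yi < h) or not mask[yi, xi]:
                return t
            t = nt

    tp = march(direction)
    tm = march(-direction)
    return tp + tm, origin + tp * direction, origin - tm * direction


def build_worm_frame(head: HeadContour, i_head: np.ndarray) -> WormFrame:
    """Build the worm frame from the head mask and its projection image.

    Points of interest are head pixels with value >= mean + std (statistics
    over the head mask).  O is their intensity-weighted center of mass; the
    A-P axis is the longest chord through O (directions sampled at 1 degree,
    ties broken toward the smaller angle index); the V-D axis is the
    perpendicular chord; orientation signs come from point-of-interest count
    dominance.
    """
    mask = head.head_mask
    if not mask.any():
        raise ValueError("empty head mask")
    vals = np.asarray(i_head, dtype=np.float64)[mask]
    # mean + std, clipped to the brightest head value so a (near-)uniform
    # head still yields its brightest pixels as points of interest
    level = min(vals.mean() + vals.std(), vals.max())
    poi_mask = mask & (np.asarray(i_head) >= level)
    if not poi_mask.any():
        raise ValueError("no points of interest above mean + std")
    ys, xs = np.nonzero(poi_mask)
    weights = np.asarray(i_head, dtype=np.float64)[ys, xs]
    m00 = weights.sum()
    m10 = (xs * weights).sum()
    m01 = (ys * weights).sum()
    origin = np.array([m10 / m00, m01 / m00])

    best_len, best_dir, best = -1.0, None, None
    for deg in range(180):
        d = np.array([np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))])
        length, pp_, pm_ = _chord(mask, origin, d)
        if length > best_len + 1e-9:
            best_len, best_dir, best = length, d, (pp_, pm_)
    if best_dir is None or best_len <= 0:
        raise ValueError("degenerate contour: chord search failed")
    ap = best_dir
    vd = np.array([-ap[1], ap[0]])
    _, pv_plus, pv_minus = _chord(mask, origin, vd)

    poi = np.column_stack([xs, ys]).astype(float) - origin

    def orient(axis):
        proj = poi @ axis
        n_pos, n_neg = int((proj > 0).sum()), int((proj < 0).sum())
        if n_pos != n_neg:
            return 1.0 if n_pos > n_neg else -1.0
        # tie: side of the contour point farthest from O
        cont = head.head_contour - origin
        far = cont[np.argmax(np.linalg.norm(cont, axis=1))]
        logger.warning("orientation tie on axis %s; breaking by farthest contour point", axis)
        return 1.0 if far @ axis >= 0 else -1.0

    s_ap = orient(ap)
    ap = ap * s_ap
    pa, pp_pt = (best[0], best[1]) if s_ap > 0 else (best[1], best[0])
    s_vd = orient(vd)
    vd = vd * s_vd
    pv, pd = (pv_plus, pv_minus) if s_vd > 0 else (pv_minus, pv_plus)

    return WormFrame(
        origin=origin,
        ap_axis=ap,
        vd_axis=vd,
        pa=pa,
        pp=pp_pt,
        pv=pv,
        pd=pd,
        moments={"m00": m00, "m10": m10, "m01": m01},
    )


def to_worm_coords(
    points: np.ndarray,
    frame: WormFrame,
    origin3: np.ndarray | None = None,
    z_scale: float = 1.0,
):
    """Transform (x, y, z) pixel/frame points into worm coordinates.

    Returns ``(cart, cyl)``: Cartesian (x' along A-P anterior-positive, y'
    along V-D ventral-positive, z') and cylindrical (rho, phi, z') with
    phi = atan2(y', x'), so phi in [-pi/2, pi/2] is the ventral territory.
    ``origin3`` defaults to (O, 0); pass a neuron centroid to center the
    frame on that neuron.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if origin3 is None:
        origin3 = np.array([frame.origin[0], frame.origin[1], 0.0])
    origin3 = np.asarray(origin3, dtype=float)
    rel = pts[:, :2] - origin3[:2]
    xp = rel @ frame.ap_axis
    yp = rel @ frame.vd_axis
    zp = (pts[:, 2] - origin3[2]) * z_scale
    cart = np.column_stack([xp, yp, zp])
    cyl = np.column_stack([np.hypot(xp, yp), np.arctan2(yp, xp), zp])
    return cart, cyl


def from_worm_coords(
    cart: np.ndarray,
    frame: WormFrame,
    origin3: np.ndarray | None = None,
    z_scale: float = 1.0,
) -> np.ndarray:
    """Inverse of :func:`to_worm_coords` (Cartesian form)."""
    c = np.atleast_2d(np.asarray(cart, dtype=float))
    if origin3 is None:
        origin3 = np.array([frame.origin[0], frame.origin[1], 0.0])
    origin3 = np.asarray(origin3, dtype=float)
    xy = np.outer(c[:, 0], frame.ap_axis) + np.outer(c[:, 1], frame.vd_axis)
    return np.column_stack(
        [xy[:, 0] + origin3[0], xy[:, 1] + origin3[1], c[:, 2] / z_scale + origin3[2]]
    )


def rotated_frame(frame: WormFrame, degrees: float) -> WormFrame:
    """Copy of a worm frame with both axes rotated by ``degrees`` (used to
    augment recognition training against axis-recovery noise)."""
    th = np.deg2rad(degrees)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return WormFrame(
        origin=frame.origin, ap_axis=rot @ frame.ap_axis, vd_axis=rot @ frame.vd_axis
    )


def true_worm_frame(pose) -> WormFrame:
    """Worm frame from a synthetic ground-truth pose (for closed-loop tests
    and oracle features)."""
    return WormFrame(origin=pose.origin, ap_axis=pose.ap_axis, vd_axis=pose.vd_axis)
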