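"""Ground-truthed synthetic 4D volumes emulating a deforming worm head.

A single canonical layout of nucleus-like blobs inside an ellipsoidal head is
generated once per animal, then independently posed per volume with a rigid
rotation/translation plus a smooth anterior-posterior bending field, and
rendered frame by frame with a cumulative in-plane drift during the Z-scan
(motion during acquisition), per-blob intensity variation, additive Gaussian
background noise, and a dim body-shaped smear outside the head.  Every output
carries full ground truth: per-frame 2D boxes, 3D objects with stable digital
IDs, the true head pose, and (optionally) per-neuron activity multipliers for
the green channel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import NeuronObject, Region2D

# axial step / lateral pixel size ratio (1.50 um z-step vs 0.30 um/px) used to
# express inter-frame z offsets in pixel-equivalent units for blob exclusion
Z_TO_PX = 5.0

# rendered blob footprint boundary: pixels above this pure-signal level belong
# to the ground-truth box
FOOTPRINT_LEVEL = 25.0


@dataclass
class LayoutSpec:
    """Parameters of one synthetic animal.  Defaults are the easy desk-scale
    regime: 256 x 256 x 12 volumes with 60 neurons and mild motion."""

    n_neurons: int = 60
    image_size: tuple[int, int] = (256, 256)  # (W, H)
    head_center: tuple[float, float] = (100.0, 128.0)
    head_axes: tuple[float, float] = (62.0, 38.0)  # semi-major, semi-minor (px)
    z_extent: int = 12
    blob_radius_range: tuple[float, float] = (2.2, 3.6)
    intensity_range: tuple[float, float] = (130.0, 250.0)
    background_level: float = 12.0
    background_noise_sigma: float = 5.0
    interframe_shift_px: float = 2.0
    intervolume_bend: float = 25.0  # max bending angle (degrees)
    intervolume_rotation: float = 20.0  # max rigid rotation (degrees)
    intervolume_translation: float = 8.0  # max rigid translation (px)
    anterior_bias: float = 0.72  # fraction of neurons on the anterior side
    ventral_bias: float = 0.72  # fraction of neurons on the ventral side
    anterior_gradient: float = 0.25  # relative brightness increase at the tip
    ventral_gradient: float = 0.18  # relative brightness increase ventrally
    anterior_compression: float = 0.60  # spread of the anterior cluster
    ventral_compression: float = 0.65  # spread of the ventral cluster
    exclusion_radius: float = 8.0  # min 3D center distance (px, z scaled)
    intensity_jitter: float = 0.12  # per-volume lognormal sigma per blob
    body_smear: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid blob_radius_range")


def preset(name: str, seed: int = 0, **overrides) -> LayoutSpec:
    """Named regimes: 'easy' (default desk scale) and 'hard' (denser head,
    stronger motion, deeper stack)."""
    if name == "easy":
        spec = LayoutSpec(seed=seed)
    elif name == "hard":
        spec = LayoutSpec(
            n_neurons=150,
            image_size=(512, 512),
            head_center=(190.0, 256.0),
            head_axes=(120.0, 72.0),
            z_extent=18,
            interframe_shift_px=4.0,
            intervolume_bend=40.0,
            intervolume_rotation=30.0,
            intervolume_translation=14.0,
            background_noise_sigma=8.0,
            exclusion_radius=9.0,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return dataclasses.replace(spec, **overrides) if overrides else spec


@dataclass
class Layout:
    """Canonical (unposed) animal: blob centers in head coordinates
    (x anterior-positive px, y ventral-positive px, z frames relative to the
    stack center), one radius and base intensity per blob."""

    points: np.ndarray  # (N, 3)
    radii: np.ndarray  # (N,)
    intensities: np.ndarray  # (N,)


@dataclass
class TruePose:
    """Ground-truth pose of the head in one volume."""

    origin: np.ndarray  # (2,) head center in pixel coords
    theta: float  # rigid rotation (radians)
    bend: float  # bending angle (radians)
    ap_axis: np.ndarray  # (2,) unit vector, anterior positive
    vd_axis: np.ndarray  # (2,) unit vector, ventral positive


@dataclass
class GroundTruth:
    regions: list[Region2D]
    objects: list[NeuronObject]
    pose: TruePose
    activity: np.ndarray | None = None  # (N,) green/red multipliers
    frame_shift: np.ndarray | None = None  # (Z, 2) cumulative in-plane drift


@dataclass
class Volume:
    """One time point: red reference stack (Z, H, W) and optional green
    activity stack of identical shape."""

    red: np.ndarray
    green: np.ndarray | None = None
    index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.red.ndim != 3 or self.red.shape[0] < 1:
            raise ValueError("red stack must be (Z, H, W) with Z >= 1")
        if self.green is not None and self.green.shape != self.red.shape:
            raise ValueError("green/red channel shapes differ")


def generate_layout(spec: LayoutSpec) -> Layout:
    """Place ``n_neurons`` blob centers inside the ellipsoidal head with a
    minimum pairwise 3D distance; deterministic given ``spec.seed``."""
    rng = np.random.default_rng((spec.seed, 0))
    a, b = spec.head_axes
    a_eff, b_eff = 0.88 * a, 0.82 * b
    z_half = max(0.5, (spec.z_extent - 1) / 2.0 - 2.0)
    scale = np.array([1.0, 1.0, Z_TO_PX])

    pts = np.empty((spec.n_neurons, 3))
    n_placed = 0
    max_tries = 100 * spec.n_neurons + 1000
    tries = 0
    while n_placed < spec.n_neurons:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {spec.n_neurons} blobs with exclusion "
                f"radius {spec.exclusion_radius} after {max_tries} tries"
            )
        tries += 1
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        r = rng.uniform() ** (1 / 3)
        cand = u * r * np.array([a_eff, b_eff, z_half])
        # Anterior / ventral asymmetry: most neurons sit in a compact
        # anterior-ventral cluster (nerve ring, amphids) with a sparser
        # posterior-dorsal tail.  The resulting skew keeps the orientation
        # steps of the coordinate-system algorithm resolvable per volume.
        if rng.uniform() < spec.anterior_bias:
            cand[0] = abs(cand[0]) * spec.anterior_compression
        else:
            cand[0] = -abs(cand[0])
        if rng.uniform() < spec.ventral_bias:
            cand[1] = abs(cand[1]) * spec.ventral_compression
        else:
            cand[1] = -abs(cand[1])
        if n_placed:
            d = np.linalg.norm((pts[:n_placed] - cand) * scale, axis=1)
            if d.min() < spec.exclusion_radius:
                continue
        pts[n_placed] = cand
        n_placed += 1

    radii = rng.uniform(*spec.blob_radius_range, size=spec.n_neurons)
    intensities = rng.uniform(*spec.intensity_range, size=spec.n_neurons)
    # anterior and ventral brightness gradients (denser, brighter ganglia
    # toward the tip and the ventral cord) keep the orientation steps of the
    # worm-frame algorithm stable across deformations
    intensities *= 1.0 + spec.anterior_gradient * np.clip(pts[:, 0] / a, -1, 1)
    intensities *= 1.0 + spec.ventral_gradient * np.clip(pts[:, 1] / b, -1, 1)
    return Layout(pts, radii, intensities)


def _bend_points(points: np.ndarray, bend: float, half_span: float) -> np.ndarray:
    """Smooth in-plane bending: rotate each point about the head center by an
    angle ramping linearly from -bend/2 (posterior) to +bend/2 (anterior),
    saturating beyond +-half_span along the A-P axis."""
    s = np.clip(points[:, 0] / half_span, -1.0, 1.0)
    ang = 0.5 * bend * s
    c, sn = np.cos(ang), np.sin(ang)
    out = points.copy()
    out[:, 0] = c * points[:, 0] - sn * points[:, 1]
    out[:, 1] = sn * points[:, 0] + c * points[:, 1]
    return out


@dataclass
class PosedLayout:
    points: np.ndarray  # (N, 3): x, y in pixel coords; z in frame units
    radii: np.ndarray
    intensities: np.ndarray
    pose: TruePose


def deform_layout(layout: Layout, volume_index: int, spec: LayoutSpec) -> PosedLayout:
    """Pose the canonical layout for one volume: bending field then rigid
    rotation + translation, mapped into pixel coordinates."""
    rng = np.random.default_rng((spec.seed, 1, volume_index))
    bend = np.deg2rad(rng.uniform(-spec.intervolume_bend, spec.intervolume_bend))
    theta = np.deg2rad(
        rng.uniform(-spec.intervolume_rotation, spec.intervolume_rotation)
    )
    t = rng.uniform(-spec.intervolume_translation, spec.intervolume_translation, 2)

    pts = _bend_points(layout.points, bend, half_span=spec.head_axes[0] / 2.0)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    xy = pts[:, :2] @ rot.T
    origin = np.asarray(spec.head_center) + t
    posed = np.column_stack(
        [
            xy[:, 0] + origin[0],
            xy[:, 1] + origin[1],
            pts[:, 2] + (spec.z_extent - 1) / 2.0,
        ]
    )
    jitter = np.exp(rng.normal(0.0, spec.intensity_jitter, len(posed)))
    pose = TruePose(
        origin=origin,
        theta=float(theta),
        bend=float(bend),
        ap_axis=rot @ np.array([1.0, 0.0]),
        vd_axis=rot @ np.array([0.0, 1.0]),
    )
    return PosedLayout(posed, layout.radii, layout.intensities * jitter, pose)


def blob_z_span(zc: float, radius: float, z_extent: int) -> list[int]:
    """Frames a blob occupies: 1-4 consecutive frames proportional to its
    in-plane radius (nucleus X-Y size correlates with Z size), centered on
    the blob's axial position."""
    nz = int(np.clip(round(radius), 1, 4))
    z0 = int(round(zc - (nz - 1) / 2.0))
    frames = [z for z in range(z0, z0 + nz) if 0 <= z < z_extent]
    return frames if frames else [int(np.clip(round(zc), 0, z_extent - 1))]


def _render_blob_frame(canvas, cx, cy, sigma, amp):
    """Add a Gaussian-profile disc; return the tight ground-truth box or
    None when the footprint is empty."""
    h, w = canvas.shape
    if amp <= FOOTPRINT_LEVEL:
        r_fp = 0.0
    else:
        r_fp = sigma * np.sqrt(2.0 * np.log(amp / FOOTPRINT_LEVEL))
    r_draw = max(3.0 * sigma, r_fp + 1.0)
    x0, x1 = int(np.floor(cx - r_draw)), int(np.ceil(cx + r_draw)) + 1
    y0, y1 = int(np.floor(cy - r_draw)), int(np.ceil(cy + r_draw)) + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return None, None
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx, gy = np.meshgrid(xs, ys)
    patch = amp * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))
    canvas[y0c:y1c, x0c:x1c] += patch
    # tight box around the footprint, clipped to the image
    bx0 = max(int(np.floor(cx - r_fp)), 0)
    bx1 = min(int(np.ceil(cx + r_fp)) + 1, w)
    by0 = max(int(np.floor(cy - r_fp)), 0)
    by1 = min(int(np.ceil(cy + r_fp)) + 1, h)
    if bx1 <= bx0 or by1 <= by0:
        return None, None
    box = (bx0, by0, bx1 - bx0, by1 - by0)
    mean_i = float(
        patch[(by0 - y0c) : (by1 - y0c), (bx0 - x0c) : (bx1 - x0c)].mean()
    )
    return box, mean_i


def render_volume(
    posed: PosedLayout,
    spec: LayoutSpec,
    volume_index: int = 0,
    activity: np.ndarray | None = None,
) -> tuple[Volume, GroundTruth]:
    """Rasterize a posed layout into a red (and optionally green) stack with
    full ground truth.

    A per-frame in-plane drift of the whole layout, cumulative across the
    Z-scan and bounded per step by ``interframe_shift_px``, emulates worm
    motion during acquisition.
    """
    rng = np.random.default_rng((spec.seed, 2, volume_index))
    w, h = spec.image_size
    z = spec.z_extent
    red = np.zeros((z, h, w), dtype=np.float32)
    green = np.zeros_like(red) if activity is not None else None

    steps = rng.uniform(-spec.interframe_shift_px, spec.interframe_shift_px, (z, 2))
    steps[0] = 0.0
    shift = np.cumsum(steps, axis=0)  # (Z, 2)

    regions: list[Region2D] = []
    per_blob: dict[int, list[Region2D]] = {}
    for i in range(len(posed.points)):
        px, py, pz = posed.points[i]
        sigma = posed.radii[i] / 1.6
        nz_frames = blob_z_span(pz, posed.radii[i], z)
        sigma_z = max(len(nz_frames) / 2.0, 0.6)
        for zf in nz_frames:
            axial = np.exp(-((zf - pz) ** 2) / (2 * sigma_z**2))
            amp = posed.intensities[i] * axial
            cx, cy = px + shift[zf, 0], py + shift[zf, 1]
            box, mean_i = _render_blob_frame(red[zf], cx, cy, sigma, amp)
            if green is not None:
                _render_blob_frame(green[zf], cx, cy, sigma, amp * activity[i])
            if box is not None:
                reg = Region2D(*[float(v) for v in box], z=zf, mean_intensity=mean_i, id=i)
                regions.append(reg)
                per_blob.setdefault(i, []).append(reg)

    objects = [
        NeuronObject(regions=list(regs), digital_id=i) for i, regs in per_blob.items()
    ]

    if spec.body_smear:
        bx = spec.head_center[0] + spec.head_axes[0] + 0.48 * spec.image_size[0] * 0.5
        by = spec.head_center[1] + rng.uniform(-15, 15)
        xs = np.arange(w)
        ys = np.arange(h)
        gx, gy = np.meshgrid(xs, ys)
        smear = 55.0 * np.exp(
            -(((gx - bx) / 30.0) ** 2 + ((gy - by) / 16.0) ** 2) / 2.0
        )
        red += smear[None, :, :]
        if green is not None:
            green += smear[None, :, :]

    red += spec.background_level
    red += rng.normal(0.0, spec.background_noise_sigma, red.shape)
    np.clip(red, 0.0, None, out=red)
    if green is not None:
        green += spec.background_level
        green += rng.normal(0.0, spec.background_noise_sigma, green.shape)
        np.clip(green, 0.0, None, out=green)

    vol = Volume(
        red=red,
        green=green,
        index=volume_index,
        meta={"lateral_um_per_px": 0.30, "z_step_um": 1.50},
    )
    gt = GroundTruth(
        regions=regions,
        objects=objects,
        pose=posed.pose,
        activity=None if activity is None else activity.copy(),
        frame_shift=shift,
    )
    return vol, gt


def generate_activity(
    spec: LayoutSpec, n_volumes: int, lo: float = 0.5, hi: float = 2.2
) -> np.ndarray:
    """Per-neuron activity multipliers over volumes: a bounded random walk
    emulating slow calcium dynamics.  Shape (n_volumes, n_neurons)."""
    rng = np.random.default_rng((spec.seed, 3))
    a = rng.uniform(0.7, 1.8, spec.n_neurons)
    out = np.empty((n_volumes, spec.n_neurons))
    for t in range(n_volumes):
        out[t] = a
        a = np.clip(a + rng.normal(0.0, 0.08, spec.n_neurons), lo, hi)
    return out


def generate_dataset(
    n_volumes: int, spec: LayoutSpec, green: bool = False
) -> list[tuple[Volume, GroundTruth]]:
    """One canonical layout, independently deformed and rendered per volume.
    Digital IDs are the layout indices, hence consistent across volumes."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    layout = generate_layout(spec)
    act = generate_activity(spec, n_volumes) if green else None
    out = []
    for t in range(n_volumes):
        posed = deform_layout(layout, t, spec)
        out.append(
            render_volume(posed, spec, t, activity=None if act is None else act[t])
        )
    return out
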