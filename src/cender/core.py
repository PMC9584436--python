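"""Core geometric types shared across pipeline stages.

Boxes use 0-based pixel indices with (x, y) = (column, row) and half-open
extents: a box (x, y, w, h) covers columns [x, x+w) and rows [y, y+h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Region2D:
    """A 2D neuronal bounding box: quintuple (x, y, w, h, z) plus a detection
    score S and the mean pixel intensity I of the enclosed region."""

    x: float
    y: float
    w: float
    h: float
    z: int
    score: float = 1.0
    mean_intensity: float = 0.0
    id: int | None = None

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"non-positive box size {self.w} x {self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def center3(self) -> np.ndarray:
        cx, cy = self.center
        return np.array([cx, cy, float(self.z)])

    def rounded(self) -> "Region2D":
        """Integer-snapped copy (w, h rounded to nearest integer >= 1)."""
        return replace(
            self,
            x=float(round(self.x)),
            y=float(round(self.y)),
            w=float(max(1, round(self.w))),
            h=float(max(1, round(self.h))),
        )


@dataclass
class AnchorBox:
    """Fixed-size candidate box A = (x_A, y_A, w_A, h_A, z_A) centered on a
    local intensity maximum.  ``clipped`` marks anchors extending past the
    image border (the box is retained)."""

    x: float
    y: float
    w: float
    h: float
    z: int
    clipped: bool = False

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass
class Correction:
    """Dimensionless box corrections (dx, dy, omega, eta): offsets are in
    units of the anchor size, omega/eta are width/height ratios."""

    dx: float
    dy: float
    omega: float
    eta: float

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.eta <= 0:
            raise ValueError("scale ratios must be positive")


def box_iou(a, b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes (half-open, so for
    integer boxes this equals pixel-set counting).  The frame index is
    ignored; callers enforce same-frame semantics where needed."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = min(ax + aw, bx + bw) - max(ax, bx)
    iy = min(ay + ah, by + bh) - max(ay, by)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return float(inter / union)


@dataclass
class NeuronObject:
    """A 3D neuron: a stack of 2D regions on consecutive frames.

    Invariants (Exclusion / Continuum principles): at most one region per
    frame, and the occupied frames are consecutive.
    """

    regions: list[Region2D] = field(default_factory=list)
    digital_id: int | None = None

    def __post_init__(self) -> None:
        self.regions.sort(key=lambda r: r.z)
        zs = self.zs
        if len(set(zs)) != len(zs):
            raise ValueError("Exclusion violated: duplicate frame in object")
        if zs and zs[-1] - zs[0] != len(zs) - 1:
            raise ValueError("Continuum violated: frames not consecutive")

    @property
    def zs(self) -> list[int]:
        return [r.z for r in self.regions]

    @property
    def intensity_profile(self) -> np.ndarray:
        """Mean pixel intensity I(z) of the member regions, in z order."""
        return np.array([r.mean_intensity for r in self.regions], dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        """Intensity-weighted mean of member box centers, (x, y, z) in
        pixels / frame units; falls back to the plain mean when all member
        intensities are zero."""
        pts = np.array([r.center3 for r in self.regions])
        w = np.array([max(r.mean_intensity, 0.0) for r in self.regions])
        if w.sum() <= 0:
            w = np.ones(len(pts))
        return (pts * w[:, None]).sum(axis=0) / w.sum()
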