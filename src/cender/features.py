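"""Per-neuron density and K-nearest-neighbour features in worm coordinates.

Both features describe a neuron by its surroundings, which stay far more
stable across a deforming recording than the neuron's own shape or texture.

The density feature counts neighbouring neuronal points between nested
concentric cylinders centred on the neuron: with radii l_t = t*dl and full
heights z_t = t*dz (t = 1..q), shell t is the set difference C_t \\ C_{t-1}
where C_t = {rho <= l_t, |z| <= z_t / 2}.  Counts are further split into
4 territories by azimuth (ventral phi in [-pi/2, pi/2] vs dorsal) and axial
side (z >= 0 vs z < 0), giving a q x 4 vector.  The shells are disjoint and
their union is the outermost cylinder, so the total count equals the number
of context points inside C_q.

The KNN feature lists the cylindrical coordinates (rho, phi, z) of the K
nearest neighbouring neuron objects in ascending distance order (3K values,
zero-padded when fewer than K neighbours exist).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NeuronObject
from .preprocessing import WormFrame, to_worm_coords


@dataclass
class FeatureConfig:
    q: int = 8  # number of cylindrical shells
    dl: float | None = None  # shell radius step (px); default head_radius / q
    dz: float | None = None  # height step (frames x z_scale); default depth / q
    K: int = 25  # nearest neighbours
    z_scale: float = 1.0  # frames -> feature z units
    source_mode: str = "regions"  # density context: "regions" or "objects"

    def resolve(self, head_radius: float | None = None, depth: float | None = None):
        dl = self.dl if self.dl is not None else (head_radius or 64.0) / self.q
        dz = self.dz if self.dz is not None else (depth or 12.0) * self.z_scale / self.q
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if dl <= 0 or dz <= 0:
            raise ValueError("bin widths must be positive")
        return dl, dz

    @property
    def length(self) -> int:
        return self.q * 4 + 3 * self.K


@dataclass
class DensityFeature:
    counts: np.ndarray  # (q, 4) int; territory order (z+,V), (z-,V), (z+,D), (z-,D)
    radii: np.ndarray  # l_1..l_q
    heights: np.ndarray  # z_1..z_q
    dl: float
    dz: float

    @property
    def vector(self) -> np.ndarray:
        return self.counts.reshape(-1).astype(float)


@dataclass
class KnnFeature:
    coords: np.ndarray  # (3K,) [rho_1, phi_1, z_1, ...] ascending by distance
    K: int
    n_padded: int = 0

    @property
    def vector(self) -> np.ndarray:
        return self.coords.astype(float)


def density_feature(
    target_centroid: np.ndarray,
    context_points: np.ndarray,
    frame: WormFrame,
    q: int = 8,
    dl: float = 8.0,
    dz: float = 1.5,
    z_scale: float = 1.0,
) -> DensityFeature:
    """Count context points in the 4-territory nested-cylinder shells around
    the target centroid (the target's own regions must be excluded by the
    caller)."""
    if q < 1:
        raise ValueError("q must be >= 1")
    if dl <= 0 or dz <= 0:
        raise ValueError("bin widths must be positive")
    counts = np.zeros((q, 4), dtype=int)
    radii = dl * np.arange(1, q + 1)
    heights = dz * np.arange(1, q + 1)
    pts = np.asarray(context_points, dtype=float).reshape(-1, 3)
    if len(pts):
        _, cyl = to_worm_coords(pts, frame, origin3=target_centroid, z_scale=z_scale)
        rho, phi, z = cyl[:, 0], cyl[:, 1], cyl[:, 2]
        # membership level: smallest t with rho <= l_t and |z| <= z_t/2
        t_rho = np.searchsorted(radii, rho, side="left")
        t_z = np.searchsorted(heights / 2.0, np.abs(z), side="left")
        level = np.maximum(t_rho, t_z)  # 0-based shell index; >= q -> outside
        ventral = (phi >= -np.pi / 2) & (phi <= np.pi / 2)
        z_plus = z >= 0
        terr = np.where(
            ventral, np.where(z_plus, 0, 1), np.where(z_plus, 2, 3)
        )
        inside = level < q
        np.add.at(counts, (level[inside], terr[inside]), 1)
    return DensityFeature(counts=counts, radii=radii, heights=heights, dl=dl, dz=dz)


def knn_feature(
    target_centroid: np.ndarray,
    context_centroids: np.ndarray,
    frame: WormFrame,
    K: int = 25,
    z_scale: float = 1.0,
) -> KnnFeature:
    """Cylindrical coordinates of the K nearest context centroids, ascending
    by Euclidean 3D distance in worm coordinates; ties break by context
    index; zero-padded when the context is smaller than K."""
    pts = np.asarray(context_centroids, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty context")
    cart, cyl = to_worm_coords(pts, frame, origin3=target_centroid, z_scale=z_scale)
    dist = np.linalg.norm(cart, axis=1)
    order = np.argsort(dist, kind="stable")[:K]
    coords = np.zeros((K, 3))
    coords[: len(order)] = cyl[order]
    return KnnFeature(coords=coords.reshape(-1), K=K, n_padded=max(0, K - len(order)))


def featurize_volume(
    objects: list[NeuronObject],
    frame: WormFrame,
    cfg: FeatureConfig | None = None,
    head_radius: float | None = None,
    depth: float | None = None,
) -> np.ndarray:
    """One concatenated [density, knn] feature row per object.

    Density context follows ``cfg.source_mode``: the member-region centers of
    all *other* objects ("regions") or their centroids ("objects"); the KNN
    context is always the other objects' centroids."""
    cfg = cfg or FeatureConfig()
    dl, dz = cfg.resolve(head_radius, depth)
    cents = np.array([o.centroid for o in objects]) if objects else np.zeros((0, 3))
    feats = np.zeros((len(objects), cfg.length))
    for i, obj in enumerate(objects):
        if cfg.source_mode == "regions":
            ctx_pts = [
                r.center3 for j, o in enumerate(objects) if j != i for r in o.regions
            ]
        elif cfg.source_mode == "objects":
            ctx_pts = [cents[j] for j in range(len(objects)) if j != i]
        else:
            raise ValueError(f"unknown source_mode {cfg.source_mode!r}")
        ctx_pts = np.array(ctx_pts) if ctx_pts else np.zeros((0, 3))
        den = density_feature(
            cents[i], ctx_pts, frame, cfg.q, dl, dz, z_scale=cfg.z_scale
        )
        ctx_cents = np.array([cents[j] for j in range(len(objects)) if j != i])
        if len(ctx_cents):
            knn = knn_feature(cents[i], ctx_cents, frame, cfg.K, z_scale=cfg.z_scale).vector
        else:
            knn = np.zeros(3 * cfg.K)
        feats[i] = np.concatenate([den.vector, knn])
    return feats
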