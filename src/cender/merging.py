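"""Merge per-frame 2D regions into 3D neuron objects.

Region linking is a maximum-weight matching on a chain of bipartite graphs:
one graph per adjacent frame pair, edge weights given by box IoU, weights
below a threshold tau zeroed, each pair solved independently by the Hungarian
algorithm (the chain objective decomposes over pairs because no edge spans
non-adjacent frames).  Matched edges are chased into chains; each chain is a
neuron object satisfying the Exclusion principle (at most one region per
frame) and the Continuum principle (consecutive frames only).  Objects whose
axial intensity profile I(z) has an interior local minimum are split there —
two neurons stacked along Z produce a bimodal profile, a single nucleus a
unimodal one.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import NeuronObject, Region2D, box_iou

TAU_DEFAULT = 0.05


def iou(r1: Region2D, r2: Region2D) -> float:
    """Intersection-over-union of two regions' boxes (frame ignored)."""
    return box_iou((r1.x, r1.y, r1.w, r1.h), (r2.x, r2.y, r2.w, r2.h))


def match_adjacent(
    regions_z: list[Region2D],
    regions_z1: list[Region2D],
    tau: float = TAU_DEFAULT,
) -> list[tuple[int, int, float]]:
    """Maximum-total-IoU one-to-one assignment between two frames' regions.

    Weights below ``tau`` are set to zero and zero-weight assignments are
    discarded, so only genuinely overlapping regions link."""
    if not regions_z or not regions_z1:
        return []
    w = np.zeros((len(regions_z), len(regions_z1)))
    for i, a in enumerate(regions_z):
        for j, b in enumerate(regions_z1):
            v = iou(a, b)
            w[i, j] = v if v >= tau else 0.0
    rows, cols = linear_sum_assignment(w, maximize=True)
    return [(int(i), int(j), float(w[i, j])) for i, j in zip(rows, cols) if w[i, j] > 0]


def link_volume(
    regions_by_frame: list[list[Region2D]], tau: float = TAU_DEFAULT
) -> list[NeuronObject]:
    """Chain the per-pair matchings of a volume into neuron objects.

    ``regions_by_frame[z]`` lists the regions of frame z.  Unmatched regions
    start single-frame objects; every input region appears in exactly one
    output object."""
    z_count = len(regions_by_frame)
    # owner chain id per (z, index)
    chains: list[list[tuple[int, int]]] = []
    owner: dict[tuple[int, int], int] = {}
    for z in range(z_count):
        for i in range(len(regions_by_frame[z])):
            owner[(z, i)] = -1
    for z in range(z_count - 1):
        for i, j, _w in match_adjacent(regions_by_frame[z], regions_by_frame[z + 1], tau):
            cid = owner[(z, i)]
            if cid < 0:
                cid = len(chains)
                chains.append([(z, i)])
                owner[(z, i)] = cid
            chains[cid].append((z + 1, j))
            owner[(z + 1, j)] = cid
    objects = []
    for chain in chains:
        objects.append(
            NeuronObject(regions=[regions_by_frame[z][i] for z, i in chain])
        )
    for (z, i), cid in owner.items():
        if cid < 0:
            objects.append(NeuronObject(regions=[regions_by_frame[z][i]]))
    return objects


def group_by_frame(regions: list[Region2D], z_count: int | None = None) -> list[list[Region2D]]:
    if z_count is None:
        z_count = (max(r.z for r in regions) + 1) if regions else 0
    out: list[list[Region2D]] = [[] for _ in range(z_count)]
    for r in regions:
        out[r.z].append(r)
    return out


def _local_minima(profile: np.ndarray) -> list[int]:
    """Strict interior local minima (plateaus excluded)."""
    return [
        k
        for k in range(1, len(profile) - 1)
        if profile[k] < profile[k - 1] and profile[k] < profile[k + 1]
    ]


def split_fused(neuron: NeuronObject, smooth: bool = False) -> list[NeuronObject]:
    """Split an object at interior local minima of its intensity profile.

    The region at the minimum frame z0 joins the *later* object, which keeps
    both parts non-empty even when the minimum sits at the second frame.
    Recurses until no interior minimum remains.  ``smooth`` applies a
    3-point running mean before the minimum scan."""
    if len(neuron.regions) < 3:
        return [neuron]
    profile = neuron.intensity_profile
    scan = profile
    if smooth:
        scan = np.convolve(profile, np.ones(3) / 3, mode="same")
        scan[0] = (profile[0] + profile[1]) / 2
        scan[-1] = (profile[-2] + profile[-1]) / 2
    minima = _local_minima(scan)
    if not minima:
        return [neuron]
    k = minima[0]
    head = NeuronObject(regions=neuron.regions[:k], digital_id=neuron.digital_id)
    tail = NeuronObject(regions=neuron.regions[k:])
    return [head] + split_fused(tail, smooth=smooth)


def enforce_z_bound(neuron: NeuronObject, max_len: int) -> list[NeuronObject]:
    """Re-split objects longer than ``max_len`` frames at their weakest
    internal IoU link.  The bound reflects the longitudinal nucleus size,
    which can be read off annotated data (nucleus X-Y and Z sizes are
    strongly correlated)."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(neuron.regions) <= max_len:
        return [neuron]
    links = [
        iou(neuron.regions[k], neuron.regions[k + 1])
        for k in range(len(neuron.regions) - 1)
    ]
    k = int(np.argmin(links)) + 1
    head = NeuronObject(regions=neuron.regions[:k], digital_id=neuron.digital_id)
    tail = NeuronObject(regions=neuron.regions[k:])
    return enforce_z_bound(head, max_len) + enforce_z_bound(tail, max_len)


def split_all(
    objects: list[NeuronObject], smooth: bool = False, max_len: int | None = None
) -> list[NeuronObject]:
    """Intensity-profile splitting of all objects, optionally followed by
    the z-length bound re-split."""
    out = []
    for o in objects:
        out.extend(split_fused(o, smooth=smooth))
    if max_len is not None:
        out = [part for o in out for part in enforce_z_bound(o, max_len)]
    return out


def _object_match_score(a: NeuronObject, b: NeuronObject) -> tuple[float, float]:
    """(mean IoU over shared frames, shared-frame fraction of the z union)."""
    za = {r.z: r for r in a.regions}
    zb = {r.z: r for r in b.regions}
    shared = sorted(set(za) & set(zb))
    union = set(za) | set(zb)
    if not shared:
        return 0.0, 0.0
    mean_iou = float(np.mean([iou(za[z], zb[z]) for z in shared]))
    return mean_iou, len(shared) / len(union)


def evaluate_merging(
    pred: list[NeuronObject],
    gt: list[NeuronObject],
    iou_threshold: float = 0.3,
    span_fraction: float = 0.5,
) -> tuple[float, float, float]:
    """Precision/recall/F1 for 3D objects: a prediction is a true positive
    when matched one-to-one to a ground-truth object with mean member-region
    IoU >= ``iou_threshold`` over shared frames and shared frames covering at
    least ``span_fraction`` of the frame-span union."""
    if not gt:
        raise ValueError("empty ground truth")
    cands = []
    for i, p in enumerate(pred):
        for j, g in enumerate(gt):
            mi, sf = _object_match_score(p, g)
            if mi >= iou_threshold and sf >= span_fraction:
                cands.append((mi, i, j))
    cands.sort(key=lambda t: -t[0])
    used_p, used_g = set(), set()
    tp = 0
    for _v, i, j in cands:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        tp += 1
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(gt)
    f1 = 0.0 if tp == 0 else 2 / (1 / recall + 1 / precision)
    return precision, recall, f1
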