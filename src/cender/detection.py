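"""Multi-field detection of 2D neuronal regions.

Candidate anchor boxes are centered on local intensity maxima in the head
region.  A small residual convolutional network scores each anchor from a
5-channel stack of concentric crops (the anchor itself plus 15x15, 31x31,
41x41 and 81x81 fields, all normalized and brought to 41x41) and regresses
dimensionless corrections (dx, dy, omega, eta) that refine the anchor into a
neuronal region; greedy non-maximum suppression removes overlaps.

Corrections follow the standard box-regression parameterization:

    dx = (xG - xA) / wA     omega = wG / wA
    dy = (yG - yA) / hA     eta   = hG / hA

and are inverted exactly at inference (x = dx * wA + xA, w = omega * wA, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .core import AnchorBox, Correction, Region2D, box_iou


@dataclass
class DetectionConfig:
    anchor_sizes: tuple[int, ...] = (9,)
    peak_neighborhood: int = 3
    peak_floor_nstd: float = 0.5
    field_sizes: tuple[int, ...] = (15, 31, 41, 81)
    patch_size: int = 41
    score_floor: float = 0.4
    nms_iou: float = 0.20
    eval_iou: float = 0.3
    pos_iou: float = 0.3  # anchors with max-IoU >= this are positives
    neg_iou: float = 0.1  # anchors below this are negatives; between: ignored
    neg_per_pos: float = 2.0
    pos_weight: float = 2.5  # BCE weight of positive anchors (recall emphasis)
    epochs: int = 12
    batch_size: int = 256
    lr: float = 0.02
    warm_restart_epochs: int = 4
    stem_channels: int = 12
    seed: int = 0


def find_local_maxima(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    neighborhood: int = 5,
    floor: float | None = None,
    floor_nstd: float = 0.5,
) -> np.ndarray:
    """(x, y) points that are neighborhood maxima above an intensity floor
    (default: mean + floor_nstd * std over the mask), in row-major order."""
    img = np.asarray(image, dtype=float)
    if floor is None:
        vals = img[mask] if mask is not None else img.ravel()
        floor = vals.mean() + floor_nstd * vals.std()
    maxf = ndimage.maximum_filter(img, size=neighborhood, mode="constant")
    peaks = (img >= maxf) & (img >= floor)
    if mask is not None:
        peaks &= mask
    ys, xs = np.nonzero(peaks)  # nonzero is row-major already
    return np.column_stack([xs, ys])


def make_anchors(
    peaks: np.ndarray, sizes, image_shape: tuple[int, int], z: int = 0
) -> list[AnchorBox]:
    """|peaks| x |sizes| anchor boxes centered on the peaks.  Boxes crossing
    the image border are flagged ``clipped`` but retained."""
    h, w = image_shape
    anchors = []
    for px, py in np.atleast_2d(peaks):
        for s in sizes:
            x0, y0 = px - s // 2, py - s // 2
            clipped = x0 < 0 or y0 < 0 or x0 + s > w or y0 + s > h
            anchors.append(AnchorBox(float(x0), float(y0), float(s), float(s), z, clipped))
    return anchors


def _crop_centered(img: np.ndarray, cx: int, cy: int, size: int) -> np.ndarray:
    """Square crop centered at (cx, cy); out-of-image area is zero."""
    h, w = img.shape
    half = size // 2
    out = np.zeros((size, size), dtype=img.dtype)
    x0, x1 = cx - half, cx - half + size
    y0, y1 = cy - half, cy - half + size
    sx0, sx1 = max(x0, 0), min(x1, w)
    sy0, sy1 = max(y0, 0), min(y1, h)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
    return out


def crop_multifield(
    frame_image: np.ndarray,
    anchor: AnchorBox,
    cfg: DetectionConfig | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """5-channel patch concentric with the anchor: [anchor crop, 15, 31, 41,
    81], crops below the patch size zero-padded, larger ones bilinearly
    resized down; values scaled to [0, 1]."""
    cfg = cfg or DetectionConfig()
    p = cfg.patch_size
    cx = int(round(anchor.x + anchor.w / 2))
    cy = int(round(anchor.y + anchor.h / 2))
    if scale is None:
        m = float(frame_image.max())
        scale = m if m > 0 else 1.0
    chans = []
    sizes = (int(round(anchor.w)),) + tuple(cfg.field_sizes)
    for s in sizes:
        crop = _crop_centered(frame_image, cx, cy, s).astype(np.float32) / scale
        if s < p:
            padded = np.zeros((p, p), dtype=np.float32)
            off = (p - s) // 2
            padded[off : off + s, off : off + s] = crop
            crop = padded
        elif s > p:
            crop = resize(
                crop, (p, p), order=1, preserve_range=True, anti_aliasing=False
            ).astype(np.float32)
        chans.append(crop)
    return np.stack(chans)


def correction_targets(anchor: AnchorBox, gt: Region2D) -> Correction:
    """Target corrections turning the anchor into the ground-truth box."""
    return Correction(
        dx=(gt.x - anchor.x) / anchor.w,
        dy=(gt.y - anchor.y) / anchor.h,
        omega=gt.w / anchor.w,
        eta=gt.h / anchor.h,
    )


def apply_correction(
    anchor: AnchorBox, pred: Correction, score: float = 1.0
) -> Region2D:
    """Invert the correction parameterization; exact floats (round at final
    output via ``Region2D.rounded``)."""
    return Region2D(
        x=pred.dx * anchor.w + anchor.x,
        y=pred.dy * anchor.h + anchor.y,
        w=pred.omega * anchor.w,
        h=pred.eta * anchor.h,
        z=anchor.z,
        score=score,
    )


def nms(
    regions: list[Region2D], score_floor: float = 0.4, overlap_threshold: float = 0.20
) -> list[Region2D]:
    """Drop regions scoring below the floor, then greedily keep the highest
    scoring region and suppress any remaining region with IoU above the
    overlap threshold against a kept one.  Ties break by (score desc, x, y)."""
    cand = sorted(
        (r for r in regions if r.score >= score_floor),
        key=lambda r: (-r.score, r.x, r.y),
    )
    kept: list[Region2D] = []
    for r in cand:
        if all(
            box_iou((r.x, r.y, r.w, r.h), (k.x, k.y, k.w, k.h)) <= overlap_threshold
            for k in kept
            if k.z == r.z
        ):
            kept.append(r)
    return kept


class DetectorModel:
    """Residual conv network: stride-2 stem, residual block, stride-2
    downsample, residual block, global average pooling, a sigmoid score head
    and a linear correction head (omega, eta through exp for positivity)."""

    def __init__(self, cfg: DetectionConfig | None = None, rng=None):
        self.cfg = cfg or DetectionConfig()
        rng = rng or np.random.default_rng(self.cfg.seed)
        c1 = self.cfg.stem_channels
        c2 = 2 * c1
        self.trunk = nn.Sequential(
            nn.Conv2d(5, c1, k=5, stride=3, pad=2, rng=rng),
            nn.ReLU(),
            nn.ResidualBlock(c1, rng=rng),
            nn.Conv2d(c1, c2, k=3, stride=2, pad=1, rng=rng),
            nn.ReLU(),
            nn.ResidualBlock(c2, rng=rng),
            nn.GlobalAvgPool(),
        )
        self.head_score = nn.Linear(c2, 1, rng=rng)
        self.head_corr = nn.Linear(c2, 4, rng=rng)

    def params(self):
        return self.trunk.params() + self.head_score.params() + self.head_corr.params()

    def _forward(self, x, train=False):
        feats = self.trunk.forward(x.astype(np.float32), train)
        logit = self.head_score.forward(feats, train)[:, 0]
        raw = self.head_corr.forward(feats, train)
        return logit, raw

    def predict(self, patches: np.ndarray):
        """(B, 5, 41, 41) -> scores (B,), corrections (B, 4) with the scale
        components mapped through exp."""
        logit, raw = self._forward(patches, train=False)
        scores = 1.0 / (1.0 + np.exp(-logit))
        corr = raw.copy()
        corr[:, 2:] = np.exp(np.clip(raw[:, 2:], -4, 4))
        return scores, corr

    def save(self, path):
        nn.save_params(path, self.params(), extra={"stem_channels": self.cfg.stem_channels})

    @classmethod
    def load(cls, path, cfg: DetectionConfig | None = None):
        data = np.load(path)
        cfg = cfg or DetectionConfig()
        cfg = replace(cfg, stem_channels=int(data["stem_channels"]))
        model = cls(cfg)
        nn.load_params(path, model.params())
        return model


@dataclass
class TrainingPatches:
    x: np.ndarray  # (M, 5, 41, 41)
    labels: np.ndarray  # (M,) 0/1
    targets: np.ndarray  # (M, 4) regression targets (dx, dy, log w, log h)


def build_training_patches(
    samples: list[tuple[np.ndarray, np.ndarray | None, list[Region2D]]],
    cfg: DetectionConfig,
    rng: np.random.Generator,
) -> TrainingPatches:
    """Assemble labeled multi-field patches from (frame, head_mask, gt
    regions) triples.  Positives: anchors whose best-IoU ground truth reaches
    ``pos_iou`` (plus anchors re-centered on each ground-truth box, which
    guarantees positives even for weak peaks); negatives: below ``neg_iou``,
    subsampled to ``neg_per_pos`` per positive; in-between anchors ignored."""
    xs, ys, ts = [], [], []
    n_pos = 0
    negatives = []
    for frame, mask, gts in samples:
        z = gts[0].z if gts else 0
        peaks = find_local_maxima(frame, mask, cfg.peak_neighborhood, floor_nstd=cfg.peak_floor_nstd)
        anchors = make_anchors(peaks, cfg.anchor_sizes, frame.shape, z)
        for g in gts:
            cx, cy = int(round(g.x + g.w / 2)), int(round(g.y + g.h / 2))
            anchors.extend(
                make_anchors(np.array([[cx, cy]]), cfg.anchor_sizes, frame.shape, z)
            )
        scale = float(frame.max()) or 1.0
        for a in anchors:
            best, best_iou = None, 0.0
            for g in gts:
                v = box_iou((a.x, a.y, a.w, a.h), (g.x, g.y, g.w, g.h))
                if v > best_iou:
                    best, best_iou = g, v
            if best_iou >= cfg.pos_iou:
                c = correction_targets(a, best)
                xs.append(crop_multifield(frame, a, cfg, scale))
                ys.append(1.0)
                ts.append([c.dx, c.dy, np.log(c.omega), np.log(c.eta)])
                n_pos += 1
            elif best_iou < cfg.neg_iou:
                negatives.append((frame, a, scale))
    if n_pos == 0:
        raise ValueError("no positive anchors found in the training data")
    n_neg = min(len(negatives), int(cfg.neg_per_pos * n_pos))
    idx = rng.permutation(len(negatives))[:n_neg]
    for i in idx:
        frame, a, scale = negatives[i]
        xs.append(crop_multifield(frame, a, cfg, scale))
        ys.append(0.0)
        ts.append([0.0, 0.0, 0.0, 0.0])
    return TrainingPatches(
        x=np.stack(xs).astype(np.float32),
        labels=np.array(ys, dtype=np.float32),
        targets=np.array(ts, dtype=np.float32),
    )


def train_detector(
    patches: TrainingPatches,
    cfg: DetectionConfig | None = None,
    seed: int = 0,
    val: TrainingPatches | None = None,
) -> DetectorModel:
    """Train the detector with binary cross-entropy on the score and L2 on
    the corrections of positive anchors, using SGD with warm restarts and
    cosine annealing.  Deterministic given ``seed``."""
    cfg = cfg or DetectionConfig()
    rng = np.random.default_rng(seed)
    model = DetectorModel(cfg, rng=rng)
    params = model.params()
    opt = nn.SGD(params, momentum=0.9, weight_decay=1e-4)
    n = len(patches.labels)
    steps_per_epoch = max(1, n // cfg.batch_size)
    sched = nn.cosine_warm_restarts(cfg.lr, cfg.warm_restart_epochs * steps_per_epoch)
    step = 0
    history = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            xb = patches.x[idx]
            yb = patches.labels[idx]
            tb = patches.targets[idx]
            nn.zero_grads(params)
            logit, raw = model._forward(xb, train=True)
            p = 1.0 / (1.0 + np.exp(-logit))
            eps = 1e-7
            wts = np.where(yb > 0.5, cfg.pos_weight, 1.0)
            wts = wts / wts.sum()
            bce = -(wts * (yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))).sum()
            pos = yb > 0.5
            npos = max(int(pos.sum()), 1)
            diff = (raw - tb) * pos[:, None]
            l2 = (diff**2).sum() / npos
            losses.append(bce + l2)
            dlogit = (p - yb) * wts
            draw = 2.0 * diff / npos
            gfeat = self_backward(model, dlogit, draw)
            del gfeat
            opt.step(sched(step))
            step += 1
        history.append(float(np.mean(losses)))
    model.loss_history = history
    return model


def self_backward(model: DetectorModel, dlogit, draw):
    g1 = model.head_score.backward(dlogit[:, None])
    g2 = model.head_corr.backward(draw.astype(np.float32))
    return model.trunk.backward(g1 + g2)


def detect_frame(
    frame: np.ndarray,
    z: int,
    model: DetectorModel,
    cfg: DetectionConfig,
    mask: np.ndarray | None = None,
) -> list[Region2D]:
    """Detect neuronal regions in one frame: peaks -> anchors -> network ->
    corrections -> NMS.  Region mean intensities are filled from the frame."""
    peaks = find_local_maxima(frame, mask, cfg.peak_neighborhood, floor_nstd=cfg.peak_floor_nstd)
    if len(peaks) == 0:
        return []
    anchors = make_anchors(peaks, cfg.anchor_sizes, frame.shape, z)
    scale = float(frame.max()) or 1.0
    batch = np.stack([crop_multifield(frame, a, cfg, scale) for a in anchors])
    scores, corr = model.predict(batch)
    regions = []
    for a, s, c in zip(anchors, scores, corr):
        if s < cfg.score_floor:
            continue
        reg = apply_correction(
            a, Correction(c[0], c[1], max(c[2], 1e-3), max(c[3], 1e-3)), score=float(s)
        ).rounded()
        regions.append(reg)
    kept = nms(regions, cfg.score_floor, cfg.nms_iou)
    h, w = frame.shape
    out = []
    for r in kept:
        x0, y0 = int(max(r.x, 0)), int(max(r.y, 0))
        x1, y1 = int(min(r.x + r.w, w)), int(min(r.y + r.h, h))
        mean_i = float(frame[y0:y1, x0:x1].mean()) if x1 > x0 and y1 > y0 else 0.0
        out.append(replace(r, mean_intensity=mean_i))
    return out


def detect_volume(
    stack: np.ndarray,
    model: DetectorModel,
    cfg: DetectionConfig | None = None,
    mask: np.ndarray | None = None,
) -> list[Region2D]:
    """Run per-frame detection over a (Z, H, W) stack."""
    cfg = cfg or DetectionConfig()
    regions = []
    for z in range(stack.shape[0]):
        regions.extend(detect_frame(stack[z], z, model, cfg, mask))
    return regions


def evaluate_detection(
    pred: list[Region2D], gt: list[Region2D], iou_threshold: float = 0.3
) -> tuple[float, float, float]:
    """Precision, recall and F1 of predicted regions against ground truth
    under optimal one-to-one matching (same frame only); a matched pair with
    IoU above the threshold is a true positive."""
    from scipy.optimize import linear_sum_assignment

    if not gt:
        raise ValueError("empty ground truth: recall undefined")
    tp = 0
    if pred:
        w = np.zeros((len(pred), len(gt)))
        for i, p in enumerate(pred):
            for j, g in enumerate(gt):
                if p.z != g.z:
                    continue
                v = box_iou((p.x, p.y, p.w, p.h), (g.x, g.y, g.w, g.h))
                if v > iou_threshold:
                    w[i, j] = 1.0 + v  # maximize TP count, break ties by IoU
        rows, cols = linear_sum_assignment(w, maximize=True)
        tp = int((w[rows, cols] >= 1.0).sum())
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(gt)
    f1 = 0.0 if tp == 0 else 2 / (1 / recall + 1 / precision)
    return precision, recall, f1
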