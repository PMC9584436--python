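"""Digital-ID recognition: hypersphere embedding with a combined angular
margin loss, and Hungarian assignment on cosine distances.

An MLP embeds each neuron's feature vector into a d-dimensional vector c.
Training drives the normalized embedding toward its class weight column w_xi
on a hypersphere of radius s using the combined-margin softmax loss

    L' = -log  exp(s (cos(m1 * theta_xi + m2) - m3))
              ------------------------------------------------
              exp(s (cos(m1 * theta_xi + m2) - m3)) + sum_{j != xi} exp(s cos theta_j)

where theta_j is the angle between c and w_j; m1 (multiplicative angle),
m2 (additive angle) and m3 (additive cosine) enlarge the angular separation
between identity clusters.  With m1 = 1, m2 = m3 = 0 this is the plain
normalized, s-scaled softmax cross-entropy.

At inference the digital IDs of one volume are assigned jointly: the cosine
distance matrix D_ij = 1 - cos(c_i, w_j) is minimized over one-to-one
assignments by the Hungarian algorithm (within-animal mode); for a new
animal, W is replaced by the embeddings of a chosen template volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nn

PAD_COST = 2.0  # cosine-distance ceiling used to pad rectangular problems


@dataclass
class RecognitionConfig:
    n_classes: int = 61  # tracked IDs + 1 extra class
    d: int = 64  # embedding dimension
    hidden: tuple[int, ...] = (512, 256)
    s: float = 30.0  # hypersphere radius
    m1: float = 1.05
    m2: float = 0.0
    m3: float = 0.05
    epochs: int = 160
    batch_size: int = 256
    lr: float = 2e-3
    weight_decay: float = 1e-4
    seed: int = 0


def _normalize(v: np.ndarray, axis=-1) -> np.ndarray:
    return v / np.maximum(np.linalg.norm(v, axis=axis, keepdims=True), 1e-12)


def margin_logits(
    c: np.ndarray, w: np.ndarray, labels: np.ndarray, s, m1, m2, m3
) -> np.ndarray:
    """Scaled class logits with the margin applied to each row's target
    class.  ``c`` (B, d) and ``w`` (d, N) are normalized internally."""
    ch = _normalize(np.atleast_2d(c))
    wh = _normalize(w, axis=0)
    cos = np.clip(ch @ wh, -1.0, 1.0)
    logits = s * cos
    rows = np.arange(len(ch))
    theta = np.arccos(cos[rows, labels])
    logits[rows, labels] = s * (np.cos(m1 * theta + m2) - m3)
    return logits


def margin_loss(
    c: np.ndarray,
    label,
    w: np.ndarray,
    s: float = 30.0,
    m1: float = 1.05,
    m2: float = 0.0,
    m3: float = 0.05,
) -> float:
    """Mean combined-margin cross-entropy of embeddings against the class
    weight matrix (single vector or batch)."""
    c2 = np.atleast_2d(c)
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    if s <= 0:
        raise ValueError("s must be positive")
    logits = margin_logits(c2, w, labels, s, m1, m2, m3)
    logits = logits - logits.max(axis=1, keepdims=True)
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(c2)), labels].mean())


class RecognitionModel:
    """Embedding MLP (Linear-BatchNorm-ReLU hidden layers, linear output)
    plus the class-weight matrix W on the hypersphere."""

    def __init__(self, in_dim: int, cfg: RecognitionConfig | None = None, rng=None):
        self.cfg = cfg or RecognitionConfig()
        rng = rng or np.random.default_rng(self.cfg.seed)
        layers = []
        prev = in_dim
        for hdim in self.cfg.hidden:
            layers += [nn.Linear(prev, hdim, rng), nn.BatchNorm1d(hdim), nn.ReLU()]
            prev = hdim
        layers.append(nn.Linear(prev, self.cfg.d, rng))
        self.mlp = nn.Sequential(*layers)
        self.W = (rng.standard_normal((self.cfg.d, self.cfg.n_classes)) * 0.05).astype(
            np.float32
        )
        self.dW = np.zeros_like(self.W)
        self.in_dim = in_dim
        self.feat_mean = np.zeros(in_dim, dtype=np.float32)
        self.feat_std = np.ones(in_dim, dtype=np.float32)
        self.history: dict = {"loss": [], "val_top1": []}

    def params(self):
        return self.mlp.params() + [{"value": self.W, "grad": self.dW}]

    def embed(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xs = (np.atleast_2d(x) - self.feat_mean) / self.feat_std
        return self.mlp.forward(xs.astype(np.float32), train)

    def save(self, path):
        extra = {
            "W": self.W,
            "feat_mean": self.feat_mean,
            "feat_std": self.feat_std,
            "in_dim": np.array(self.in_dim),
        }
        bn_state = {}
        for i, layer in enumerate(self.mlp.layers):
            if isinstance(layer, nn.BatchNorm1d):
                bn_state[f"bn{i}_mean"] = layer.running_mean
                bn_state[f"bn{i}_var"] = layer.running_var
        extra.update(bn_state)
        nn.save_params(path, self.params(), extra=extra)

    @classmethod
    def load(cls, path, cfg: RecognitionConfig | None = None):
        data = np.load(path)
        model = cls(int(data["in_dim"]), cfg)
        nn.load_params(path, model.params())
        model.feat_mean = data["feat_mean"]
        model.feat_std = data["feat_std"]
        for i, layer in enumerate(model.mlp.layers):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean = data[f"bn{i}_mean"]
                layer.running_var = data[f"bn{i}_var"]
        return model


def _margin_backward(c, w, labels, s, m1, m2, m3):
    """Loss, gradient wrt raw embeddings c, gradient wrt W (both un-normalized)."""
    cn = np.linalg.norm(c, axis=1, keepdims=True)
    wn = np.linalg.norm(w, axis=0, keepdims=True)
    ch = c / np.maximum(cn, 1e-12)
    wh = w / np.maximum(wn, 1e-12)
    cos = np.clip(ch @ wh, -1.0 + 1e-7, 1.0 - 1e-7)
    b = len(c)
    rows = np.arange(b)
    theta = np.arccos(cos[rows, labels])
    logits = s * cos.copy()
    logits[rows, labels] = s * (np.cos(m1 * theta + m2) - m3)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    loss = float(-np.log(p[rows, labels] + 1e-12).mean())

    dlogits = p.copy()
    dlogits[rows, labels] -= 1.0
    dlogits /= b
    # d logit / d cos: s for non-target; s * m1 * sin(m1 t + m2) / sin(t) target
    sin_t = np.sqrt(np.maximum(1.0 - cos[rows, labels] ** 2, 1e-12))
    dcos = dlogits * s
    dcos[rows, labels] = dlogits[rows, labels] * s * m1 * np.sin(m1 * theta + m2) / sin_t
    # back through the double normalization of cos = ch . wh
    dch = dcos @ wh.T
    dwh = ch.T @ dcos
    dc = (dch - ch * (dch * ch).sum(axis=1, keepdims=True)) / np.maximum(cn, 1e-12)
    dw = (dwh - wh * (dwh * wh).sum(axis=0, keepdims=True)) / np.maximum(wn, 1e-12)
    return loss, dc.astype(np.float32), dw.astype(np.float32)


def top1_accuracy(model: RecognitionModel, x: np.ndarray, y: np.ndarray) -> float:
    logits = _normalize(model.embed(x)) @ _normalize(model.W, axis=0)
    return float((logits.argmax(axis=1) == y).mean())


def train_recognizer(
    x: np.ndarray,
    y: np.ndarray,
    cfg: RecognitionConfig | None = None,
    seed: int = 0,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> RecognitionModel:
    """Train the recognition model on labeled feature vectors.

    Labels are class indices in [0, n_classes); neurons outside the tracked
    ID set should carry the extra-class index n_classes - 1.  Classes without
    examples keep their random weight column (with a warning).  Deterministic
    given ``seed``."""
    cfg = cfg or RecognitionConfig()
    y = np.asarray(y, dtype=int)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("need at least 2 classes to train")
    missing = set(range(cfg.n_classes)) - set(present.tolist())
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "%d classes have no training examples; their weight columns stay "
            "randomly initialized",
            len(missing),
        )
    rng = np.random.default_rng(seed)
    model = RecognitionModel(x.shape[1], cfg, rng=rng)
    model.feat_mean = x.mean(axis=0).astype(np.float32)
    model.feat_std = np.maximum(x.std(axis=0), 1e-6).astype(np.float32)
    params = model.params()
    opt = nn.Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(x)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least 2 samples
            nn.zero_grads(params)
            c = model.embed(x[idx], train=True)
            loss, dc, dw = _margin_backward(
                c, model.W, y[idx], cfg.s, cfg.m1, cfg.m2, cfg.m3
            )
            model.dW += dw
            model.mlp.backward(dc)
            # cosine-decayed learning rate over the full run
            lr = cfg.lr * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs))
            opt.step(lr)
            losses.append(loss)
        model.history["loss"].append(float(np.mean(losses)))
        if x_val is not None:
            model.history["val_top1"].append(top1_accuracy(model, x_val, y_val))
    return model


class RecognizerEnsemble:
    """A small committee of recognizers trained from different seeds; the
    cosine-distance matrices are averaged before Hungarian assignment, which
    smooths out individual models' embedding noise."""

    def __init__(self, models: list[RecognitionModel]):
        if not models:
            raise ValueError("empty ensemble")
        self.models = models

    @property
    def n_classes(self) -> int:
        return self.models[0].cfg.n_classes


def train_recognizer_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    cfg: RecognitionConfig | None = None,
    seeds=(0, 1),
) -> RecognizerEnsemble:
    return RecognizerEnsemble([train_recognizer(x, y, cfg, seed=s) for s in seeds])


def _class_distances(model, x: np.ndarray) -> np.ndarray:
    """Mean cosine-distance matrix D_ij = 1 - cos(c_i, w_j) for a model or
    an ensemble."""
    models = model.models if isinstance(model, RecognizerEnsemble) else [model]
    ds = []
    for m in models:
        ch = _normalize(m.embed(x))
        wh = _normalize(m.W, axis=0)
        ds.append(1.0 - ch @ wh)
    return np.mean(ds, axis=0)


@dataclass
class AssignmentResult:
    distance: np.ndarray  # (n_neurons, n_classes) cosine distances
    ids: list[int | None]  # assigned class per neuron (None = unassigned)
    margins: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _assign(distance: np.ndarray, valid_cols: np.ndarray) -> AssignmentResult:
    n, m = distance.shape
    size = max(n, m)
    padded = np.full((size, size), PAD_COST)
    padded[:n, :m] = distance
    rows, cols = linear_sum_assignment(padded)
    ids: list[int | None] = [None] * n
    for r, c in zip(rows, cols):
        if r < n and c < m and valid_cols[c]:
            ids[r] = int(c)
    margins = np.zeros(n)
    for r in range(n):
        row = np.sort(distance[r, valid_cols])
        if len(row) >= 2:
            margins[r] = row[1] - row[0]
    return AssignmentResult(distance=distance, ids=ids, margins=margins)


def assign_ids_within(
    model, x: np.ndarray, exclude_extra: bool = True
) -> AssignmentResult:
    """Jointly assign digital IDs to one volume's neurons by Hungarian
    matching on D_ij = 1 - cos(c_i, w_j) (model or ensemble).  The extra
    class is excluded from matching; neurons left on padded columns are
    unassigned."""
    d = _class_distances(model, x)
    valid = np.ones(d.shape[1], dtype=bool)
    if exclude_extra:
        valid[-1] = False
        d = np.where(valid[None, :], d, PAD_COST)
    return _assign(d, valid)


def assign_ids_across(
    model,
    x_template: np.ndarray,
    x_test: np.ndarray,
    template_ids: np.ndarray | None = None,
) -> AssignmentResult:
    """Cross-animal mode: the template volume's embeddings replace W, then
    the test volume is assigned against them.  Returned ids index the
    template's neurons (or ``template_ids`` when given)."""
    models = model.models if isinstance(model, RecognizerEnsemble) else [model]
    ds = []
    for m in models:
        ct = _normalize(m.embed(x_template))
        ch = _normalize(m.embed(x_test))
        ds.append(1.0 - ch @ ct.T)
    d = np.mean(ds, axis=0)
    res = _assign(d, np.ones(d.shape[1], dtype=bool))
    if template_ids is not None:
        res.ids = [None if i is None else int(template_ids[i]) for i in res.ids]
    return res


def evaluate_tracking(pred_ids: list, true_ids: list) -> float:
    """Top-1 accuracy: fraction of neurons whose assigned digital ID equals
    the ground truth, averaged per volume then over volumes.  ``pred_ids``
    and ``true_ids`` are parallel lists (one entry per volume) of per-neuron
    id sequences; unassigned predictions count as wrong."""
    if not pred_ids:
        raise ValueError("no volumes to evaluate")
    accs = []
    for pv, tv in zip(pred_ids, true_ids):
        if len(tv) == 0:
            raise ValueError("volume with no labeled neurons")
        correct = sum(1 for p, t in zip(pv, tv) if p is not None and p == t)
        accs.append(correct / len(tv))
    return float(np.mean(accs))
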