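"""End-to-end orchestration: preprocess -> detect -> merge -> featurize ->
assign IDs -> (optionally) extract activity, volume by volume.

Volumes are processed independently (sequence-independent tracking): the
output for a volume is a pure function of (volume, models, config).  Per
volume failures are isolated and reported without aborting the batch.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import detection, features, merging, preprocessing, recognition
from .detection import DetectionConfig, DetectorModel
from .features import FeatureConfig
from .io import ChannelMap, extract_activity
from .recognition import RecognitionConfig, RecognitionModel
from .synthetic import Volume

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    recognition: RecognitionConfig = field(default_factory=RecognitionConfig)
    tau: float = merging.TAU_DEFAULT
    split_smooth: bool = False

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class VolumeResult:
    volume_index: int
    objects: list = field(default_factory=list)
    ids: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    worm_frame: object = None
    activity: object = None  # DataFrame when extracted
    timings: dict = field(default_factory=dict)
    error: str | None = None
    config_hash: str = ""


def process_volume(
    volume: Volume,
    detector: DetectorModel,
    recognizer: RecognitionModel | None,
    config: PipelineConfig | None = None,
    channel_map: ChannelMap | None = None,
    extract: bool = False,
) -> VolumeResult:
    cfg = config or PipelineConfig()
    res = VolumeResult(volume_index=volume.index, config_hash=cfg.hash())
    t0 = time.perf_counter()
    mip = preprocessing.max_intensity_projection(volume)
    head = preprocessing.segment_head(mip)
    frame = preprocessing.build_worm_frame(head, mip)
    res.worm_frame = frame
    res.timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    regions = detection.detect_volume(
        volume.red, detector, cfg.detection, mask=head.head_mask
    )
    res.regions = regions
    res.timings["detect"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    by_frame = merging.group_by_frame(regions, volume.red.shape[0])
    objects = merging.split_all(
        merging.link_volume(by_frame, cfg.tau), smooth=cfg.split_smooth
    )
    res.objects = objects
    res.timings["merge"] = time.perf_counter() - t0

    if recognizer is not None and objects:
        t0 = time.perf_counter()
        head_radius = max(head.head_bbox[2], head.head_bbox[3]) / 2.0
        feats = features.featurize_volume(
            objects, frame, cfg.feature, head_radius=head_radius,
            depth=volume.red.shape[0],
        )
        assign = recognition.assign_ids_within(recognizer, feats)
        res.ids = assign.ids
        for obj, did in zip(objects, assign.ids):
            obj.digital_id = did
        res.timings["recognize"] = time.perf_counter() - t0

    if extract and volume.green is not None:
        t0 = time.perf_counter()
        res.activity = extract_activity(objects, volume, channel_map)
        res.timings["extract"] = time.perf_counter() - t0
    return res


def run_pipeline(
    volumes: list[Volume],
    detector: DetectorModel,
    recognizer: RecognitionModel | None = None,
    config: PipelineConfig | None = None,
    channel_map: ChannelMap | None = None,
    extract: bool = False,
) -> list[VolumeResult]:
    """Process a batch of volumes independently; a failing volume yields a
    result with its ``error`` set instead of aborting the batch."""
    cfg = config or PipelineConfig()
    results = []
    for vol in volumes:
        try:
            res = process_volume(vol, detector, recognizer, cfg, channel_map, extract)
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            logger.exception("volume %d failed", vol.index)
            res = VolumeResult(
                volume_index=vol.index, error=str(exc), config_hash=cfg.hash()
            )
        logger.info(
            "volume %d: %s",
            vol.index,
            {k: f"{v:.3f}s" for k, v in res.timings.items()},
        )
        results.append(res)
    return results


ROTATION_AUG_DEG = (0.0, -12.0, -6.0, 6.0, 12.0)


def build_recognition_training_set(
    volumes_objects: list[list],
    frames: list,
    labels: list[np.ndarray],
    cfg: FeatureConfig | None = None,
    head_radii: list[float] | None = None,
    depth: int = 12,
    rotations=ROTATION_AUG_DEG,
):
    """Featurize training volumes for the recognizer, augmenting each volume
    with copies computed under small rotations of its worm frame.  The
    augmentation emulates the axis-recovery noise of the head-coordinate
    stage, which is the dominant feature perturbation across volumes.

    ``labels[i]`` carries one digital ID (or -1 to drop) per object of
    volume i.  Returns (X, y)."""
    cfg = cfg or FeatureConfig()
    xs, ys = [], []
    for i, (objects, frame) in enumerate(zip(volumes_objects, frames)):
        lab = np.asarray(labels[i])
        keep = np.flatnonzero(lab >= 0)
        if len(keep) == 0:
            continue
        hr = head_radii[i] if head_radii else None
        for deg in rotations:
            f = preprocessing.rotated_frame(frame, deg) if deg else frame
            feats = features.featurize_volume(
                objects, f, cfg, head_radius=hr, depth=depth
            )
            xs.append(feats[keep])
            ys.append(lab[keep])
    return np.vstack(xs), np.concatenate(ys)


def match_objects_to_truth(
    objects: list, gt_objects: list, max_dist: float = 6.0
) -> list[int | None]:
    """One-to-one match of predicted objects to ground-truth objects by
    centroid distance (Hungarian, gated at ``max_dist`` px); returns the
    matched ground-truth digital ID per predicted object."""
    from scipy.optimize import linear_sum_assignment

    if not objects or not gt_objects:
        return [None] * len(objects)
    pc = np.array([o.centroid for o in objects])
    gc = np.array([o.centroid for o in gt_objects])
    d = np.linalg.norm(pc[:, None, :] - gc[None, :, :], axis=2)
    big = 1e6
    cost = np.where(d <= max_dist, d, big)
    n, m = cost.shape
    size = max(n, m)
    padded = np.full((size, size), big)
    padded[:n, :m] = cost
    rows, cols = linear_sum_assignment(padded)
    out: list[int | None] = [None] * n
    for r, c in zip(rows, cols):
        if r < n and c < m and cost[r, c] < big:
            out[r] = gt_objects[c].digital_id
    return out
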