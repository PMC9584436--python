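"""Shared fixtures: the easy synthetic study regime and models trained on it.

Heavy artifacts (the 40-volume dataset, the trained detector and
recognizers) are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from cender import detection, features, merging, preprocessing, recognition, synthetic

N_VOLUMES = 40
N_TRAIN = 30


@pytest.fixture(scope="session")
def easy_spec():
    return synthetic.preset("easy", seed=0)


@pytest.fixture(scope="session")
def dataset(easy_spec):
    """40 easy-regime volumes with green channel and full ground truth."""
    return synthetic.generate_dataset(N_VOLUMES, easy_spec, green=True)


@pytest.fixture(scope="session")
def preprocessed(dataset):
    """(mip, head, worm_frame) per volume, computed by the APP stage."""
    out = []
    for vol, _gt in dataset:
        mip = preprocessing.max_intensity_projection(vol)
        head = preprocessing.segment_head(mip)
        out.append((mip, head, preprocessing.build_worm_frame(head, mip)))
    return out


@pytest.fixture(scope="session")
def detector(dataset, preprocessed):
    """Detector trained on the first 30 volumes' ground-truth regions."""
    cfg = detection.DetectionConfig()
    samples = []
    for (vol, gt), (_mip, head, _frame) in zip(dataset[:N_TRAIN], preprocessed[:N_TRAIN]):
        by = merging.group_by_frame(gt.regions, vol.red.shape[0])
        for z in range(vol.red.shape[0]):
            samples.append((vol.red[z], head.head_mask, by[z]))
    patches = detection.build_training_patches(samples, cfg, np.random.default_rng(0))
    return detection.train_detector(patches, cfg, seed=0)


@pytest.fixture(scope="session")
def gt_features(dataset, preprocessed):
    """Ground-truth-object features and labels, per volume."""
    fcfg = features.FeatureConfig()
    feats, labels = [], []
    for (vol, gt), (_mip, head, frame) in zip(dataset, preprocessed):
        hr = max(head.head_bbox[2], head.head_bbox[3]) / 2.0
        feats.append(
            features.featurize_volume(
                gt.objects, frame, fcfg, head_radius=hr, depth=vol.red.shape[0]
            )
        )
        labels.append(np.array([o.digital_id for o in gt.objects]))
    return feats, labels


def train_recognizer_on(gt_features, n_volumes: int, seed: int = 0):
    feats, labels = gt_features
    x = np.vstack(feats[:n_volumes])
    y = np.concatenate(labels[:n_volumes])
    cfg = recognition.RecognitionConfig(n_classes=int(max(np.concatenate(labels))) + 2)
    return recognition.train_recognizer(x, y, cfg, seed=seed)


@pytest.fixture(scope="session")
def recognizer(gt_features):
    """Recognizer trained on ground-truth features of the 30 training volumes."""
    return train_recognizer_on(gt_features, N_TRAIN)


def detect_and_merge(vol, head, detector, max_len=4):
    """Shared inference path: detect regions, link, split."""
    cfg = detection.DetectionConfig()
    regions = detection.detect_volume(vol.red, detector, cfg, mask=head.head_mask)
    objects = merging.split_all(
        merging.link_volume(merging.group_by_frame(regions, vol.red.shape[0])),
        max_len=max_len,
    )
    return regions, objects


@pytest.fixture(scope="session")
def e2e_results(dataset, preprocessed, detector):
    """Full-pipeline outputs: per-volume detection metrics, merged objects,
    their features and ground-truth id matches, for all 40 volumes."""
    from cender import pipeline

    fcfg = features.FeatureConfig()
    out = []
    for (vol, gt), (_mip, head, frame) in zip(dataset, preprocessed):
        regions, objects = detect_and_merge(vol, head, detector)
        det_prf = detection.evaluate_detection(regions, gt.regions)
        hr = max(head.head_bbox[2], head.head_bbox[3]) / 2.0
        feats = features.featurize_volume(
            objects, frame, fcfg, head_radius=hr, depth=vol.red.shape[0]
        )
        true_ids = pipeline.match_objects_to_truth(objects, gt.objects)
        out.append(
            {
                "regions": regions,
                "objects": objects,
                "frame": frame,
                "head_radius": hr,
                "feats": feats,
                "true_ids": true_ids,
                "det_prf": det_prf,
                "n_gt": len(gt.objects),
            }
        )
    return out


@pytest.fixture(scope="session")
def recognizer_e2e(e2e_results):
    """Recognizer ensemble trained on the pipeline's own detections of the
    training volumes (labels carried over from the annotations by centroid
    match), with rotation augmentation of the worm frames."""
    from cender import pipeline

    labels = [
        np.array([-1 if t is None else t for t in res["true_ids"]])
        for res in e2e_results[:N_TRAIN]
    ]
    x, y = pipeline.build_recognition_training_set(
        [res["objects"] for res in e2e_results[:N_TRAIN]],
        [res["frame"] for res in e2e_results[:N_TRAIN]],
        labels,
        head_radii=[res["head_radius"] for res in e2e_results[:N_TRAIN]],
    )
    cfg = recognition.RecognitionConfig(n_classes=int(y.max()) + 2)
    return recognition.train_recognizer_ensemble(x, y, cfg, seeds=(0, 1))


@pytest.fixture(scope="session")
def learning_curve(gt_features, dataset):
    """Held-out tracking top-1 after training on 5/10/20/30 volumes."""
    feats, labels = gt_features
    curve = {}
    for n in (5, 10, 20, 30):
        model = train_recognizer_on(gt_features, n)
        accs = [
            float(np.mean([p == t for p, t in zip(
                recognition.assign_ids_within(model, f).ids, y)]))
            for f, y in zip(feats[N_TRAIN:], labels[N_TRAIN:])
        ]
        curve[n] = float(np.mean(accs))
    return curve
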