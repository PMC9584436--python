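"""Readers/writers for volumes and annotations, channel mapping, and
ratiometric activity extraction.

Volumes are multi-page TIFF files (one page per z) or directories of
per-frame TIFFs.  Annotations are JSON: per-volume lists of region
quintuples with digital IDs and the objects grouping them; boxes are
0-based, half-open, documented in-file by a ``convention`` field.

Neural activity is the ratiometric measure R = F_GCaMP / F_RFP: the mean
green fluorescence over a neuron's pixels (sampled through a calibrated
linear red->green channel map) divided by the mean red fluorescence, which
suppresses motion artifacts common to both channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import NeuronObject, Region2D
from .synthetic import GroundTruth, Volume

BOX_CONVENTION = "0-based pixel indices; (x, y) = (column, row); boxes half-open [x, x+w) x [y, y+h)"


def write_volume(volume: Volume, path, green_path=None) -> None:
    tifffile.imwrite(path, np.asarray(volume.red))
    if volume.green is not None and green_path is not None:
        tifffile.imwrite(green_path, np.asarray(volume.green))


def read_volume(path, green_path=None, index: int = 0, meta=None) -> Volume:
    """Read a (Z, H, W) stack from a multi-page TIFF or a directory of
    per-frame TIFFs; page shapes must agree."""

    def read_stack(p):
        p = Path(p)
        if p.is_dir():
            frames = [tifffile.imread(f) for f in sorted(p.glob("*.tif*"))]
            if not frames:
                raise ValueError(f"no TIFF frames in {p}")
            shapes = {f.shape for f in frames}
            if len(shapes) != 1:
                raise ValueError(f"mixed frame shapes in {p}: {sorted(shapes)}")
            return np.stack(frames)
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected a (Z, H, W) stack in {p}, got {arr.shape}")
        return arr

    red = read_stack(path)
    green = read_stack(green_path) if green_path else None
    if green is not None and green.shape != red.shape:
        raise ValueError("green/red stack shapes differ")
    return Volume(red=red, green=green, index=index, meta=meta or {})


def _region_to_dict(r: Region2D) -> dict:
    d = {"x": r.x, "y": r.y, "w": r.w, "h": r.h, "z": int(r.z)}
    if r.id is not None:
        d["id"] = int(r.id)
    if r.score != 1.0:
        d["score"] = r.score
    if r.mean_intensity:
        d["mean_intensity"] = r.mean_intensity
    return d


def _region_from_dict(d: dict, where: str) -> Region2D:
    for key in ("x", "y", "w", "h", "z"):
        if key not in d:
            raise ValueError(f"{where}: region missing field {key!r}")
    return Region2D(
        x=float(d["x"]),
        y=float(d["y"]),
        w=float(d["w"]),
        h=float(d["h"]),
        z=int(d["z"]),
        score=float(d.get("score", 1.0)),
        mean_intensity=float(d.get("mean_intensity", 0.0)),
        id=d.get("id"),
    )


def write_annotations(records: list[dict], path) -> None:
    """``records``: per-volume dicts with keys ``volume_index``, ``regions``
    (list of Region2D) and optionally ``objects`` (list of NeuronObject)."""
    out = {"convention": BOX_CONVENTION, "volumes": []}
    for rec in records:
        regions = list(rec.get("regions", []))
        vol = {
            "volume_index": int(rec["volume_index"]),
            "regions": [_region_to_dict(r) for r in regions],
        }
        objs = []
        index_of = {id(r): i for i, r in enumerate(regions)}
        for o in rec.get("objects", []):
            objs.append(
                {
                    "id": None if o.digital_id is None else int(o.digital_id),
                    "region_indices": [index_of[id(r)] for r in o.regions],
                    "centroid": [float(v) for v in o.centroid],
                }
            )
        vol["objects"] = objs
        out["volumes"].append(vol)
    Path(path).write_text(json.dumps(out, indent=1))


def read_annotations(path) -> list[dict]:
    data = json.loads(Path(path).read_text())
    if "volumes" not in data:
        raise ValueError(f"{path}: missing top-level 'volumes' list")
    records = []
    for vi, vol in enumerate(data["volumes"]):
        where = f"{path}: volumes[{vi}]"
        if "volume_index" not in vol:
            raise ValueError(f"{where}: missing volume_index")
        regions = [
            _region_from_dict(d, f"{where}.regions[{i}]")
            for i, d in enumerate(vol.get("regions", []))
        ]
        objects = []
        for oi, od in enumerate(vol.get("objects", [])):
            idxs = od.get("region_indices")
            if idxs is None:
                raise ValueError(f"{where}.objects[{oi}]: missing region_indices")
            objects.append(
                NeuronObject(
                    regions=[regions[k] for k in idxs], digital_id=od.get("id")
                )
            )
        records.append(
            {"volume_index": int(vol["volume_index"]), "regions": regions, "objects": objects}
        )
    return records


def ground_truth_record(gt: GroundTruth, volume_index: int) -> dict:
    """Export synthetic ground truth in the annotation record form."""
    return {"volume_index": volume_index, "regions": gt.regions, "objects": gt.objects}


@dataclass
class ChannelMap:
    """2D affine transform mapping red-channel pixel coordinates into the
    green channel: [x', y']^T = A [x, y, 1]^T."""

    a: np.ndarray = None

    def __post_init__(self):
        if self.a is None:
            self.a = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (2, 3):
            raise ValueError("channel map must be a 2x3 matrix")
        if abs(np.linalg.det(self.a[:, :2])) < 1e-12:
            raise ValueError("channel map is not invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.a[:, :2].T + self.a[:, 2]


def fit_channel_map(red_points: np.ndarray, green_points: np.ndarray) -> ChannelMap:
    """Least-squares affine fit from matched landmark pairs (>= 3)."""
    rp = np.atleast_2d(red_points)
    gp = np.atleast_2d(green_points)
    if len(rp) < 3:
        raise ValueError("need at least 3 landmark pairs")
    design = np.column_stack([rp, np.ones(len(rp))])
    sol, *_ = np.linalg.lstsq(design, gp, rcond=None)
    return ChannelMap(a=sol.T)


def extract_activity(
    objects: list[NeuronObject],
    volume: Volume,
    cmap: ChannelMap | None = None,
    background: str | float | None = "median",
) -> pd.DataFrame:
    """Per-neuron ratiometric traces for one volume.

    F_RFP is the mean red intensity over the neuron's member-region pixels;
    F_GCaMP samples the green channel at the affine-mapped coordinates
    (nearest pixel).  Each channel's diffuse background (``background``:
    per-frame median by default, a constant, or None to disable) is
    subtracted before the ratio so R tracks the indicator rather than the
    camera offset.  A neuron whose mapped region leaves the green frame is
    flagged ``missing`` with R = NaN rather than zero."""
    if volume.green is None:
        raise ValueError("green channel not present")
    cmap = cmap or ChannelMap()
    z_max, h, w = volume.red.shape
    if background == "median":
        bg_r = np.median(volume.red, axis=(1, 2))
        bg_g = np.median(volume.green, axis=(1, 2))
    elif background is None:
        bg_r = bg_g = np.zeros(z_max)
    else:
        bg_r = bg_g = np.full(z_max, float(background))
    rows = []
    for obj in objects:
        red_vals, green_vals = [], []
        missing = False
        for r in obj.regions:
            x0, y0 = int(round(r.x)), int(round(r.y))
            x1, y1 = x0 + int(round(r.w)), y0 + int(round(r.h))
            x0c, y0c = max(x0, 0), max(y0, 0)
            x1c, y1c = min(x1, w), min(y1, h)
            if x1c <= x0c or y1c <= y0c:
                missing = True
                continue
            xs, ys = np.meshgrid(np.arange(x0c, x1c), np.arange(y0c, y1c))
            red_vals.append(volume.red[r.z, ys, xs].ravel() - bg_r[r.z])
            mapped = cmap.apply(np.column_stack([xs.ravel(), ys.ravel()]))
            gx = np.round(mapped[:, 0]).astype(int)
            gy = np.round(mapped[:, 1]).astype(int)
            ok = (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h)
            if not ok.all():
                missing = True
            if ok.any():
                green_vals.append(volume.green[r.z, gy[ok], gx[ok]].ravel() - bg_g[r.z])
        f_r = float(np.concatenate(red_vals).mean()) if red_vals else np.nan
        f_g = float(np.concatenate(green_vals).mean()) if green_vals else np.nan
        if missing:
            flag = "missing"
        elif not np.isfinite(f_r) or f_r <= 0:
            flag = "invalid"  # reference signal at or below background
        else:
            flag = "ok"
        ratio = f_g / f_r if flag == "ok" else np.nan
        rows.append(
            {
                "volume": volume.index,
                "digital_id": obj.digital_id,
                "F_R": f_r,
                "F_G": f_g,
                "R": ratio,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
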