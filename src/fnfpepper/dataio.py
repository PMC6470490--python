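"""Dataset readers and writers.

A dataset is a directory of scene subdirectories, each holding
``flash.png`` and ``noflash.png`` (8-bit RGB), optionally ``fnf.png`` (a
previously written composite), ``labels.png`` (8-bit single-channel class
raster) and ``truth.json`` (per-object bounding boxes, maturity classes and
run-length-encoded masks).  ``classmap.json`` at the dataset root declares
the label codes.  This mirrors the layout written by
:func:`fnfpepper.simulator.generate_dataset`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detector import Detection
from .evaluation import EvalResult, GroundTruthObject, MaturityClass
from .imaging import RGBImage
from .simulator import CLASS_CODES, Scene, SceneTruth, rle_to_mask

__all__ = [
    "read_scene_dir",
    "read_dataset",
    "write_composite",
    "write_detections_json",
    "write_metrics",
    "write_category_csv",
]


def _read_rgb(path: Path) -> RGBImage:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return RGBImage(arr.astype(np.int64))


def _read_classmap(dataset_root: Path) -> dict[int, str]:
    path = dataset_root / "classmap.json"
    if path.exists():
        raw = json.loads(path.read_text())
        return {int(k): v for k, v in raw.items()}
    return {v: k for k, v in CLASS_CODES.items()}


def _read_truth(scene_dir: Path, classmap: dict[int, str]) -> Optional[SceneTruth]:
    labels_path = scene_dir / "labels.png"
    truth_path = scene_dir / "truth.json"
    if not labels_path.exists() and not truth_path.exists():
        return None
    if not labels_path.exists() or not truth_path.exists():
        missing = "labels.png" if not labels_path.exists() else "truth.json"
        raise FileNotFoundError(f"{scene_dir}: missing {missing}")
    label_mask = np.asarray(iio.imread(labels_path))
    if label_mask.ndim != 2:
        raise ValueError(f"{labels_path}: labels must be single-channel")
    codes = set(np.unique(label_mask).tolist())
    unknown = codes - set(classmap)
    if unknown:
        raise ValueError(
            f"{labels_path}: label codes {sorted(unknown)} absent from classmap.json"
        )
    raw = json.loads(truth_path.read_text())
    h, w = int(raw["height"]), int(raw["width"])
    if (h, w) != label_mask.shape:
        raise ValueError(f"{truth_path}: dimensions disagree with labels.png")
    objects = [
        GroundTruthObject(
            mask=rle_to_mask(entry["rle"], h, w),
            bbox=tuple(entry["bbox"]),  # type: ignore[arg-type]
            maturity=MaturityClass(entry["maturity"]),
        )
        for entry in raw["objects"]
    ]
    return SceneTruth(label_mask=label_mask.astype(np.uint8), objects=objects)


def read_scene_dir(path: str | Path, classmap: dict[int, str] | None = None) -> Scene:
    """Load one scene directory: the image pair plus optional composite/truth."""
    scene_dir = Path(path)
    if not scene_dir.is_dir():
        raise FileNotFoundError(f"scene directory not found: {scene_dir}")
    for name in ("flash.png", "noflash.png"):
        if not (scene_dir / name).exists():
            raise FileNotFoundError(f"{scene_dir}: missing {name}")
    flash = _read_rgb(scene_dir / "flash.png")
    noflash = _read_rgb(scene_dir / "noflash.png")
    if flash.shape != noflash.shape:
        raise ValueError(f"{scene_dir}: flash and noflash dimensions differ")
    composite = None
    if (scene_dir / "fnf.png").exists():
        composite = _read_rgb(scene_dir / "fnf.png")
    if classmap is None:
        classmap = _read_classmap(scene_dir.parent)
    truth = _read_truth(scene_dir, classmap)
    return Scene(scene_dir.name, flash, noflash, truth=truth, composite=composite)


def read_dataset(root: str | Path) -> list[Scene]:
    """Load every scene directory under a dataset root, in sorted order."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root not found: {root}")
    classmap = _read_classmap(root)
    scene_dirs = sorted(
        d for d in root.iterdir() if d.is_dir() and (d / "flash.png").exists()
    )
    if not scene_dirs:
        raise FileNotFoundError(f"no scene directories under {root}")
    return [read_scene_dir(d, classmap) for d in scene_dirs]


def write_composite(scene_dir: str | Path, composite: RGBImage) -> Path:
    """Write an FNF composite alongside its inputs as ``fnf.png``."""
    out = Path(scene_dir) / "fnf.png"
    iio.imwrite(out, composite.pixels)
    return out


def write_detections_json(
    path: str | Path, detections_per_scene: dict[str, Sequence[Detection]]
) -> Path:
    """Serialize detections as JSON: per image, a list of bbox/area records."""
    payload = [
        {"image_id": scene_id, "bbox": list(det.bbox), "area": det.area}
        for scene_id, dets in detections_per_scene.items()
        for det in dets
    ]
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_metrics(
    prefix: str | Path, results: Sequence[tuple[str, EvalResult]]
) -> tuple[Path, Path]:
    """Write a metrics grid as CSV and JSON.

    ``results`` pairs a modality name with an :class:`EvalResult`; the CSV
    has one row per scheme x cluster-mode x modality cell.
    """
    rows = []
    for modality, res in results:
        rows.append(
            {
                "modality": modality,
                "scheme": res.scheme,
                "cluster_mode": res.cluster_mode,
                **{k.lower(): v for k, v in res.counts.as_dict().items()},
                "precision": res.precision,
                "recall": res.recall,
            }
        )
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(rows, indent=1))
    return csv_path, json_path


def write_category_csv(path: str | Path, distribution: dict[str, int]) -> Path:
    """Write the six-way detection-category distribution as CSV."""
    path = Path(path)
    pd.DataFrame(
        [{"category": k, "count": v} for k, v in distribution.items()]
    ).to_csv(path, index=False)
    return path
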