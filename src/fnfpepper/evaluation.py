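"""Cluster-aware detection evaluation.

Detections are matched to labeled fruit by bounding-box overlap (IoU of at
least 50 % by default) and classified into a six-way taxonomy:

* ``TP``  — correct detection of a mature fruit;
* ``FP2`` — partially mature fruit detected as mature;
* ``FP1`` — immature (green) fruit detected as mature;
* ``DC``  — distant, out-of-working-range fruit detected (ignored: it
  contributes to neither precision nor recall);
* ``FP``  — detection overlapping no labeled fruit;
* ``FN``  — countable fruit with no detection.

Two scoring schemes reflect how a harvesting robot uses the detector:
``strict`` counts a detected partially mature fruit as a false positive,
``flexible`` as a true positive.  Two cluster modes reflect that
morphological cleanup merges touching fruit into a single blob: under
``per_object`` matching each fruit must be matched one-to-one, so a merged
cluster scores one TP and the rest FN; under ``cluster_credit`` every
countable fruit lying (mostly) inside a single detected region counts as
detected, since visual servoing resolves merged detections during the
approach.

Precision = NTP / (NTP + NFP) and Recall = NTP / (NTP + NFN), with FP1 and
FP2 folded into NFP and DC excluded entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .detector import Detection, DetectorParams, detect
from .imaging import FNFParams, RGBImage, compose_images, rgb_to_hsv

__all__ = [
    "MaturityClass",
    "GroundTruthObject",
    "EvalCounts",
    "EvalParams",
    "EvalResult",
    "iou",
    "match_detections",
    "cluster_credit_counts",
    "precision_recall",
    "evaluate_dataset",
    "labeled_pixel_stats",
    "sweep_thresholds",
]

Box = tuple[int, int, int, int]


class MaturityClass(str, enum.Enum):
    """Fruit maturity classes used in labeling and scoring."""

    MATURE = "mature"
    PARTIALLY_MATURE = "partially_mature"
    IMMATURE = "immature"
    DISTANT = "distant"


@dataclass(frozen=True)
class GroundTruthObject:
    """A labeled fruit region: boolean mask, tight half-open bbox, maturity."""

    mask: np.ndarray
    bbox: Box
    maturity: MaturityClass

    def __post_init__(self) -> None:
        if not np.asarray(self.mask, dtype=bool).any():
            raise ValueError("ground-truth mask must be non-empty")


@dataclass
class EvalCounts:
    """Raw counts of the six-way detection taxonomy."""

    n_tp: int = 0
    n_fp: int = 0
    n_fn: int = 0
    n_fp1: int = 0
    n_fp2: int = 0
    n_dc: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            self.n_tp + other.n_tp,
            self.n_fp + other.n_fp,
            self.n_fn + other.n_fn,
            self.n_fp1 + other.n_fp1,
            self.n_fp2 + other.n_fp2,
            self.n_dc + other.n_dc,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "TP": self.n_tp,
            "FP2": self.n_fp2,
            "FP1": self.n_fp1,
            "DC": self.n_dc,
            "FP": self.n_fp,
            "FN": self.n_fn,
        }


@dataclass(frozen=True)
class EvalParams:
    """Matching thresholds.

    iou_threshold
        Minimum bounding-box overlap ratio (intersection over union) for a
        detection to match a labeled fruit; default 0.5.
    containment_threshold
        Cluster-credit only: minimum fraction of a fruit's pixels that must
        lie inside one detection's blob for the fruit to count as covered.
    """

    iou_threshold: float = 0.5
    containment_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("iou_threshold", "containment_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class EvalResult:
    """Aggregate counts plus derived precision/recall for one scheme cell.

    ``precision`` or ``recall`` is ``None`` when its denominator is zero
    (an explicit undefined marker, distinct from 0.0 and 1.0).
    """

    counts: EvalCounts
    precision: Optional[float]
    recall: Optional[float]
    scheme: str
    cluster_mode: str


def _countable(maturity: MaturityClass, scheme: str) -> bool:
    if maturity is MaturityClass.MATURE:
        return True
    return maturity is MaturityClass.PARTIALLY_MATURE and scheme == "flexible"


def _check_scheme(scheme: str) -> None:
    if scheme not in ("strict", "flexible"):
        raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def iou(box_a: Box, box_b: Box) -> float:
    """Overlap ratio of two half-open boxes: |A n B| / |A u B|."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("boxes must have positive area")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(iw, 0) * max(ih, 0)
    return inter / (area_a + area_b - inter)


def match_detections(
    dets: Sequence[Detection],
    truths: Sequence[GroundTruthObject],
    scheme: str = "strict",
    params: EvalParams | None = None,
) -> EvalCounts:
    """One-to-one greedy bounding-box matching and taxonomy counting.

    Candidate (detection, truth) pairs with IoU at or above the threshold
    are matched greedily in descending IoU (ties broken by truth index,
    then detection index); each detection and each truth is used at most
    once.  Matched pairs are classified by the truth's maturity; unmatched
    detections are FP; unmatched countable truths are FN.
    """
    _check_scheme(scheme)
    params = params or EvalParams()
    candidates: list[tuple[float, int, int]] = []
    for ti, truth in enumerate(truths):
        for di, det in enumerate(dets):
            ov = iou(det.bbox, truth.bbox)
            if ov >= params.iou_threshold:
                candidates.append((ov, ti, di))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    matched_truth: dict[int, int] = {}
    used_det: set[int] = set()
    for _, ti, di in candidates:
        if ti in matched_truth or di in used_det:
            continue
        matched_truth[ti] = di
        used_det.add(di)

    counts = EvalCounts()
    for ti, truth in enumerate(truths):
        if ti in matched_truth:
            if truth.maturity is MaturityClass.MATURE:
                counts.n_tp += 1
            elif truth.maturity is MaturityClass.PARTIALLY_MATURE:
                if scheme == "flexible":
                    counts.n_tp += 1
                else:
                    counts.n_fp2 += 1
            elif truth.maturity is MaturityClass.IMMATURE:
                counts.n_fp1 += 1
            else:
                counts.n_dc += 1
        elif _countable(truth.maturity, scheme):
            counts.n_fn += 1
    counts.n_fp = len(dets) - len(used_det)
    return counts


def cluster_credit_counts(
    dets: Sequence[Detection],
    truths: Sequence[GroundTruthObject],
    scheme: str = "strict",
    params: EvalParams | None = None,
) -> EvalCounts:
    """Cluster-credit counting over blob masks.

    A fruit is *covered* when at least ``containment_threshold`` of its mask
    pixels lie inside a single detection's blob mask.  Every covered
    countable fruit is a TP (so one merged blob over a cluster credits every
    fruit in it); an uncovered countable fruit is FN.  A detection covering
    at least one countable fruit is credited once; a detection covering only
    non-countable fruit contributes to FP2/FP1/DC by the best class it
    covers; a detection covering nothing is a plain FP.
    """
    _check_scheme(scheme)
    params = params or EvalParams()
    for det in dets:
        if det.blob_mask is None:
            raise ValueError("cluster-credit counting requires detection blob masks")

    # coverage[ti] = (best fraction, detection index)
    cover_det: dict[int, int] = {}
    for ti, truth in enumerate(truths):
        tmask = np.asarray(truth.mask, dtype=bool)
        npix = tmask.sum()
        best, best_di = 0.0, -1
        for di, det in enumerate(dets):
            frac = np.logical_and(tmask, det.blob_mask).sum() / npix
            if frac > best:
                best, best_di = frac, di
        if best >= params.containment_threshold:
            cover_det[ti] = best_di

    counts = EvalCounts()
    covered_by_det: dict[int, list[MaturityClass]] = {}
    for ti, di in cover_det.items():
        covered_by_det.setdefault(di, []).append(truths[ti].maturity)

    for ti, truth in enumerate(truths):
        if not _countable(truth.maturity, scheme):
            continue
        if ti in cover_det:
            counts.n_tp += 1
        else:
            counts.n_fn += 1

    for di in range(len(dets)):
        classes = covered_by_det.get(di, [])
        if not classes:
            counts.n_fp += 1
        elif any(_countable(c, scheme) for c in classes):
            continue  # credited once via the TPs it covers
        elif MaturityClass.PARTIALLY_MATURE in classes:
            counts.n_fp2 += 1
        elif MaturityClass.IMMATURE in classes:
            counts.n_fp1 += 1
        else:
            counts.n_dc += 1
    return counts


def precision_recall(counts: EvalCounts) -> tuple[Optional[float], Optional[float]]:
    """Precision and recall from taxonomy counts.

    FP1 and FP2 are folded into the false positives; DC never enters.  A
    zero denominator yields ``None`` (undefined), not 0 or 1.
    """
    nfp = counts.n_fp + counts.n_fp1 + counts.n_fp2
    precision = counts.n_tp / (counts.n_tp + nfp) if counts.n_tp + nfp > 0 else None
    recall = (
        counts.n_tp / (counts.n_tp + counts.n_fn)
        if counts.n_tp + counts.n_fn > 0
        else None
    )
    return precision, recall


# ---------------------------------------------------------------------------
# Dataset-level evaluation
# ---------------------------------------------------------------------------

class SceneLike(Protocol):
    """What a scene must expose: the image pair and its ground truth."""

    flash: RGBImage
    noflash: RGBImage
    composite: Optional[RGBImage]
    truth: "object"  # needs .objects: list[GroundTruthObject]


def _modality_image(scene: SceneLike, modality: str, fnf_params: FNFParams) -> RGBImage:
    if modality == "flash":
        return scene.flash
    if modality == "noflash":
        return scene.noflash
    if modality == "fnf":
        composite = getattr(scene, "composite", None)
        if composite is not None:
            return composite
        return compose_images(scene.flash, scene.noflash, fnf_params)
    raise ValueError(f"unknown modality {modality!r}")


def _scene_counts(
    scene: SceneLike,
    modality: str,
    detector_params: DetectorParams,
    eval_params: EvalParams,
    fnf_params: FNFParams,
    scheme: str,
    cluster_mode: str,
) -> EvalCounts:
    img = _modality_image(scene, modality, fnf_params)
    dets = detect(img, detector_params)
    truths = scene.truth.objects
    if cluster_mode == "cluster_credit":
        return cluster_credit_counts(dets, truths, scheme, eval_params)
    if cluster_mode == "per_object":
        return match_detections(dets, truths, scheme, eval_params)
    raise ValueError(f"unknown cluster_mode {cluster_mode!r}")


def evaluate_dataset(
    scenes: Sequence[SceneLike],
    detector_params: DetectorParams | None = None,
    eval_params: EvalParams | None = None,
    scheme: str = "strict",
    cluster_mode: str = "per_object",
    modality: str = "fnf",
    fnf_params: FNFParams | None = None,
) -> tuple[EvalResult, pd.DataFrame, dict[str, int]]:
    """Run the detector over a labeled dataset and accumulate counts.

    Returns the aggregate :class:`EvalResult`, a per-scene breakdown table,
    and the six-way category distribution over all scenes.
    """
    if len(scenes) == 0:
        raise ValueError("dataset is empty")
    detector_params = detector_params or DetectorParams()
    eval_params = eval_params or EvalParams()
    fnf_params = fnf_params or FNFParams()
    total = EvalCounts()
    rows = []
    for idx, scene in enumerate(scenes):
        truth = getattr(scene, "truth", None)
        if truth is None or getattr(truth, "objects", None) is None:
            name = getattr(scene, "scene_id", idx)
            raise ValueError(f"scene {name!r} has no ground-truth labels")
        counts = _scene_counts(
            scene, modality, detector_params, eval_params, fnf_params, scheme, cluster_mode
        )
        total = total + counts
        p, r = precision_recall(counts)
        rows.append(
            {
                "scene": getattr(scene, "scene_id", idx),
                "n_tp": counts.n_tp,
                "n_fp": counts.n_fp,
                "n_fn": counts.n_fn,
                "n_fp1": counts.n_fp1,
                "n_fp2": counts.n_fp2,
                "n_dc": counts.n_dc,
                "precision": p,
                "recall": r,
            }
        )
    precision, recall = precision_recall(total)
    result = EvalResult(
        counts=total,
        precision=precision,
        recall=recall,
        scheme=scheme,
        cluster_mode=cluster_mode,
    )
    return result, pd.DataFrame(rows), total.as_dict()


# ---------------------------------------------------------------------------
# Color-stability statistics
# ---------------------------------------------------------------------------

def labeled_pixel_stats(
    images: Sequence[RGBImage],
    truths_per_image: Sequence[Sequence[GroundTruthObject]],
    class_filter: MaturityClass = MaturityClass.MATURE,
    n_bins: int = 100,
) -> dict[str, np.ndarray | float | int]:
    """Hue/saturation distribution of fruit pixels of one maturity class.

    Hue is normalized to [0, 1] by dividing by 360 and saturation by 255;
    the returned ``hue_std`` / ``sat_std`` are population standard
    deviations on that normalized scale, and the histograms use ``n_bins``
    fixed bins over [0, 1].  Comparing these statistics between FNF
    composites and flash-only images quantifies how much ambient-light
    cancellation stabilizes fruit color.
    """
    if len(images) != len(truths_per_image):
        raise ValueError("images and truths_per_image must have equal length")
    hues: list[np.ndarray] = []
    sats: list[np.ndarray] = []
    for img, truths in zip(images, truths_per_image):
        mask = np.zeros(img.shape, dtype=bool)
        for truth in truths:
            if truth.maturity is class_filter:
                mask |= np.asarray(truth.mask, dtype=bool)
        if mask.any():
            hsv = rgb_to_hsv(img)
            hues.append(hsv.hue[mask] / 360.0)
            sats.append(hsv.saturation[mask] / 255.0)
    if not hues:
        raise ValueError(f"no labeled pixels of class {class_filter.value!r}")
    hue = np.concatenate(hues)
    sat = np.concatenate(sats)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return {
        "hue_hist": np.histogram(hue, bins=edges)[0],
        "sat_hist": np.histogram(sat, bins=edges)[0],
        "bin_edges": edges,
        "hue_std": float(np.std(hue)),
        "sat_std": float(np.std(sat)),
        "n_pixels": int(hue.size),
    }


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def sweep_thresholds(
    scenes: Sequence[SceneLike],
    grid: Sequence[DetectorParams],
    eval_params: EvalParams | None = None,
    scheme: str = "strict",
    cluster_mode: str = "per_object",
    modality: str = "fnf",
    fnf_params: FNFParams | None = None,
) -> pd.DataFrame:
    """Evaluate the dataset at every detector-parameter grid point.

    Returns one row per grid point (in grid order) with the parameter
    values, the aggregate counts and precision/recall — the raw material
    for precision-recall trade-off plots.
    """
    if len(grid) == 0:
        raise ValueError("parameter grid is empty")
    rows = []
    for params in grid:
        result, _, _ = evaluate_dataset(
            scenes, params, eval_params, scheme, cluster_mode, modality, fnf_params
        )
        rows.append(
            {
                "hue_min": params.hue_min,
                "hue_max": params.hue_max,
                "sat_min": params.sat_min,
                "sat_max": params.sat_max,
                "min_area_ref": params.min_area_ref,
                "n_tp": result.counts.n_tp,
                "n_fp": result.counts.n_fp,
                "n_fn": result.counts.n_fn,
                "precision": result.precision,
                "recall": result.recall,
            }
        )
    return pd.DataFrame(rows)
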