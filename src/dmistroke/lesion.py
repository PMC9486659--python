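"""Infarct-core segmentation and pooled ROC / descriptive lesion analysis.

Thresholding convention: ischemic tissue has *reduced* diffusivity, so a
voxel is lesion-positive when its score (ADC or d_ax_intra) falls **below**
the threshold.  ROC curves are built on voxels pooled across subjects
inside their brain masks, swept over all unique observed score values plus
±∞ (the exact empirical ROC), with AUC by trapezoid — which makes AUC equal
the Mann–Whitney concordance probability with half-credit for ties.  The
operating point maximizes Youden's J = sensitivity + specificity − 1; J
ties break toward the lower threshold (the more specific segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ParameterMaps, VoxelMask


def youden(sens: float, spec: float) -> float:
    """Youden's statistic J = sensitivity + specificity − 1."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sens + spec - 1.0


def threshold_segment(score_map: np.ndarray, tau: float, mask: VoxelMask,
                      direction: str = "below") -> VoxelMask:
    """Binary segmentation of in-mask voxels with score below (or above) ``tau``."""
    score_map = np.asarray(score_map, dtype=float)
    if score_map.shape != mask.data.shape:
        raise ValueError("score map and mask shapes disagree")
    if direction == "below":
        hit = score_map < tau
    elif direction == "above":
        hit = score_map > tau
    else:
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    return VoxelMask(hit & mask.data)


def combine_masks(a: VoxelMask, b: VoxelMask, mode: str) -> VoxelMask:
    """Voxelwise union (OR) or intersection (AND) of two congruent masks."""
    if a.data.shape != b.data.shape:
        raise ValueError("mask shapes disagree")
    if mode == "union":
        return VoxelMask(a.data | b.data)
    if mode == "intersection":
        return VoxelMask(a.data & b.data)
    raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")


def mirror_mask(mask: VoxelMask, clip_mask: VoxelMask | None = None) -> VoxelMask:
    """Reflect a mask across the mid-sagittal plane (x → W−1−x).

    Assumes a midline-aligned grid (the phantom guarantees this; no
    registration is performed).  An optional clip mask — typically the brain
    mask with CSF removed — intersects the flipped result.
    """
    flipped = mask.data[::-1, :, :].copy()
    if clip_mask is not None:
        flipped &= clip_mask.data
    return VoxelMask(flipped)


@dataclass
class RocResult:
    """Exact empirical ROC with its Youden-optimal operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    j_max: float
    optimal_threshold: float
    sens_at_opt: float
    spec_at_opt: float
    n_positive: int = 0
    n_negative: int = 0


def _pool(per_subject, truths, brain_masks):
    scores, labels = [], []
    for score_map, truth, brain in zip(per_subject, truths, brain_masks):
        score_map = np.asarray(score_map, dtype=float)
        if score_map.shape != truth.data.shape or score_map.shape != brain.data.shape:
            raise ValueError("per-subject map/mask shapes disagree")
        m = brain.data & np.isfinite(score_map)
        scores.append(score_map[m])
        labels.append(truth.data[m])
    return np.concatenate(scores), np.concatenate(labels)


def pooled_roc(score_maps, truth_masks, brain_masks) -> RocResult:
    """ROC for lesion-positive = score *below* threshold, voxels pooled
    across subjects.

    Parameters are equal-length sequences (or single items) of per-subject
    score maps, ground-truth lesion masks and brain masks; non-finite scores
    are excluded.  Raises if the pooled truth is empty or covers everything
    (sensitivity/specificity undefined).
    """
    if isinstance(score_maps, np.ndarray) and np.asarray(score_maps).ndim == 3:
        score_maps = [score_maps]
    if isinstance(truth_masks, VoxelMask):
        truth_masks = [truth_masks]
    if isinstance(brain_masks, VoxelMask):
        brain_masks = [brain_masks]
    scores, labels = _pool(score_maps, truth_masks, brain_masks)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pooled ground truth must contain both classes")

    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    thresholds = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    # positive := score < tau  (left-side search counts strictly-below values)
    sens = np.searchsorted(pos, thresholds, side="left") / n_pos
    spec = 1.0 - np.searchsorted(neg, thresholds, side="left") / n_neg
    auc = float(np.trapezoid(sens, 1.0 - spec))

    j = sens + spec - 1.0
    k = int(np.argmax(j))  # first = lowest threshold on ties
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=auc, j_max=float(j[k]),
                     optimal_threshold=float(thresholds[k]),
                     sens_at_opt=float(sens[k]), spec_at_opt=float(spec[k]),
                     n_positive=n_pos, n_negative=n_neg)


def lesion_statistics(maps: ParameterMaps, lesion: VoxelMask,
                      contra: VoxelMask) -> pd.DataFrame:
    """Mean and 5th/95th percentiles of every parameter, lesion vs mirrored
    contralateral side (linear-interpolation percentile convention).
    """
    if lesion.n_voxels == 0 or contra.n_voxels == 0:
        raise ValueError("lesion and contralateral masks must be non-empty")
    rows = []
    for name, arr in maps.items():
        for side, m in (("lesion", lesion), ("contra", contra)):
            vals = np.asarray(arr, dtype=float)[m.data]
            vals = vals[np.isfinite(vals)]
            rows.append({
                "parameter": name, "side": side,
                "mean": float(vals.mean()),
                "p5": float(np.percentile(vals, 5, method="linear")),
                "p95": float(np.percentile(vals, 95, method="linear")),
                "n_voxels": int(vals.size),
            })
    return pd.DataFrame(rows)


#: Ground-truth variant names in report order.
VARIANTS = ("dwi", "dmi", "union", "intersection")


def variant_masks(dwi_truth: VoxelMask, dmi_truth: VoxelMask) -> dict:
    """The four ground-truth variants: each rater mask, their union and
    their intersection (the two consensus truths)."""
    return {
        "dwi": dwi_truth,
        "dmi": dmi_truth,
        "union": combine_masks(dwi_truth, dmi_truth, "union"),
        "intersection": combine_masks(dwi_truth, dmi_truth, "intersection"),
    }


def roc_table(score_maps: dict, truth_variants: dict, brain_mask) -> pd.DataFrame:
    """ROC summary table: one row per (ground-truth variant, contrast).

    ``score_maps`` maps contrast name (e.g. ``"d_ax_intra"``, ``"adc"``) to a
    3D score map; ``truth_variants`` maps variant name to a truth mask.
    Columns mirror the standard ROC report layout:
    ground_truth_variant, contrast, auc, j_max, optimal_threshold, sens, spec.
    """
    rows = []
    for variant, truth in truth_variants.items():
        for contrast, smap in score_maps.items():
            r = pooled_roc([smap], [truth], [brain_mask])
            rows.append({
                "ground_truth_variant": variant,
                "contrast": contrast,
                "auc": r.auc,
                "j_max": r.j_max,
                "optimal_threshold": r.optimal_threshold,
                "sens": r.sens_at_opt,
                "spec": r.spec_at_opt,
            })
    return pd.DataFrame(rows)
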