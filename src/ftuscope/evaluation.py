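"""Segmentation and classification evaluation.

Segmentation is scored with the Dice similarity coefficient,
``2|A ∩ B| / (|A| + |B|)`` between ground-truth and predicted foreground
pixel sets; for multiclass masks the class-blind variant collapses every
nonzero label to foreground first.  Classification is scored per
ground-truth annotation by the predicted label at its *center pixel*
(hit = predicted label equals the annotation's class; a Background
prediction records a segmentation miss).  Per-image Dice scores can be
stratified by Gleason score (no tumor; low <= 6; medium = 7; high > 7)
and compared across model checkpoints with a Kruskal-Wallis omnibus test
followed by pairwise Dunn tests with Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .annotation_io import AnnotationSet, FTUAnnotation
from .errors import GeometryError
from .postprocess import annotation_footprint
from .vocabulary import BACKGROUND_ID, BACKGROUND_NAME, ControlledVocabulary

# ---------------------------------------------------------------------------
# Dice


def dice_binary(gt: np.ndarray, pred: np.ndarray) -> float:
    """Dice coefficient between two masks binarized as nonzero=foreground.

    Defined as 1.0 when both masks are empty (perfect agreement on
    absence); this case does not arise in practice but keeps the metric
    total.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch {gt.shape} vs {pred.shape}")
    a = gt != 0
    b = pred != 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def dice_multiclass_collapsed(gt: np.ndarray, pred: np.ndarray) -> float:
    """Class-blind Dice: every nonzero label counts as foreground."""
    return dice_binary(gt, pred)


# ---------------------------------------------------------------------------
# Center pixel and classification accuracy


def center_pixel(a: FTUAnnotation, shape: tuple[int, int] | None = None) -> tuple[int, int]:
    """Representative interior pixel ``(x, y)`` of an annotation.

    The pixel containing the polygon centroid, i.e. ``(floor(cx),
    floor(cy))``, when that pixel belongs to the annotation's raster
    footprint; otherwise (non-convex shapes whose centroid falls outside)
    the innermost footprint pixel by Euclidean distance transform, ties
    broken by smallest (row, col).
    """
    minx, miny, maxx, maxy = a.geometry.bounds
    if shape is None:
        shape = (int(math.ceil(maxy)) + 1, int(math.ceil(maxx)) + 1)
    foot = annotation_footprint(a, shape)
    if not foot.any():
        raise GeometryError(f"annotation {a.uuid} has zero raster area")
    cx, cy = a.geometry.centroid.x, a.geometry.centroid.y
    px, py = int(math.floor(cx)), int(math.floor(cy))
    if 0 <= py < shape[0] and 0 <= px < shape[1] and foot[py, px]:
        return (px, py)
    dist = ndimage.distance_transform_edt(foot)
    best = dist.max()
    rr, cc = np.nonzero(dist == best)
    i = np.lexsort((cc, rr))[0]
    return (int(cc[i]), int(rr[i]))


@dataclass
class ConfusionMatrix:
    """Ground-truth (rows) vs predicted (columns) annotation counts.

    Index 0 is Background: its column records segmentation failures
    (structures the model missed entirely); its row is unused for
    annotation-level scoring but kept so the matrix is square over
    vocabulary classes + Background.
    """

    class_ids: list[int]  # vocabulary class IDs, ascending (no background)
    counts: np.ndarray  # (K+1, K+1) ints; axis order: [Background, *class_ids]
    names: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[int]:
        return [BACKGROUND_ID, *self.class_ids]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_normalized(self) -> np.ndarray:
        """Each row scaled to sum to 1; all-zero rows stay all-zero."""
        c = self.counts.astype(float)
        sums = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(sums > 0, c / sums, 0.0)
        return norm

    def to_dataframe(self, normalized: bool = False) -> pd.DataFrame:
        names = self.names or [str(l) for l in self.labels]
        data = self.row_normalized if normalized else self.counts
        return pd.DataFrame(data, index=names, columns=names)


def classification_accuracy(
    gt_set: AnnotationSet,
    pred: np.ndarray,
    vocabulary: ControlledVocabulary,
) -> tuple[float, ConfusionMatrix]:
    """Center-pixel classification accuracy against a predicted mask.

    For each ground-truth annotation, reads the predicted label at the
    annotation's center pixel; a hit is an exact class match.  Accuracy
    is hits / total annotations.  Returns the accuracy and the full
    confusion matrix over vocabulary classes + Background.
    """
    pred = np.asarray(pred)
    class_ids = vocabulary.class_ids
    index = {BACKGROUND_ID: 0, **{cid: i + 1 for i, cid in enumerate(class_ids)}}
    counts = np.zeros((len(class_ids) + 1, len(class_ids) + 1), dtype=np.int64)
    hits = 0
    for a in gt_set:
        px, py = center_pixel(a, shape=pred.shape)
        if not (0 <= py < pred.shape[0] and 0 <= px < pred.shape[1]):
            raise ValueError(
                f"center pixel ({px}, {py}) of {a.uuid} outside predicted mask"
            )
        plabel = int(pred[py, px])
        if plabel not in index:
            raise ValueError(f"predicted label {plabel} not in vocabulary")
        counts[index[a.class_id], index[plabel]] += 1
        if plabel == a.class_id:
            hits += 1
    total = len(gt_set)
    accuracy = hits / total if total else 0.0
    names = [BACKGROUND_NAME] + [vocabulary.id_to_name(c) for c in class_ids]
    return accuracy, ConfusionMatrix(class_ids=class_ids, counts=counts, names=names)


def random_baseline_accuracy(n_classes: int) -> float:
    """Accuracy expected from uniform random class assignment: 1/K."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 / n_classes


# ---------------------------------------------------------------------------
# Grade stratification

STRATA = ("no_tumor", "low", "medium", "high")


def stratify_by_grade(gleason_score: int) -> str:
    """Map a Gleason score to its stratum.

    0 encodes no tumor; valid tumor scores are 6-10 (sum of the two
    dominant patterns).  low: <= 6, medium: = 7, high: > 7.
    """
    s = int(gleason_score)
    if s == 0:
        return "no_tumor"
    if s not in range(6, 11):
        raise ValueError(f"Gleason score must be 0 or 6..10, got {s}")
    if s <= 6:
        return "low"
    if s == 7:
        return "medium"
    return "high"


@dataclass
class DiceReport:
    """Per-image Dice scores with their arithmetic mean and grade strata."""

    per_image: dict[str, float]
    grade: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.per_image.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"Dice {v} for image {k} outside [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_image.values())))

    def by_stratum(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for img, d in self.per_image.items():
            out.setdefault(self.grade.get(img, "unknown"), []).append(d)
        return out


def dice_report(
    per_image: dict[str, float], gleason: dict[str, int] | None = None
) -> DiceReport:
    grade = {k: stratify_by_grade(v) for k, v in (gleason or {}).items()}
    return DiceReport(per_image=dict(per_image), grade=grade)


# ---------------------------------------------------------------------------
# Checkpoint comparison: Kruskal-Wallis + Dunn/Bonferroni


@dataclass
class GroupComparison:
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adjusted


def compare_dice_distributions(groups: dict[str, list[float]]) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus pairwise Dunn tests.

    Dunn's z statistic uses pooled mid-ranks with tie correction; raw
    two-sided p-values are Bonferroni-adjusted over all unordered pairs
    (``p_adj = min(1, p * n_pairs)``).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    try:
        h_stat, omnibus_p = stats.kruskal(*data)
    except ValueError:
        # All values identical across every group: no evidence of separation.
        h_stat, omnibus_p = 0.0, 1.0

    pooled = np.concatenate(data)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for name, vals in zip(names, data):
        mean_ranks[name] = ranks[i : i + len(vals)].mean()
        i += len(vals)
    # Tie correction term for the rank variance.
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * len(pairs)),
            }
        )
    return GroupComparison(
        omnibus_statistic=float(h_stat),
        omnibus_p=float(omnibus_p),
        pairwise=pd.DataFrame(rows),
    )
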