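"""Human-in-the-loop curation-efficiency bookkeeping.

For each curated image, ``Am`` counts annotations that required manual
segmentation effort - drawn from scratch (``manual``) or AI-generated
then manually edited (``auto_edited``) - and ``At`` is the total
annotation count.  Confirmation without editing (``auto_checked``) is
not segmentation effort and does not count toward Am.  With ``t`` the
assumed manual segmentation time per annotation (default 10 s):

* fraction of manual annotations  Pm = Am / At
* efficiency gain                 1 / Pm   (infinite when Am = 0)
* fraction fully AI generated     1 - Pm
* time saved                      t * (At - Am)  seconds

Quantities are computed per image, then averaged arithmetically;
infinite gains are excluded from the mean with an explicit tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .annotation_io import AnnotationSet, AnnotationType

DEFAULT_SECONDS_PER_ANNOTATION = 10.0

MANUAL_EFFORT_TYPES = frozenset({AnnotationType.MANUAL, AnnotationType.AUTO_EDITED})


@dataclass(frozen=True)
class ImageEfficiency:
    """Per-image efficiency quantities derived from (Am, At, t)."""

    image_id: str
    manual_count: int  # Am
    total_count: int  # At
    seconds_per_annotation: float  # t

    def __post_init__(self) -> None:
        if self.total_count < 1:
            raise ValueError(f"{self.image_id}: total annotation count must be >= 1")
        if not (0 <= self.manual_count <= self.total_count):
            raise ValueError(
                f"{self.image_id}: Am={self.manual_count} outside [0, At={self.total_count}]"
            )

    @property
    def manual_fraction(self) -> float:
        """Pm = Am / At."""
        return self.manual_count / self.total_count

    @property
    def efficiency_gain(self) -> float:
        """1 / Pm; infinite when no annotation needed manual effort."""
        if self.manual_count == 0:
            return math.inf
        return self.total_count / self.manual_count

    @property
    def fully_ai_fraction(self) -> float:
        """1 - Pm."""
        return 1.0 - self.manual_fraction

    @property
    def time_saved_seconds(self) -> float:
        """t * (At - Am)."""
        return self.seconds_per_annotation * (self.total_count - self.manual_count)

    def as_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "Am": self.manual_count,
            "At": self.total_count,
            "t_seconds": self.seconds_per_annotation,
            "manual_fraction": self.manual_fraction,
            "efficiency_gain": self.efficiency_gain,
            "fully_ai_fraction": self.fully_ai_fraction,
            "time_saved_seconds": self.time_saved_seconds,
        }


def efficiency_from_counts(
    image_id: str,
    manual_count: int,
    total_count: int,
    t: float = DEFAULT_SECONDS_PER_ANNOTATION,
) -> ImageEfficiency:
    return ImageEfficiency(image_id, int(manual_count), int(total_count), float(t))


def efficiency_from_annotations(
    aset: AnnotationSet, t: float = DEFAULT_SECONDS_PER_ANNOTATION
) -> ImageEfficiency:
    """Derive (Am, At) from annotation provenance types."""
    if len(aset) == 0:
        raise ValueError(f"annotation set {aset.image_id!r} is empty")
    am = sum(1 for a in aset if a.annotation_type in MANUAL_EFFORT_TYPES)
    return ImageEfficiency(aset.image_id, am, len(aset), float(t))


def efficiency_from_action_log(
    records: list[dict], t: float = DEFAULT_SECONDS_PER_ANNOTATION
) -> list[ImageEfficiency]:
    """Reconstruct per-image (Am, At) from a JSONL action log.

    The final provenance type per uuid (last ``to_type`` seen in log
    order) decides whether it counts toward Am.
    """
    final: dict[str, dict[str, str]] = {}
    for rec in records:
        img = rec["image_id"]
        final.setdefault(img, {})[rec["uuid"]] = rec["to_type"]
    out = []
    for img in sorted(final):
        types = final[img].values()
        am = sum(1 for tt in types if AnnotationType(tt) in MANUAL_EFFORT_TYPES)
        out.append(ImageEfficiency(img, am, len(final[img]), float(t)))
    return out


@dataclass
class EfficiencySummary:
    """Cross-image means of the per-image efficiency quantities."""

    n_images: int
    mean_manual_fraction: float
    mean_efficiency_gain: float  # over images with finite gain
    n_infinite_gain: int
    mean_fully_ai_fraction: float
    mean_time_saved_seconds: float
    pooled_gain: float  # 1 / (sum Am / sum At): differs from mean of gains
    per_image: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "mean_manual_fraction": self.mean_manual_fraction,
            "mean_efficiency_gain": self.mean_efficiency_gain,
            "n_infinite_gain": self.n_infinite_gain,
            "mean_fully_ai_fraction": self.mean_fully_ai_fraction,
            "mean_time_saved_seconds": self.mean_time_saved_seconds,
            "pooled_gain": self.pooled_gain,
        }


def aggregate_efficiency(per_image: list[ImageEfficiency]) -> EfficiencySummary:
    """Average per-image quantities (the headline aggregation).

    The mean of per-image gains is not ``1 / mean(Pm)`` in general
    (Jensen's inequality), so the pooled gain is reported alongside,
    clearly labeled.  Infinite per-image gains (Am = 0) are excluded
    from the gain mean and tallied.
    """
    if not per_image:
        raise ValueError("need at least one image")

    def _mean(vals):
        return math.fsum(vals) / len(vals)  # order-invariant

    gains = [e.efficiency_gain for e in per_image]
    finite = [g for g in gains if math.isfinite(g)]
    total_am = sum(e.manual_count for e in per_image)
    total_at = sum(e.total_count for e in per_image)
    table = pd.DataFrame([e.as_dict() for e in per_image])
    return EfficiencySummary(
        n_images=len(per_image),
        mean_manual_fraction=_mean([e.manual_fraction for e in per_image]),
        mean_efficiency_gain=_mean(finite) if finite else math.inf,
        n_infinite_gain=len(gains) - len(finite),
        mean_fully_ai_fraction=_mean([e.fully_ai_fraction for e in per_image]),
        mean_time_saved_seconds=_mean([e.time_saved_seconds for e in per_image]),
        pooled_gain=(total_at / total_am) if total_am else math.inf,
        per_image=table,
    )
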