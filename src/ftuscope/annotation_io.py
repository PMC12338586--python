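"""Provenance-typed FTU annotations and their GeoJSON persistence.

Each functional tissue unit (FTU) is one polygon in 0-based image pixel
coordinates (x rightward, y downward, GeoJSON position ``[x, y]``) with a
UUID, a vocabulary class, free-form string metadata, a review flag, and a
provenance *annotation type* recording the degree of automation:

* ``auto`` - created by an AI model,
* ``auto_checked`` - AI-created, confirmed by a pathologist,
* ``auto_edited`` - AI-created, edited by a pathologist,
* ``manual`` - created manually by a pathologist.

Files are RFC 7946 FeatureCollections.  ftuscope's own properties live
under a nested ``"miroscope"`` object so they cannot collide with other
GeoJSON dialects; a compatibility reader also accepts the same keys flat
in ``properties``.  Serialization is canonical - sorted keys, compact
separators, shortest-round-trip floats - so write -> read -> write is a
fixed point byte for byte.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import uuid as _uuid
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
from shapely.geometry import Polygon
from shapely.validation import make_valid

from .errors import GeometryError, SchemaError, VocabularyError
from .vocabulary import BACKGROUND_ID, ControlledVocabulary


class AnnotationType(str, Enum):
    """Provenance of an annotation, from fully automatic to fully manual."""

    AUTO = "auto"
    AUTO_CHECKED = "auto_checked"
    AUTO_EDITED = "auto_edited"
    MANUAL = "manual"


def _check_polygon(geom: Polygon, *, context: str = "") -> Polygon:
    """Validate a polygon, tolerating rings that self-touch at a point.

    Pixel-boundary tracing of 8-connected components can produce rings
    that revisit a corner vertex (a "pinch"); those rasterize exactly and
    are accepted.  True self-crossings change the area under repair and
    are rejected, as are empty or zero-area geometries.
    """
    if geom is None or geom.is_empty:
        raise GeometryError(f"empty geometry{context}")
    if not isinstance(geom, Polygon):
        raise GeometryError(f"geometry must be a Polygon, got {geom.geom_type}{context}")
    area = geom.area
    if area <= 0:
        raise GeometryError(f"polygon has zero area{context}")
    if not geom.is_valid:
        repaired = make_valid(geom)
        if not math.isclose(repaired.area, area, rel_tol=1e-9, abs_tol=1e-9):
            raise GeometryError(f"self-intersecting polygon{context}")
    return geom


def _orient_canonical(geom: Polygon) -> Polygon:
    """Exterior counter-clockwise (positive shoelace), holes clockwise."""
    ext = list(geom.exterior.coords)
    if _shoelace(ext) < 0:
        ext = ext[::-1]
    holes = []
    for ring in geom.interiors:
        coords = list(ring.coords)
        if _shoelace(coords) > 0:
            coords = coords[::-1]
        holes.append(coords)
    return Polygon(ext, holes)


def _shoelace(coords) -> float:
    s = 0.0
    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
        s += x1 * y2 - x2 * y1
    return 0.5 * s


@dataclass(frozen=True)
class FTUAnnotation:
    """One polygonal FTU annotation with provenance and metadata."""

    uuid: str
    class_id: int
    class_name: str
    annotation_type: AnnotationType
    geometry: Polygon
    metadata: tuple[tuple[str, str], ...] = ()
    flagged_for_review: bool = False

    def __post_init__(self) -> None:
        _uuid.UUID(self.uuid)  # raises ValueError on a malformed UUID
        _check_polygon(self.geometry, context=f" (uuid {self.uuid})")
        object.__setattr__(self, "geometry", _orient_canonical(self.geometry))
        if isinstance(self.metadata, dict):
            object.__setattr__(self, "metadata", tuple(sorted(self.metadata.items())))
        else:
            object.__setattr__(self, "metadata", tuple(sorted(self.metadata)))

    @property
    def metadata_dict(self) -> dict[str, str]:
        return dict(self.metadata)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FTUAnnotation):
            return NotImplemented
        return (
            self.uuid == other.uuid
            and self.class_id == other.class_id
            and self.class_name == other.class_name
            and self.annotation_type == other.annotation_type
            and self.metadata == other.metadata
            and self.flagged_for_review == other.flagged_for_review
            and _coords(self.geometry) == _coords(other.geometry)
        )

    __hash__ = None  # type: ignore[assignment]


def _coords(geom: Polygon):
    return (
        tuple(geom.exterior.coords),
        tuple(tuple(r.coords) for r in geom.interiors),
    )


@dataclass
class AnnotationSet:
    """All FTU annotations of one image, tied to a vocabulary reference."""

    image_id: str
    annotations: list[FTUAnnotation] = field(default_factory=list)
    vocabulary_ref: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a in self.annotations:
            if a.uuid in seen:
                raise SchemaError(f"duplicate uuid {a.uuid} in annotation set")
            seen.add(a.uuid)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)


def new_uuid(rng: np.random.Generator | None = None) -> str:
    """A version-4 UUID, optionally drawn from a seeded generator."""
    if rng is None:
        return str(_uuid.uuid4())
    n = int.from_bytes(rng.bytes(16), "big")
    n &= ~(0xF << 76)
    n |= 0x4 << 76  # version 4
    n &= ~(0x3 << 62)
    n |= 0x2 << 62  # RFC 4122 variant
    return str(_uuid.UUID(int=n))


# ---------------------------------------------------------------------------
# GeoJSON persistence


def _polygon_to_geojson(geom: Polygon) -> dict:
    rings = [[list(xy) for xy in geom.exterior.coords]]
    for ring in geom.interiors:
        rings.append([list(xy) for xy in ring.coords])
    return {"type": "Polygon", "coordinates": rings}


def _polygon_from_geojson(g: dict, *, where: str) -> Polygon:
    if not isinstance(g, dict) or g.get("type") != "Polygon":
        raise SchemaError(f"{where}: geometry must be a GeoJSON Polygon")
    coords = g.get("coordinates")
    if not coords:
        raise SchemaError(f"{where}: Polygon has no coordinates")
    shell = [tuple(p) for p in coords[0]]
    holes = [[tuple(p) for p in ring] for ring in coords[1:]]
    return Polygon(shell, holes)


def annotation_to_feature(a: FTUAnnotation) -> dict:
    props = {
        "miroscope": {
            "annotation_type": a.annotation_type.value,
            "class_id": a.class_id,
            "class_name": a.class_name,
            "flagged_for_review": a.flagged_for_review,
            "metadata": dict(a.metadata),
            "uuid": a.uuid,
        }
    }
    return {
        "type": "Feature",
        "geometry": _polygon_to_geojson(a.geometry),
        "properties": props,
    }


_REQUIRED = ("uuid", "class_id", "annotation_type")


def feature_to_annotation(
    feat: dict, vocabulary: ControlledVocabulary, index: int
) -> FTUAnnotation:
    where = f"feature {index}"
    props = feat.get("properties") or {}
    body = props.get("miroscope")
    if body is None:
        # Compatibility: flat properties carrying the same keys.
        body = props
    for key in _REQUIRED:
        if key not in body:
            raise SchemaError(f"{where}: missing required property {key!r}")
    type_str = body["annotation_type"]
    try:
        atype = AnnotationType(type_str)
    except ValueError:
        legal = ", ".join(t.value for t in AnnotationType)
        raise SchemaError(
            f"{where}: annotation_type {type_str!r} is not one of {legal}"
        ) from None
    class_id = int(body["class_id"])
    try:
        expected_name = vocabulary.id_to_name(class_id)
    except VocabularyError as exc:
        raise VocabularyError(f"{where}: {exc}") from exc
    class_name = body.get("class_name", expected_name)
    if class_name != expected_name:
        raise VocabularyError(
            f"{where}: class_name {class_name!r} does not match vocabulary "
            f"name {expected_name!r} for class ID {class_id}"
        )
    geom = _polygon_from_geojson(feat.get("geometry"), where=where)
    metadata = body.get("metadata", {})
    return FTUAnnotation(
        uuid=str(body["uuid"]),
        class_id=class_id,
        class_name=class_name,
        annotation_type=atype,
        geometry=geom,
        metadata=tuple(sorted((str(k), str(v)) for k, v in dict(metadata).items())),
        flagged_for_review=bool(body.get("flagged_for_review", False)),
    )


def write_geojson(aset: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as a canonical GeoJSON FeatureCollection."""
    seen: set[str] = set()
    for a in aset.annotations:
        if a.uuid in seen:
            raise SchemaError(f"refusing to write duplicate uuid {a.uuid}")
        seen.add(a.uuid)
    doc = {
        "type": "FeatureCollection",
        "features": [annotation_to_feature(a) for a in aset.annotations],
        "miroscope": {
            "image_id": aset.image_id,
            "vocabulary_ref": aset.vocabulary_ref,
        },
    }
    Path(path).write_text(
        json.dumps(doc, sort_keys=True, separators=(",", ":"), ensure_ascii=False)
        + "\n",
        encoding="utf-8",
    )


def read_geojson(path: str | Path, vocabulary: ControlledVocabulary) -> AnnotationSet:
    """Read a FeatureCollection written by :func:`write_geojson` (or the
    flat-properties dialect) into an AnnotationSet."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    header = doc.get("miroscope", {})
    annotations = [
        feature_to_annotation(f, vocabulary, i)
        for i, f in enumerate(doc.get("features", []))
    ]
    return AnnotationSet(
        image_id=str(header.get("image_id", path.stem)),
        annotations=annotations,
        vocabulary_ref=str(header.get("vocabulary_ref", "")),
    )


# ---------------------------------------------------------------------------
# Curation actions and provenance transitions


def apply_curation_action(
    a: FTUAnnotation,
    action: str,
    *,
    geometry: Polygon | None = None,
    class_id: int | None = None,
    vocabulary: ControlledVocabulary | None = None,
) -> FTUAnnotation:
    """Apply a curation action, returning a new annotation.

    Provenance transitions: ``auto`` + confirm -> ``auto_checked``;
    ``auto``/``auto_checked`` + any edit -> ``auto_edited``;
    ``manual`` and ``auto_edited`` absorb further confirms and edits
    without changing type.  The uuid is preserved.
    """
    t = a.annotation_type
    if action == "confirm":
        new_type = AnnotationType.AUTO_CHECKED if t is AnnotationType.AUTO else t
        return replace(a, annotation_type=new_type)
    if action == "edit_geometry":
        if geometry is None:
            raise ValueError("edit_geometry requires a replacement polygon")
        _check_polygon(geometry, context=f" (uuid {a.uuid})")
        new_type = _edited_type(t)
        return replace(a, geometry=geometry, annotation_type=new_type)
    if action == "edit_class":
        if class_id is None:
            raise ValueError("edit_class requires a class ID")
        if vocabulary is None:
            raise ValueError("edit_class requires the vocabulary to resolve the name")
        name = vocabulary.id_to_name(class_id)
        if class_id == BACKGROUND_ID:
            raise VocabularyError("cannot assign Background to an annotation")
        new_type = _edited_type(t)
        return replace(a, class_id=class_id, class_name=name, annotation_type=new_type)
    raise ValueError(f"unknown curation action {action!r}")


def _edited_type(t: AnnotationType) -> AnnotationType:
    if t in (AnnotationType.AUTO, AnnotationType.AUTO_CHECKED):
        return AnnotationType.AUTO_EDITED
    return t  # manual stays manual; auto_edited stays auto_edited


def create_manual(
    geometry: Polygon,
    class_id: int,
    vocabulary: ControlledVocabulary,
    *,
    metadata: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> FTUAnnotation:
    """Create a pathologist-drawn (``manual``) annotation with a fresh UUID."""
    return FTUAnnotation(
        uuid=new_uuid(rng),
        class_id=class_id,
        class_name=vocabulary.id_to_name(class_id),
        annotation_type=AnnotationType.MANUAL,
        geometry=geometry,
        metadata=tuple(sorted((metadata or {}).items())),
    )


def flag_for_review(a: FTUAnnotation, flag: bool) -> FTUAnnotation:
    """Set the review flag; every other field is untouched."""
    return replace(a, flagged_for_review=bool(flag))


# ---------------------------------------------------------------------------
# Action log (JSONL)


def append_action_log(
    path: str | Path,
    records: Iterable[dict],
) -> None:
    """Append action records to a JSONL log.

    Each record carries ``timestamp, image_id, uuid, action, from_type,
    to_type``; a missing timestamp is filled with the current UTC time.
    """
    with open(path, "a", encoding="utf-8") as fh:
        for rec in records:
            rec = dict(rec)
            rec.setdefault(
                "timestamp",
                _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
            )
            fh.write(json.dumps(rec, sort_keys=True, ensure_ascii=False) + "\n")


def read_action_log(path: str | Path) -> list[dict]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}: line {i + 1} is not valid JSON") from exc
    return records
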