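"""Post-process stitched label masks and vectorize them into annotations.

The cleaning pipeline mirrors what is done to raw model output before it
reaches a curator: fill enclosed background holes, then drop objects
below a pixel-area threshold (default 2000 px, strict ``<``).  Objects
are maximal 8-connected same-class components; hole detection uses
4-connected background, the standard complementary pair.

``mask_to_annotations`` traces each surviving component along pixel-corner
boundaries into a polygon annotation of provenance type ``auto``, such
that re-rasterizing the polygons reproduces the mask exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from ._geometry import polygon_rings, rasterize_rings, trace_binary
from .annotation_io import AnnotationSet, AnnotationType, FTUAnnotation, new_uuid
from .vocabulary import ControlledVocabulary

DEFAULT_MIN_AREA = 2000

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class InstanceComponent:
    """One maximal 8-connected same-class object in a label mask."""

    class_id: int
    pixel_count: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    binary: np.ndarray  # crop of shape (r1-r0, c1-c0)

    @property
    def top_left_pixel(self) -> tuple[int, int]:
        """First foreground pixel in row-major order (global coords)."""
        rr, cc = np.nonzero(self.binary)
        i = np.lexsort((cc, rr))[0]
        return (self.bbox[0] + int(rr[i]), self.bbox[1] + int(cc[i]))


def extract_instances(mask: np.ndarray) -> list[InstanceComponent]:
    """Partition nonzero pixels into 8-connected same-class components.

    Deterministic order: ascending class_id, then row-major top-left
    pixel within each class.
    """
    mask = np.asarray(mask)
    out: list[InstanceComponent] = []
    for cid in np.unique(mask):
        if cid == 0:
            continue
        lab, n = ndimage.label(mask == cid, structure=_EIGHT)
        slices = ndimage.find_objects(lab)
        comps = []
        for i, sl in enumerate(slices, start=1):
            binary = lab[sl] == i
            bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
            comp = InstanceComponent(
                class_id=int(cid),
                pixel_count=int(binary.sum()),
                bbox=bbox,
                binary=binary,
            )
            comps.append(comp)
        comps.sort(key=lambda c: c.top_left_pixel)
        out.extend(comps)
    return out


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background holes enclosed by each same-class component.

    A hole is a 4-connected background region unreachable from the image
    border without crossing the component.  Filling is per component, so
    a structure of one class nested inside another class's hole is never
    overwritten: only pixels that are background are relabeled.
    """
    mask = np.asarray(mask)
    out = mask.copy()
    for comp in extract_instances(mask):
        r0, c0, r1, c1 = comp.bbox
        filled = ndimage.binary_fill_holes(comp.binary)
        new = filled & ~comp.binary
        if not new.any():
            continue
        region = out[r0:r1, c0:c1]
        region[new & (region == 0)] = comp.class_id
    return out


def filter_small(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Remove components whose pixel count is strictly below ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask)
    out = mask.copy()
    for comp in extract_instances(mask):
        if comp.pixel_count < min_area:
            r0, c0, r1, c1 = comp.bbox
            region = out[r0:r1, c0:c1]
            region[comp.binary] = 0
    return out


def postprocess_mask(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Standard cleaning order: fill holes, then area-filter."""
    return filter_small(fill_holes(mask), min_area)


def component_polygon(comp: InstanceComponent) -> Polygon:
    """Trace one component into a pixel-corner polygon in global coords."""
    polys = trace_binary(comp.binary)
    assert len(polys) == 1, "an 8-connected component traces to one polygon"
    ext, holes = polys[0]
    r0, c0 = comp.bbox[0], comp.bbox[1]
    shift = lambda ring: [(x + c0, y + r0) for x, y in ring]  # noqa: E731
    return Polygon(shift(ext), [shift(h) for h in holes])


def mask_to_annotations(
    mask: np.ndarray,
    vocabulary: ControlledVocabulary,
    *,
    image_id: str = "",
    vocabulary_ref: str = "",
    annotation_type: AnnotationType = AnnotationType.AUTO,
    rng: np.random.Generator | None = None,
) -> AnnotationSet:
    """Vectorize a (post-processed) mask into one annotation per component.

    Polygons follow pixel-corner boundaries, so rasterizing them with the
    package's half-open conventions reproduces the component's pixels
    exactly.  Annotations get fresh UUIDs (seeded via ``rng`` for
    reproducible pipelines) and provenance type ``auto`` by default.
    """
    annotations = []
    for comp in extract_instances(np.asarray(mask)):
        poly = component_polygon(comp)
        annotations.append(
            FTUAnnotation(
                uuid=new_uuid(rng),
                class_id=comp.class_id,
                class_name=vocabulary.id_to_name(comp.class_id),
                annotation_type=annotation_type,
                geometry=poly,
            )
        )
    return AnnotationSet(
        image_id=image_id, annotations=annotations, vocabulary_ref=vocabulary_ref
    )


def annotation_footprint(a: FTUAnnotation, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster footprint of one annotation on an image canvas."""
    rings = [list(a.geometry.exterior.coords)] + [
        list(r.coords) for r in a.geometry.interiors
    ]
    return rasterize_rings(rings, shape)


__all__ = [
    "DEFAULT_MIN_AREA",
    "InstanceComponent",
    "extract_instances",
    "fill_holes",
    "filter_small",
    "postprocess_mask",
    "component_polygon",
    "mask_to_annotations",
    "annotation_footprint",
    "polygon_rings",
]
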