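"""Seeded generator of H&E-like test images with gland-style FTUs.

The generator is the package's no-download test substrate: it lays out
non-overlapping, vocabulary-labeled structures on a canvas and returns a
mutually consistent triple (RGB image, ground-truth LabelMask, GeoJSON
AnnotationSet).  Structure morphology echoes what each term means in
tissue - single-lumen rings for well-formed glands, multi-lumen blobs for
cribriform patterns, lumen-free solid nests for high-grade patterns, thin
elongated profiles for nerves and vessels - but shapes are perturbed
ellipses, not learned textures: the generator exercises pipeline
mechanics, it makes no realism claim.  Lumens are rendered in the RGB
image only; the mask and polygons cover the whole structure, as a
curator would outline it, so ground truth is stable under hole filling.

All randomness flows through one ``numpy`` Generator seeded from the
spec, consumed in a documented order (per structure: placement, size,
aspect, rotation, boundary modulation, lumens; then image texture), so a
seed fully determines every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from ._geometry import polygon_rings, rasterize_rings, trace_binary
from .annotation_io import AnnotationSet, AnnotationType, FTUAnnotation, new_uuid
from .errors import CapacityError, GeometryError
from .vocabulary import ControlledVocabulary, default_prostate_vocabulary

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic tissue image.

    ``diameter_range`` bounds the minor-axis diameter of each structure
    in pixels; the default (60, 96) keeps every structure comfortably
    above the 2000 px post-processing area threshold.  ``class_counts``
    maps vocabulary class IDs to the number of structures requested.
    """

    image_size: tuple[int, int] = (512, 512)
    class_counts: dict[int, int] = field(
        default_factory=lambda: {1: 2, 4: 2, 5: 1, 14: 1, 17: 1}
    )
    diameter_range: tuple[int, int] = (60, 96)
    lumen_probability: float = 0.9
    lumen_count_range: tuple[int, int] = (3, 6)  # for cribriform morphology
    noise_level: float = 4.0
    palette: dict[int, tuple[int, int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if self.diameter_range[0] < 8:
            raise ValueError("minimum structure diameter is 8 px")
        if self.diameter_range[0] > self.diameter_range[1]:
            raise ValueError("diameter_range must be (min, max)")


def _morphology(vocab: ControlledVocabulary, class_id: int) -> str:
    term = vocab.term(class_id)
    text = " ".join(term.category_path).lower() + " " + term.name.lower()
    if "cribriform" in text:
        return "cribriform"
    if "nerve" in text or "vascular" in text:
        return "elongated"
    if "gp5" in text or "solid" in text or "comedo" in text or "cords" in text:
        return "solid"
    if "glandular" in text:
        return "luminal"
    return "blob"  # inflammation, artifact, anything uncategorized


def _shape_raster(
    rng: np.random.Generator, minor_d: float, aspect: float, theta: float,
    amp: float, k: int, phase: float,
) -> np.ndarray:
    """Binary raster of a rotated, radially perturbed ellipse."""
    b = minor_d / 2.0
    a = b * aspect
    half = int(np.ceil(a * (1 + amp))) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    u = np.cos(theta) * xx + np.sin(theta) * yy
    v = -np.sin(theta) * xx + np.cos(theta) * yy
    phi = np.arctan2(v / b, u / a)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    inside = rho <= (1.0 + amp * np.sin(k * phi + phase))
    # Keep the largest 8-connected piece in case the modulation pinches.
    lab, n = ndimage.label(inside, structure=_EIGHT)
    if n > 1:
        sizes = ndimage.sum_labels(inside, lab, index=range(1, n + 1))
        inside = lab == (1 + int(np.argmax(sizes)))
    rows = np.any(inside, axis=1)
    cols = np.any(inside, axis=0)
    return inside[np.ix_(rows, cols)]


def _default_color(class_id: int) -> tuple[int, int, int]:
    rng = np.random.default_rng(1000 + class_id)
    # H&E-ish purples and pinks, darker than the background.
    base = np.array([170, 110, 170], dtype=float)
    jitter = rng.integers(-45, 45, 3)
    return tuple(int(np.clip(v, 40, 215)) for v in base + jitter)


@dataclass
class _Placed:
    class_id: int
    bbox: tuple[int, int, int, int]
    binary: np.ndarray
    morphology: str


def generate(
    spec: SyntheticSpec,
    vocabulary: ControlledVocabulary | None = None,
    *,
    annotation_type: AnnotationType = AnnotationType.MANUAL,
    max_tries: int = 300,
) -> tuple[np.ndarray, np.ndarray, AnnotationSet]:
    """Generate one synthetic image with matching mask and annotations.

    Structures are placed by rejection sampling with at least one pixel
    of background between any two, so each is its own 8-connected
    component and ``rasterize(annotations) == mask`` exactly.  Raises
    :class:`CapacityError` when a structure cannot be placed within
    ``max_tries`` attempts.
    """
    vocab = vocabulary or default_prostate_vocabulary()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    mask = np.zeros((h, w), dtype=np.uint16)
    blocked = np.zeros((h, w), dtype=bool)  # existing structures, dilated
    placed: list[_Placed] = []

    for class_id in sorted(spec.class_counts):
        count = spec.class_counts[class_id]
        morph = _morphology(vocab, class_id)
        for idx in range(count):
            ok = False
            for _ in range(max_tries):
                minor_d = rng.uniform(*spec.diameter_range)
                if morph == "elongated":
                    # Thin profile, but wide enough that the structure still
                    # clears the default 2000 px post-processing threshold.
                    minor_d = max(36.0, minor_d / 2.5)
                    aspect = rng.uniform(3.0, 4.5)
                else:
                    aspect = rng.uniform(1.0, 1.5)
                theta = rng.uniform(0, np.pi)
                amp = rng.uniform(0.03, 0.08)
                k = int(rng.integers(3, 7))
                phase = rng.uniform(0, 2 * np.pi)
                shape = _shape_raster(rng, minor_d, aspect, theta, amp, k, phase)
                sh, sw = shape.shape
                if sh + 2 >= h or sw + 2 >= w:
                    continue
                r0 = int(rng.integers(1, h - sh - 1))
                c0 = int(rng.integers(1, w - sw - 1))
                if (blocked[r0 : r0 + sh, c0 : c0 + sw] & shape).any():
                    continue
                mask[r0 : r0 + sh, c0 : c0 + sw][shape] = class_id
                pad = 2  # 2 px clearance keeps placed structures 8-disconnected
                grown = ndimage.binary_dilation(
                    np.pad(shape, pad), structure=_EIGHT, iterations=pad
                )
                pr0, pc0 = r0 - pad, c0 - pad
                pr1, pc1 = r0 + sh + pad, c0 + sw + pad
                gr0, gc0 = max(0, pr0), max(0, pc0)
                gr1, gc1 = min(h, pr1), min(w, pc1)
                blocked[gr0:gr1, gc0:gc1] |= grown[
                    gr0 - pr0 : grown.shape[0] - (pr1 - gr1),
                    gc0 - pc0 : grown.shape[1] - (pc1 - gc1),
                ]
                placed.append(_Placed(class_id, (r0, c0, r0 + sh, c0 + sw), shape, morph))
                ok = True
                break
            if not ok:
                raise CapacityError(
                    f"could not place structure {idx + 1}/{count} of class "
                    f"{class_id} within {max_tries} tries"
                )

    image = _render(rng, spec, mask, placed)
    annotations = []
    for p in placed:
        polys = trace_binary(p.binary)
        assert len(polys) == 1
        ext, holes = polys[0]
        r0, c0 = p.bbox[0], p.bbox[1]
        shift = lambda ring: [(x + c0, y + r0) for x, y in ring]  # noqa: E731
        geom = Polygon(shift(ext), [shift(hh) for hh in holes])
        annotations.append(
            FTUAnnotation(
                uuid=new_uuid(rng),
                class_id=p.class_id,
                class_name=vocab.id_to_name(p.class_id),
                annotation_type=annotation_type,
                geometry=geom,
            )
        )
    aset = AnnotationSet(
        image_id=f"synthetic-{spec.seed}",
        annotations=annotations,
        vocabulary_ref=vocab.organ,
    )
    return image, mask, aset


def _render(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    mask: np.ndarray,
    placed: list[_Placed],
) -> np.ndarray:
    h, w = mask.shape
    base = np.array([243.0, 238.0, 242.0])
    image = base[None, None, :] + rng.normal(0, spec.noise_level, (h, w, 3))
    palette = spec.palette or {}
    for p in placed:
        color = np.array(palette.get(p.class_id) or _default_color(p.class_id), float)
        r0, c0, r1, c1 = p.bbox
        region = image[r0:r1, c0:c1]
        tint = color[None, None, :] + rng.normal(0, 6.0, (r1 - r0, c1 - c0, 3))
        region[p.binary] = tint[p.binary]
        if p.morphology in ("luminal", "cribriform") and rng.random() < spec.lumen_probability:
            n_lumen = (
                1
                if p.morphology == "luminal"
                else int(rng.integers(*spec.lumen_count_range))
            )
            _carve_lumens(rng, image, p, n_lumen)
    return np.clip(image, 0, 255).astype(np.uint8)


def _carve_lumens(
    rng: np.random.Generator, image: np.ndarray, p: _Placed, n_lumen: int
) -> None:
    """Paint near-white lumen ellipses inside a gland (image only)."""
    r0, c0, r1, c1 = p.bbox
    sh, sw = p.binary.shape
    inner = ndimage.binary_erosion(p.binary, structure=_EIGHT, iterations=3)
    rr, cc = np.nonzero(inner)
    if len(rr) == 0:
        return
    frac = 0.45 if n_lumen == 1 else 0.18
    for _ in range(n_lumen):
        i = int(rng.integers(0, len(rr)))
        cy, cx = rr[i], cc[i]
        ry = max(2.0, frac * sh / 2 * rng.uniform(0.6, 1.0))
        rx = max(2.0, frac * sw / 2 * rng.uniform(0.6, 1.0))
        yy, xx = np.mgrid[0:sh, 0:sw].astype(float)
        lum = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        lum &= inner
        region = image[r0:r1, c0:c1]
        white = np.array([247.0, 245.0, 247.0]) + rng.normal(0, 2.0, 3)
        region[lum] = white


# ---------------------------------------------------------------------------
# Controlled degradation of masks (simulated backend failure modes)


@dataclass(frozen=True)
class DropInstance:
    """Remove whole components with probability ``p`` (segmentation miss)."""

    p: float


@dataclass(frozen=True)
class Erode:
    """Erode every component by a square radius (boundary under-shoot)."""

    radius: int = 1


@dataclass(frozen=True)
class Relabel:
    """With probability ``p``, swap a component's class per ``mapping``.

    Classes absent from ``mapping`` are left unchanged; an empty mapping
    is the identity.  Emulates class confusion such as high-grade
    patterns being called Gleason 3.
    """

    p: float
    mapping: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class AddSpeckle:
    """Add ``n`` small disk-shaped noise objects on background pixels."""

    n: int
    radius_range: tuple[int, int] = (2, 8)
    class_id: int = 1


DegradeOp = DropInstance | Erode | Relabel | AddSpeckle


def degrade(mask: np.ndarray, ops: Sequence[DegradeOp], seed: int) -> np.ndarray:
    """Apply degradation ops in order, deterministically under ``seed``."""
    from .postprocess import extract_instances  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    out = np.asarray(mask).copy()
    for op in ops:
        if isinstance(op, DropInstance):
            for comp in extract_instances(out):
                if rng.random() < op.p:
                    r0, c0, r1, c1 = comp.bbox
                    region = out[r0:r1, c0:c1]
                    region[comp.binary] = 0
        elif isinstance(op, Erode):
            eroded = np.zeros_like(out)
            structure = np.ones((2 * op.radius + 1,) * 2, dtype=bool)
            for comp in extract_instances(out):
                r0, c0, r1, c1 = comp.bbox
                shrunk = ndimage.binary_erosion(comp.binary, structure=structure)
                eroded[r0:r1, c0:c1][shrunk] = comp.class_id
            out = eroded
        elif isinstance(op, Relabel):
            mapping = dict(op.mapping)
            for comp in extract_instances(out):
                if comp.class_id in mapping and rng.random() < op.p:
                    r0, c0, r1, c1 = comp.bbox
                    region = out[r0:r1, c0:c1]
                    region[comp.binary] = mapping[comp.class_id]
        elif isinstance(op, AddSpeckle):
            h, w = out.shape
            for _ in range(op.n):
                for _try in range(100):
                    r = int(rng.integers(0, h))
                    c = int(rng.integers(0, w))
                    rad = int(rng.integers(op.radius_range[0], op.radius_range[1] + 1))
                    yy, xx = np.mgrid[
                        max(0, r - rad) : min(h, r + rad + 1),
                        max(0, c - rad) : min(w, c + rad + 1),
                    ]
                    disk = (yy - r) ** 2 + (xx - c) ** 2 <= rad * rad
                    window = out[
                        max(0, r - rad) : min(h, r + rad + 1),
                        max(0, c - rad) : min(w, c + rad + 1),
                    ]
                    # Only ever write on background, with a 1 px clearance
                    # so speckles stay separate components.
                    clear = ndimage.binary_dilation(disk, structure=_EIGHT)
                    if (window[clear[: window.shape[0], : window.shape[1]]] != 0).any():
                        continue
                    window[disk] = op.class_id
                    break
        else:
            raise TypeError(f"unknown degradation op {op!r}")
    return out


# ---------------------------------------------------------------------------
# Rasterization (oracle inverse of mask_to_annotations)


def rasterize(aset: AnnotationSet, image_size: tuple[int, int]) -> np.ndarray:
    """Rasterize an AnnotationSet onto a LabelMask.

    Uses the same half-open pixel-center conventions as polygon tracing,
    so ``rasterize(mask_to_annotations(m)) == m`` for any clean mask.
    Overlapping annotations of different classes raise.
    """
    h, w = image_size
    out = np.zeros((h, w), dtype=np.uint16)
    for a in aset:
        rings = polygon_rings(
            list(a.geometry.exterior.coords),
            [list(r.coords) for r in a.geometry.interiors],
        )
        foot = rasterize_rings(rings, (h, w))
        clash = foot & (out != 0) & (out != a.class_id)
        if clash.any():
            raise GeometryError(
                f"annotation {a.uuid} overlaps a different class at "
                f"{int(clash.sum())} pixels"
            )
        out[foot] = a.class_id
    return out
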