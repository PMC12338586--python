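"""Tiled whole-image inference: window planning, backends, restitching.

Two strategies mirror the two ways a large histology region is fed to a
patch-based segmentation model:

* ``overlapped`` - fixed-size tiles (default 1200 px) with a fractional
  overlap (default 5%); the final row/column is clamped to end exactly at
  the image edge.  Overlap conflicts are resolved during restitching by a
  nearest-tile-center rule.
* ``sliding`` - a disjoint grid of tiles (default 1024 px) over a canvas
  reflect-padded up to a tile multiple, then cropped back, producing a
  seamless mask with no overlap to resolve.

The segmentation model itself sits behind the ``SegmentationBackend``
seam: any callable mapping an RGB tile (H, W, 3) to a same-shape integer
label mask.  Backends that declare a ``window`` parameter also receive
the tile's window, which lets the oracle backend crop ground truth.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import BackendContractError, CoverageError

DEFAULT_TILE_SIZE = 1200
DEFAULT_OVERLAP = 0.05
SLIDING_TILE_SIZE = 1024


@dataclass(frozen=True)
class TileWindow:
    """Half-open window [x0, x0+width) x [y0, y0+height) in pixel coords."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"degenerate window {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"negative window origin {self}")

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) in continuous coordinates."""
        return (self.x0 + self.width / 2.0, self.y0 + self.height / 2.0)

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for numpy indexing."""
        return (slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width))


@dataclass(frozen=True)
class TilingPlan:
    windows: tuple[TileWindow, ...]
    strategy: str
    tile_size: int
    overlap_fraction: float
    image_size: tuple[int, int]  # (height, width)
    canvas_size: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.canvas_size is None:
            object.__setattr__(self, "canvas_size", self.image_size)

    def __len__(self) -> int:
        return len(self.windows)


def _axis_offsets_overlapped(size: int, tile: int, stride: int) -> list[int]:
    if size <= tile:
        return [0]
    offs = [0]
    while offs[-1] + tile < size:
        nxt = offs[-1] + stride
        if nxt + tile > size:
            nxt = size - tile
        offs.append(nxt)
    return offs


def plan_tiles(
    image_size: tuple[int, int],
    tile_size: int = DEFAULT_TILE_SIZE,
    strategy: str = "overlapped",
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> TilingPlan:
    """Plan tile windows covering an image.

    ``image_size`` is (height, width).  For the overlapped strategy the
    stride is ``tile_size - round(tile_size * overlap_fraction)`` (round
    half to even); the last row/column is clamped to end at the image
    edge.  For the sliding strategy windows form a disjoint grid over a
    canvas padded up to a multiple of ``tile_size``; windows are emitted
    in row-major order.
    """
    h, w = image_size
    if h < 1 or w < 1:
        raise ValueError(f"zero-sized image {image_size}")
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")

    if strategy == "overlapped":
        overlap_px = round(tile_size * overlap_fraction)
        stride = tile_size - overlap_px
        if stride < 1:
            raise ValueError(
                f"overlap {overlap_fraction} leaves a non-positive stride "
                f"for tile size {tile_size}"
            )
        xs = _axis_offsets_overlapped(w, tile_size, stride)
        ys = _axis_offsets_overlapped(h, tile_size, stride)
        windows = tuple(
            TileWindow(x, y, min(tile_size, w), min(tile_size, h))
            for y in ys
            for x in xs
        )
        return TilingPlan(windows, "overlapped", tile_size, overlap_fraction, (h, w))
    if strategy == "sliding":
        ch = -(-h // tile_size) * tile_size
        cw = -(-w // tile_size) * tile_size
        windows = tuple(
            TileWindow(x, y, tile_size, tile_size)
            for y in range(0, ch, tile_size)
            for x in range(0, cw, tile_size)
        )
        return TilingPlan(windows, "sliding", tile_size, 0.0, (h, w), (ch, cw))
    raise ValueError(f"unknown strategy {strategy!r}")


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract for a pluggable per-tile segmentation model."""

    labels: frozenset[int] | None  # None = unrestricted (full vocabulary)

    def __call__(self, tile: np.ndarray) -> np.ndarray: ...


class OracleBackend:
    """Returns the ground-truth crop for each window.

    A desk-scale stand-in for a trained model: with this backend, tiled
    inference must reproduce the ground-truth mask exactly, which pins
    down the stitching bookkeeping.  Windows reaching past the ground
    truth (sliding-strategy padding) are served from a reflect-padded
    view; a window entirely outside raises.
    """

    def __init__(self, ground_truth: np.ndarray):
        self.ground_truth = np.asarray(ground_truth)
        self.labels = frozenset(np.unique(self.ground_truth).tolist())

    def __call__(self, tile: np.ndarray, window: TileWindow) -> np.ndarray:
        gt = self.ground_truth
        h, w = gt.shape
        if window.x0 >= w or window.y0 >= h:
            raise ValueError(f"oracle window {window} lies outside the ground truth")
        pad_y = max(0, window.y0 + window.height - h)
        pad_x = max(0, window.x0 + window.width - w)
        view = gt
        if pad_y or pad_x:
            view = np.pad(gt, ((0, pad_y), (0, pad_x)), mode="reflect")
        return view[window.slices]


class ThresholdBackend:
    """Pixel-local stain-intensity baseline producing binary masks.

    A pixel is foreground (label 1) when its mean RGB intensity falls
    below ``threshold`` - i.e. it is stained darker than the glass/white
    background.  Deterministic and purely pixel-local, so tiled and
    whole-image inference agree exactly under any strategy.
    """

    labels = frozenset({0, 1})

    def __init__(self, threshold: float = 225.0):
        self.threshold = float(threshold)

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        mean = np.asarray(tile, dtype=np.float64).mean(axis=2)
        return (mean < self.threshold).astype(np.uint16)


def make_reference_backend(
    kind: str,
    ground_truth: np.ndarray | None = None,
    threshold: float = 225.0,
):
    """Construct a reference backend: ``oracle`` or ``threshold_baseline``."""
    if kind == "oracle":
        if ground_truth is None:
            raise ValueError("oracle backend requires a ground-truth mask")
        return OracleBackend(ground_truth)
    if kind in ("threshold", "threshold_baseline"):
        return ThresholdBackend(threshold)
    raise ValueError(f"unknown reference backend {kind!r}")


def _wants_window(backend) -> bool:
    try:
        sig = inspect.signature(backend.__call__ if not inspect.isfunction(backend) else backend)
    except (TypeError, ValueError):  # pragma: no cover
        return False
    return "window" in sig.parameters


def resolve_borders(
    tile_masks: list[tuple[TileWindow, np.ndarray]],
    canvas_size: tuple[int, int] | None = None,
) -> np.ndarray:
    """Merge per-tile masks into one canvas by the nearest-center rule.

    Every pixel covered by k >= 1 windows takes its label from the window
    whose center is nearest (Euclidean distance between the pixel center
    and the window center); ties go to the earliest window in plan order.
    """
    if not tile_masks:
        raise CoverageError("no tile masks to stitch")
    if canvas_size is None:
        hh = max(w.y0 + w.height for w, _ in tile_masks)
        ww = max(w.x0 + w.width for w, _ in tile_masks)
        canvas_size = (hh, ww)
    h, w = canvas_size
    out = np.zeros((h, w), dtype=np.uint16)
    best = np.full((h, w), np.inf, dtype=np.float64)
    covered = np.zeros((h, w), dtype=bool)
    for win, mask in tile_masks:
        mask = np.asarray(mask)
        if mask.shape != (win.height, win.width):
            raise CoverageError(
                f"tile mask shape {mask.shape} does not match window {win}"
            )
        y1 = min(win.y0 + win.height, h)
        x1 = min(win.x0 + win.width, w)
        if y1 <= win.y0 or x1 <= win.x0:
            continue
        cx, cy = win.center
        yy = np.arange(win.y0, y1, dtype=np.float64) + 0.5
        xx = np.arange(win.x0, x1, dtype=np.float64) + 0.5
        d2 = (yy - cy)[:, None] ** 2 + (xx - cx)[None, :] ** 2
        region = (slice(win.y0, y1), slice(win.x0, x1))
        take = d2 < best[region]  # strict: earlier windows win ties
        best[region] = np.where(take, d2, best[region])
        sub = mask[: y1 - win.y0, : x1 - win.x0]
        out[region] = np.where(take, sub, out[region])
        covered[region] = True
    if not covered.all():
        n = int((~covered).sum())
        raise CoverageError(f"{n} canvas pixels not covered by any window")
    return out


def run_tiled_inference(
    image: np.ndarray,
    backend,
    plan: TilingPlan,
    declared_labels: frozenset[int] | None = None,
) -> np.ndarray:
    """Run a backend over every planned tile and restitch one LabelMask.

    Tiles are processed in plan (row-major) order.  For the sliding
    strategy the image is reflect-padded to the plan's canvas and the
    stitched result cropped back.  Backend output is checked against its
    declared label set and the tile shape; violations name the window.
    """
    image = np.asarray(image)
    h, w = plan.image_size
    if image.shape[:2] != (h, w):
        raise ValueError(f"image shape {image.shape[:2]} does not match plan {(h, w)}")
    ch, cw = plan.canvas_size
    work = image
    if (ch, cw) != (h, w):
        work = np.pad(image, ((0, ch - h), (0, cw - w), (0, 0)), mode="reflect")
    labels = declared_labels
    if labels is None:
        labels = getattr(backend, "labels", None)
    pass_window = _wants_window(backend)
    results: list[tuple[TileWindow, np.ndarray]] = []
    for win in plan.windows:
        tile = work[win.slices]
        pred = backend(tile, window=win) if pass_window else backend(tile)
        pred = np.asarray(pred)
        if pred.shape != tile.shape[:2]:
            raise BackendContractError(
                f"backend returned shape {pred.shape} for window {win} "
                f"(expected {tile.shape[:2]})"
            )
        if labels is not None:
            extra = set(np.unique(pred).tolist()) - set(labels) - {0}
            if extra:
                raise BackendContractError(
                    f"backend emitted undeclared labels {sorted(extra)} for window {win}"
                )
        results.append((win, pred.astype(np.uint16, copy=False)))
    stitched = resolve_borders(results, plan.canvas_size)
    return stitched[:h, :w]
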