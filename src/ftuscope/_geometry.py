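"""Exact raster <-> polygon conversion on the half-open pixel model.

Pixel (r, c) occupies the unit square [c, c+1) x [r, r+1) in (x, y)
coordinates with x rightward and y downward; its center is (c+0.5, r+0.5).
Polygon vertices sit on integer pixel corners, so a traced boundary
re-rasterizes to exactly the pixels it was traced from.

Tracing walks directed unit edges that keep foreground on the left
(positive shoelace area for exterior rings, negative for holes).  At a
corner where two foreground pixels touch only diagonally, the walk turns
through the corner so that the 8-connected component stays a single ring;
the ring then revisits that vertex, which even-odd rasterization handles
exactly because scanlines and pixel centers sit at half-integer
coordinates and never meet an integer corner.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import GeometryError

Ring = list[tuple[float, float]]


def ring_area(ring: Ring) -> float:
    """Signed shoelace area of a closed ring (last vertex may repeat the first)."""
    pts = list(ring)
    if pts[0] == pts[-1]:
        pts = pts[:-1]
    s = 0.0
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return 0.5 * s


def _boundary_edges(binary: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Directed boundary edges of a binary raster, keyed by start vertex."""
    padded = np.zeros((binary.shape[0] + 2, binary.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = binary
    core = padded[1:-1, 1:-1]
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def _add(mask, dx, dy, off_x, off_y):
        rr, cc = np.nonzero(mask)
        for r, c in zip(rr.tolist(), cc.tolist()):
            start = (c + off_x, r + off_y)
            edges.setdefault(start, []).append((start[0] + dx, start[1] + dy))

    _add(core & ~padded[:-2, 1:-1], 1, 0, 0, 0)   # top:    (c, r)     -> (c+1, r)
    _add(core & ~padded[2:, 1:-1], -1, 0, 1, 1)   # bottom: (c+1, r+1) -> (c, r+1)
    _add(core & ~padded[1:-1, :-2], 0, -1, 0, 1)  # left:   (c, r+1)   -> (c, r)
    _add(core & ~padded[1:-1, 2:], 0, 1, 1, 0)    # right:  (c+1, r)   -> (c+1, r+1)
    return edges


def _walk_ring(
    edges: dict[tuple[int, int], list[tuple[int, int]]],
    start: tuple[int, int],
) -> Ring:
    """Consume edges starting at ``start`` until the walk closes on it."""
    outs = edges[start]
    cur = sorted(outs)[0]
    outs.remove(cur)
    if not outs:
        del edges[start]
    ring: Ring = [start, cur]
    prev = start
    while True:
        candidates = edges.get(cur)
        if not candidates:
            if cur != start:  # pragma: no cover - balanced edge graph
                raise GeometryError("boundary walk ended away from its start")
            break
        if len(candidates) == 1:
            nxt = candidates[0]
        else:
            # Pinch corner: prefer the right turn so diagonally touching
            # foreground stays a single ring (8-connectivity convention).
            din = (cur[0] - prev[0], cur[1] - prev[1])
            nxt = min(
                candidates,
                key=lambda e: din[0] * (e[1] - cur[1]) - din[1] * (e[0] - cur[0]),
            )
        candidates.remove(nxt)
        if not candidates:
            del edges[cur]
        ring.append(nxt)
        prev, cur = cur, nxt
        if cur == start and cur not in edges:
            break
    return ring


def trace_binary(binary: np.ndarray) -> list[tuple[Ring, list[Ring]]]:
    """Trace a binary raster into polygons, one per 8-connected component.

    Returns a list of ``(exterior, holes)`` pairs.  Exterior rings are
    counter-clockwise in the (x, y) plane (positive shoelace), holes
    clockwise.  Rings are closed (first vertex repeated at the end).
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return []
    edges = _boundary_edges(binary)
    rings: list[Ring] = []
    while edges:
        start = min(edges)
        rings.append(_walk_ring(edges, start))

    exteriors = [r for r in rings if ring_area(r) > 0]
    holes = [r for r in rings if ring_area(r) < 0]
    if len(exteriors) == 1:
        return [(exteriors[0], holes)]
    # Multiple components traced in one call: assign each hole to the
    # exterior ring that contains it.
    assigned: list[list[Ring]] = [[] for _ in exteriors]
    for h in holes:
        hx, hy = _interior_probe(h)
        for i, ext in enumerate(exteriors):
            if _point_in_ring(hx, hy, ext):
                assigned[i].append(h)
                break
        else:  # pragma: no cover - every hole lies in some exterior
            raise GeometryError("hole ring not contained in any exterior ring")
    return list(zip(exteriors, assigned))


def _interior_probe(ring: Ring) -> tuple[float, float]:
    """A point strictly inside the region bounded by a pixel-corner ring."""
    xs = [p[0] for p in ring[:-1]]
    ys = [p[1] for p in ring[:-1]]
    y = math.floor(min(ys)) + 0.5
    for cx in range(int(math.floor(min(xs))), int(math.ceil(max(xs)))):
        if _point_in_ring(cx + 0.5, y, ring):
            return (cx + 0.5, y)
    raise GeometryError("could not find interior point of ring")  # pragma: no cover


def _point_in_ring(px: float, py: float, ring: Ring) -> bool:
    """Even-odd point-in-polygon test at a half-integer probe point."""
    inside = False
    pts = ring if ring[0] == ring[-1] else list(ring) + [ring[0]]
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        if (y1 <= py) != (y2 <= py):
            x = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x:
                inside = not inside
    return inside


def rasterize_rings(rings: list[Ring], shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization of a set of rings onto pixel centers.

    A pixel (r, c) is set when its center (c+0.5, r+0.5) lies inside the
    region described by the rings (holes cancel by parity).  Exact for
    integer-corner rings; deterministic for arbitrary float rings.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    rows: dict[int, list[tuple[float, float, float, float]]] = {}
    for ring in rings:
        pts = ring if ring[0] == ring[-1] else list(ring) + [ring[0]]
        for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
            if y1 == y2:
                continue
            ymin, ymax = (y1, y2) if y1 < y2 else (y2, y1)
            r0 = max(0, int(math.ceil(ymin - 0.5)))
            r1 = min(h, int(math.ceil(ymax - 0.5)))
            for r in range(r0, r1):
                rows.setdefault(r, []).append((x1, y1, x2, y2))
    for r, segs in rows.items():
        y = r + 0.5
        xs = sorted(x1 + (y - y1) * (x2 - x1) / (y2 - y1) for x1, y1, x2, y2 in segs)
        for a, b in zip(xs[0::2], xs[1::2]):
            c0 = max(0, int(math.ceil(a - 0.5)))
            c1 = min(w, int(math.ceil(b - 0.5)))
            if c1 > c0:
                out[r, c0:c1] = True
    return out


def polygon_rings(exterior: Ring, holes: list[Ring]) -> list[Ring]:
    """Concatenate exterior and hole rings for even-odd rasterization."""
    return [exterior, *holes]
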