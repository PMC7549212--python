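"""Silhouette morphometry: segmentation and the four size/shape traits.

From an RGB photograph of a single plant on a light-box (white) background
the module extracts a binary silhouette by band thresholding of the
greyscale image, then measures:

* A — projected area: foreground pixel count after hole filling (px^2,
  scaled by ``scale``^2 when a physical pixel size is known);
* H — shoot height: vertical extent from the basal-most to the apical-most
  foreground row;
* S — shoot diameter: the median width of the main stem over the middle
  third of the plant's vertical extent;
* B — branch count: number of first-order laterals leaving the main
  skeleton path.

Coordinates are 0-based, row-major, origin top-left; the plant's base is the
bottom-most foreground row. Measurements are axis-aligned by design (the
height of a horizontal bar is its stroke width, not its length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "MorphometricRecord",
    "to_greyscale",
    "segment",
    "projected_area",
    "shoot_height",
    "shoot_diameter",
    "count_branches",
    "measure_mask",
]


@dataclass(frozen=True)
class MorphometricRecord:
    """Per-plant morphometry: area A, branches B, diameter S, height H and
    box-counting fractal dimension FD."""

    A: float
    B: int
    S: float
    H: float
    FD: float


class EmptyMaskError(ValueError):
    """Raised when a measurement is undefined on an empty silhouette."""


def to_greyscale(image: np.ndarray) -> np.ndarray:
    """Luminance greyscale with ITU-R BT.601 weights, rounded half-up.

    grey = 0.299 R + 0.587 G + 0.114 B, the convention of mainstream image
    analysis tools.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    lum = (0.299 * image[..., 0].astype(np.float64)
           + 0.587 * image[..., 1]
           + 0.114 * image[..., 2])
    return np.floor(lum + 0.5).astype(np.uint8)


def segment(grey: np.ndarray, t_low: int = 135, t_high: int = 240,
            keep_largest: bool = True, fill_holes: bool = True) -> np.ndarray:
    """Band-threshold segmentation: foreground where t_low <= grey <= t_high.

    Both bounds are inclusive. By default only the largest connected
    component is kept and interior holes are filled, which suppresses
    background speckle on light-box photographs.
    """
    if not 0 <= t_low <= t_high <= 255:
        raise ValueError("thresholds must satisfy 0 <= t_low <= t_high <= 255")
    grey = np.asarray(grey)
    mask = (grey >= t_low) & (grey <= t_high)
    if not mask.any():
        warnings.warn("segmentation produced an empty mask", stacklevel=2)
        return mask
    if keep_largest:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def projected_area(mask: np.ndarray, scale: float = 1.0) -> float:
    """Projected area A: pixels inside the borderline (holes filled) x scale^2."""
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    return float(filled.sum()) * scale * scale


def shoot_height(mask: np.ndarray, scale: float = 1.0) -> float:
    """Shoot height H: vertical extent from base to apex, in scaled units."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise EmptyMaskError("height undefined on an empty mask")
    return float(rows[-1] - rows[0] + 1) * scale


def shoot_diameter(mask: np.ndarray, scale: float = 1.0,
                   width_quantile: float = 0.15) -> float:
    """Shoot diameter S: stem width over the middle third of the shoot.

    In each row of the middle third of the vertical extent, the contiguous
    foreground run intersecting the main-stem column is measured; S is the
    ``width_quantile`` quantile of those run lengths. The main-stem column is
    the column that is foreground in the largest number of band rows — the
    stem crosses every row of the band, branches only a few. A low quantile
    rather than the median reads the bare-stem rows of the band: on bushy
    silhouettes the rows at branch junctions (often most of the band) merge
    stem and branch into one run, while the uncontaminated rows concentrate
    at the bottom of the width distribution. On a branch-free stem every row
    has the same width and any quantile returns it. Fails when the stem
    column is missed in at least half of the rows.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise EmptyMaskError("diameter undefined on an empty mask")
    r0, r1 = rows[0], rows[-1]
    span = r1 - r0 + 1
    lo = r0 + span // 3
    hi = r0 + (2 * span) // 3
    band = mask[lo:hi + 1]
    if not band.any():
        raise EmptyMaskError("middle third of the shoot is empty")
    stem_col = int(np.argmax(band.sum(axis=0)))
    widths: List[int] = []
    missed = 0
    for row in band:
        if not row[stem_col]:
            missed += 1
            continue
        left = stem_col
        while left > 0 and row[left - 1]:
            left -= 1
        right = stem_col
        while right < row.size - 1 and row[right + 1]:
            right += 1
        widths.append(right - left + 1)
    if missed > len(band) / 2:
        raise EmptyMaskError("main stem not identifiable in the middle third")
    return float(np.quantile(widths, width_quantile)) * scale


# -- skeleton graph utilities -------------------------------------------------

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_adjacency(skel: np.ndarray) -> Dict[Tuple[int, int],
                                                  List[Tuple[int, int]]]:
    pts = set(map(tuple, np.argwhere(skel)))
    adj: Dict[Tuple[int, int], List[Tuple[int, int]]] = {p: [] for p in pts}
    for (r, c) in pts:
        for dr, dc in _OFFSETS:
            q = (r + dr, c + dc)
            if q in adj:
                adj[(r, c)].append(q)
    return adj


def _geodesic_farthest(adj, start):
    """Dijkstra over the pixel graph; returns (distances, predecessors)."""
    import heapq

    dist = {start: 0.0}
    prev = {start: None}
    heap = [(0.0, start)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        for v in adj[u]:
            w = 1.0 if u[0] == v[0] or u[1] == v[1] else np.sqrt(2.0)
            nd = d + w
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, prev


def _prune_spurs(adj, min_length: float) -> None:
    """Iteratively delete terminal twigs with geodesic length < min_length.

    A twig is a chain from an endpoint up to (not including) the first
    junction (degree >= 3 node). Chains without a junction — a component that
    is itself a bare path — are never pruned.
    """
    sqrt2 = np.sqrt(2.0)
    while True:
        removed_any = False
        for tip in [p for p, nb in adj.items() if len(nb) == 1]:
            if tip not in adj or len(adj[tip]) != 1:
                continue
            chain = [tip]
            chain_set = {tip}
            length = 0.0
            prev, cur = None, tip
            junction = None
            while True:
                nxt_candidates = [q for q in adj[cur] if q != prev]
                if not nxt_candidates:
                    break  # bare-path component
                nxt = nxt_candidates[0]
                length += 1.0 if cur[0] == nxt[0] or cur[1] == nxt[1] else sqrt2
                if len(adj[nxt]) >= 3:
                    junction = nxt
                    break
                chain.append(nxt)
                chain_set.add(nxt)
                prev, cur = cur, nxt
                if len(adj[cur]) == 1:
                    break  # walked to the opposite endpoint
            if junction is not None and length < min_length:
                for p in chain:
                    for q in adj[p]:
                        if q not in chain_set:
                            adj[q].remove(p)
                    del adj[p]
                removed_any = True
        if not removed_any:
            break


def _largest_component(adj):
    seen: Set[Tuple[int, int]] = set()
    best: Set[Tuple[int, int]] = set()
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        if len(comp) > len(best):
            best = comp
    return best


def count_branches(mask: np.ndarray, spur_prune_px: float = 5.0) -> int:
    """Branch count B: first-order laterals off the main skeleton path.

    The mask is skeletonised to a 1-px medial axis; terminal twigs shorter
    than ``spur_prune_px`` (rasterisation spurs) are pruned; the main path is
    the geodesic from the basal-most to the apical-most skeleton point — the
    base-to-apex axis, the same axis the height trait measures. (Anchoring
    the apex rather than taking the longest geodesic keeps the main path on
    the stem even when a branch-and-descendants chain is geodesically longer
    than the remaining stem, as happens on bushy crowns.) B is the number of
    connected lateral subtrees hanging off that path.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("branch count undefined on an empty mask")
    skel = skeletonize(mask)
    adj = _skeleton_adjacency(skel)
    if not adj:
        return 0
    comp = _largest_component(adj)
    if len(comp) < len(adj):
        warnings.warn("disconnected mask: counting branches on the largest "
                      "skeleton component", stacklevel=2)
        adj = {p: [q for q in nb if q in comp]
               for p, nb in adj.items() if p in comp}
    _prune_spurs(adj, spur_prune_px)
    if not adj:
        return 0
    if len(adj) == 1:
        return 0
    # basal-most point: max row; apical-most: min row (ties: min column)
    base = max(adj, key=lambda p: (p[0], -p[1]))
    dist, prev = _geodesic_farthest(adj, base)
    apex = min(dist, key=lambda p: (p[0], p[1]))
    main: Set[Tuple[int, int]] = set()
    cur = apex
    while cur is not None:
        main.add(cur)
        cur = prev[cur]
    # laterals = connected components of (skeleton minus main path) whose
    # geodesic reach from the main path is at least the spur-prune length
    # (catches residual junction nubs the endpoint walk cannot classify)
    off = {p: [q for q in nb if q not in main]
           for p, nb in adj.items() if p not in main}
    seen: Set[Tuple[int, int]] = set()
    laterals = 0
    for start in off:
        if start in seen:
            continue
        compo = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in off[u]:
                if v not in compo:
                    compo.add(v)
                    stack.append(v)
        seen |= compo
        import heapq

        roots = [p for p in compo
                 if any(q in main for q in adj[p])]
        dist = {p: 0.0 for p in roots}
        heap = [(0.0, p) for p in roots]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            for v in off[u]:
                w = 1.0 if u[0] == v[0] or u[1] == v[1] else np.sqrt(2.0)
                if d + w < dist.get(v, np.inf):
                    dist[v] = d + w
                    heapq.heappush(heap, (d + w, v))
        reach = max(dist.values()) + 1.0 if dist else 1.0
        if reach >= spur_prune_px:
            laterals += 1
    return laterals


def measure_mask(mask: np.ndarray, scale: float = 1.0,
                 spur_prune_px: float = 5.0,
                 fd: Optional[float] = None) -> MorphometricRecord:
    """All four silhouette traits (plus an externally computed FD) at once."""
    from .fractal import fractal_dimension

    if fd is None:
        fd = fractal_dimension(mask).fd
    return MorphometricRecord(
        A=projected_area(mask, scale),
        B=count_branches(mask, spur_prune_px),
        S=shoot_diameter(mask, scale),
        H=shoot_height(mask, scale),
        FD=fd,
    )
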