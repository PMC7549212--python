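"""Box-counting fractal dimension of binary silhouettes.

The estimator tiles the mask from a fixed top-left origin with boxes of side
epsilon (powers of 2 by default, no origin search) and fits log N(eps)
against log(1/eps) by ordinary least squares; the slope is the fractal
dimension FD. Curves give FD near 1 and plane-filling silhouettes FD near 2,
so connected plant shapes land in [1, 2]. Saturated scales — where every box
in the grid is occupied, which forces the local slope to the embedding
dimension — are excluded from the fit; if fewer than four scales survive the
filter the unfiltered series is used (a fully plane-filling mask is then fit
over all scales, correctly yielding FD = 2).

By default the mask is cropped to its bounding box and padded to the next
power-of-2 square before counting, so FD reflects the plant, not the frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = ["BoxCountResult", "box_count", "fractal_dimension"]


@dataclass(frozen=True)
class BoxCountResult:
    box_sizes: Tuple[int, ...]
    counts: Tuple[int, ...]
    fd: float
    r2: float
    intercept: float

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts):
            raise ValueError("box counts must be positive")
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("counts must be non-increasing with box size")


def box_count(mask: np.ndarray,
              box_sizes: Sequence[int]) -> Tuple[List[int], List[int]]:
    """Count occupied boxes for each box side length.

    The grid is anchored at the top-left origin; edge boxes may be partial.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("box counting undefined on an empty mask")
    h, w = mask.shape
    sizes, counts = [], []
    for eps in box_sizes:
        if eps < 2 or eps > min(h, w):
            raise ValueError(f"box size {eps} outside [2, min(H, W)]")
        ph = (-h) % eps
        pw = (-w) % eps
        padded = np.pad(mask, ((0, ph), (0, pw)))
        blocks = padded.reshape(padded.shape[0] // eps, eps,
                                padded.shape[1] // eps, eps)
        occupied = blocks.any(axis=(1, 3))
        sizes.append(int(eps))
        counts.append(int(occupied.sum()))
    return sizes, counts


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def _crop_pad(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    crop = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    side = max(_next_pow2(max(crop.shape)), 16)
    out = np.zeros((side, side), dtype=bool)
    out[:crop.shape[0], :crop.shape[1]] = crop
    return out


def fractal_dimension(mask: np.ndarray,
                      box_sizes: Optional[Sequence[int]] = None,
                      crop_to_bbox: bool = True) -> BoxCountResult:
    """Estimate FD as the OLS slope of log N(eps) vs log(1/eps).

    With ``box_sizes`` unset, powers of 2 from 2 up to a quarter of the
    (cropped, power-of-2-padded) image side, capped at 64 px, are used; at
    least four usable scales are required. The 64 px cap mirrors the default
    box series of the standard box-count plugin in mainstream image-analysis
    software, which probes fine scales only: at coarser scales every
    branched silhouette degenerates towards its skeleton and the slope no
    longer reflects crown texture. Natural logs — the slope is
    base-invariant.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("fractal dimension undefined on an empty mask")
    if crop_to_bbox:
        mask = _crop_pad(mask)
    h, w = mask.shape
    if box_sizes is None:
        limit = min(min(h, w) // 4, 64)
        box_sizes = [2 ** k for k in range(1, limit.bit_length())
                     if 2 ** k <= limit]
    if len(box_sizes) < 4:
        raise ValueError("need at least four box sizes for a stable fit")
    sizes, counts = box_count(mask, sorted(box_sizes))

    sizes_a = np.array(sizes, dtype=float)
    counts_a = np.array(counts, dtype=float)
    total_boxes = np.ceil(h / sizes_a) * np.ceil(w / sizes_a)
    usable = counts_a < total_boxes
    if usable.sum() >= 4:
        sizes_fit, counts_fit = sizes_a[usable], counts_a[usable]
    else:  # plane-filling mask: every scale saturates, fit them all
        sizes_fit, counts_fit = sizes_a, counts_a
    fit = stats.linregress(np.log(1.0 / sizes_fit), np.log(counts_fit))
    return BoxCountResult(tuple(sizes), tuple(counts), float(fit.slope),
                          float(fit.rvalue ** 2), float(fit.intercept))
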