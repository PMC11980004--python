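"""Texture-matrix builders.

All builders operate on a :class:`~lge_radiomics.core.QuantizedROI` (integer
gray levels 1..Ng on a boolean mask) and compute 2D matrices with the
conventional four direction offsets at distance 1 — (0,1), (1,0), (1,1),
(1,-1) — pooled into a single matrix.  A neighbour pair contributes only
when BOTH pixels are masked; there is no intensity padding, so co-occurrence
counts are never contaminated by background at the ROI border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..core import DegenerateSliceError, QuantizedROI

__all__ = [
    "DIRECTIONS_2D",
    "CooccurrenceMatrix",
    "NeighborhoodDifferenceTable",
    "RunLengthMatrix",
    "SizeZoneMatrix",
    "DependenceMatrix",
    "glcm",
    "ngtdm",
    "glrlm",
    "glszm",
    "gldm",
]

#: distance-1 offsets covering the 0/45/90/135 degree directions
DIRECTIONS_2D: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

_EIGHT_NEIGHBORS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass
class CooccurrenceMatrix:
    """Symmetric gray-level co-occurrence probabilities p(i, j).

    ``p[i-1, j-1]`` is the probability that a masked pixel of level i has a
    masked neighbour of level j at distance 1, pooled over the four
    directions and both pair orders (symmetric GLCM).
    """

    p: np.ndarray
    n_levels: int
    n_pairs: int  # ordered pair count before normalization
    distance: int = 1

    def __post_init__(self) -> None:
        total = self.p.sum()
        if not np.isclose(total, 1.0):
            raise ValueError(f"co-occurrence probabilities sum to {total}, not 1")


@dataclass
class NeighborhoodDifferenceTable:
    """NGTDM components: per-level neighbourhood difference sums.

    ``s[i-1]`` accumulates |level - mean(masked 8-neighbours)| over valid
    pixels of level i; ``n[i-1]`` counts those pixels; ``p = n / n_valid``.
    """

    s: np.ndarray
    n: np.ndarray
    p: np.ndarray
    n_valid: int
    n_levels: int


@dataclass
class RunLengthMatrix:
    """Gray-level run-length counts R(i, l), pooled over 4 directions."""

    counts: np.ndarray  # (Ng, max_run_length)
    n_levels: int
    n_voxels: int
    n_directions: int


@dataclass
class SizeZoneMatrix:
    """Gray-level size-zone counts S(i, z): 8-connected constant-level zones."""

    counts: np.ndarray  # (Ng, max_zone_size)
    n_levels: int
    n_voxels: int


@dataclass
class DependenceMatrix:
    """Gray-level dependence counts D(i, d).

    The dependence of a masked pixel is 1 + the number of masked 8-neighbours
    whose level differs by at most ``alpha`` (the centre pixel always depends
    on itself, so d >= 1).
    """

    counts: np.ndarray  # (Ng, max_dependence)
    n_levels: int
    n_voxels: int
    alpha: int = 0


def _shifted_valid(mask: np.ndarray, dr: int, dc: int) -> tuple[slice, slice, slice, slice]:
    """Slices (src_r, src_c, dst_r, dst_c) aligning array with its (dr, dc) shift."""
    n_r, n_c = mask.shape
    src_r = slice(max(0, -dr), min(n_r, n_r - dr))
    src_c = slice(max(0, -dc), min(n_c, n_c - dc))
    dst_r = slice(max(0, dr), min(n_r, n_r + dr))
    dst_c = slice(max(0, dc), min(n_c, n_c + dc))
    return src_r, src_c, dst_r, dst_c


def glcm(
    roi: QuantizedROI,
    directions: tuple[tuple[int, int], ...] = DIRECTIONS_2D,
) -> CooccurrenceMatrix:
    """Symmetric distance-1 co-occurrence matrix pooled over directions.

    Raises :class:`DegenerateSliceError` when the mask admits no valid
    neighbour pair.
    """
    ng = roi.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    levels, mask = roi.levels, roi.mask
    for dr, dc in directions:
        src_r, src_c, dst_r, dst_c = _shifted_valid(mask, dr, dc)
        valid = mask[src_r, src_c] & mask[dst_r, dst_c]
        i = levels[src_r, src_c][valid] - 1
        j = levels[dst_r, dst_c][valid] - 1
        np.add.at(counts, (i, j), 1)
        np.add.at(counts, (j, i), 1)  # symmetric: count both orders
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise DegenerateSliceError("mask has no valid neighbour pair for GLCM")
    return CooccurrenceMatrix(counts / n_pairs, ng, n_pairs)


def ngtdm(roi: QuantizedROI) -> NeighborhoodDifferenceTable:
    """Neighbouring gray-tone difference table over the masked 8-neighbourhood."""
    ng = roi.n_levels
    mask = roi.mask
    levels = roi.levels.astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = ndimage.convolve(levels * mask, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_cnt > 0.5)
    if not valid.any():
        raise DegenerateSliceError("no masked pixel has a masked neighbour for NGTDM")
    diffs = np.abs(levels[valid] - nbr_sum[valid] / nbr_cnt[valid])
    lv = roi.levels[valid] - 1
    s = np.bincount(lv, weights=diffs, minlength=ng)
    n = np.bincount(lv, minlength=ng).astype(np.int64)
    n_valid = int(valid.sum())
    return NeighborhoodDifferenceTable(s, n, n / n_valid, n_valid, ng)


def _run_lengths_of_line(line: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode one scan line; level 0 marks out-of-mask breaks."""
    runs = []
    if line.size == 0:
        return runs
    change = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [line.size]))
    for a, b in zip(starts, ends):
        if line[a] > 0:
            runs.append((int(line[a]), int(b - a)))
    return runs


def _lines(levels: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    """Scan lines of ``levels`` along a direction offset."""
    n_r, n_c = levels.shape
    if direction == (0, 1):
        return [levels[r] for r in range(n_r)]
    if direction == (1, 0):
        return [levels[:, c] for c in range(n_c)]
    if direction == (1, 1):
        return [np.diagonal(levels, offset=k) for k in range(-(n_r - 1), n_c)]
    if direction == (1, -1):
        flipped = levels[:, ::-1]
        return [np.diagonal(flipped, offset=k) for k in range(-(n_r - 1), n_c)]
    raise ValueError(f"unsupported direction {direction}")


def glrlm(
    roi: QuantizedROI,
    directions: tuple[tuple[int, int], ...] = DIRECTIONS_2D,
) -> RunLengthMatrix:
    """Run-length matrix: maximal constant-level runs inside the mask,
    pooled over the four directions (out-of-mask pixels break runs)."""
    masked_levels = np.where(roi.mask, roi.levels, 0)
    max_len = max(roi.levels.shape)
    counts = np.zeros((roi.n_levels, max_len), dtype=np.int64)
    for direction in directions:
        for line in _lines(masked_levels, direction):
            for level, length in _run_lengths_of_line(np.asarray(line)):
                counts[level - 1, length - 1] += 1
    if counts.sum() == 0:
        raise DegenerateSliceError("empty mask for GLRLM")
    # trim trailing all-zero run-length columns
    last = int(np.flatnonzero(counts.any(axis=0)).max()) + 1
    return RunLengthMatrix(counts[:, :last], roi.n_levels, roi.n_masked, len(directions))


_CONN8 = np.ones((3, 3), dtype=int)


def glszm(roi: QuantizedROI) -> SizeZoneMatrix:
    """Size-zone matrix: 8-connected zones of equal gray level inside the mask."""
    n_voxels = roi.n_masked
    if n_voxels == 0:
        raise DegenerateSliceError("empty mask for GLSZM")
    zones: list[tuple[int, int]] = []
    for level in roi.occupied_levels:
        labelled, n_zones = ndimage.label((roi.levels == level) & roi.mask, structure=_CONN8)
        if n_zones:
            sizes = np.bincount(labelled.ravel())[1:]
            zones.extend((int(level), int(sz)) for sz in sizes)
    max_size = max(sz for _, sz in zones)
    counts = np.zeros((roi.n_levels, max_size), dtype=np.int64)
    for level, sz in zones:
        counts[level - 1, sz - 1] += 1
    return SizeZoneMatrix(counts, roi.n_levels, n_voxels)


def gldm(roi: QuantizedROI, alpha: int = 0) -> DependenceMatrix:
    """Dependence matrix at distance 1 with gray-level tolerance ``alpha``."""
    mask = roi.mask
    if not mask.any():
        raise DegenerateSliceError("empty mask for GLDM")
    levels = roi.levels
    dep = np.ones(levels.shape, dtype=np.int64)  # centre counts itself
    for dr, dc in _EIGHT_NEIGHBORS:
        # GLDM neighbourhood is the 4-direction distance-1 set on both sides,
        # i.e. all 8 neighbours
        src_r, src_c, dst_r, dst_c = _shifted_valid(mask, dr, dc)
        ok = (
            mask[src_r, src_c]
            & mask[dst_r, dst_c]
            & (np.abs(levels[src_r, src_c] - levels[dst_r, dst_c]) <= alpha)
        )
        dep_block = dep[src_r, src_c]
        dep_block[ok] += 1
        dep[src_r, src_c] = dep_block
    d = dep[mask]
    lv = levels[mask] - 1
    max_dep = int(d.max())
    counts = np.zeros((roi.n_levels, max_dep), dtype=np.int64)
    np.add.at(counts, (lv, d - 1), 1)
    return DependenceMatrix(counts, roi.n_levels, roi.n_masked, alpha)
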