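"""Independent brute-force oracles for the texture matrices and statistics.

Every function here re-implements a definition by exhaustive looping, with
no shared code with the package implementation, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))
EIGHT = tuple((dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0))


def glcm_brute(levels, mask, n_levels, directions=DIRECTIONS):
    """Symmetric pooled co-occurrence counts by literal pair enumeration."""
    n_r, n_c = levels.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(n_r):
        for c in range(n_c):
            if not mask[r, c]:
                continue
            for dr, dc in directions:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n_r and 0 <= c2 < n_c and mask[r2, c2]:
                    i, j = levels[r, c] - 1, levels[r2, c2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    return counts / counts.sum()


def ngtdm_brute(levels, mask, n_levels):
    """Per-level |level - neighbourhood mean| sums by per-pixel loops."""
    n_r, n_c = levels.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels, dtype=int)
    for r in range(n_r):
        for c in range(n_c):
            if not mask[r, c]:
                continue
            nbrs = []
            for dr, dc in EIGHT:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n_r and 0 <= c2 < n_c and mask[r2, c2]:
                    nbrs.append(levels[r2, c2])
            if not nbrs:
                continue
            lv = levels[r, c]
            s[lv - 1] += abs(lv - sum(nbrs) / len(nbrs))
            n[lv - 1] += 1
    total = n.sum()
    return s, n, n / total, int(total)


def glrlm_brute(levels, mask, n_levels, directions=DIRECTIONS):
    """Run-length counts by walking every line pixel by pixel."""
    n_r, n_c = levels.shape
    masked = np.where(mask, levels, 0)
    runs = []
    for dr, dc in directions:
        # line starts: pixels with no predecessor along (dr, dc)
        for r in range(n_r):
            for c in range(n_c):
                pr, pc = r - dr, c - dc
                if 0 <= pr < n_r and 0 <= pc < n_c:
                    continue  # not a line start
                rr, cc = r, c
                current, length = 0, 0
                while 0 <= rr < n_r and 0 <= cc < n_c:
                    v = masked[rr, cc]
                    if v == current and v != 0:
                        length += 1
                    else:
                        if current != 0:
                            runs.append((current, length))
                        current, length = v, (1 if v != 0 else 0)
                    rr, cc = rr + dr, cc + dc
                if current != 0:
                    runs.append((current, length))
    max_len = max(length for _, length in runs)
    counts = np.zeros((n_levels, max_len), dtype=int)
    for level, length in runs:
        counts[level - 1, length - 1] += 1
    return counts


def glszm_brute(levels, mask, n_levels):
    """Zone sizes by breadth-first flood fill with 8-connectivity."""
    n_r, n_c = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(n_r):
        for c in range(n_c):
            if not mask[r, c] or seen[r, c]:
                continue
            level = levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in EIGHT:
                    r2, c2 = rr + dr, cc + dc
                    if (
                        0 <= r2 < n_r
                        and 0 <= c2 < n_c
                        and mask[r2, c2]
                        and not seen[r2, c2]
                        and levels[r2, c2] == level
                    ):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            zones.append((level, size))
    max_size = max(sz for _, sz in zones)
    counts = np.zeros((n_levels, max_size), dtype=int)
    for level, sz in zones:
        counts[level - 1, sz - 1] += 1
    return counts


def gldm_brute(levels, mask, n_levels, alpha=0):
    """Dependence counts (1 + matching 8-neighbours) per pixel."""
    n_r, n_c = levels.shape
    entries = []
    for r in range(n_r):
        for c in range(n_c):
            if not mask[r, c]:
                continue
            d = 1
            for dr, dc in EIGHT:
                r2, c2 = r + dr, c + dc
                if (
                    0 <= r2 < n_r
                    and 0 <= c2 < n_c
                    and mask[r2, c2]
                    and abs(int(levels[r, c]) - int(levels[r2, c2])) <= alpha
                ):
                    d += 1
            entries.append((levels[r, c], d))
    max_dep = max(d for _, d in entries)
    counts = np.zeros((n_levels, max_dep), dtype=int)
    for level, d in entries:
        counts[level - 1, d - 1] += 1
    return counts


def auc_brute(risks, events):
    """Concordance by exhaustive pair counting with half credit for ties."""
    risks = np.asarray(risks, float)
    events = np.asarray(events).astype(bool)
    pos = risks[events]
    neg = risks[~events]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def delong_components_brute(risks, events):
    """Structural components V10/V01 by definition (pairwise indicators)."""
    risks = np.asarray(risks, float)
    events = np.asarray(events).astype(bool)
    pos = risks[events]
    neg = risks[~events]

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
    v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
    return v10, v01


def youden_brute(risks, events):
    """Exhaustive scan over observed thresholds (rule: high iff risk >= t)."""
    risks = np.asarray(risks, float)
    events = np.asarray(events).astype(bool)
    best_t, best_j = None, -np.inf
    for t in sorted(set(risks)):
        sens = np.mean(risks[events] >= t)
        spec = np.mean(risks[~events] < t)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:  # strict improvement keeps the lowest threshold
            best_j, best_t = j, t
    return best_t


def medoid_brute(columns: dict[str, np.ndarray]) -> str:
    """Exhaustive argmin of summed Euclidean distances; ties by name."""
    names = sorted(columns)
    best, best_cost = None, np.inf
    for y in names:
        cost = sum(float(np.linalg.norm(columns[y] - columns[x])) for x in names)
        if cost < best_cost - 1e-12:
            best, best_cost = y, cost
    return best
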