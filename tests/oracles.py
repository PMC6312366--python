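"""Independent brute-force reference implementations used by the tests.

These deliberately share no code with the package: flood-fill patch
labelling by explicit stack traversal, NODF straight from the published
paired-overlap formula on a sorted matrix, exhaustive enumeration of
integer contingency tables for entropy extremes, and rank-then-Pearson
Spearman correlation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def flood_fill_patches(cover: np.ndarray, connectivity: int = 8) -> list[frozenset]:
    """Connected components of 1-cells as sets of (row, col), by DFS."""
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n_rows, n_cols = cover.shape
    seen = np.zeros_like(cover, dtype=bool)
    patches = []
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if cover[r0, c0] != 1 or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            cells = []
            while stack:
                r, c = stack.pop()
                cells.append((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        if cover[rr, cc] == 1 and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            patches.append(frozenset(cells))
    return patches


def min_pair_distance(cells_a, cells_b, cell_size: float = 10.0) -> float:
    """Exhaustive minimum centre-to-centre distance between two cell sets."""
    best = math.inf
    for (r1, c1) in cells_a:
        for (r2, c2) in cells_b:
            d = math.hypot(r1 - r2, c1 - c2) * cell_size
            best = min(best, d)
    return best


def nodf_brute(matrix: np.ndarray) -> float:
    """NODF from the published definition: sort rows/cols by decreasing
    marginal totals, take paired overlap only when the upper line is
    strictly denser, average over all row pairs and column pairs."""
    binary = (np.asarray(matrix) > 0).astype(int)
    binary = binary[binary.sum(axis=1) > 0][:, binary.sum(axis=0) > 0]
    n, m = binary.shape
    if n < 2 or m < 2:
        return float("nan")

    def axis_sum(b: np.ndarray) -> float:
        order = np.argsort(-b.sum(axis=1), kind="stable")
        b = b[order]
        fills = b.sum(axis=1)
        total = 0.0
        for i in range(b.shape[0]):
            for j in range(i + 1, b.shape[0]):
                if fills[i] > fills[j] and fills[j] > 0:
                    shared = int(np.logical_and(b[i], b[j]).sum())
                    total += 100.0 * shared / fills[j]
        return total

    pairs = n * (n - 1) / 2 + m * (m - 1) / 2
    return (axis_sum(binary) + axis_sum(binary.T)) / pairs


def enumerate_tables(row_sums, col_sums):
    """All non-negative integer matrices with the given marginals."""
    row_sums = list(row_sums)
    col_sums = list(col_sums)

    def rows_with_sum(total, k):
        if k == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in rows_with_sum(total - first, k - 1):
                yield (first, *rest)

    k = len(col_sums)

    def recurse(i, remaining_cols, acc):
        if i == len(row_sums):
            if all(v == 0 for v in remaining_cols):
                yield np.array(acc, dtype=int)
            return
        for row in rows_with_sum(row_sums[i], k):
            if all(row[j] <= remaining_cols[j] for j in range(k)):
                yield from recurse(
                    i + 1,
                    tuple(remaining_cols[j] - row[j] for j in range(k)),
                    acc + [row],
                )

    yield from recurse(0, tuple(col_sums), [])


def shannon_entropy(table: np.ndarray) -> float:
    p = table.ravel().astype(float)
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def exhaustive_entropy_extremes(row_sums, col_sums) -> tuple[float, float]:
    """(min, max) Shannon entropy over all integer tables with the marginals."""
    lo, hi = math.inf, -math.inf
    for table in enumerate_tables(row_sums, col_sums):
        h = shannon_entropy(table)
        lo = min(lo, h)
        hi = max(hi, h)
    return lo, hi


def spearman_brute(x, y) -> float:
    """Rank (average ranks for ties) then Pearson, from first principles."""

    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def moran_i_rook(values: np.ndarray) -> float:
    """Moran's I with rook (4-neighbour) contiguity weights."""
    v = values - values.mean()
    num = 0.0
    w_sum = 0
    num += 2 * (v[:-1, :] * v[1:, :]).sum()
    w_sum += 2 * v[:-1, :].size
    num += 2 * (v[:, :-1] * v[:, 1:]).sum()
    w_sum += 2 * v[:, :-1].size
    denom = (v**2).sum()
    n = values.size
    return float(n / w_sum * num / denom)
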