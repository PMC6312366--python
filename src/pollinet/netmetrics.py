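"""Bipartite network descriptors of a bee x flower visitation matrix.

Five network-level descriptors are computed from an integer visitation
matrix (rows = bee species, columns = plant species):

- connectance: realised fraction of possible links;
- nestedness: NODF (paired nested overlap over decreasing marginal
  totals, 0-100) by default, matrix temperature not implemented;
- H2': network-level complementary specialization, a two-dimensional
  Shannon-entropy statistic standardised between the minimum and maximum
  entropies attainable under the observed marginal totals, so that 0 is
  the most generalized network the marginals allow and 1 is perfect
  reciprocal specialization;
- network size: number of species (both guilds) with at least one
  interaction;
- web asymmetry: (plants - bees) / (plants + bees) among active species.

Conventions follow common bipartite-network practice: nestedness, H2',
size and asymmetry operate on the matrix pruned to active species.  For
connectance both the full configured matrix ("full", the default) and
the pruned matrix ("active") are supported, since field studies usually
report the pruned variant while a fixed simulated community has a
natural fixed denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkMetrics",
    "connectance",
    "nestedness",
    "h2prime",
    "network_size_and_asymmetry",
    "compute_metrics",
]


@dataclass(frozen=True)
class NetworkMetrics:
    connectance: float
    connectance_active: float
    nestedness: float
    nestedness_method: str
    h2: float
    size: int
    asymmetry: float

    def as_dict(self) -> dict[str, float]:
        return {
            "connectance": self.connectance,
            "connectance_active": self.connectance_active,
            "nestedness": self.nestedness,
            "h2": self.h2,
            "size": self.size,
            "asymmetry": self.asymmetry,
        }


def _as_matrix(m) -> np.ndarray:
    arr = np.asarray(getattr(m, "counts", m))
    if arr.ndim != 2:
        raise ValueError("visitation matrix must be 2-D")
    if (arr < 0).any():
        raise ValueError("visitation counts must be non-negative")
    return arr


def _prune(arr: np.ndarray) -> np.ndarray:
    return arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]


def connectance(m, mode: str = "full") -> float:
    """Fraction of matrix cells with at least one interaction.

    ``mode='full'`` divides by the full configured matrix size;
    ``mode='active'`` prunes species without interactions first (the
    R bipartite convention).
    """
    arr = _as_matrix(m)
    if mode == "active":
        arr = _prune(arr)
    if arr.size == 0:
        warnings.warn("empty visitation matrix; connectance set to 0")
        return 0.0
    return float((arr > 0).sum()) / arr.size


def nestedness(m, method: str = "NODF") -> float:
    """Nestedness of the pruned binary interaction matrix.

    NODF (Almeida-Neto et al.): for every pair of rows and every pair of
    columns, the paired overlap is the percentage of the sparser line's
    links shared with the denser line, counted only when the marginal
    totals differ strictly; NODF is the mean over all row and column
    pairs.  0 = no nested structure, 100 = perfectly nested.  Returns
    NaN when the pruned matrix has fewer than 2 rows or 2 columns.
    """
    if method != "NODF":
        raise ValueError(f"unsupported nestedness method {method!r}")
    arr = _prune(_as_matrix(m)) > 0
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return float("nan")
    return (_nodf_axis(arr) + _nodf_axis(arr.T)) / (
        _n_pairs(arr.shape[0]) + _n_pairs(arr.shape[1])
    )


def _n_pairs(n: int) -> float:
    return n * (n - 1) / 2.0


def _nodf_axis(binary: np.ndarray) -> float:
    """Sum of paired overlap percentages over all row pairs."""
    degrees = binary.sum(axis=1)
    shared = (binary.astype(np.int64) @ binary.T.astype(np.int64)).astype(float)
    total = 0.0
    for i in range(binary.shape[0]):
        for j in range(i + 1, binary.shape[0]):
            hi, lo = (i, j) if degrees[i] > degrees[j] else (j, i)
            if degrees[hi] > degrees[lo] and degrees[lo] > 0:
                total += 100.0 * shared[hi, lo] / degrees[lo]
    return total


# ---------------------------------------------------------------------------
# H2' — standardised two-dimensional Shannon entropy


def _xlogx(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def _entropy_sum(a: np.ndarray) -> float:
    """S = sum a*ln(a); H2 = ln(N) - S/N for marginal-preserving tables."""
    return float(_xlogx(a).sum())


def _cycle_improve(a: np.ndarray, maximize_S: bool, unit_only: bool = True) -> None:
    """Greedy 4-cycle transfers preserving marginals, in place.

    A transfer of ``d`` units along the cycle (i1,j1)+(i2,j2) / (i1,j2)+
    (i2,j1) keeps both marginals fixed.  Moves are applied while they
    strictly improve S = sum a*ln(a) in the requested direction.  With
    ``unit_only`` False, the full feasible transfer is also tried, which
    drives the table toward a vertex (useful when minimising entropy,
    i.e. maximising S).
    """
    n_rows, n_cols = a.shape
    if n_rows < 2 or n_cols < 2:
        return
    sign = 1.0 if maximize_S else -1.0
    rr = np.arange(n_rows)
    cc = np.arange(n_cols)
    max_iter = 50 * a.size + 200

    def delta_S(transfer: np.ndarray) -> np.ndarray:
        """Change of S for transferring `transfer` units along each cycle
        (axes: i1, i2, j1, j2); gains at (i1,j1),(i2,j2), losses at
        (i1,j2),(i2,j1)."""
        a11 = np.broadcast_to(a[:, None, :, None].astype(float), transfer.shape)
        a22 = np.broadcast_to(a[None, :, None, :].astype(float), transfer.shape)
        a12 = np.broadcast_to(a[:, None, None, :].astype(float), transfer.shape)
        a21 = np.broadcast_to(a[None, :, :, None].astype(float), transfer.shape)
        return (
            _xlogx(a11 + transfer) - _xlogx(a11)
            + _xlogx(a22 + transfer) - _xlogx(a22)
            + _xlogx(a12 - transfer) - _xlogx(a12)
            + _xlogx(a21 - transfer) - _xlogx(a21)
        )

    for _ in range(max_iter):
        feas = np.minimum(a[:, None, None, :], a[None, :, :, None])  # max transfer
        candidates: list[np.ndarray] = [np.minimum(feas, 1).astype(float)]
        if not unit_only:
            candidates.append(feas.astype(float))
        best_score = 1e-12
        best_move = None
        for transfer in candidates:
            score = sign * delta_S(transfer)
            score[transfer <= 0] = -np.inf
            score[rr, rr, :, :] = -np.inf
            score[:, :, cc, cc] = -np.inf
            idx = np.unravel_index(np.argmax(score), score.shape)
            if score[idx] > best_score:
                best_score = score[idx]
                best_move = (idx, int(transfer[idx]))
        if best_move is None:
            return
        (i1, i2, j1, j2), d = best_move
        a[i1, j1] += d
        a[i2, j2] += d
        a[i1, j2] -= d
        a[i2, j1] -= d


def _max_entropy_table(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Integer table with the given marginals and (heuristically) maximal
    Shannon entropy: largest-remainder rounding of the independence table
    followed by greedy 4-cycle improvement."""
    n = rows.sum()
    target = np.outer(rows, cols) / n
    a = np.floor(target).astype(np.int64)
    row_def = rows - a.sum(axis=1)
    col_def = cols - a.sum(axis=0)
    frac = target - a
    # assign leftover units to cells with the largest fractional remainder
    while row_def.sum() > 0:
        masked = np.where(
            (row_def[:, None] > 0) & (col_def[None, :] > 0), frac, -1.0
        )
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        a[i, j] += 1
        frac[i, j] -= 1.0
        row_def[i] -= 1
        col_def[j] -= 1
    _cycle_improve(a, maximize_S=False, unit_only=True)
    return a


def _min_entropy_table(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Integer table with the given marginals and (heuristically) minimal
    Shannon entropy: greedy mass concentration followed by 4-cycle
    improvement including full transfers."""
    a = np.zeros((rows.size, cols.size), dtype=np.int64)
    row_rem = rows.astype(np.int64).copy()
    col_rem = cols.astype(np.int64).copy()
    while row_rem.sum() > 0:
        cap = np.minimum(row_rem[:, None], col_rem[None, :])
        i, j = np.unravel_index(np.argmax(cap), cap.shape)
        a[i, j] += cap[i, j]
        row_rem[i] -= cap[i, j]
        col_rem[j] -= cap[i, j]
    _cycle_improve(a, maximize_S=True, unit_only=False)
    return a


def entropy_extremes(rows, cols) -> tuple[float, float]:
    """(H2_min, H2_max): extreme two-dimensional Shannon entropies over
    integer tables with the given marginal totals (heuristic search)."""
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    if rows.sum() != cols.sum():
        raise ValueError("row and column totals must agree")
    # extremes depend only on the marginal multisets; canonical ordering
    # makes the heuristic invariant to row/column permutation
    rows = np.sort(rows)[::-1]
    cols = np.sort(cols)[::-1]
    n = rows.sum()
    if n == 0:
        return float("nan"), float("nan")
    log_n = np.log(n)
    h_max = log_n - _entropy_sum(_max_entropy_table(rows, cols)) / n
    h_min = log_n - _entropy_sum(_min_entropy_table(rows, cols)) / n
    return float(h_min), float(h_max)


def h2prime(m) -> float:
    """H2' complementary specialization of an integer visitation matrix.

    H2 = -sum p_ij ln p_ij over the pruned matrix; H2' = (H2max - H2) /
    (H2max - H2min) with the extremes taken over integer matrices sharing
    the observed marginal totals, clamped to [0, 1].  Returns NaN for an
    empty (zero-total) matrix, and 0 when the marginals admit only one
    entropy value (degenerate 1 x k networks).
    """
    arr = _prune(_as_matrix(m)).astype(np.int64)
    total = int(arr.sum())
    if total == 0:
        warnings.warn("zero-total visitation matrix; H2' undefined")
        return float("nan")
    if not np.issubdtype(np.asarray(getattr(m, "counts", m)).dtype, np.integer):
        raise ValueError("H2' requires integer visit counts")
    h2 = np.log(total) - _entropy_sum(arr) / total
    h_min, h_max = entropy_extremes(arr.sum(axis=1), arr.sum(axis=0))
    if h_max - h_min <= 1e-12:
        return 0.0
    return float(np.clip((h_max - h2) / (h_max - h_min), 0.0, 1.0))


def network_size_and_asymmetry(m) -> tuple[int, float]:
    """Active species count (bees + plants) and web asymmetry.

    Asymmetry is (plants - bees) / (plants + bees) over species with at
    least one interaction; positive when plants outnumber bees; 0 for an
    empty network.
    """
    arr = _as_matrix(m)
    bees = int((arr.sum(axis=1) > 0).sum())
    plants = int((arr.sum(axis=0) > 0).sum())
    size = bees + plants
    asym = 0.0 if size == 0 else (plants - bees) / size
    return size, float(asym)


def compute_metrics(m) -> NetworkMetrics:
    """All five descriptors for one visitation matrix."""
    size, asym = network_size_and_asymmetry(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conn_full = connectance(m, mode="full")
        conn_active = connectance(m, mode="active")
        h2 = h2prime(m) if np.asarray(getattr(m, "counts", m)).sum() > 0 else float("nan")
    return NetworkMetrics(
        connectance=conn_full,
        connectance_active=conn_active,
        nestedness=nestedness(m),
        nestedness_method="NODF",
        h2=h2,
        size=size,
        asymmetry=asym,
    )
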