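"""Functional-connectivity modularity with a rewired-null normalization.

Pipeline: a region x time parcellated timeseries is turned into an
unthresholded Pearson correlation matrix; the Louvain algorithm searches
for a modular partition maximizing

    Q = (1/l) * sum_{i,j} [ w_ij - gamma * k_i k_j / l ] * delta(m_i, m_j)

with l the total weight (over ordered pairs), k_i the weighted degree,
gamma the resolution (default 1) and the diagonal excluded.  Correlation
matrices carry negative weights; these are treated asymmetrically in the
standard signed-network fashion: the positive and negative parts are scored
separately and combined as

    Q = Q+  -  ( l- / (l+ + l-) ) * Q-

so that antagonistic within-module weights penalize the partition in
proportion to their share of total weight.  Louvain is run many times with
randomized node order (the only stochastic element); the subject-level
statistic is the mean Q over runs, normalized by the mean Q of "rewired"
null matrices obtained by symmetrically permuting the off-diagonal weights
(which preserves the weight distribution and hence the average correlation
strength the raw Q is sensitive to).

The greedy two-phase optimization operates on the dense (signed) modularity
matrix, so the same code serves the aggregation phase; the node-sweep inner
loop is JIT-compiled with numba when available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParcelTimeseries",
    "FcMatrix",
    "ModularityResult",
    "fc_matrix",
    "q_value",
    "louvain_partition",
    "modularity_score",
]


@dataclass
class ParcelTimeseries:
    """A subject's parcellated recording: regions x time samples."""

    subject: str
    timepoint: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be regions x time")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 time samples")


@dataclass
class FcMatrix:
    """Symmetric Pearson connectivity; the diagonal is ignored downstream."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = self.w.shape[0]
        if self.w.ndim != 2 or self.w.shape != (n, n):
            raise ValueError("w must be square")
        if not np.allclose(self.w, self.w.T, atol=1e-10):
            raise ValueError("w must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.w.shape[0]


@dataclass
class ModularityResult:
    partition: np.ndarray
    q_raw: float
    q_null_mean: float
    q_norm: float
    gamma: float
    n_louvain: int
    n_null: int
    seed: int | None


def fc_matrix(ts) -> FcMatrix:
    """Unthresholded pairwise Pearson correlation of regional timeseries.

    Constant regions get zero correlations (with a warning) rather than NaN.
    """
    data = ts.data if isinstance(ts, ParcelTimeseries) else np.asarray(ts, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a regions x time matrix with >= 2 samples")
    sd = data.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant region timeseries: correlations set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.corrcoef(data)
    w = np.where(np.isfinite(w), w, 0.0)
    np.fill_diagonal(w, 1.0)
    return FcMatrix(w=w)


def _split_signed(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    wz = w.copy()
    np.fill_diagonal(wz, 0.0)  # self-connections excluded from all sums
    wp = np.where(wz > 0, wz, 0.0)
    wn = np.where(wz < 0, -wz, 0.0)
    return wp, wn, float(wp.sum()), float(wn.sum())


def _q_one_sign(w: np.ndarray, l: float, partition: np.ndarray, gamma: float) -> float:
    if l <= 0:
        return 0.0
    k = w.sum(axis=1)
    same = partition[:, None] == partition[None, :]
    return float(((w - gamma * np.outer(k, k) / l) * same).sum() / l)


def q_value(w, partition, gamma: float = 1.0) -> float:
    """Modularity Q of a partition, with asymmetric negative weighting.

    For non-negative matrices this is exactly the degree-corrected Q over
    ordered node pairs (diagonal excluded); for signed matrices
    ``Q = Q+ - (l-/(l+ + l-)) Q-``.
    """
    w = w.w if isinstance(w, FcMatrix) else np.asarray(w, dtype=float)
    partition = np.asarray(partition)
    if partition.shape != (w.shape[0],):
        raise ValueError(
            f"partition length {partition.shape} does not match matrix size {w.shape[0]}"
        )
    wp, wn, lp, ln = _split_signed(w)
    qp = _q_one_sign(wp, lp, partition, gamma)
    qn = _q_one_sign(wn, ln, partition, gamma)
    if lp + ln == 0:
        return 0.0
    return qp - (ln / (lp + ln)) * qn


def _signed_modularity_matrix(w: np.ndarray, gamma: float) -> np.ndarray:
    """Dense matrix B with Q(partition) = sum_{ij} B_ij delta(m_i, m_j)."""
    wp, wn, lp, ln = _split_signed(w)
    B = np.zeros_like(wp)
    if lp > 0:
        kp = wp.sum(axis=1)
        B += (wp - gamma * np.outer(kp, kp) / lp) / lp
    if ln > 0:
        kn = wn.sum(axis=1)
        B -= (wn - gamma * np.outer(kn, kn) / ln) / (lp + ln)
    np.fill_diagonal(B, 0.0)
    return B


def _louvain_sweep_kernel(B, labels, order):
    """One pass of greedy local moves on modularity matrix B; returns #moves."""
    n = B.shape[0]
    n_comm = n
    moves = 0
    gains = np.zeros(n_comm)
    for oi in range(n):
        i = order[oi]
        old = labels[i]
        for c in range(n_comm):
            gains[c] = 0.0
        for j in range(n):
            if j != i:
                gains[labels[j]] += B[i, j]
        best = old
        best_gain = gains[old]
        for c in range(n_comm):
            if gains[c] > best_gain + 1e-12:
                best_gain = gains[c]
                best = c
        if best != old:
            labels[i] = best
            moves += 1
    return moves


try:  # pragma: no cover
    from numba import njit

    _louvain_sweep = njit(cache=True)(_louvain_sweep_kernel)
except Exception:  # pragma: no cover
    _louvain_sweep = _louvain_sweep_kernel


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(np.int64)


def _louvain_on_matrix(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two-phase Louvain on a dense modularity matrix (symmetric, zero diag)."""
    n0 = B.shape[0]
    assignment = np.arange(n0)
    current = B
    while True:
        n = current.shape[0]
        labels = np.arange(n, dtype=np.int64)
        improved = False
        while True:
            order = rng.permutation(n).astype(np.int64)
            moves = _louvain_sweep(current, labels, order)
            if moves == 0:
                break
            improved = True
        labels = _relabel(labels)
        n_comm = int(labels.max()) + 1
        if not improved or n_comm == n:
            return _relabel(labels[assignment])
        # aggregation: collapse communities into super-nodes
        S = np.zeros((n_comm, n))
        S[labels, np.arange(n)] = 1.0
        current = S @ current @ S.T
        np.fill_diagonal(current, 0.0)  # within-community mass is a constant offset
        assignment = labels[assignment]


def louvain_partition(
    w,
    gamma: float = 1.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, float]:
    """One seeded Louvain run; returns (partition, Q per ``q_value``)."""
    wm = w.w if isinstance(w, FcMatrix) else np.asarray(w, dtype=float)
    if not np.all(np.isfinite(wm)):
        raise ValueError("weights must be finite")
    B = _signed_modularity_matrix(wm, gamma)
    rng = np.random.default_rng(seed)
    partition = _louvain_on_matrix(B, rng)
    return partition, q_value(wm, partition, gamma)


def _rewired_null(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Symmetric permutation of the off-diagonal weights; diagonal untouched."""
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu].copy()
    rng.shuffle(vals)
    out = np.zeros_like(w)
    out[iu] = vals
    out = out + out.T
    np.fill_diagonal(out, np.diag(w))
    return out


def modularity_score(
    w,
    n_louvain: int = 100,
    n_null: int = 100,
    gamma: float = 1.0,
    seed: int | None = 0,
) -> ModularityResult:
    """Subject-level normalized modularity.

    ``q_raw`` is the mean Q over ``n_louvain`` randomized Louvain runs
    (the partition reported is the best-Q run's); each of the ``n_null``
    rewired matrices is scored with a single Louvain run, and
    ``q_norm = q_raw / mean(null Q)``.
    """
    wm = w.w if isinstance(w, FcMatrix) else np.asarray(w, dtype=float)
    rng = np.random.default_rng(seed)
    qs = np.empty(n_louvain)
    best_partition, best_q = None, -np.inf
    B = _signed_modularity_matrix(wm, gamma)
    for i in range(n_louvain):
        part = _louvain_on_matrix(B, rng)
        qs[i] = q_value(wm, part, gamma)
        if qs[i] > best_q:
            best_q, best_partition = qs[i], part
    q_raw = float(qs.mean())

    null_qs = np.empty(n_null)
    for i in range(n_null):
        wn = _rewired_null(wm, rng)
        Bn = _signed_modularity_matrix(wn, gamma)
        part = _louvain_on_matrix(Bn, rng)
        null_qs[i] = q_value(wn, part, gamma)
    q_null = float(null_qs.mean())
    if q_null <= 0:
        raise ValueError(
            f"mean null Q = {q_null:.4g} <= 0: normalization undefined for this matrix"
        )
    return ModularityResult(
        partition=best_partition,
        q_raw=q_raw,
        q_null_mean=q_null,
        q_norm=q_raw / q_null,
        gamma=gamma,
        n_louvain=n_louvain,
        n_null=n_null,
        seed=seed,
    )
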