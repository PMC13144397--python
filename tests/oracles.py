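"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive — written straight from the definitions, with
no shared code or algorithmic ideas with the package implementations they
check.
"""

from __future__ import annotations

import numpy as np


def lz76_reference(s: str) -> int:
    """Exhaustive-history component count, straight from the definition.

    Scanning left to right, each component is the shortest prefix of the
    remaining suffix that cannot be produced by copying from the extended
    history (substring search over everything before the component's last
    character); the final component may remain producible.
    """
    n = len(s)
    i = 0
    c = 0
    while i < n:
        l = 1
        while i + l <= n and s[i : i + l] in s[: i + l - 1]:
            l += 1
        c += 1
        i += l
    return c


def modularity_reference(w: np.ndarray, partition: np.ndarray, gamma: float = 1.0) -> float:
    """Signed modularity via explicit double loops over ordered node pairs.

    Positive and negative parts each follow
    ``(1/l) sum_ij [w_ij - gamma k_i k_j / l] delta(m_i, m_j)`` with the
    diagonal weights excluded, combined as ``Q+ - (l-/(l+ + l-)) Q-``.
    """
    n = w.shape[0]

    def one_sign(mat):
        l = 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    l += mat[i, j]
        if l <= 0:
            return 0.0, 0.0
        k = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i != j:
                    k[i] += mat[i, j]
        q = 0.0
        for i in range(n):
            for j in range(n):
                if partition[i] == partition[j]:
                    wij = mat[i, j] if i != j else 0.0
                    q += wij - gamma * k[i] * k[j] / l
        return q / l, l

    wp = np.where(w > 0, w, 0.0).copy()
    wn = np.where(w < 0, -w, 0.0).copy()
    np.fill_diagonal(wp, 0.0)
    np.fill_diagonal(wn, 0.0)
    qp, lp = one_sign(wp)
    qn, ln = one_sign(wn)
    if lp + ln == 0:
        return 0.0
    return qp - (ln / (lp + ln)) * qn


def set_partitions(items: list):
    """All set partitions of *items* (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def best_partition_exhaustive(w: np.ndarray, gamma: float = 1.0) -> tuple[np.ndarray, float]:
    """Globally optimal partition by enumerating every set partition."""
    n = w.shape[0]
    best_q, best = -np.inf, None
    for blocks in set_partitions(list(range(n))):
        labels = np.zeros(n, dtype=int)
        for m, block in enumerate(blocks):
            for i in block:
                labels[i] = m
        q = modularity_reference(w, labels, gamma)
        if q > best_q:
            best_q, best = q, labels
    return best, best_q
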