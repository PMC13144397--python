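"""Lempel-Ziv 1976 exhaustive-parsing complexity.

The complexity c(S) of a finite sequence S is the number of components in
its exhaustive production history: scanning left to right, each component is
the shortest prefix of the remaining suffix that cannot be copied from the
already-seen extended history (the final component may be copyable).  For a
binary sequence of length n, 1 <= c(S) <= n, and for i.i.d. fair-coin input
c(S) concentrates around n / log2(n).

The scanning loop is O(n^2) in the worst case; it is JIT-compiled with numba
when available and falls back to the identical pure-Python code otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lz76"]


def _lz76_kernel(s):
    # Kaspar-Schuster scan. s: 1-D uint8 array of symbols (any alphabet).
    n = s.shape[0]
    c = 1
    i = 0        # start of the history prefix being matched against
    u = 1        # start of the current component (relative split point)
    v = 1        # length of the current candidate extension
    vmax = 1     # longest match found for the current component
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            if v > vmax:
                vmax = v
            i += 1
            if i == u:          # all history start points exhausted
                c += 1
                u += vmax if vmax > v else v
                v = 1
                i = 0
                vmax = 1
            else:
                v = 1
    if v != 1:
        c += 1
    return c


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _lz76_jit = njit(cache=True)(_lz76_kernel)
except Exception:  # pragma: no cover
    _lz76_jit = _lz76_kernel


def lz76(sequence) -> int:
    """Number of components in the LZ76 exhaustive parsing of *sequence*.

    Parameters
    ----------
    sequence
        1-D array-like of symbols (binary in normal use; any small integer
        alphabet is accepted), or a string of single-character symbols.

    Returns
    -------
    int
        The parse-component count ``c(S)``, between 1 and ``len(sequence)``.
    """
    if isinstance(sequence, str):
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    else:
        arr = np.ascontiguousarray(np.asarray(sequence), dtype=np.uint8).ravel()
    if arr.size == 0:
        raise ValueError("lz76 requires a non-empty sequence")
    return int(_lz76_jit(arr))
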