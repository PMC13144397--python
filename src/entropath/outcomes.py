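"""Change-score correlation structure across the seven study outcomes.

Two analyses operate on per-subject change scores for the active-vs-placebo
contrast:

* ``adjusted_change_correlation`` — the modularity-change vs
  well-being-change association controlling for the baseline covariate
  (both change scores are residualized on baseline well-being by OLS and
  the residuals correlated; two-tailed p at df = n - 3).
* ``correlation_cluster_test`` — a non-parametric cluster test of the
  K x K Pearson correlation matrix.  Cells significant at ``alpha_cell``
  define edges of an outcome graph; clusters are connected components;
  the cluster mass is the summed |Fisher-z(r)| over member edges; the null
  permutes each outcome's subject order independently (destroying all
  cross-outcome association while preserving marginals) and records the
  maximum cluster mass, giving a family-wise-corrected p per observed
  cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrClusterResult", "adjusted_change_correlation", "correlation_cluster_test"]


@dataclass
class CorrClusterResult:
    outcomes: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    significant_mask: np.ndarray
    clusters: list[list[str]]
    cluster_masses: np.ndarray
    cluster_p: np.ndarray
    n_perm: int
    alpha_cell: float

    def significant_clusters(self, alpha: float = 0.05) -> list[list[str]]:
        return [c for c, p in zip(self.clusters, self.cluster_p) if p < alpha]


def adjusted_change_correlation(x_change, y_change, baseline_covariate) -> tuple[float, float]:
    """Partial correlation of two change scores given a baseline covariate.

    Both change scores are residualized on the covariate by OLS; returns
    the Pearson r of the residuals and its two-tailed p at df = n - 3.
    A constant covariate falls back to the plain Pearson correlation
    (df = n - 2) with a warning.
    """
    x = np.asarray(x_change, dtype=float)
    y = np.asarray(y_change, dtype=float)
    z = np.asarray(baseline_covariate, dtype=float)
    n = x.size
    if y.size != n or z.size != n:
        raise ValueError("inputs must be aligned")
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[mask], y[mask], z[mask]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 complete cases")
    if z.std() == 0:
        warnings.warn("constant covariate: falling back to plain Pearson correlation")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    def _resid(v: np.ndarray) -> np.ndarray:
        zc = z - z.mean()
        beta = (zc @ (v - v.mean())) / (zc @ zc)
        return v - v.mean() - beta * zc

    rx, ry = _resid(x), _resid(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def _corr_and_p(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r and two-tailed p for a subjects x outcomes array."""
    n, k = data.shape
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(p, 1.0)
    return r, p


def _cluster_stats(
    r: np.ndarray, p: np.ndarray, alpha_cell: float
) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected components over outcomes linked by significant cells."""
    k = r.shape[0]
    sig = (p < alpha_cell) & ~np.eye(k, dtype=bool)
    comps: list[np.ndarray] = []
    seen = np.zeros(k, dtype=bool)
    for start in range(k):
        if seen[start] or not sig[start].any():
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for w_ in np.flatnonzero(sig[v]):
                if not seen[w_]:
                    seen[w_] = True
                    stack.append(w_)
        comps.append(np.sort(np.array(comp)))
    zmat = np.abs(np.arctanh(np.clip(r, -0.999999, 0.999999)))
    masses = []
    for comp in comps:
        sub = sig[np.ix_(comp, comp)]
        masses.append(float(zmat[np.ix_(comp, comp)][sub].sum() / 2.0))  # each edge once
    return comps, np.asarray(masses)


def correlation_cluster_test(
    table,
    alpha_cell: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = 0,
) -> CorrClusterResult:
    """Non-parametric cluster test of an outcome change-score matrix.

    ``table`` is a subjects x outcomes DataFrame (or array).  Missing
    values are not supported below n = 5 complete pairs; rows with missing
    entries are used pairwise-complete for the observed matrix but the
    permutation scheme requires complete data, so tables with missing
    values raise unless every pair has >= 5 complete cases and rows are
    dropped to the complete subset.
    """
    if isinstance(table, pd.DataFrame):
        names = tuple(str(c) for c in table.columns)
        data = table.to_numpy(dtype=float)
    else:
        data = np.asarray(table, dtype=float)
        names = tuple(f"outcome_{j}" for j in range(data.shape[1]))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a subjects x outcomes table with >= 2 outcomes")
    if np.isnan(data).any():
        pair_n = np.array(
            [
                [np.sum(np.isfinite(data[:, i]) & np.isfinite(data[:, j])) for j in range(data.shape[1])]
                for i in range(data.shape[1])
            ]
        )
        if (pair_n < 5).any():
            raise ValueError("some outcome pairs have fewer than 5 complete cases")
        keep = np.all(np.isfinite(data), axis=1)
        warnings.warn(
            f"dropping {np.sum(~keep)} rows with missing values for the permutation test"
        )
        data = data[keep]
    n = data.shape[0]
    if n < 6:
        raise ValueError("need at least 6 subjects")

    r, p = _corr_and_p(data)
    comps, masses = _cluster_stats(r, p, alpha_cell)
    k = data.shape[1]
    sig_mask = (p < alpha_cell) & ~np.eye(k, dtype=bool)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        perm = rng.permuted(data, axis=0)  # each outcome's subject order shuffled independently
        rp, pp = _corr_and_p(perm)
        _, m = _cluster_stats(rp, pp, alpha_cell)
        null_max[b] = m.max() if m.size else 0.0
    cluster_p = np.array([(1 + np.sum(null_max >= m)) / (1 + n_perm) for m in masses])

    order = np.argsort(-masses) if masses.size else np.array([], dtype=int)
    return CorrClusterResult(
        outcomes=names,
        r=r,
        p=p,
        significant_mask=sig_mask,
        clusters=[[names[i] for i in comps[j]] for j in order],
        cluster_masses=masses[order],
        cluster_p=cluster_p[order],
        n_perm=n_perm,
        alpha_cell=alpha_cell,
    )
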