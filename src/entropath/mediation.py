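"""Three-variable linear mediation: X -> M -> Y.

In the emulated study X is the all-sensor-average brain entropy (LZc) at
2 h post-dose, M is next-day psychological insight and Y the one-month
well-being change.  Paths are ordinary least squares fits:

    a  : M ~ X            (X -> M)
    b  : Y ~ X + M        (M -> Y adjusting X)
    c  : Y ~ X            (total effect)
    c' : Y ~ X + M        (direct effect adjusting M)

OLS algebra guarantees c = c' + a*b exactly on any sample.  Normalized
coefficients come from refitting on z-scored variables; the indirect effect
a*b gets a percentile bootstrap interval (subjects resampled with
replacement).  The verdict follows Baron-Kenny-style criteria: *full*
mediation when a and b are significant and the direct path loses
significance (with |c'| < |c|), *partial* when a and b are significant but
c' stays significant, *none* otherwise.  Both the verdict and the bootstrap
interval are reported so users can apply either standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["PathEstimate", "MediationResult", "fit_mediation"]


@dataclass
class PathEstimate:
    beta: float
    se: float
    p: float
    beta_normalized: float


@dataclass
class MediationResult:
    path_a: PathEstimate
    path_b: PathEstimate
    path_c: PathEstimate
    path_c_prime: PathEstimate
    indirect_effect: float
    indirect_ci: tuple[float, float]
    verdict: str  # {"full", "partial", "none"}
    n: int
    n_boot: int
    alpha: float

    def to_dict(self) -> dict:
        def path(p: PathEstimate) -> dict:
            return {"beta": p.beta, "se": p.se, "p": p.p, "beta_normalized": p.beta_normalized}

        return {
            "path_a": path(self.path_a),
            "path_b": path(self.path_b),
            "path_c": path(self.path_c),
            "path_c_prime": path(self.path_c_prime),
            "indirect_effect": self.indirect_effect,
            "indirect_ci": list(self.indirect_ci),
            "verdict": self.verdict,
            "n": self.n,
            "n_boot": self.n_boot,
            "alpha": self.alpha,
        }


def _ols_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Raw (beta, se, p) for paths a, b, c, c' on one sample."""
    Xa = sm.add_constant(x)
    fit_a = sm.OLS(m, Xa).fit()
    fit_c = sm.OLS(y, Xa).fit()
    Xb = sm.add_constant(np.column_stack([x, m]))
    fit_bc = sm.OLS(y, Xb).fit()
    a = (fit_a.params[1], fit_a.bse[1], fit_a.pvalues[1])
    c = (fit_c.params[1], fit_c.bse[1], fit_c.pvalues[1])
    cp = (fit_bc.params[1], fit_bc.bse[1], fit_bc.pvalues[1])
    b = (fit_bc.params[2], fit_bc.bse[2], fit_bc.pvalues[2])
    return a, b, c, cp


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (v - v.mean()) / sd


def _bootstrap_indirect(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized percentile bootstrap of a*b (closed-form OLS moments)."""
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = (xc**2).sum(axis=1)
    smm = (mc**2).sum(axis=1)
    sxm = (xc * mc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    smy = (mc * yc).sum(axis=1)
    det = smm * sxx - sxm**2
    with np.errstate(divide="ignore", invalid="ignore"):
        a_hat = np.where(sxx > 0, sxm / sxx, np.nan)
        b_hat = np.where(det > 1e-12 * sxx * smm + 1e-300, (smy * sxx - sxy * sxm) / det, np.nan)
    boots = a_hat * b_hat
    return boots[np.isfinite(boots)]


def fit_mediation(
    x,
    m,
    y,
    n_boot: int = 5000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Fit the mediation model and bootstrap the indirect effect.

    Parameters
    ----------
    x, m, y
        Per-subject predictor, mediator and outcome (aligned, complete).
    n_boot
        Bootstrap resamples for the percentile interval of a*b.
    alpha
        Significance level for path tests and the (1 - alpha) interval.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must be aligned")
    if n < 5:
        raise ValueError("need at least 5 complete cases")
    if not np.all(np.isfinite(np.concatenate([x, m, y]))):
        raise ValueError("inputs must be finite")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 0.999:
        raise ValueError(
            f"predictor and mediator are collinear (|r| = {abs(r_xm):.4f}); "
            "the b and c' paths are not identifiable"
        )

    raw = _ols_paths(x, m, y)
    norm = _ols_paths(_zscore(x), _zscore(m), _zscore(y))
    a, b, c, cp = (
        PathEstimate(beta=float(r[0]), se=float(r[1]), p=float(r[2]), beta_normalized=float(z[0]))
        for r, z in zip(raw, norm)
    )

    indirect = a.beta * b.beta
    rng = np.random.default_rng(seed)
    boots = _bootstrap_indirect(x, m, y, n_boot, rng)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    a_sig = a.p < alpha
    b_sig = b.p < alpha
    cp_sig = cp.p < alpha
    if a_sig and b_sig and not cp_sig and abs(cp.beta) < abs(c.beta):
        verdict = "full"
    elif a_sig and b_sig and cp_sig:
        verdict = "partial"
    else:
        verdict = "none"

    return MediationResult(
        path_a=a,
        path_b=b,
        path_c=c,
        path_c_prime=cp,
        indirect_effect=float(indirect),
        indirect_ci=(float(lo), float(hi)),
        verdict=verdict,
        n=n,
        n_boot=n_boot,
        alpha=alpha,
    )
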