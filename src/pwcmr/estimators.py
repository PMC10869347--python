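"""Two-sample summary-statistic MR estimators and heterogeneity statistics.

Given per-variant effects on an exposure (beta_x, se_x) and an outcome
(beta_y, se_y), each instrument's ratio estimate is r_i = beta_y_i/beta_x_i.
The estimators implemented:

* IVW — inverse-variance-weighted mean of the ratios with weights
  w_i = beta_x_i^2 / se_y_i^2, identical to weighted zero-intercept
  regression of beta_y on beta_x with weights 1/se_y^2. Fixed-effect SE
  1/sqrt(sum w) by default; ``random_effects=True`` inflates the SE by
  max(1, sqrt(Q/(L-1))).
* Weighted median — inverse-variance-weighted median of the ratios
  (ratio SE by the delta approximation se_y/|beta_x|), SE by seeded
  parametric bootstrap.
* Simple / weighted mode — mode of the ratio density under a Gaussian
  kernel with Silverman bandwidth (tuning factor phi), SE by seeded
  parametric bootstrap.

Heterogeneity: Cochran's Q over instruments (chi-square, L-1 df) with the
average per-IV heterogeneity Q/(L-1); an analogous Q across cluster-level
estimates; and a difference Z-test between two estimates (SEs may be given
as 95% CIs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MRInput",
    "MRResult",
    "ivw",
    "weighted_median",
    "mode_estimator",
    "run_all_estimators",
    "mr_per_cluster",
    "cross_cluster_q",
    "difference_z",
    "EstimatorUnavailable",
]

METHOD_ORDER = ("IVW", "weighted_median", "weighted_mode", "simple_mode")


class EstimatorUnavailable(ValueError):
    """Raised when an estimator's minimum instrument count is not met."""


@dataclass
class MRInput:
    """Harmonised per-instrument effects on exposure and outcome."""

    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self):
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        ln = len(self.beta_x)
        if not (len(self.se_x) == len(self.beta_y) == len(self.se_y) == ln):
            raise ValueError("MRInput vectors must have equal length")
        if ln == 0:
            raise ValueError("MRInput needs at least one instrument")
        if (self.se_x <= 0).any() or (self.se_y <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.ids is None:
            self.ids = [f"iv{i}" for i in range(ln)]

    def __len__(self) -> int:
        return len(self.beta_x)

    def drop_null_exposure(self) -> "MRInput":
        """Exclude instruments with beta_x == 0 (undefined ratio)."""
        keep = self.beta_x != 0
        if not keep.any():
            raise ValueError("no instrument with nonzero exposure effect")
        return MRInput(
            self.beta_x[keep],
            self.se_x[keep],
            self.beta_y[keep],
            self.se_y[keep],
            [v for v, k in zip(self.ids, keep) if k],
        )

    def subset(self, idx) -> "MRInput":
        idx = np.asarray(idx)
        return MRInput(
            self.beta_x[idx],
            self.se_x[idx],
            self.beta_y[idx],
            self.se_y[idx],
            [self.ids[i] for i in np.flatnonzero(idx) if idx.dtype == bool]
            if idx.dtype == bool
            else [self.ids[i] for i in idx],
        )


@dataclass
class MRResult:
    """A causal-effect estimate with its uncertainty and heterogeneity."""

    method: str
    alpha: float
    se: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_pval: float | None = None
    avg_het: float | None = None

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        zq = stats.norm.ppf(0.5 + level / 2)
        return (self.alpha - zq * self.se, self.alpha + zq * self.se)


def _normal_p(alpha: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(alpha) / se)) if se > 0 else float("nan")


def ivw(d: MRInput, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted estimate with Cochran's Q heterogeneity."""
    d = d.drop_null_exposure()
    r = d.beta_y / d.beta_x
    w = d.beta_x**2 / d.se_y**2
    sw = float(w.sum())
    alpha = float((w * r).sum() / sw)
    se = 1.0 / math.sqrt(sw)
    L = len(d)
    q = float((w * (r - alpha) ** 2).sum())
    if L > 1:
        q_pval = float(stats.chi2.sf(q, L - 1))
        avg_het = q / (L - 1)
        if random_effects:
            se *= max(1.0, math.sqrt(q / (L - 1)))
    else:
        q, q_pval, avg_het = None, None, None
    return MRResult(
        method="IVW",
        alpha=alpha,
        se=se,
        pval=_normal_p(alpha, se),
        n_snp=L,
        q_stat=q,
        q_pval=q_pval,
        avg_het=avg_het,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (cumulative weight mid-point rule)."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, p, v))


def weighted_median(
    d: MRInput, n_boot: int = 1000, seed: int = 1
) -> MRResult:
    """Weighted median of ratio estimates; bootstrap SE.

    Ratio weights are 1/se_ratio^2 with se_ratio = se_y/|beta_x|. The SE is
    the standard deviation of the weighted median over ``n_boot`` parametric
    resamples of (beta_x, beta_y); weights are held at their point values.
    """
    d = d.drop_null_exposure()
    if len(d) < 3:
        raise EstimatorUnavailable("weighted median needs >= 3 instruments")
    r = d.beta_y / d.beta_x
    w = (d.beta_x / d.se_y) ** 2
    alpha = _weighted_median(r, w)
    rng = np.random.default_rng(seed)
    bx = rng.normal(d.beta_x, d.se_x, size=(n_boot, len(d)))
    by = rng.normal(d.beta_y, d.se_y, size=(n_boot, len(d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = by / bx
    ests = np.empty(n_boot)
    for i in range(n_boot):
        ri = rb[i]
        ok = np.isfinite(ri)
        ests[i] = _weighted_median(ri[ok], w[ok])
    se = float(ests.std(ddof=1))
    return MRResult(
        method="weighted_median",
        alpha=alpha,
        se=se,
        pval=_normal_p(alpha, se),
        n_snp=len(d),
    )


def _silverman_bandwidth(r: np.ndarray, phi: float) -> float:
    s = r.std(ddof=1)
    iqr = np.subtract(*np.percentile(r, [75, 25])) / 1.349
    spread = min(s, iqr) if iqr > 0 else s
    if spread <= 0:
        return 0.0
    return float(phi * 0.9 * spread * len(r) ** (-0.2))


def _kde_mode(r: np.ndarray, w: np.ndarray, h: float, grid_size: int = 512, refine: bool = True) -> float:
    """Argmax of the weighted Gaussian-kernel density of the ratios."""
    if h <= 0:  # all ratios (essentially) identical
        return float(r[0])
    lo, hi = r.min() - 3 * h, r.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2)).sum(axis=0)
    i = int(np.argmax(dens))
    if not refine:
        return float(grid[i])
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_size - 1)]

    def negdens(x):
        return -(w * np.exp(-0.5 * ((x - r) / h) ** 2)).sum()

    res = optimize.minimize_scalar(negdens, bounds=(a, b), method="bounded")
    return float(res.x)


def mode_estimator(
    d: MRInput,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 1,
    grid_size: int = 512,
) -> MRResult:
    """Mode-based estimate (simple or inverse-variance weighted); bootstrap SE."""
    d = d.drop_null_exposure()
    if len(d) < 3:
        raise EstimatorUnavailable("mode estimator needs >= 3 instruments")
    r = d.beta_y / d.beta_x
    if weighted:
        w = (np.abs(d.beta_x) / d.se_y) ** 2
    else:
        w = np.ones(len(d))
    w = w / w.sum()
    alpha = _kde_mode(r, w, _silverman_bandwidth(r, phi), grid_size=grid_size)
    rng = np.random.default_rng(seed)
    bx = rng.normal(d.beta_x, d.se_x, size=(n_boot, len(d)))
    by = rng.normal(d.beta_y, d.se_y, size=(n_boot, len(d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = np.where(bx != 0, by / bx, np.nan)
    ests = np.empty(n_boot)
    # chunked vectorised grid argmax (no refinement needed for an SE)
    chunk = 256
    gs = 160
    for start in range(0, n_boot, chunk):
        block = rb[start : start + chunk]
        finite = np.isfinite(block)
        filled = np.where(finite, block, np.nanmedian(block, axis=1, keepdims=True))
        s = filled.std(axis=1, ddof=1)
        q75, q25 = np.percentile(filled, [75, 25], axis=1)
        iqr = (q75 - q25) / 1.349
        spread = np.where(iqr > 0, np.minimum(s, iqr), s)
        h = phi * 0.9 * spread * filled.shape[1] ** (-0.2)
        h = np.where(h > 0, h, 1e-12)
        lo = filled.min(axis=1) - 3 * h
        hi = filled.max(axis=1) + 3 * h
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, gs)[None, :]
        z = (grid[:, None, :] - filled[:, :, None]) / h[:, None, None]
        dens = (w[None, :, None] * np.exp(-0.5 * z**2) * finite[:, :, None]).sum(axis=1)
        ests[start : start + chunk] = np.take_along_axis(
            grid, np.argmax(dens, axis=1)[:, None], axis=1
        )[:, 0]
    se = float(ests.std(ddof=1))
    return MRResult(
        method="weighted_mode" if weighted else "simple_mode",
        alpha=alpha,
        se=se,
        pval=_normal_p(alpha, se),
        n_snp=len(d),
    )


def run_all_estimators(d: MRInput, n_boot: int = 1000, seed: int = 1) -> list[MRResult]:
    """IVW, weighted median, weighted mode and simple mode on one input."""
    return [
        ivw(d),
        weighted_median(d, n_boot=n_boot, seed=seed),
        mode_estimator(d, weighted=True, n_boot=n_boot, seed=seed),
        mode_estimator(d, weighted=False, n_boot=n_boot, seed=seed),
    ]


def mr_per_cluster(d: MRInput, assignments: dict[str, int]) -> tuple[dict[int, MRResult | None], MRResult]:
    """Cluster-specific IVW estimates plus the all-instrument estimate.

    ``assignments`` maps each instrument id in ``d`` to a cluster index. A
    cluster whose instruments are all unusable (zero exposure effect) yields
    ``None`` rather than failing the whole analysis.
    """
    labels = np.array([assignments[v] for v in d.ids])
    out: dict[int, MRResult | None] = {}
    for c in sorted(set(labels.tolist())):
        sub = d.subset(labels == c)
        try:
            out[c] = ivw(sub)
        except ValueError:
            out[c] = None
    return out, ivw(d)


def cross_cluster_q(results: Sequence[MRResult]) -> tuple[float, float]:
    """Cochran's Q across cluster-level estimates (chi-square, K-1 df)."""
    results = [r for r in results if r is not None and np.isfinite(r.se) and r.se > 0]
    if len(results) < 2:
        raise ValueError("cross-cluster Q needs >= 2 cluster estimates")
    alpha = np.array([r.alpha for r in results])
    w = np.array([1.0 / r.se**2 for r in results])
    pooled = float((w * alpha).sum() / w.sum())
    q = float((w * (alpha - pooled) ** 2).sum())
    pval = float(stats.chi2.sf(q, len(results) - 1))
    return q, pval


def _as_alpha_se(est) -> tuple[float, float]:
    alpha, unc = est
    if np.ndim(unc) == 1 and len(unc) == 2:
        lo, hi = unc
        se = (hi - lo) / (2 * 1.959963984540054)
    else:
        se = float(unc)
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(alpha), se


def difference_z(est1, est2) -> tuple[float, float]:
    """Two-sided heterogeneity test between two estimates.

    Each estimate is (alpha, se) or (alpha, (ci_lower, ci_upper)); a 95% CI
    is converted to an SE as (upper - lower) / (2 * 1.96).
    """
    a1, s1 = _as_alpha_se(est1)
    a2, s2 = _as_alpha_se(est2)
    z = (a1 - a2) / math.sqrt(s1**2 + s2**2)
    return z, float(2.0 * stats.norm.sf(abs(z)))
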