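"""Multivariable MR: Z-score matrix, rank-based clumping, stepwise selection,
conditional F-statistics and the joint IVW fit.

The joint analysis works on a Z-score matrix over the union of variants that
are genome-wide significant for at least one candidate trait. Rank-based
clumping orders that union by an importance score — each SNP's best
(smallest) rank of |Z| across traits — and greedily thins it with an LD
window (default 5 Mb, r2 0.01). Traits left with fewer than three
significant independent instruments are dropped, as are variants in excluded
regions such as the HLA locus.

Stepwise selection (forward with backward pruning) adds, at each step, the
candidate whose multivariable IVW p-value is smallest and below the
Bonferroni threshold 0.05/m, then prunes any included trait whose joint
p-value has risen above the threshold.

The conditional F-statistic follows the Sanderson–Windmeijer construction:
the primary exposure's instrument effects are regressed on the other
exposures' effects (inverse-variance weights from the primary exposure's
SEs) and F = Q_x / (L - k) with k = #others + 1; with no other exposures it
reduces to the univariable mean F = mean(beta_x^2 / se_x^2) up to the
(L vs L-k) scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phewas import standardize_effects
from .sumstats import LdTable, SumStatTable

__all__ = [
    "ZMatrix",
    "MvmrResult",
    "build_zmatrix",
    "rank_clump",
    "filter_min_instruments",
    "stepwise_mvmr",
    "conditional_f",
    "mvmr_fit",
]

GW_Z = float(stats.norm.isf(5e-8 / 2))  # |z| for two-sided p = 5e-8


@dataclass
class ZMatrix:
    """Joint instrument matrix across candidate exposures.

    Arrays are (L, M) over ``snp_ids`` x ``trait_ids``; ``positions`` maps
    each SNP to (chrom, pos). Every retained SNP is genome-wide significant
    for at least one trait.
    """

    snp_ids: list[str]
    trait_ids: list[str]
    z: np.ndarray
    beta_std: np.ndarray
    se_std: np.ndarray
    positions: dict[str, tuple[str, int]]
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        L, M = len(self.snp_ids), len(self.trait_ids)
        for name in ("z", "beta_std", "se_std"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (L, M):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(L, M)}")

    def trait_col(self, trait_id: str) -> int:
        return self.trait_ids.index(trait_id)

    def significant_counts(self, p_thresh: float = 5e-8) -> dict[str, int]:
        zthr = float(stats.norm.isf(p_thresh / 2))
        sig = np.abs(self.z) > zthr
        return {t: int(sig[:, j].sum()) for j, t in enumerate(self.trait_ids)}

    def subset(self, snp_ids: Sequence[str] | None = None, trait_ids: Sequence[str] | None = None) -> "ZMatrix":
        snp_ids = list(snp_ids) if snp_ids is not None else list(self.snp_ids)
        trait_ids = list(trait_ids) if trait_ids is not None else list(self.trait_ids)
        ri = [self.snp_ids.index(s) for s in snp_ids]
        ci = [self.trait_ids.index(t) for t in trait_ids]
        return ZMatrix(
            snp_ids,
            trait_ids,
            self.z[np.ix_(ri, ci)],
            self.beta_std[np.ix_(ri, ci)],
            self.se_std[np.ix_(ri, ci)],
            {s: self.positions[s] for s in snp_ids},
            dict(self.dropped),
        )


@dataclass
class MvmrResult:
    """Joint multivariable IVW estimates, one row per exposure."""

    trait_ids: list[str]
    alpha: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    n_snp: int
    conditional_f: dict[str, float] = field(default_factory=dict)
    selected_traits: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait_ids,
                "alpha": self.alpha,
                "se": self.se,
                "pval": self.pval,
            }
        )

    def for_trait(self, trait_id: str) -> tuple[float, float, float]:
        i = self.trait_ids.index(trait_id)
        return float(self.alpha[i]), float(self.se[i]), float(self.pval[i])


def build_zmatrix(
    tables: Sequence[SumStatTable],
    p_thresh: float = 5e-8,
    exclude: Sequence[tuple[str, int, int]] = (),
    missing_policy: str = "drop",
) -> ZMatrix:
    """Union of per-trait genome-wide-significant variants, all traits' effects.

    ``tables`` must already be harmonised to a common effect-allele frame.
    A variant absent from some trait's table is dropped (complete-case,
    default) or kept with z = 0 under ``missing_policy="impute_zero"``.
    Variants inside any ``exclude`` region are removed.
    """
    if missing_policy not in ("drop", "impute_zero"):
        raise ValueError("missing_policy must be 'drop' or 'impute_zero'")
    stds = []
    for t in tables:
        s = standardize_effects(t).set_index("variant_id")
        s["z"] = s["beta_std"] / s["se_std"]
        stds.append(s)
    zthr = float(stats.norm.isf(p_thresh / 2))
    union: list[str] = []
    seen: set[str] = set()
    for t, s in zip(tables, stds):
        sig = s.index[np.abs(s["z"]) > zthr]
        for v in sig:
            if v not in seen:
                seen.add(v)
                union.append(v)
    dropped = {"excluded_region": 0, "missing_in_some_trait": 0}
    positions_all: dict[str, tuple[str, int]] = {}
    for t in tables:
        positions_all.update(t.positions())
    kept = []
    for v in union:
        chrom, pos = positions_all[v]
        if any(str(chrom) == str(c) and s <= pos <= e for c, s, e in exclude):
            dropped["excluded_region"] += 1
            continue
        if missing_policy == "drop" and not all(v in s.index for s in stds):
            dropped["missing_in_some_trait"] += 1
            continue
        kept.append(v)
    if not kept:
        raise ValueError("no genome-wide significant variant available for the Z matrix")
    L, M = len(kept), len(tables)
    z = np.zeros((L, M))
    beta = np.zeros((L, M))
    se = np.full((L, M), np.nan)
    for j, (t, s) in enumerate(zip(tables, stds)):
        present = [i for i, v in enumerate(kept) if v in s.index]
        idx = [kept[i] for i in present]
        sub = s.loc[idx]
        z[present, j] = sub["z"].to_numpy()
        beta[present, j] = sub["beta_std"].to_numpy()
        se[present, j] = sub["se_std"].to_numpy()
    if missing_policy == "impute_zero":
        # a missing cell keeps z = beta = 0; give it the trait's median SE
        for j in range(M):
            col = se[:, j]
            col[np.isnan(col)] = np.nanmedian(col)
    return ZMatrix(
        snp_ids=kept,
        trait_ids=[t.trait_id for t in tables],
        z=z,
        beta_std=beta,
        se_std=se,
        positions={v: positions_all[v] for v in kept},
        dropped=dropped,
    )


def rank_clump(
    zm: ZMatrix,
    ld: LdTable,
    clump_kb: int = 5000,
    clump_r2: float = 0.01,
) -> ZMatrix:
    """Greedy LD thinning ordered by cross-trait importance ranks.

    For each trait, SNPs are ranked by descending |z| (rank 1 = strongest;
    ties share the better rank). A SNP's importance is its best rank across
    traits; clumping retains SNPs in ascending importance (variant_id breaks
    ties) and discards any unprocessed SNP on the same chromosome within
    ``clump_kb`` kilobases with r2 >= ``clump_r2``.
    """
    absz = np.abs(zm.z)
    # competition ranking: rank = 1 + count of strictly larger values
    ranks = np.empty_like(absz, dtype=int)
    for j in range(absz.shape[1]):
        col = absz[:, j]
        ranks[:, j] = 1 + (col[None, :] > col[:, None]).sum(axis=1)
    importance = ranks.min(axis=1)
    order = sorted(range(len(zm.snp_ids)), key=lambda i: (importance[i], zm.snp_ids[i]))
    window_bp = int(clump_kb) * 1000
    retained: list[int] = []
    for i in order:
        vid, (chrom, pos) = zm.snp_ids[i], zm.positions[zm.snp_ids[i]]
        ok = True
        for r in retained:
            rchrom, rpos = zm.positions[zm.snp_ids[r]]
            if (
                str(chrom) == str(rchrom)
                and abs(int(pos) - int(rpos)) <= window_bp
                and ld.r2(vid, zm.snp_ids[r]) >= clump_r2
            ):
                ok = False
                break
        if ok:
            retained.append(i)
    keep_ids = [zm.snp_ids[i] for i in sorted(retained)]
    return zm.subset(snp_ids=keep_ids)


def filter_min_instruments(zm: ZMatrix, min_iv: int = 3, p_thresh: float = 5e-8) -> ZMatrix:
    """Drop traits with fewer than ``min_iv`` surviving significant SNPs.

    SNPs left significant for no kept trait are dropped with the traits.
    An all-traits-dropped outcome returns an empty-trait matrix rather than
    raising, so callers can report the status.
    """
    counts = zm.significant_counts(p_thresh)
    kept_traits = [t for t in zm.trait_ids if counts[t] >= min_iv]
    if not kept_traits:
        out = zm.subset(trait_ids=[])
        out.dropped = dict(zm.dropped, all_traits_dropped=1)
        return out
    sub = zm.subset(trait_ids=kept_traits)
    zthr = float(stats.norm.isf(p_thresh / 2))
    sig_any = (np.abs(sub.z) > zthr).any(axis=1)
    return sub.subset(snp_ids=[v for v, s in zip(sub.snp_ids, sig_any) if s])


def _align_outcome(zm: ZMatrix, outcome: SumStatTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Outcome standardised effects aligned to the matrix SNPs (complete case)."""
    s = standardize_effects(outcome).set_index("variant_id")
    ids = [v for v in zm.snp_ids if v in s.index]
    if len(ids) < 1:
        raise ValueError("no overlap between Z matrix and outcome table")
    sub = s.loc[ids]
    return sub["beta_std"].to_numpy(), sub["se_std"].to_numpy(), ids


def _wls_zero_intercept(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted zero-intercept LS: estimates, SEs from (X'WX)^-1 (fixed effect)."""
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    cond = np.linalg.cond(XtWX)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("rank-deficient exposure matrix")
    cov = np.linalg.inv(XtWX)
    est = cov @ (Xw.T @ y)
    se = np.sqrt(np.diag(cov))
    return est, se


def mvmr_fit(
    zm: ZMatrix,
    outcome: SumStatTable,
    exposures: Sequence[str],
    conditional_f_traits: bool = False,
) -> MvmrResult:
    """Multivariable IVW of the outcome on the named exposures.

    Weighted zero-intercept regression of the outcome's standardised
    effects on the exposure-effect matrix with weights 1/se_y^2; SEs from
    the fixed-effect covariance, p-values from the normal reference.
    """
    exposures = list(exposures)
    if not exposures:
        raise ValueError("need at least one exposure")
    by, sey, ids = _align_outcome(zm, outcome)
    if len(ids) < len(exposures) + 1:
        raise ValueError("fewer instruments than exposures + 1")
    sub = zm.subset(snp_ids=ids, trait_ids=exposures)
    X = sub.beta_std
    w = 1.0 / sey**2
    # an all-zero exposure column carries no information: estimate 0, SE inf
    nonzero = [j for j in range(X.shape[1]) if np.any(X[:, j] != 0)]
    est = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.inf)
    try:
        est_nz, se_nz = _wls_zero_intercept(X[:, nonzero], by, w)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"rank-deficient exposure design: {e}") from e
    est[nonzero] = est_nz
    se[nonzero] = se_nz
    with np.errstate(invalid="ignore"):
        pval = np.where(np.isfinite(se), 2.0 * stats.norm.sf(np.abs(est) / se), 1.0)
    cond_f = {}
    if conditional_f_traits:
        for t in exposures:
            cond_f[t] = conditional_f(zm.subset(snp_ids=ids), t, [o for o in exposures if o != t])
    return MvmrResult(
        trait_ids=exposures,
        alpha=est,
        se=se,
        pval=pval,
        n_snp=len(ids),
        conditional_f=cond_f,
        selected_traits=exposures,
    )


def stepwise_mvmr(
    zm: ZMatrix,
    outcome: SumStatTable,
    bonferroni_m: int | None = None,
    alpha: float = 0.05,
    prune: bool = True,
) -> tuple[list[str], MvmrResult | None]:
    """Forward stepwise multivariable IVW with optional backward pruning.

    Starting from the empty set, each step fits the joint model with every
    remaining candidate added in turn, then admits the candidate with the
    smallest joint p-value if it clears alpha/m (m = ``bonferroni_m``,
    default the number of candidate traits). After each addition any
    included trait whose joint p has risen above the threshold is pruned.
    A candidate producing a rank-deficient design is set aside.
    """
    candidates = list(zm.trait_ids)
    m = bonferroni_m if bonferroni_m is not None else max(len(candidates), 1)
    thresh = alpha / m
    selected: list[str] = []
    blocked: set[str] = set()
    fit: MvmrResult | None = None
    while True:
        best = None
        for cand in candidates:
            if cand in selected or cand in blocked:
                continue
            try:
                trial = mvmr_fit(zm, outcome, selected + [cand])
            except ValueError:
                blocked.add(cand)
                continue
            p_cand = trial.for_trait(cand)[2]
            if p_cand < thresh and (best is None or p_cand < best[1]):
                best = (cand, p_cand, trial)
        if best is None:
            break
        selected.append(best[0])
        fit = best[2]
        if prune and len(selected) > 1:
            while True:
                worst = max(selected, key=lambda t: fit.for_trait(t)[2])
                if fit.for_trait(worst)[2] > thresh:
                    selected.remove(worst)
                    if not selected:
                        fit = None
                        break
                    fit = mvmr_fit(zm, outcome, selected)
                else:
                    break
    if selected and fit is None:
        fit = mvmr_fit(zm, outcome, selected)
    if fit is not None:
        fit.selected_traits = list(selected)
    return selected, fit


def conditional_f(zm: ZMatrix, primary: str, others: Sequence[str]) -> float:
    """Sanderson–Windmeijer conditional F-statistic for ``primary``.

    Weighted regression (weights 1/se_primary^2) of the primary exposure's
    instrument effects on the other exposures' effects; the weighted
    residual sum of squares Q_x over (L - k) degrees of freedom, k =
    #others + 1. With ``others`` empty this is the univariable
    mean-instrument-strength F up to the L/(L-1) scaling.
    """
    others = list(others)
    pj = zm.trait_col(primary)
    bx = zm.beta_std[:, pj]
    sex = zm.se_std[:, pj]
    L = len(bx)
    k = len(others) + 1
    if L <= k:
        raise ValueError("need more instruments than exposures")
    w = 1.0 / sex**2
    if others:
        X = zm.beta_std[:, [zm.trait_col(t) for t in others]]
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        cond = np.linalg.cond(XtWX)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(f"collinear exposures among {others}")
        coef = np.linalg.solve(XtWX, Xw.T @ bx)
        resid = bx - X @ coef
    else:
        resid = bx
    q_x = float((w * resid**2).sum())
    return q_x / (L - k)
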