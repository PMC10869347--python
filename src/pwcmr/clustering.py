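"""Instrument clustering and per-cluster trait enrichment.

Instruments are clustered on their phenome-wide association profiles: the
absolute standardised effects of each SNP across the trait panel are scaled
so that each SNP's row has unit variance (absolute values make negatively
correlated traits look similar under the Euclidean metric), then k-means is
run for each candidate number of clusters and the number of clusters is
chosen by AIC.

The default model-choice criterion is the unscaled penalised
within-cluster sum of squares

    AIC(k) = W_k + 2 * k * d

with n SNPs, d traits and W_k the total within-cluster sum of squares. The
spherical-Gaussian log form n*d*ln(W_k/(n*d)) + 2*k*d is available via
``criterion="gaussian"`` but is scale-invariant and therefore over-splits
whenever the SNP count per cluster is not much larger than the trait count
(sample-level overfitting reduces W_k by more, relatively, than the linear
penalty tolerates, at any noise scale). Absolute AIC values are not
comparable across forms — only the argmin is meaningful.

Cluster annotation uses the *standardised* (not row-normalised) effects:
sigma2[j, t] is cluster j's per-SNP average squared effect on trait t, and
the enrichment ratio ER[j, t] divides it by the across-cluster mean, so the
mean of ER over clusters is exactly 1 for every trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .phewas import PhewasMatrix

__all__ = [
    "ClusterModel",
    "EnrichmentTable",
    "normalize_for_clustering",
    "fit_kmeans_aic",
    "enrichment_ratio",
    "top_enriched",
]


@dataclass
class ClusterModel:
    """Fitted k-means clustering of instruments with AIC-based model choice."""

    k: int
    assignments: dict[str, int]  # snp_id -> cluster index in 1..k
    centroids: np.ndarray  # (k, d)
    aic_by_k: dict[int, float]
    wk_by_k: dict[int, float] = field(default_factory=dict)
    seed: int = 1
    restarts: int = 25

    def __post_init__(self):
        if min(self.aic_by_k, key=lambda kk: self.aic_by_k[kk]) != self.k:
            raise ValueError("chosen k is not the argmin of aic_by_k")
        sizes = self.cluster_sizes()
        if len(sizes) != self.k or any(s < 1 for s in sizes.values()):
            raise ValueError("every cluster must contain at least one SNP")

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.assignments.values():
            sizes[c] = sizes.get(c, 0) + 1
        return dict(sorted(sizes.items()))

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cluster]

    def labels_for(self, snp_ids) -> np.ndarray:
        return np.array([self.assignments[s] for s in snp_ids])

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant_id": list(self.assignments), "cluster": list(self.assignments.values())}
        )


@dataclass
class EnrichmentTable:
    """Per-cluster trait enrichment: sigma2 (K, T), er (K, T) and rankings."""

    cluster_ids: list[int]
    trait_ids: list[str]
    sigma2: np.ndarray
    er: np.ndarray
    undefined_traits: list[str] = field(default_factory=list)

    def er_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.er, index=self.cluster_ids, columns=self.trait_ids)


def normalize_for_clustering(beta_std: np.ndarray, snp_ids=None) -> np.ndarray:
    """Row-scale absolute effects so each SNP's variance across traits is 1.

    Entry (i, t) is |beta_std[i, t]| / s_i where s_i is the standard
    deviation (ddof=1) of row i's absolute effects. Raises on a
    zero-variance row (degenerate instrument), naming the SNP.
    """
    a = np.abs(np.asarray(beta_std, dtype=float))
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("need at least 2 SNPs and 2 traits")
    s = a.std(axis=1, ddof=1)
    bad = np.flatnonzero(s == 0)
    if bad.size:
        name = snp_ids[bad[0]] if snp_ids is not None else f"row {bad[0]}"
        raise ValueError(f"zero-variance instrument profile: {name}")
    return a / s[:, None]


def _kmeans_aic(wk: float, n: int, d: int, k: int, criterion: str) -> float:
    if criterion == "gaussian":
        # guard: W_k can hit 0 on duplicated degenerate input
        return n * d * float(np.log(max(wk, 1e-300) / (n * d))) + 2.0 * k * d
    if criterion == "wk":
        return wk + 2.0 * k * d
    raise ValueError(f"unknown AIC criterion {criterion!r}")


def fit_kmeans_aic(
    x: np.ndarray,
    snp_ids,
    k_min: int = 2,
    k_max: int = 50,
    seed: int = 1,
    restarts: int = 25,
    criterion: str = "wk",
) -> ClusterModel:
    """Fit k-means for each k in [k_min, k_max] and keep the AIC-argmin model.

    Each k uses best-of-``restarts`` k-means++ runs (deterministic under
    ``seed``). ``k_max`` must be below the number of SNPs.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    if not (2 <= k_min <= k_max):
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be < number of SNPs ({n})")
    aic_by_k: dict[int, float] = {}
    wk_by_k: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, init="k-means++")
        km.fit(x)
        wk = float(km.inertia_)
        wk_by_k[k] = wk
        aic_by_k[k] = _kmeans_aic(wk, n, d, k, criterion)
        fits[k] = km
    best_k = min(aic_by_k, key=lambda kk: (aic_by_k[kk], kk))
    km = fits[best_k]
    assignments = {s: int(c) + 1 for s, c in zip(snp_ids, km.labels_)}
    return ClusterModel(
        k=best_k,
        assignments=assignments,
        centroids=km.cluster_centers_,
        aic_by_k=aic_by_k,
        wk_by_k=wk_by_k,
        seed=seed,
        restarts=restarts,
    )


def enrichment_ratio(m: PhewasMatrix, cm: ClusterModel, include_exposure: bool = False) -> EnrichmentTable:
    """Per-cluster per-trait enrichment ratios from standardised effects.

    sigma2[j, t] = mean over SNPs in cluster j of beta_std[i, t]**2;
    er[j, t] = sigma2[j, t] / mean over clusters of sigma2[., t]. Traits with
    zero average squared effect in every cluster have undefined ER and are
    excluded from rankings.
    """
    if include_exposure:
        beta, trait_ids = m.beta_std, list(m.trait_ids)
    else:
        beta, _, trait_ids = m.drop_exposure_column()
    labels = cm.labels_for(m.snp_ids)
    clusters = sorted(set(labels.tolist()))
    b2 = beta**2
    sigma2 = np.vstack([b2[labels == c].mean(axis=0) for c in clusters])
    denom = sigma2.mean(axis=0)
    undefined = [t for t, dnm in zip(trait_ids, denom) if dnm == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        er = np.where(denom > 0, sigma2 / denom, np.nan)
    return EnrichmentTable(
        cluster_ids=clusters,
        trait_ids=trait_ids,
        sigma2=sigma2,
        er=er,
        undefined_traits=undefined,
    )


def top_enriched(e: EnrichmentTable, n: int = 10) -> dict[int, list[tuple[str, float]]]:
    """Top-n traits per cluster by descending ER; ties broken by trait_id.

    Traits with undefined ER are excluded. n > T returns the full ranking.
    """
    out: dict[int, list[tuple[str, float]]] = {}
    undefined = set(e.undefined_traits)
    for j, cid in enumerate(e.cluster_ids):
        pairs = [
            (t, float(e.er[j, ti]))
            for ti, t in enumerate(e.trait_ids)
            if t not in undefined
        ]
        pairs.sort(key=lambda p: (-p[1], p[0]))
        out[cid] = pairs[:n]
    return out
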