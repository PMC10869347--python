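"""Synthetic GWAS summary statistics under a multi-pathway instrument model.

The generator emulates the causal diagram the clustering pipeline is built
for: an exposure X influenced by K distinct SNP clusters (mechanisms), each
cluster exerting its own total causal effect alpha_k on the outcome Y. One
cluster can act purely through a heritable confounder U (SNP -> U -> X and
U -> Y), which induces correlated pleiotropy: that cluster's ratio
estimates converge on q_uy/q_ux instead of a causal effect. The phenome
panel contains per-cluster marker traits (downstream of each mechanism), a
U-proxy trait, a mediator of the X -> Y path, pure-noise traits, and an
optional null candidate trait with its own instruments but no effect on X
or Y (useful for selection specificity tests).

Summary statistics are produced directly in standardised-effect space:
observed beta_std = true beta_std + N(0, 1/n_gwas), se_std = 1/sqrt(n_gwas).
This is exact for the large-sample standardised-effect model and fast; only
the coarsened-exposure experiment simulates individual-level data, because
binning is a nonlinearity that cannot be expressed in effect space.

Convention: ``alpha_k`` is the TOTAL pathway effect of cluster k's
exposure-component on Y (the quantity cluster-specific IVW estimates). When
a mediator is planted, the direct effect is derived internally so the
totals stay as configured.

By default variants are mutually independent (identity LD). ``ld_blocks``
adds AR(1)-decaying r2 entries within consecutive blocks to exercise
clumping logic; marginal effects remain independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phewas import TraitMeta
from .sumstats import LdTable, SumStatTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "simulate_study",
    "IndividualExposure",
    "simulate_individual_exposure",
    "coarsen_exposure",
    "coarsening_experiment",
]


@dataclass
class SyntheticConfig:
    """Generative parameters (defaults are the package's study conditions)."""

    n_gwas: int = 360_000  # biobank-scale GWAS
    n_snps_per_cluster: tuple[int, ...] = (30, 30, 30)
    #: total pathway effect of each cluster on Y; the confounder cluster's
    #: entry is its DIRECT effect (0 = pure confounding)
    alpha_k: tuple[float, ...] = (-0.09, -0.09, 0.0)
    confounder_cluster: int | None = 2  # 0-based index into the clusters
    q_ux: float = 0.6  # U -> X
    q_uy: float = -0.3  # U -> Y  (apparent cluster effect q_uy/q_ux = -0.5)
    loading_mean: float = 0.05  # per-SNP pathway loading scale (SD units)
    loading_sd: float = 0.01
    traits_per_cluster: int = 4
    marker_loading: float = 0.7  # marker-trait effect per unit SNP->X effect
    #                              (< 1 keeps the exposure the best-explained
    #                              trait, as for genuine instruments)
    n_noise_traits: int = 3
    u_proxy_loading: float = 0.5  # U -> proxy trait
    include_mediator: bool = True
    m_x: float = 0.08  # X -> mediator (kept small so the mediator's own
    #                     instruments stay its only genome-wide hits)
    alpha_m: float = 0.3  # mediator -> Y
    n_mediator_snps: int = 30
    n_outcome_snps: int = 30  # outcome's own instruments (reverse-MR support)
    include_null_candidate: bool = True
    n_null_candidate_snps: int = 30
    seed: int = 1
    coarsen_bins: int | None = None
    ld_blocks: int = 0  # 0 = identity LD
    ld_block_size: int = 4
    ld_r: float = 0.6

    def __post_init__(self):
        if len(self.alpha_k) != len(self.n_snps_per_cluster):
            raise ValueError("alpha_k and n_snps_per_cluster lengths differ")
        if self.n_gwas <= 0:
            raise ValueError("n_gwas must be positive")
        if any(abs(a) > 1 for a in self.alpha_k):
            raise ValueError("|alpha_k| must be bounded by 1 in SD units")
        if self.confounder_cluster is not None and not (
            0 <= self.confounder_cluster < len(self.alpha_k)
        ):
            raise ValueError("confounder_cluster out of range")

    @property
    def k_true(self) -> int:
        return len(self.n_snps_per_cluster)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    cluster_labels: dict[str, int]  # exposure-IV snp -> 1..K
    alpha_k: tuple[float, ...]
    confounder_cluster: int | None  # 1-based cluster index, or None
    apparent_confounder_effect: float | None  # q_uy/q_ux
    univariable_expectation: float  # IV-weighted mix of cluster effects
    marker_traits: dict[int, list[str]]  # 1-based cluster -> marker trait ids
    proxy_trait: str | None
    mediator_trait: str | None
    null_candidate_trait: str | None
    trait_effects: pd.DataFrame  # true standardised effects, snp x trait
    mediator_snps: list[str] = field(default_factory=list)
    outcome_snps: list[str] = field(default_factory=list)


@dataclass
class SyntheticStudy:
    """Everything one pipeline run needs, plus the generating truth."""

    exposure: SumStatTable
    outcome: SumStatTable
    panel: list[SumStatTable]
    trait_meta: list[TraitMeta]
    ld: LdTable
    truth: SyntheticTruth

    def panel_table(self, trait_id: str) -> SumStatTable:
        for t in self.panel:
            if t.trait_id == trait_id:
                return t
        raise KeyError(trait_id)


def _variant_frame(n: int) -> pd.DataFrame:
    """Deterministic variant universe: ids, positions, fixed A/G alleles."""
    ids = [f"rs{i + 1:05d}" for i in range(n)]
    chrom = [str(1 + i % 22) for i in range(n)]
    # spaced 20 Mb within a chromosome; keeps clear of the HLA interval
    pos = [1_000_000 + 40_000_000 * (i // 22) for i in range(n)]
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )


def _table_from_std(
    trait_id: str, variants: pd.DataFrame, beta_std: np.ndarray, n: int, eaf: np.ndarray
) -> SumStatTable:
    se = 1.0 / np.sqrt(n)
    z = beta_std / se
    df = variants.copy()
    df["beta"] = beta_std
    df["se"] = se
    df["pval"] = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-320, 1.0)
    df["n"] = n
    df["eaf"] = eaf
    return SumStatTable(trait_id, df)


def simulate_study(cfg: SyntheticConfig) -> SyntheticStudy:
    """Draw one synthetic study (deterministic under ``cfg.seed``)."""
    rng = np.random.default_rng(cfg.seed)
    K = cfg.k_true
    n_iv = int(np.sum(cfg.n_snps_per_cluster))
    n_total = (
        n_iv
        + (cfg.n_mediator_snps if cfg.include_mediator else 0)
        + cfg.n_outcome_snps
        + (cfg.n_null_candidate_snps if cfg.include_null_candidate else 0)
    )
    variants = _variant_frame(n_total)
    vid = variants["variant_id"].tolist()
    eaf = rng.uniform(0.15, 0.85, size=n_total)

    # --- index blocks ---------------------------------------------------
    cluster_of = np.zeros(n_total, dtype=int)  # 0 = not an exposure IV
    start = 0
    cluster_slices = []
    for k, nk in enumerate(cfg.n_snps_per_cluster, start=1):
        cluster_of[start : start + nk] = k
        cluster_slices.append(slice(start, start + nk))
        start += nk
    med_slice = slice(start, start + (cfg.n_mediator_snps if cfg.include_mediator else 0))
    start = med_slice.stop
    out_slice = slice(start, start + cfg.n_outcome_snps)
    start = out_slice.stop
    null_slice = slice(
        start, start + (cfg.n_null_candidate_snps if cfg.include_null_candidate else 0)
    )

    # --- true standardised effects --------------------------------------
    loadings = np.abs(rng.normal(cfg.loading_mean, cfg.loading_sd, size=n_total))
    conf = cfg.confounder_cluster  # 0-based or None

    beta_x = np.zeros(n_total)
    for k in range(K):
        sl = cluster_slices[k]
        if conf is not None and k == conf:
            beta_x[sl] = cfg.q_ux * loadings[sl]  # SNP -> U -> X
        else:
            beta_x[sl] = loadings[sl]

    # mediator trait value: m_x * X plus its own instruments
    beta_med = cfg.m_x * beta_x if cfg.include_mediator else np.zeros(n_total)
    if cfg.include_mediator:
        beta_med[med_slice] = loadings[med_slice]

    beta_y = np.zeros(n_total)
    for k in range(K):
        sl = cluster_slices[k]
        if conf is not None and k == conf:
            # pure confounding plus any configured direct effect
            beta_y[sl] = cfg.q_uy * loadings[sl] + cfg.alpha_k[k] * beta_x[sl]
        else:
            # alpha_k is the TOTAL pathway effect (mediated part included)
            beta_y[sl] = cfg.alpha_k[k] * beta_x[sl]
    if cfg.include_mediator:
        beta_y[med_slice] = cfg.alpha_m * loadings[med_slice]
    beta_y[out_slice] = loadings[out_slice]

    # --- panel traits ----------------------------------------------------
    trait_cols: dict[str, np.ndarray] = {}
    marker_traits: dict[int, list[str]] = {}
    for k in range(K):
        marker_traits[k + 1] = []
        for j in range(cfg.traits_per_cluster):
            tid = f"marker_c{k + 1}_{j + 1}"
            col = np.zeros(n_total)
            sl = cluster_slices[k]
            col[sl] = cfg.marker_loading * beta_x[sl]
            trait_cols[tid] = col
            marker_traits[k + 1].append(tid)
    proxy_id = None
    if conf is not None:
        proxy_id = "u_proxy"
        col = np.zeros(n_total)
        sl = cluster_slices[conf]
        col[sl] = cfg.u_proxy_loading * loadings[sl]
        trait_cols[proxy_id] = col
        marker_traits[conf + 1].append(proxy_id)
    mediator_id = None
    if cfg.include_mediator:
        mediator_id = "mediator"
        trait_cols[mediator_id] = beta_med
    null_id = None
    if cfg.include_null_candidate:
        null_id = "null_candidate"
        col = np.zeros(n_total)
        col[null_slice] = loadings[null_slice]
        trait_cols[null_id] = col
    for j in range(cfg.n_noise_traits):
        trait_cols[f"noise_{j + 1}"] = np.zeros(n_total)

    # --- observed tables (truth + sampling noise) ------------------------
    noise_sd = 1.0 / np.sqrt(cfg.n_gwas)

    def observe(true_beta):
        return true_beta + rng.normal(0.0, noise_sd, size=n_total)

    exposure = _table_from_std("exposure", variants, observe(beta_x), cfg.n_gwas, eaf)
    outcome = _table_from_std("outcome", variants, observe(beta_y), cfg.n_gwas, eaf)
    panel = [
        _table_from_std(tid, variants, observe(col), cfg.n_gwas, eaf)
        for tid, col in trait_cols.items()
    ]

    meta = [
        TraitMeta(
            trait_id=tid,
            description=f"synthetic trait {tid}",
            n_eff=float(cfg.n_gwas),
            var_type="continuous",
            rg_exposure=0.2,
            rg_outcome=0.1,
            version_date="2024-01-01",
        )
        for tid in trait_cols
    ]

    ld = LdTable.identity()
    if cfg.ld_blocks > 0:
        idx = 0
        for _ in range(cfg.ld_blocks):
            block = vid[idx : idx + cfg.ld_block_size]
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    ld.add(block[i], block[j], cfg.ld_r ** (j - i))
            idx += cfg.ld_block_size
            if idx >= n_total:
                break

    w = beta_x**2
    iv = cluster_of > 0
    univ = float((w[iv] * np.where(beta_x[iv] != 0, beta_y[iv] / beta_x[iv], 0)).sum() / w[iv].sum())
    truth = SyntheticTruth(
        cluster_labels={vid[i]: int(cluster_of[i]) for i in range(n_total) if cluster_of[i] > 0},
        alpha_k=tuple(cfg.alpha_k),
        confounder_cluster=None if conf is None else conf + 1,
        apparent_confounder_effect=None if conf is None else cfg.q_uy / cfg.q_ux,
        univariable_expectation=univ,
        marker_traits=marker_traits,
        proxy_trait=proxy_id,
        mediator_trait=mediator_id,
        null_candidate_trait=null_id,
        trait_effects=pd.DataFrame(trait_cols, index=vid),
        mediator_snps=vid[med_slice],
        outcome_snps=vid[out_slice],
    )
    return SyntheticStudy(exposure, outcome, panel, meta, ld, truth)


# --------------------------------------------------------------------------
# Coarsened-exposure experiment (individual-level)
# --------------------------------------------------------------------------


@dataclass
class IndividualExposure:
    """Individual-level genotypes and exposure for the coarsening experiment."""

    genotypes: np.ndarray  # (n_ind, L), standardised
    exposure: np.ndarray  # (n_ind,), standardised
    gamma: np.ndarray  # true per-SNP standardised effects
    variants: pd.DataFrame
    eaf: np.ndarray


def simulate_individual_exposure(
    n_ind: int = 4000,
    n_snps: int = 30,
    loading_mean: float = 0.05,
    loading_sd: float = 0.01,
    seed: int = 1,
) -> IndividualExposure:
    """Simulate genotypes and a continuous exposure they influence."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.15, 0.5, size=n_snps)
    g = rng.binomial(2, maf, size=(n_ind, n_snps)).astype(float)
    g = (g - g.mean(axis=0)) / g.std(axis=0)
    gamma = np.abs(rng.normal(loading_mean, loading_sd, size=n_snps))
    genetic = g @ gamma
    env_sd = float(np.sqrt(max(1.0 - genetic.var(), 0.05)))
    x = genetic + rng.normal(0.0, env_sd, size=n_ind)
    x = (x - x.mean()) / x.std()
    return IndividualExposure(g, x, gamma, _variant_frame(n_snps), maf)


def _gwas_of(ind: IndividualExposure, pheno: np.ndarray, trait_id: str) -> SumStatTable:
    n = len(pheno)
    y = (pheno - pheno.mean()) / pheno.std()
    beta = ind.genotypes.T @ y / n  # standardised per-SNP effect
    return _table_from_std(trait_id, ind.variants, beta, n, ind.eaf)


def coarsen_exposure(ind: IndividualExposure, bins: int, trait_id: str = "exposure_coarse") -> SumStatTable:
    """Summary statistics for the exposure coarsened into ordered categories.

    The exposure is quantile-binned into ``bins`` categories (emulating a
    self-reported ordinal proxy of a continuous trait) and GWAS effects are
    recomputed on the binned variable. Effect attenuation relative to the
    continuous exposure is emergent, not imposed.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.quantile(ind.exposure, np.linspace(0, 1, bins + 1)[1:-1])
    binned = np.searchsorted(edges, ind.exposure).astype(float)
    return _gwas_of(ind, binned, trait_id)


def coarsening_experiment(
    alpha: float = -0.09,
    bins: int = 3,
    n_ind: int = 4000,
    n_snps: int = 30,
    n_reps: int = 200,
    seed: int = 1,
) -> pd.DataFrame:
    """Paired IVW estimates using the true vs the coarsened exposure.

    For each replicate, individuals are simulated with Y = alpha * X + noise,
    GWAS summary statistics are computed for X, its ``bins``-category proxy
    and Y, and IVW is run with each exposure version. Returns one row per
    replicate with columns ``ivw_true``, ``ivw_proxy``, ``mean_abs_beta_true``
    and ``mean_abs_beta_proxy``.
    """
    from .estimators import MRInput, ivw

    rows = []
    for r in range(n_reps):
        ind = simulate_individual_exposure(n_ind, n_snps, seed=seed + r)
        rng = np.random.default_rng(seed + 10_000 + r)
        y = alpha * ind.exposure + rng.normal(0, np.sqrt(1 - alpha**2), size=n_ind)
        tab_true = _gwas_of(ind, ind.exposure, "exposure_true")
        tab_proxy = coarsen_exposure(ind, bins)
        tab_y = _gwas_of(ind, y, "outcome")

        def mri(tab_x):
            return MRInput(
                beta_x=tab_x.df["beta"].to_numpy(),
                se_x=tab_x.df["se"].to_numpy(),
                beta_y=tab_y.df["beta"].to_numpy(),
                se_y=tab_y.df["se"].to_numpy(),
                ids=tab_x.df["variant_id"].tolist(),
            )

        rows.append(
            {
                "ivw_true": ivw(mri(tab_true)).alpha,
                "ivw_proxy": ivw(mri(tab_proxy)).alpha,
                "mean_abs_beta_true": float(np.abs(tab_true.df["beta"]).mean()),
                "mean_abs_beta_proxy": float(np.abs(tab_proxy.df["beta"]).mean()),
            }
        )
    return pd.DataFrame(rows)
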