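"""Standardised SNP x trait effect matrix, trait QC and trait-wide Steiger filtering.

The phenome-wide (PheWAS) stage turns per-trait summary statistics for a set
of exposure instruments into a single standardised effect matrix
``beta_std[i, t]`` on the SD/SD scale (``beta_std = z / sqrt(n)``,
``se_std = 1 / sqrt(n)``; ``beta_std**2`` is the variance of the trait
explained by the variant). Binary traits are deliberately treated like
continuous ones — at biobank sample sizes linear and logistic effect
estimates are nearly proportional, so the clustering geometry is unaffected.

Trait QC removes traits with missing instrument effects, duplicates (keeping
the most recent version), low effective sample size (default < 50,000), and
traits too genetically correlated with the exposure (default |rG| > 0.75).

The trait-wide Steiger filter drops any instrument that explains
significantly more variance in some other trait than in the exposure,
guarding against reverse causation / mislabelled instruments. The variance
comparison is a delta-method z-test on squared standardised effects
(Var(b^2) ~= 4 b^2 SE^2), Bonferroni-corrected across the trait panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStatTable

__all__ = [
    "TraitMeta",
    "PhewasMatrix",
    "QcReport",
    "standardize_effects",
    "qc_traits",
    "build_phewas_matrix",
    "steiger_filter",
]


@dataclass(frozen=True)
class TraitMeta:
    """Trait-level metadata used by the QC filters."""

    trait_id: str
    description: str = ""
    n_eff: float = float("nan")
    var_type: str = "continuous"  # continuous | binary | ordinal
    rg_exposure: float | None = None
    rg_outcome: float | None = None
    version_date: str | None = None  # ISO date; lexicographic order == temporal

    def __post_init__(self):
        for rg in (self.rg_exposure, self.rg_outcome):
            if rg is not None and abs(rg) > 1 + 1e-12:
                raise ValueError(f"|rg| > 1 for trait {self.trait_id!r}")

    @staticmethod
    def read_tsv(path) -> list["TraitMeta"]:
        df = pd.read_csv(path, sep="\t")
        metas = []
        for row in df.itertuples(index=False):
            def _opt(name):
                v = getattr(row, name, None)
                return None if v is None or pd.isna(v) else v
            metas.append(
                TraitMeta(
                    trait_id=str(row.trait_id),
                    description=str(getattr(row, "description", "")),
                    n_eff=float(row.n_eff),
                    var_type=str(getattr(row, "var_type", "continuous")),
                    rg_exposure=_opt("rg_exposure"),
                    rg_outcome=_opt("rg_outcome"),
                    version_date=_opt("version_date"),
                )
            )
        return metas


@dataclass
class QcReport:
    """Counts of removals per QC rule; sums to input minus output."""

    n_in: int = 0
    n_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def note(self, rule: str, trait_id: str) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + 1
        self.removed_ids.setdefault(rule, []).append(trait_id)


@dataclass
class PhewasMatrix:
    """Standardised SNP x trait effect matrix with SEs.

    ``beta_std`` and ``se_std`` are (I, T) arrays aligned to ``snp_ids`` and
    ``trait_ids``; ``exposure_col`` names the exposure trait's column. No
    missing cells are allowed after construction.
    """

    snp_ids: list[str]
    trait_ids: list[str]
    beta_std: np.ndarray
    se_std: np.ndarray
    exposure_col: str

    def __post_init__(self):
        i, t = len(self.snp_ids), len(self.trait_ids)
        self.beta_std = np.asarray(self.beta_std, dtype=float)
        self.se_std = np.asarray(self.se_std, dtype=float)
        if self.beta_std.shape != (i, t) or self.se_std.shape != (i, t):
            raise ValueError("matrix dimensions inconsistent with id lists")
        if len(set(self.snp_ids)) != i or len(set(self.trait_ids)) != t:
            raise ValueError("snp_ids / trait_ids must be unique")
        if np.isnan(self.beta_std).any() or np.isnan(self.se_std).any():
            raise ValueError("missing cells in PhewasMatrix")
        if self.exposure_col not in self.trait_ids:
            raise ValueError(f"exposure column {self.exposure_col!r} not in trait_ids")

    @property
    def exposure_idx(self) -> int:
        return self.trait_ids.index(self.exposure_col)

    def subset_snps(self, ids: Sequence[str]) -> "PhewasMatrix":
        idx = [self.snp_ids.index(v) for v in ids]
        return PhewasMatrix(
            list(ids),
            list(self.trait_ids),
            self.beta_std[idx],
            self.se_std[idx],
            self.exposure_col,
        )

    def drop_exposure_column(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(beta, se, trait_ids) with the exposure column removed."""
        keep = [j for j, t in enumerate(self.trait_ids) if t != self.exposure_col]
        return (
            self.beta_std[:, keep],
            self.se_std[:, keep],
            [self.trait_ids[j] for j in keep],
        )

    def to_tsv(self, beta_path, se_path) -> None:
        pd.DataFrame(self.beta_std, index=self.snp_ids, columns=self.trait_ids).to_csv(
            beta_path, sep="\t", index_label="variant_id"
        )
        pd.DataFrame(self.se_std, index=self.snp_ids, columns=self.trait_ids).to_csv(
            se_path, sep="\t", index_label="variant_id"
        )


def standardize_effects(t: SumStatTable) -> pd.DataFrame:
    """Per-variant standardised effects on the SD/SD scale.

    beta_std = z / sqrt(n) with z = beta/se, and se_std = 1/sqrt(n); the
    variant's explained variance is beta_std**2. Records without a usable n
    are dropped (reason recorded in the returned frame's attrs).
    """
    df = t.df
    usable = df["n"] > 0
    dropped = int((~usable).sum())
    df = df[usable]
    z = df["beta"].to_numpy() / df["se"].to_numpy()
    n = df["n"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "variant_id": df["variant_id"].to_numpy(),
            "beta_std": z / np.sqrt(n),
            "se_std": 1.0 / np.sqrt(n),
        }
    )
    out.attrs["dropped_missing_n"] = dropped
    return out


def qc_traits(
    traits: Iterable[TraitMeta],
    missing_effects: Mapping[str, bool] | None = None,
    n_eff_min: float = 50_000,
    rg_threshold: float = 0.75,
) -> tuple[list[TraitMeta], QcReport]:
    """Apply the trait-level QC filters in order.

    Removes, in order: traits with missing instrument effects (per the
    ``missing_effects`` flag map), duplicate trait_ids (keeping the most
    recent ``version_date``), traits with ``n_eff`` below ``n_eff_min``, and
    traits with ``|rg_exposure| > rg_threshold``. Missing rg passes with no
    removal (only known high-rG traits are filtered).
    """
    traits = list(traits)
    report = QcReport(n_in=len(traits))
    missing_effects = missing_effects or {}

    stage1 = []
    for m in traits:
        if missing_effects.get(m.trait_id, False):
            report.note("missing_effects", m.trait_id)
        else:
            stage1.append(m)

    # duplicates: keep latest version_date (missing date sorts earliest)
    best: dict[str, TraitMeta] = {}
    order: list[str] = []
    for m in stage1:
        if m.trait_id not in best:
            best[m.trait_id] = m
            order.append(m.trait_id)
        else:
            old = best[m.trait_id]
            if (m.version_date or "") > (old.version_date or ""):
                best[m.trait_id] = m
            report.note("duplicate", m.trait_id)
    stage2 = [best[tid] for tid in order]

    stage3 = []
    for m in stage2:
        if not np.isnan(m.n_eff) and m.n_eff < n_eff_min:
            report.note("n_eff", m.trait_id)
        else:
            stage3.append(m)

    out = []
    for m in stage3:
        if m.rg_exposure is not None and abs(m.rg_exposure) > rg_threshold:
            report.note("rg_exposure", m.trait_id)
        else:
            out.append(m)

    report.n_out = len(out)
    return out, report


def build_phewas_matrix(
    exposure: SumStatTable,
    panel: Sequence[SumStatTable],
    instruments: Sequence[str],
    drop_missing_traits: bool = True,
) -> tuple[PhewasMatrix, QcReport]:
    """Assemble the standardised instrument x trait matrix.

    The exposure's own column is included (needed by the Steiger filter);
    downstream clustering excludes it. Traits missing any instrument are
    dropped when ``drop_missing_traits`` (complete-case trait policy).
    """
    instruments = list(instruments)
    report = QcReport(n_in=len(panel))
    cols_beta, cols_se, kept_traits = [], [], []
    for table in [exposure] + list(panel):
        std = standardize_effects(table).set_index("variant_id")
        if not set(instruments) <= set(std.index):
            if table.trait_id == exposure.trait_id:
                missing = sorted(set(instruments) - set(std.index))[:3]
                raise ValueError(
                    f"exposure table missing instrument(s) {missing} ..."
                )
            if drop_missing_traits:
                report.note("missing_effects", table.trait_id)
                continue
            raise ValueError(f"trait {table.trait_id!r} missing instrument effects")
        std = std.loc[instruments]
        cols_beta.append(std["beta_std"].to_numpy())
        cols_se.append(std["se_std"].to_numpy())
        kept_traits.append(table.trait_id)
    report.n_out = len(kept_traits) - 1
    m = PhewasMatrix(
        snp_ids=instruments,
        trait_ids=kept_traits,
        beta_std=np.column_stack(cols_beta),
        se_std=np.column_stack(cols_se),
        exposure_col=exposure.trait_id,
    )
    return m, report


def steiger_filter(
    m: PhewasMatrix, alpha: float = 0.05
) -> tuple[list[str], dict[str, list[str]]]:
    """Trait-wide Steiger-style filter on instruments.

    For each SNP i and each non-exposure trait t, tests one-sided
    H1: explained variance on t exceeds that on the exposure, with

        z = (b_t^2 - b_x^2) / sqrt(4 b_t^2 se_t^2 + 4 b_x^2 se_x^2)

    and removes the SNP if any trait reaches one-sided p < alpha / T where T
    is the number of non-exposure traits. Returns (kept ids, mapping removed
    id -> offending trait ids).
    """
    xi = m.exposure_idx
    mask = np.ones(len(m.trait_ids), dtype=bool)
    mask[xi] = False
    T = int(mask.sum())
    if T == 0:
        return list(m.snp_ids), {}
    b2 = m.beta_std**2
    se2 = m.se_std**2
    bx2 = b2[:, xi][:, None]
    sex2 = se2[:, xi][:, None]
    bt2 = b2[:, mask]
    set2 = se2[:, mask]
    denom = np.sqrt(4.0 * bt2 * set2 + 4.0 * bx2 * sex2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, (bt2 - bx2) / denom, 0.0)
    p = stats.norm.sf(z)
    cutoff = alpha / T
    offending = p < cutoff
    trait_ids = [t for t, keep in zip(m.trait_ids, mask) if keep]
    kept, removed = [], {}
    for i, snp in enumerate(m.snp_ids):
        bad = np.flatnonzero(offending[i])
        if bad.size:
            removed[snp] = [trait_ids[j] for j in bad]
        else:
            kept.append(snp)
    return kept, removed
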