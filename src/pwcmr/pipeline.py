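"""End-to-end orchestration of the clustering pipeline and confounder search.

Two entry points mirror the two arms of the workflow:

* :func:`run_pwcmr` — instrument selection, PheWAS matrix assembly and QC,
  trait-wide Steiger filtering, k-means clustering with AIC model choice,
  per-cluster trait enrichment, and cluster-specific IVW with the
  cross-cluster heterogeneity test.
* :func:`run_confounder_pipeline` — outcome-side rG filtering, bidirectional
  MR of each panel trait against exposure and outcome, directionality calls
  and trait classification, then stepwise multivariable MR over the
  candidate confounders and a final joint fit with the exposure, guarded by
  the conditional F-statistic.

Both write a JSON report plus TSV side-tables into an output directory and
raise :class:`StageError` (carrying the stage name and an exit-code class)
on failure. File-based configuration is a flat YAML mapping; in-memory
variants (:func:`run_pwcmr_study`, :func:`run_confounder_study`) accept the
synthetic-study container directly and are what the tests exercise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import confounders as cf
from . import clustering as cl
from . import estimators as est
from . import mvmr as mv
from . import phewas as ph
from . import sumstats as ss
from .simulate import SyntheticStudy

__all__ = [
    "RunConfig",
    "RunReport",
    "StageError",
    "run_pwcmr",
    "run_confounder_pipeline",
    "run_pwcmr_study",
    "run_confounder_study",
]

log = logging.getLogger("pwcmr")

EXIT_CONFIG = 2
EXIT_IO = 3
EXIT_ANALYSIS = 4


class StageError(RuntimeError):
    """Pipeline failure labelled with its stage and an exit-code class."""

    def __init__(self, stage: str, message: str, exit_code: int = EXIT_ANALYSIS):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class RunConfig:
    """Flat run configuration (paths + thresholds); YAML-loadable."""

    exposure: str = ""
    outcome: str = ""
    traits_dir: str = ""
    ld: str = ""
    trait_meta: str = ""
    out_dir: str = "pwcmr_out"
    p_iv: float = 5e-8
    clump_kb: int = 10_000
    clump_r2: float = 0.001
    exclude_hla: bool = True
    hla_region: tuple[str, int, int] = ss.HLA_REGION
    n_eff_min: float = 50_000
    rg_max: float = 0.75
    steiger_alpha: float = 0.05
    k_min: int = 2
    k_max: int = 50
    restarts: int = 25
    # unscaled W + 2kd is robust when clusters are tight; see docs/methods.md
    aic_criterion: str = "wk"
    direction_lo: float = 0.05
    direction_hi: float = 0.95
    nominal_mr_p: float = 0.05
    mvmr_clump_kb: int = 5000
    mvmr_clump_r2: float = 0.01
    min_iv: int = 3
    cond_f_min: float = 10.0
    n_boot: int = 1000
    seed: int = 1

    def __post_init__(self):
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        for name in ("p_iv", "steiger_alpha", "nominal_mr_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1)")
        if not (0 <= self.direction_lo < self.direction_hi <= 1):
            raise ValueError("need 0 <= direction_lo < direction_hi <= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Machine-readable run summary (counts, estimates, config echo)."""

    stage_counts: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self._jsonable(), indent=2))

    def _jsonable(self):
        def conv(o):
            if isinstance(o, dict):
                return {str(k): conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o

        return conv(
            {
                "stage_counts": self.stage_counts,
                "estimates": self.estimates,
                "config": self.config,
                "version": self.version,
            }
        )


def _mr_input_from_matrix(
    m: ph.PhewasMatrix, outcome: ss.SumStatTable, exposure: ss.SumStatTable
) -> est.MRInput:
    """Harmonise the outcome to the exposure frame at the matrix SNPs."""
    paired = ss.harmonize(exposure.subset(m.snp_ids), outcome)
    ids = paired["variant_id"].tolist()
    if not ids:
        raise StageError("cluster-mr", "no instrument overlaps the outcome table")
    idx = [m.snp_ids.index(v) for v in ids]
    xj = m.exposure_idx
    sy = ph.standardize_effects(outcome.subset(ids)).set_index("variant_id").loc[ids]
    sign_b = np.sign(paired["beta_b"].to_numpy())
    raw = np.sign(sy["beta_std"].to_numpy())
    flip = np.where((sign_b != 0) & (raw != 0) & (sign_b != raw), -1.0, 1.0)
    return est.MRInput(
        beta_x=m.beta_std[idx, xj],
        se_x=m.se_std[idx, xj],
        beta_y=sy["beta_std"].to_numpy() * flip,
        se_y=sy["se_std"].to_numpy(),
        ids=ids,
    )


def run_pwcmr_study(
    exposure: ss.SumStatTable,
    outcome: ss.SumStatTable,
    panel: Sequence[ss.SumStatTable],
    trait_meta: Sequence[ph.TraitMeta],
    ld: ss.LdTable,
    cfg: RunConfig,
) -> RunReport:
    """The clustering arm on in-memory tables; returns the run report."""
    report = RunReport(config={k: v for k, v in asdict(cfg).items() if not str(k).startswith("_")})

    # (i) instrument selection
    ivs = ss.select_instruments(exposure, ld, cfg.p_iv, cfg.clump_kb, cfg.clump_r2)
    if cfg.exclude_hla:
        ivs = ss.exclude_region(ivs, exposure.positions(), cfg.hla_region)
    if len(ivs) < cfg.k_min + 1:
        raise StageError("iv-selection", f"only {len(ivs)} instruments selected")
    report.stage_counts["ivs_selected"] = len(ivs)

    # trait QC + matrix
    metas, qc_report = ph.qc_traits(trait_meta, n_eff_min=cfg.n_eff_min, rg_threshold=cfg.rg_max)
    kept_ids = {m.trait_id for m in metas}
    panel_kept = [t for t in panel if t.trait_id in kept_ids]
    matrix, m_report = ph.build_phewas_matrix(exposure, panel_kept, ivs)
    report.stage_counts["traits_after_qc"] = len(matrix.trait_ids) - 1
    report.stage_counts["trait_qc_removed"] = dict(qc_report.removed)

    # Steiger
    kept, removed = ph.steiger_filter(matrix, alpha=cfg.steiger_alpha)
    report.stage_counts["steiger_removed"] = len(removed)
    if len(kept) <= cfg.k_min:
        raise StageError("steiger", "too few instruments survive Steiger filtering")
    matrix = matrix.subset_snps(kept)

    # (ii) clustering
    beta_panel, _, _ = matrix.drop_exposure_column()
    x = cl.normalize_for_clustering(beta_panel, matrix.snp_ids)
    k_max = min(cfg.k_max, len(kept) - 1)
    model = cl.fit_kmeans_aic(
        x, matrix.snp_ids, cfg.k_min, k_max, cfg.seed, cfg.restarts,
        criterion=cfg.aic_criterion,
    )
    report.stage_counts["k_chosen"] = model.k
    report.stage_counts["cluster_sizes"] = model.cluster_sizes()

    # (iii) enrichment + per-cluster MR
    enr = cl.enrichment_ratio(matrix, model)
    top = cl.top_enriched(enr, n=10)
    d = _mr_input_from_matrix(matrix, outcome, exposure)
    assignments = {v: model.assignments[v] for v in d.ids}
    per_cluster, overall = est.mr_per_cluster(d, assignments)
    q, q_p = est.cross_cluster_q([r for r in per_cluster.values() if r is not None])

    report.estimates["overall_ivw"] = asdict(overall)
    report.estimates["per_cluster_ivw"] = {
        str(c): (None if r is None else asdict(r)) for c, r in per_cluster.items()
    }
    report.estimates["cross_cluster_q"] = {"q": q, "pval": q_p}
    report.estimates["top_enriched"] = {str(c): lst for c, lst in top.items()}
    report.estimates["aic_by_k"] = model.aic_by_k
    report._artifacts = {"matrix": matrix, "model": model, "enrichment": enr}  # type: ignore[attr-defined]
    return report


def run_confounder_study(
    exposure: ss.SumStatTable,
    outcome: ss.SumStatTable,
    panel: Sequence[ss.SumStatTable],
    trait_meta: Sequence[ph.TraitMeta],
    ld: ss.LdTable,
    cfg: RunConfig,
    scan_traits: Sequence[str] | None = None,
) -> RunReport:
    """The confounder-search arm on in-memory tables.

    ``scan_traits`` restricts the bidirectional scan to a subset of the
    panel (all QC-passing traits by default).
    """
    report = RunReport(config={k: v for k, v in asdict(cfg).items()})
    metas_x, _ = ph.qc_traits(trait_meta, n_eff_min=cfg.n_eff_min, rg_threshold=cfg.rg_max)
    metas, rg_report = cf.qc_outcome_rg(metas_x, rg_threshold=cfg.rg_max)
    keep = {m.trait_id for m in metas}
    if scan_traits is not None:
        keep &= set(scan_traits)
    tables = [t for t in panel if t.trait_id in keep]
    report.stage_counts["traits_scanned"] = len(tables)
    report.stage_counts["rg_outcome_removed"] = rg_report.removed.get("rg_outcome", 0)

    tests_x: dict[str, cf.DirectionTest | None] = {}
    tests_y: dict[str, cf.DirectionTest | None] = {}
    p_on_x: dict[str, float | None] = {}
    p_on_y: dict[str, float | None] = {}
    for trait in tables:
        for target, tests, pmap in (
            (exposure, tests_x, p_on_x),
            (outcome, tests_y, p_on_y),
        ):
            fwd, rev = cf.bidirectional_mr(
                trait, target, ld, cfg.p_iv, cfg.clump_kb, cfg.clump_r2,
                n_boot=cfg.n_boot, seed=cfg.seed,
            )
            if fwd is None or rev is None:
                tests[trait.trait_id] = None
                pmap[trait.trait_id] = None if fwd is None else fwd.pval
                continue
            tests[trait.trait_id] = cf.direction_test(
                trait.trait_id, target.trait_id,
                fwd.alpha, fwd.se, rev.alpha, rev.se,
                lo=cfg.direction_lo, hi=cfg.direction_hi,
            )
            pmap[trait.trait_id] = fwd.pval

    classes = cf.classify_traits(
        [t.trait_id for t in tables], tests_x, tests_y, p_on_x, p_on_y,
        nominal_p=cfg.nominal_mr_p,
    )
    by_cat: dict[str, list[str]] = {}
    for c in classes:
        by_cat.setdefault(c.category, []).append(c.trait_id)
    report.stage_counts["traits_per_category"] = {k: len(v) for k, v in by_cat.items()}
    report.estimates["classifications"] = [asdict(c) for c in classes]
    candidates = by_cat.get("candidate_confounder", [])
    report.estimates["candidate_confounders"] = candidates

    # univariable reference estimate
    ivs = ss.select_instruments(exposure, ld, cfg.p_iv, cfg.clump_kb, cfg.clump_r2)
    if cfg.exclude_hla:
        ivs = ss.exclude_region(ivs, exposure.positions(), cfg.hla_region)
    matrix, _ = ph.build_phewas_matrix(exposure, [], ivs)
    d_uni = _mr_input_from_matrix(matrix, outcome, exposure)
    uni = est.ivw(d_uni)
    report.estimates["univariable_ivw"] = asdict(uni)

    if not candidates:
        report.estimates["mvmr"] = None
        report.estimates["selected_confounders"] = []
        return report

    cand_tables = [t for t in tables if t.trait_id in candidates]
    exclude = [cfg.hla_region] if cfg.exclude_hla else []
    zm_cand = mv.build_zmatrix(cand_tables, cfg.p_iv, exclude=exclude)
    zm_cand = mv.rank_clump(zm_cand, ld, cfg.mvmr_clump_kb, cfg.mvmr_clump_r2)
    zm_cand = mv.filter_min_instruments(zm_cand, cfg.min_iv, cfg.p_iv)
    report.stage_counts["mvmr_candidate_traits"] = len(zm_cand.trait_ids)
    if not zm_cand.trait_ids:
        report.estimates["mvmr"] = None
        report.estimates["selected_confounders"] = []
        return report
    selected, _ = mv.stepwise_mvmr(zm_cand, outcome, bonferroni_m=len(zm_cand.trait_ids))
    report.estimates["stepwise_selected"] = selected

    # joint matrix with the exposure; trim the set until the exposure's
    # conditional F clears the adequacy bound
    zm_joint = mv.build_zmatrix([exposure] + [t for t in cand_tables if t.trait_id in selected],
                                cfg.p_iv, exclude=exclude)
    zm_joint = mv.rank_clump(zm_joint, ld, cfg.mvmr_clump_kb, cfg.mvmr_clump_r2)
    chosen = list(selected)
    while chosen:
        f = mv.conditional_f(zm_joint, exposure.trait_id, chosen)
        if f >= cfg.cond_f_min:
            break
        drop_scores = {
            t: mv.conditional_f(zm_joint, exposure.trait_id, [o for o in chosen if o != t])
            for t in chosen
        }
        chosen.remove(max(drop_scores, key=drop_scores.get))
    report.estimates["selected_confounders"] = chosen
    if chosen:
        fit = mv.mvmr_fit(zm_joint, outcome, [exposure.trait_id] + chosen, conditional_f_traits=True)
        report.estimates["mvmr"] = {
            "traits": fit.trait_ids,
            "alpha": fit.alpha.tolist(),
            "se": fit.se.tolist(),
            "pval": fit.pval.tolist(),
            "n_snp": fit.n_snp,
            "conditional_f": fit.conditional_f,
        }
    else:
        report.estimates["mvmr"] = None
    return report


# --------------------------------------------------------------------------
# File-based entry points
# --------------------------------------------------------------------------


def _load_inputs(cfg: RunConfig):
    try:
        exposure = ss.read_sumstats(cfg.exposure, trait_id="exposure")
        outcome = ss.read_sumstats(cfg.outcome, trait_id="outcome")
        ld = ss.LdTable.read_tsv(cfg.ld) if cfg.ld else ss.LdTable.identity()
        metas = ph.TraitMeta.read_tsv(cfg.trait_meta) if cfg.trait_meta else []
        panel = []
        if cfg.traits_dir:
            for p in sorted(Path(cfg.traits_dir).glob("*.tsv")):
                panel.append(ss.read_sumstats(p, trait_id=p.stem))
        if not metas:
            metas = [ph.TraitMeta(trait_id=t.trait_id, n_eff=float(t.n_total)) for t in panel]
    except FileNotFoundError as e:
        raise StageError("load", str(e), EXIT_IO) from e
    except (ss.SchemaError, ValueError) as e:
        raise StageError("load", str(e), EXIT_CONFIG) from e
    return exposure, outcome, panel, metas, ld


def _write_common(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_json(out_dir / "report.json")


def run_pwcmr(cfg: RunConfig) -> RunReport:
    """File-based clustering arm: load inputs, run, write report + TSVs."""
    exposure, outcome, panel, metas, ld = _load_inputs(cfg)
    report = run_pwcmr_study(exposure, outcome, panel, metas, ld, cfg)
    out = Path(cfg.out_dir)
    _write_common(report, out)
    art = getattr(report, "_artifacts", None)
    if art:
        art["model"].assignments_frame().to_csv(out / "assignments.tsv", sep="\t", index=False)
        art["enrichment"].er_frame().to_csv(out / "enrichment_ratio.tsv", sep="\t", index_label="cluster")
        pd.DataFrame(
            {"k": list(art["model"].aic_by_k), "aic": list(art["model"].aic_by_k.values())}
        ).to_csv(out / "aic_by_k.tsv", sep="\t", index=False)
    log.info("pwcmr run complete: k=%s", report.stage_counts.get("k_chosen"))
    return report


def run_confounder_pipeline(cfg: RunConfig, scan_traits: Sequence[str] | None = None) -> RunReport:
    """File-based confounder-search arm."""
    exposure, outcome, panel, metas, ld = _load_inputs(cfg)
    report = run_confounder_study(exposure, outcome, panel, metas, ld, cfg, scan_traits)
    out = Path(cfg.out_dir)
    _write_common(report, out)
    pd.DataFrame(report.estimates["classifications"]).to_csv(
        out / "classifications.tsv", sep="\t", index=False
    )
    return report


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Persist a synthetic study in the TSV dialects the readers consume."""
    out = Path(out_dir)
    (out / "traits").mkdir(parents=True, exist_ok=True)
    study.exposure.to_tsv(out / "exposure.tsv")
    study.outcome.to_tsv(out / "outcome.tsv")
    for t in study.panel:
        t.to_tsv(out / "traits" / f"{t.trait_id}.tsv")
    study.ld.to_tsv(out / "ld.tsv")
    rows = []
    for m in study.trait_meta:
        rows.append(
            {
                "trait_id": m.trait_id,
                "description": m.description,
                "n_eff": m.n_eff,
                "var_type": m.var_type,
                "rg_exposure": m.rg_exposure,
                "rg_outcome": m.rg_outcome,
                "version_date": m.version_date,
            }
        )
    pd.DataFrame(rows).to_csv(out / "trait_meta.tsv", sep="\t", index=False)
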