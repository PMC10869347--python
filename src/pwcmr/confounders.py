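"""Systematic candidate-confounder search.

For every trait in the panel (after removing traits too genetically
correlated with the outcome), bidirectional MR is run against both the
exposure and the outcome. Each direction is estimated with four methods
(IVW, weighted median, simple mode, weighted mode) and the estimate of the
*second most significant* method is kept, so that at least one other method
supports the causal claim.

Directionality between traits A and B is decided by the one-sided statistic

    t_AB = (|a_{A->B}| - |a_{B->A}|) / sqrt(SE_{A->B}^2 + SE_{B->A}^2)

with P = Phi(t_AB): P > hi (default 0.95) calls A->B dominant, P < lo
(default 0.05) calls B->A dominant, anything between is undetermined.

A candidate confounder is a trait whose effects on BOTH exposure and
outcome dominate the reverse directions, subject to a nominally significant
MR estimate (p < 0.05) on both; mediators (exposure->trait and
trait->outcome) and colliders (exposure->trait and outcome->trait) are
recognised but not pursued further.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .estimators import (
    EstimatorUnavailable,
    METHOD_ORDER,
    MRInput,
    MRResult,
    run_all_estimators,
)
from .phewas import QcReport, TraitMeta, standardize_effects
from .sumstats import LdTable, SumStatTable, harmonize, select_instruments

__all__ = [
    "DirectionTest",
    "TraitClassification",
    "second_most_significant",
    "bidirectional_mr",
    "direction_test",
    "classify_traits",
    "qc_outcome_rg",
]


@dataclass
class DirectionTest:
    """One-sided comparison of causal-effect strength between two traits."""

    trait_a: str
    trait_b: str
    alpha_ab: float
    se_ab: float
    alpha_ba: float
    se_ba: float
    t: float
    p_one_sided: float
    call: str  # a_to_b | b_to_a | undetermined


@dataclass
class TraitClassification:
    """Category call for one panel trait against the exposure/outcome pair."""

    trait_id: str
    vs_exposure: str  # trait_dominant | exposure_dominant | undetermined | unavailable
    vs_outcome: str  # trait_dominant | outcome_dominant | undetermined | unavailable
    category: str  # candidate_confounder | mediator | collider | exposure_only |
    #               outcome_only | unclassified
    mr_p_on_x: float | None = None
    mr_p_on_y: float | None = None
    reason: str = ""


def second_most_significant(results: Sequence[MRResult]) -> MRResult:
    """Pick the second most significant of the four estimates.

    Ordering is by ascending p-value; exact p ties are broken by the stable
    method order IVW > weighted median > weighted mode > simple mode.
    """
    if len(results) < 2:
        raise ValueError("need at least two method results")
    rank = {m: i for i, m in enumerate(METHOD_ORDER)}
    ordered = sorted(results, key=lambda r: (r.pval, rank.get(r.method, len(rank))))
    return ordered[1]


def _mr_one_direction(
    source: SumStatTable,
    target: SumStatTable,
    ld: LdTable,
    p_thresh: float,
    clump_kb: int,
    clump_r2: float,
    n_boot: int,
    seed: int,
) -> MRResult | None:
    """source -> target MR via the second-most-significant of four methods."""
    ivs = select_instruments(source, ld, p_thresh=p_thresh, clump_kb=clump_kb, clump_r2=clump_r2)
    if len(ivs) < 3:
        return None
    paired = harmonize(source.subset(ivs), target)
    if len(paired) < 3:
        return None
    # standardised scale keeps the estimators on SD/SD units throughout
    sx = standardize_effects(source.subset(paired["variant_id"].tolist()))
    sy = standardize_effects(target.subset(paired["variant_id"].tolist()))
    sx = sx.set_index("variant_id").loc[paired["variant_id"]]
    sy = sy.set_index("variant_id").loc[paired["variant_id"]]
    # standardize_effects works off the unharmonised table, so reapply the
    # allele-harmonised sign of the target effect
    sign_b = np.sign(paired["beta_b"].to_numpy())
    raw_sign_b = np.sign(sy["beta_std"].to_numpy())
    flip = np.where((sign_b != 0) & (raw_sign_b != 0) & (sign_b != raw_sign_b), -1.0, 1.0)
    d = MRInput(
        beta_x=sx["beta_std"].to_numpy(),
        se_x=sx["se_std"].to_numpy(),
        beta_y=sy["beta_std"].to_numpy() * flip,
        se_y=sy["se_std"].to_numpy(),
        ids=paired["variant_id"].tolist(),
    )
    try:
        results = run_all_estimators(d, n_boot=n_boot, seed=seed)
    except EstimatorUnavailable:
        return None
    return second_most_significant(results)


def bidirectional_mr(
    trait: SumStatTable,
    target: SumStatTable,
    ld: LdTable,
    p_thresh: float = 5e-8,
    clump_kb: int = 10_000,
    clump_r2: float = 0.001,
    n_boot: int = 1000,
    seed: int = 1,
) -> tuple[MRResult | None, MRResult | None]:
    """(trait -> target, target -> trait) second-most-significant estimates.

    A direction with fewer than three usable instruments is returned as
    ``None`` (unavailable) rather than raising.
    """
    fwd = _mr_one_direction(trait, target, ld, p_thresh, clump_kb, clump_r2, n_boot, seed)
    rev = _mr_one_direction(target, trait, ld, p_thresh, clump_kb, clump_r2, n_boot, seed + 1)
    return fwd, rev


def direction_test(
    trait_a: str,
    trait_b: str,
    alpha_ab: float,
    se_ab: float,
    alpha_ba: float,
    se_ba: float,
    lo: float = 0.05,
    hi: float = 0.95,
) -> DirectionTest:
    """One-sided strength comparison between the A->B and B->A estimates."""
    if se_ab <= 0 or se_ba <= 0:
        raise ValueError("standard errors must be positive")
    t = (abs(alpha_ab) - abs(alpha_ba)) / (se_ab**2 + se_ba**2) ** 0.5
    p = float(stats.norm.cdf(t))
    if p > hi:
        call = "a_to_b"
    elif p < lo:
        call = "b_to_a"
    else:
        call = "undetermined"
    return DirectionTest(
        trait_a=trait_a,
        trait_b=trait_b,
        alpha_ab=alpha_ab,
        se_ab=se_ab,
        alpha_ba=alpha_ba,
        se_ba=se_ba,
        t=float(t),
        p_one_sided=p,
        call=call,
    )


def _vs_call(dt: DirectionTest | None, target: str) -> str:
    if dt is None:
        return "unavailable"
    if dt.call == "a_to_b":
        return "trait_dominant"
    if dt.call == "b_to_a":
        return f"{target}_dominant"
    return "undetermined"


def classify_traits(
    trait_ids: Iterable[str],
    tests_vs_exposure: dict[str, DirectionTest | None],
    tests_vs_outcome: dict[str, DirectionTest | None],
    mr_p_on_x: dict[str, float | None],
    mr_p_on_y: dict[str, float | None],
    nominal_p: float = 0.05,
) -> list[TraitClassification]:
    """Apply the direction-based truth table to every trait.

    trait->X and trait->Y dominant (with nominal MR significance on both)
    => candidate_confounder; X->trait and trait->Y => mediator; X->trait and
    Y->trait => collider; a single trait-dominant call => exposure_only /
    outcome_only; anything else => unclassified.
    """
    out = []
    for tid in trait_ids:
        vx = _vs_call(tests_vs_exposure.get(tid), "exposure")
        vy = _vs_call(tests_vs_outcome.get(tid), "outcome")
        px = mr_p_on_x.get(tid)
        py = mr_p_on_y.get(tid)
        reason = ""
        if vx == "unavailable" or vy == "unavailable":
            category = "unclassified"
            reason = "direction test unavailable"
        elif vx == "trait_dominant" and vy == "trait_dominant":
            if px is not None and py is not None and px < nominal_p and py < nominal_p:
                category = "candidate_confounder"
            else:
                category = "unclassified"
                reason = "failed nominal MR significance on exposure or outcome"
        elif vx == "exposure_dominant" and vy == "trait_dominant":
            category = "mediator"
        elif vx == "exposure_dominant" and vy == "outcome_dominant":
            category = "collider"
        elif vx == "trait_dominant" and vy != "trait_dominant":
            category = "exposure_only"
        elif vy == "trait_dominant" and vx != "trait_dominant":
            category = "outcome_only"
        else:
            category = "unclassified"
        out.append(
            TraitClassification(
                trait_id=tid,
                vs_exposure=vx,
                vs_outcome=vy,
                category=category,
                mr_p_on_x=px,
                mr_p_on_y=py,
                reason=reason,
            )
        )
    return out


def qc_outcome_rg(
    traits: Iterable[TraitMeta], rg_threshold: float = 0.75
) -> tuple[list[TraitMeta], QcReport]:
    """Remove traits with |rg_outcome| strictly above the threshold.

    Missing rg_outcome passes with a warning count (only known high-rG
    traits are filtered).
    """
    traits = list(traits)
    report = QcReport(n_in=len(traits))
    out = []
    for m in traits:
        if m.rg_outcome is not None and abs(m.rg_outcome) > rg_threshold:
            report.note("rg_outcome", m.trait_id)
        else:
            if m.rg_outcome is None:
                report.note("rg_outcome_missing_kept", m.trait_id)
            out.append(m)
    report.n_out = len(out)
    # the missing-rg rule keeps traits, so it must not count towards removals
    report.removed.pop("rg_outcome_missing_kept", None)
    return out, report
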