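"""Reading, harmonising and thinning GWAS summary statistics.

Summary statistics arrive as one tab-delimited table per trait (one row per
variant, per-allele effect sizes). This module validates them into
:class:`SumStatTable`, aligns two traits onto a shared effect-allele frame
(:func:`harmonize`), selects genome-wide significant instruments with greedy
LD clumping (:func:`select_instruments`) and removes variants falling in an
excluded genomic region such as the extended HLA locus
(:func:`exclude_region`).

Coordinates are 1-based and region intervals are closed, following GWAS
summary-statistic convention. Pairwise LD is an explicit input (long-format
r2 table); a pair absent from the table is treated as r2 = 0, which supports
sparse LD files but means an incomplete LD table silently under-clumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GwasRecord",
    "SumStatTable",
    "LdTable",
    "ParseReport",
    "SchemaError",
    "read_sumstats",
    "harmonize",
    "select_instruments",
    "exclude_region",
    "HLA_REGION",
]

#: Default extended HLA region (GRCh37, cytoband 6p21.3), closed interval.
HLA_REGION: tuple[str, int, int] = ("6", 25_000_000, 34_000_000)

#: Canonical column names of the summary-statistic dialect.
CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "n",
    "eaf",
)

MANDATORY_COLUMNS = CANONICAL_COLUMNS[:9]  # eaf is optional

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_ALLELE_CHARS = set("ACGT")


class SchemaError(ValueError):
    """A mandatory summary-statistic column could not be resolved."""


@dataclass(frozen=True)
class GwasRecord:
    """Per-variant association summary for one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None

    def validate(self) -> str | None:
        """Return a reason code if any invariant is violated, else ``None``."""
        if not self.variant_id:
            return "empty_variant_id"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "nonpositive_se"
        if not (0 < self.pval <= 1):
            return "pval_out_of_range"
        if not math.isfinite(self.beta):
            return "nonfinite_beta"
        for allele in (self.effect_allele, self.other_allele):
            if not allele or not (set(allele) <= _ALLELE_CHARS):
                return "bad_allele"
        if self.n is None or self.n <= 0:
            return "bad_n"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "eaf_out_of_range"
        return None


@dataclass
class ParseReport:
    """Row-level accounting for one :func:`read_sumstats` call."""

    n_read: int = 0
    n_kept: int = 0
    dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def note_drop(self, reason: str) -> None:
        self.dropped += 1
        self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + 1


@dataclass
class SumStatTable:
    """Validated summary statistics for one trait.

    ``df`` holds the canonical columns; variant ids are unique. ``n_total``
    is the study sample size (defaults to the max per-record n).
    """

    trait_id: str
    df: pd.DataFrame
    n_total: int = 0
    report: ParseReport | None = None

    def __post_init__(self) -> None:
        if self.df["variant_id"].duplicated().any():
            dup = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant_id {dup!r} in trait {self.trait_id!r}")
        if self.n_total == 0 and len(self.df):
            self.n_total = int(self.df["n"].max())

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def positions(self) -> dict[str, tuple[str, int]]:
        """Mapping variant_id -> (chrom, pos)."""
        return {
            v: (c, int(p))
            for v, c, p in zip(self.df["variant_id"], self.df["chrom"], self.df["pos"])
        }

    def subset(self, ids: Sequence[str]) -> "SumStatTable":
        keep = self.df[self.df["variant_id"].isin(set(ids))].reset_index(drop=True)
        return SumStatTable(self.trait_id, keep, n_total=self.n_total)

    @classmethod
    def from_records(
        cls, trait_id: str, records: Iterable[GwasRecord], n_total: int = 0
    ) -> "SumStatTable":
        rows = [
            {
                "variant_id": r.variant_id,
                "chrom": str(r.chrom),
                "pos": int(r.pos),
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": float(r.beta),
                "se": float(r.se),
                "pval": float(r.pval),
                "n": int(r.n),
                "eaf": np.nan if r.eaf is None else float(r.eaf),
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(trait_id, df, n_total=n_total)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


class LdTable:
    """Sparse pairwise-LD lookup.

    Stores r2 for unordered variant pairs; ``r2(a, a)`` is 1 and a missing
    pair is 0 (sparse input convention — absent means "not in LD").
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
        key = (a, b) if a <= b else (b, a)
        self._r2[key] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._r2.get(key, 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def identity(cls) -> "LdTable":
        """LD table for fully independent variants (every off-diagonal r2 = 0)."""
        return cls()

    @classmethod
    def read_tsv(cls, path) -> "LdTable":
        df = pd.read_csv(path, sep="\t")
        needed = {"variant_a", "variant_b", "r2"}
        if not needed <= set(df.columns):
            raise SchemaError(f"LD table must have columns {sorted(needed)}")
        return cls(zip(df["variant_a"].astype(str), df["variant_b"].astype(str), df["r2"]))

    def to_tsv(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
) -> SumStatTable:
    """Read a tab-delimited summary-statistic file into a validated table.

    ``column_map`` maps canonical names (``variant_id``, ``chrom``, ...) to
    the file's actual header names where they differ. Rows violating the
    per-record invariants (se <= 0, p outside (0,1], malformed alleles, ...)
    are dropped and counted in ``table.report``.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    colmap = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = colmap.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
    raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s) {missing} in {path}")
    if "eaf" not in raw.columns:
        raw["eaf"] = np.nan

    report = ParseReport(n_read=len(raw))
    kept_rows = []
    for row in raw.itertuples(index=False):
        eaf = getattr(row, "eaf")
        try:
            rec = GwasRecord(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
                eaf=None if pd.isna(eaf) else float(eaf),
            )
        except (TypeError, ValueError):
            report.note_drop("unparseable_row")
            continue
        reason = rec.validate()
        if reason is not None:
            report.note_drop(reason)
            continue
        kept_rows.append(rec)
    seen: set[str] = set()
    deduped = []
    for rec in kept_rows:
        if rec.variant_id in seen:
            report.note_drop("duplicate_variant_id")
            continue
        seen.add(rec.variant_id)
        deduped.append(rec)
    report.n_kept = len(deduped)
    table = SumStatTable.from_records(trait_id or str(path), deduped)
    table.report = report
    return table


def _is_palindromic(ea: str, oa: str) -> bool:
    return (
        len(ea) == 1
        and len(oa) == 1
        and _COMPLEMENT.get(ea) == oa
    )


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[c] for c in allele)
    except KeyError:
        return None


def harmonize(a: SumStatTable, b: SumStatTable, palindrome_eaf_band: tuple[float, float] = (0.4, 0.6)) -> pd.DataFrame:
    """Align trait *b* onto trait *a*'s effect-allele frame.

    Returns a paired frame over shared variants with columns
    ``variant_id, chrom, pos, effect_allele, other_allele,
    beta_a, se_a, pval_a, n_a, beta_b, se_b, pval_b, n_b`` plus a
    ``drop_reason`` accounting is attached as ``frame.attrs['dropped']``.

    Rules (per variant): identical alleles pass through; swapped alleles flip
    the sign of ``beta_b`` (and reflect its eaf); strand flips are resolved by
    complementing; palindromic (A/T, C/G) variants whose eaf lies in the
    ambiguity band, or is missing, are dropped; irreconcilable allele sets
    are dropped with a reason code.
    """
    lo, hi = palindrome_eaf_band
    bi = b.df.set_index("variant_id")
    dropped: dict[str, int] = {}
    rows = []
    for ra in a.df.itertuples(index=False):
        vid = ra.variant_id
        if vid not in bi.index:
            continue
        rb = bi.loc[vid]
        ea_a, oa_a = ra.effect_allele, ra.other_allele
        ea_b, oa_b = rb["effect_allele"], rb["other_allele"]
        if _is_palindromic(ea_a, oa_a):
            eafs = [x for x in (ra.eaf, rb["eaf"]) if not pd.isna(x)]
            if len(eafs) < 2 or any(lo <= x <= hi for x in eafs):
                dropped["palindromic_ambiguous"] = dropped.get("palindromic_ambiguous", 0) + 1
                continue
        flip: bool | None = None
        if (ea_b, oa_b) == (ea_a, oa_a):
            flip = False
        elif (ea_b, oa_b) == (oa_a, ea_a):
            flip = True
        else:
            cea, coa = _complement(ea_b), _complement(oa_b)
            if (cea, coa) == (ea_a, oa_a):
                flip = False
            elif (cea, coa) == (oa_a, ea_a):
                flip = True
        if flip is None:
            dropped["allele_mismatch"] = dropped.get("allele_mismatch", 0) + 1
            continue
        beta_b = -float(rb["beta"]) if flip else float(rb["beta"])
        eaf_b = rb["eaf"]
        if flip and not pd.isna(eaf_b):
            eaf_b = 1.0 - float(eaf_b)
        rows.append(
            {
                "variant_id": vid,
                "chrom": ra.chrom,
                "pos": ra.pos,
                "effect_allele": ea_a,
                "other_allele": oa_a,
                "beta_a": float(ra.beta),
                "se_a": float(ra.se),
                "pval_a": float(ra.pval),
                "n_a": int(ra.n),
                "eaf_a": ra.eaf,
                "beta_b": beta_b,
                "se_b": float(rb["se"]),
                "pval_b": float(rb["pval"]),
                "n_b": int(rb["n"]),
                "eaf_b": eaf_b,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "beta_a", "se_a", "pval_a", "n_a", "eaf_a",
            "beta_b", "se_b", "pval_b", "n_b", "eaf_b",
        ],
    )
    out.attrs["dropped"] = dropped
    return out


def select_instruments(
    t: SumStatTable,
    ld: LdTable,
    p_thresh: float = 5e-8,
    clump_kb: int = 10_000,
    clump_r2: float = 0.001,
) -> list[str]:
    """Select independent genome-wide significant instruments by greedy clumping.

    Variants with p < ``p_thresh`` are sorted by ascending p (ties broken by
    variant_id); the best is retained and every remaining variant on the same
    chromosome within ``clump_kb`` kilobases AND with r2 >= ``clump_r2``
    against it is discarded; repeat. Returns retained variant ids in
    (p, variant_id) order. An empty result is not an error.
    """
    cand = t.df[t.df["pval"] < p_thresh]
    if cand.empty:
        return []
    cand = cand.sort_values(["pval", "variant_id"], kind="mergesort")
    window_bp = int(clump_kb) * 1000
    retained: list[tuple[str, str, int]] = []  # (id, chrom, pos)
    for row in cand.itertuples(index=False):
        ok = True
        for rid, rchrom, rpos in retained:
            if (
                str(row.chrom) == rchrom
                and abs(int(row.pos) - rpos) <= window_bp
                and ld.r2(row.variant_id, rid) >= clump_r2
            ):
                ok = False
                break
        if ok:
            retained.append((row.variant_id, str(row.chrom), int(row.pos)))
    return [rid for rid, _, _ in retained]


def exclude_region(
    ids: Sequence[str],
    positions: Mapping[str, tuple[str, int]],
    region: tuple[str, int, int] = HLA_REGION,
) -> list[str]:
    """Drop variants inside a closed genomic interval (chrom, start, end)."""
    chrom, start, end = region
    out = []
    for vid in ids:
        if vid not in positions:
            raise KeyError(f"position unknown for variant {vid!r}")
        vchrom, vpos = positions[vid]
        if str(vchrom) == str(chrom) and start <= int(vpos) <= end:
            continue
        out.append(vid)
    return out
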