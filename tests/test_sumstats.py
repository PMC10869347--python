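"""Summary-statistic reading, harmonisation, clumping and region exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pwcmr import (
    HLA_REGION,
    LdTable,
    SumStatTable,
    exclude_region,
    harmonize,
    read_sumstats,
    select_instruments,
)
from pwcmr.sumstats import SchemaError


def _write_tsv(path, rows, columns=None):
    columns = columns or [
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "beta", "se", "pval", "n", "eaf",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def _row(vid="rs1", chrom="1", pos=1000, ea="A", oa="G", beta=0.1, se=0.02,
         pval=1e-9, n=10000, eaf=0.3):
    return [vid, chrom, pos, ea, oa, beta, se, pval, n, eaf]


class TestReadSumstats:
    def test_well_formed_rows_all_kept(self, tmp_path):
        p = tmp_path / "x.tsv"
        _write_tsv(p, [_row("rs1"), _row("rs2", pos=2000), _row("rs3", pos=3000)])
        t = read_sumstats(p, trait_id="x")
        assert len(t) == 3
        assert t.report.dropped == 0
        assert t.n_total == 10000

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "x.tsv"
        _write_tsv(p, [
            _row("rs1"),
            _row("rs2", se=0.0),           # nonpositive SE
            _row("rs3", pval=0.0),         # p outside (0, 1]
            _row("rs4", ea="Z"),           # malformed allele
        ])
        t = read_sumstats(p)
        assert len(t) == 1
        assert t.report.dropped == 3
        assert t.report.drop_reasons["nonpositive_se"] == 1

    def test_deterministic_parse(self, tmp_path):
        p = tmp_path / "x.tsv"
        _write_tsv(p, [_row("rs1"), _row("rs2", pos=2000)])
        t1, t2 = read_sumstats(p), read_sumstats(p)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_column_map_and_missing_column(self, tmp_path):
        p = tmp_path / "x.tsv"
        df = pd.DataFrame([_row()], columns=[
            "SNP", "chr", "bp", "A1", "A2", "b", "se", "p", "N", "freq"])
        df.to_csv(p, sep="\t", index=False)
        cmap = {"variant_id": "SNP", "chrom": "chr", "pos": "bp",
                "effect_allele": "A1", "other_allele": "A2", "beta": "b",
                "pval": "p", "n": "N", "eaf": "freq"}
        t = read_sumstats(p, column_map=cmap)
        assert len(t) == 1
        with pytest.raises(SchemaError):
            read_sumstats(p)  # unmapped headers unresolvable


def _table(trait, rows):
    p = pd.DataFrame(rows, columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "beta", "se", "pval", "n", "eaf"])
    return SumStatTable(trait, p)


class TestHarmonize:
    def test_identical_alleles_pass_through(self):
        a = _table("a", [_row(beta=0.2)])
        b = _table("b", [_row(beta=0.1)])
        out = harmonize(a, b)
        assert out["beta_b"].tolist() == [0.1]

    def test_swapped_alleles_flip_sign_and_eaf(self):
        a = _table("a", [_row(ea="A", oa="G", eaf=0.3)])
        b = _table("b", [_row(ea="G", oa="A", beta=0.1, eaf=0.7)])
        out = harmonize(a, b)
        assert out["beta_b"].tolist() == [-0.1]
        assert out["eaf_b"].tolist() == [pytest.approx(0.3)]

    def test_strand_flip_resolved_by_complement(self):
        a = _table("a", [_row(ea="A", oa="G")])
        b = _table("b", [_row(ea="T", oa="C", beta=0.1)])
        out = harmonize(a, b)
        assert out["beta_b"].tolist() == [0.1]

    def test_palindromic_ambiguous_dropped(self):
        a = _table("a", [_row(ea="A", oa="T", eaf=0.5)])
        b = _table("b", [_row(ea="A", oa="T", eaf=0.5)])
        out = harmonize(a, b)
        assert len(out) == 0
        assert out.attrs["dropped"]["palindromic_ambiguous"] == 1

    def test_palindromic_clear_eaf_kept(self):
        a = _table("a", [_row(ea="A", oa="T", eaf=0.1)])
        b = _table("b", [_row(ea="A", oa="T", beta=0.1, eaf=0.12)])
        assert len(harmonize(a, b)) == 1

    def test_irreconcilable_alleles_dropped_with_reason(self):
        a = _table("a", [_row(ea="A", oa="G")])
        b = _table("b", [_row(ea="A", oa="C")])
        out = harmonize(a, b)
        assert len(out) == 0
        assert out.attrs["dropped"]["allele_mismatch"] == 1

    def test_sign_flip_idempotence(self):
        """Pre-flipping b's alleles+signs yields the identical paired table."""
        a = _table("a", [_row("rs1", beta=0.2), _row("rs2", pos=2000, beta=-0.1)])
        b = _table("b", [_row("rs1", beta=0.1), _row("rs2", pos=2000, beta=0.3)])
        flipped = b.df.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        out1 = harmonize(a, b)
        out2 = harmonize(a, SumStatTable("b", flipped))
        pd.testing.assert_frame_equal(out1, out2)


def _clump_oracle(df, ld, window_bp, r2):
    """Exhaustive verification of a greedy-clumping result."""
    retained = select_instruments(
        SumStatTable("t", df), ld, p_thresh=1.0, clump_kb=window_bp // 1000, clump_r2=r2
    )
    pos = {r.variant_id: (r.chrom, r.pos) for r in df.itertuples()}
    pv = dict(zip(df["variant_id"], df["pval"]))
    rset = set(retained)
    # every retained pair is independent under the rule
    for i in retained:
        for j in retained:
            if i < j and pos[i][0] == pos[j][0]:
                assert (abs(pos[i][1] - pos[j][1]) > window_bp) or (ld.r2(i, j) < r2)
    # every discarded variant conflicts with a better retained one
    for v in df["variant_id"]:
        if v in rset:
            continue
        conflicts = [
            r for r in retained
            if pos[r][0] == pos[v][0]
            and abs(pos[r][1] - pos[v][1]) <= window_bp
            and ld.r2(r, v) >= r2
            and (pv[r], r) < (pv[v], v)
        ]
        assert conflicts, f"{v} discarded without a dominating retained variant"
    return retained


class TestSelectInstruments:
    def test_ld_dominance(self):
        t = _table("t", [
            _row("rs1", pos=10_000, pval=1e-10),
            _row("rs2", pos=15_000, pval=1e-9),
        ])
        ld = LdTable([("rs1", "rs2", 0.9)])
        assert select_instruments(t, ld) == ["rs1"]

    def test_different_chromosomes_both_kept(self):
        t = _table("t", [
            _row("rs1", chrom="1", pos=10_000, pval=1e-10),
            _row("rs2", chrom="2", pos=10_000, pval=1e-9),
        ])
        ld = LdTable([("rs1", "rs2", 0.99)])
        assert select_instruments(t, ld) == ["rs1", "rs2"]

    def test_no_significant_variant_returns_empty(self):
        t = _table("t", [_row("rs1", pval=0.5)])
        assert select_instruments(t, LdTable()) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        rows = [
            _row(
                f"rs{i:02d}",
                chrom=str(rng.integers(1, 3)),
                pos=int(rng.integers(1, 50) * 2000),
                pval=float(rng.uniform(1e-12, 1e-2)),
            )
            for i in range(n)
        ]
        df = pd.DataFrame(rows, columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "beta", "se", "pval", "n", "eaf"]).drop_duplicates(["chrom", "pos"])
        ld = LdTable()
        ids = df["variant_id"].tolist()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if rng.random() < 0.3:
                    ld.add(ids[i], ids[j], float(rng.random()))
        _clump_oracle(df, ld, window_bp=20_000, r2=0.2)

    @given(perm_seed=st.integers(0, 10_000))
    def test_row_order_invariance(self, perm_seed):
        rng = np.random.default_rng(42)
        rows = [
            _row(f"rs{i}", pos=5000 * (i + 1), pval=float(rng.uniform(1e-10, 1e-4)))
            for i in range(8)
        ]
        df = pd.DataFrame(rows, columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "beta", "se", "pval", "n", "eaf"])
        ld = LdTable([(f"rs{i}", f"rs{j}", 0.5) for i in range(8) for j in range(i + 1, 8)])
        base = select_instruments(SumStatTable("t", df), ld, 1.0, 10, 0.2)
        shuffled = df.sample(frac=1, random_state=perm_seed).reset_index(drop=True)
        assert select_instruments(SumStatTable("t", shuffled), ld, 1.0, 10, 0.2) == base


class TestExcludeRegion:
    def test_containment_boundaries_and_empty(self):
        positions = {
            "in": ("6", 30_000_000),
            "edge_out": ("6", 24_999_999),
            "edge_in": ("6", 25_000_000),
            "other_chrom": ("7", 30_000_000),
        }
        ids = list(positions)
        out = exclude_region(ids, positions, HLA_REGION)
        assert out == ["edge_out", "other_chrom"]
        assert exclude_region([], {}, HLA_REGION) == []

    def test_unknown_position_raises_with_name(self):
        with pytest.raises(KeyError, match="rsX"):
            exclude_region(["rsX"], {}, HLA_REGION)
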