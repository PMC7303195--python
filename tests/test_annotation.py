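import math

import numpy as np
import pandas as pd
import pytest

from spatialeqtl.annotation import (
    DEFAULT_MARK_CLASSES,
    HistoneMarkRecord,
    PWM,
    histone_overlap,
    ld_matrix,
    motif_delta,
    read_haplotypes_tsv,
    read_marks_tsv,
    read_pwms,
    reverse_complement,
    score_allele_against_pwm,
    write_marks_tsv,
    write_pwms,
)
from spatialeqtl.fragments import Variant
from oracles import ld_from_counts


def _variant(pos, chrom="chr1", ref="A", alt="C"):
    return Variant("rsT", chrom, pos, ref, alt)


class TestHistoneOverlap:
    MARKS = [
        HistoneMarkRecord("chr1", 100, 200, "adipose", "H3K27ac"),
        HistoneMarkRecord("chr1", 100, 200, "adipose", "H3K4me3"),
        HistoneMarkRecord("chr1", 100, 200, "liver", "H3K4me1"),
        HistoneMarkRecord("chr2", 100, 200, "adipose", "H3K27ac"),
    ]

    def test_enhancer_marked(self):
        out = histone_overlap(_variant(150), [self.MARKS[0]])
        assert out["adipose"]["enhancer"] and not out["adipose"]["promoter"]

    def test_half_open_boundaries(self):
        # pos0 = 200 is one past the interval end; pos0 = 99 one before start
        assert histone_overlap(_variant(201), [self.MARKS[0]]) == {}
        assert histone_overlap(_variant(100), [self.MARKS[0]]) == {}
        # pos0 = 100 (first covered base) and 199 (last) both overlap
        assert histone_overlap(_variant(101), [self.MARKS[0]]) != {}
        assert histone_overlap(_variant(200), [self.MARKS[0]]) != {}

    def test_both_enhancer_and_promoter(self):
        # mirrors variants under enhancer (H3K4me1/H3K27ac) and promoter
        # (H3K4me3/H3K9ac) marks in the same tissue
        marks = [
            HistoneMarkRecord("chr1", 100, 200, "adipose", "H3K4me1"),
            HistoneMarkRecord("chr1", 100, 200, "adipose", "H3K27ac"),
            HistoneMarkRecord("chr1", 100, 200, "adipose", "H3K4me3"),
            HistoneMarkRecord("chr1", 100, 200, "adipose", "H3K9ac"),
        ]
        out = histone_overlap(_variant(150), marks)
        assert out["adipose"]["enhancer"] and out["adipose"]["promoter"]
        assert out["adipose"]["marks"] == {"H3K4me1", "H3K27ac", "H3K4me3", "H3K9ac"}

    def test_tissue_filter(self):
        out = histone_overlap(_variant(150), self.MARKS, tissues={"liver"})
        assert set(out) == {"liver"} and out["liver"]["enhancer"]

    def test_unknown_mark_classed_other(self, caplog):
        marks = [HistoneMarkRecord("chr1", 100, 200, "adipose", "H3K36me3")]
        out = histone_overlap(_variant(150), marks)
        assert out["adipose"]["marks"] == {"H3K36me3"}
        assert not out["adipose"]["enhancer"] and not out["adipose"]["promoter"]

    def test_default_grouping(self):
        assert DEFAULT_MARK_CLASSES["H3K27ac"] == "enhancer"
        assert DEFAULT_MARK_CLASSES["H3K9ac"] == "promoter"


SINGLE = PWM("single", np.array([[0.97, 0.01, 0.01, 0.01]]))
UNIFORM = PWM("uniform", np.full((3, 4), 0.25))


class TestPwmScoring:
    def test_uniform_scores_zero(self):
        assert score_allele_against_pwm("ACGTACG", 3, "T", UNIFORM) == pytest.approx(0.0)
        assert score_allele_against_pwm("ACGTACG", 3, "G", UNIFORM) == pytest.approx(0.0)

    def test_single_column_ref(self):
        got = score_allele_against_pwm("GGAGG", 2, "A", SINGLE)
        assert got == pytest.approx(math.log2(0.97 / 0.25), abs=1e-9)  # ~1.956

    def test_single_column_alt(self):
        got = score_allele_against_pwm("GGAGG", 2, "C", SINGLE)
        assert got == pytest.approx(math.log2(0.01 / 0.25), abs=1e-9)  # ~-4.644

    def test_delta_worked_example(self):
        hits = motif_delta("GGAGG", 2, "A", "C", [SINGLE])
        assert hits[0].delta == pytest.approx(-6.5999, abs=1e-3)
        assert hits[0].delta < 0  # predicted decreased binding

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="A/C/G/T"):
            score_allele_against_pwm("GGNGG", 2, "A", SINGLE)

    def test_context_too_short(self):
        long_pwm = PWM("L5", np.full((5, 4), 0.25))
        with pytest.raises(ValueError, match="context too short"):
            score_allele_against_pwm("ACG", 1, "A", long_pwm)

    def test_palindromic_pwm_strand_symmetric(self):
        # PWM whose reverse complement equals itself
        probs = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]])
        pal = PWM("pal", probs)
        assert np.allclose(pal.reverse_complement().probs, probs)
        ctx = "GGATCC"
        for allele in "ACGT":
            fwd = score_allele_against_pwm(ctx, 2, allele, pal)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[allele]
            rev = score_allele_against_pwm(reverse_complement(ctx), 3, comp, pal)
            assert fwd == pytest.approx(rev, abs=1e-9)

    def test_revcomp_pwm_strand_consistency(self, rng):
        for _ in range(20):
            probs = rng.dirichlet(np.ones(4), size=4)
            pwm = PWM("m", probs)
            ctx = "".join(rng.choice(list("ACGT"), size=12))
            off = int(rng.integers(4, 8))
            allele = "ACGT"[int(rng.integers(4))]
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[allele]
            a = score_allele_against_pwm(ctx, off, allele, pwm)
            b = score_allele_against_pwm(
                reverse_complement(ctx), len(ctx) - 1 - off, comp, pwm.reverse_complement()
            )
            assert a == pytest.approx(b, abs=1e-9)

    def test_pseudocount_handles_zero_cells(self):
        probs = np.array([[1.0, 0.0, 0.0, 0.0]])
        pwm = PWM("hard", probs)
        s = score_allele_against_pwm("GGCGG", 2, "C", pwm, pseudocount=1e-3)
        assert math.isfinite(s)

    def test_planted_disruption_signs(self, planted_dataset):
        ds = planted_dataset
        by_rsid = {v.rsid: v for v in ds.variants}
        by_name = {p.motif_name: p for p in ds.pwms}
        for rsid, motif, sign in ds.manifest.motif_disruptions:
            v = by_rsid[rsid]
            seq = ds.genome[v.chrom]
            ctx = seq[v.pos0 - 5 : v.pos0 + 6]
            hits = motif_delta(ctx, 5, v.ref, v.alt, [by_name[motif]])
            assert (hits[0].delta < 0) == (sign == "-")


class TestPwmType:
    def test_row_sum_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PWM("bad", np.array([[0.5, 0.1, 0.1, 0.1]]))

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            PWM("bad", np.array([0.25, 0.25, 0.25, 0.25]))


class TestLD:
    def test_duplicated_columns_perfect_ld(self):
        col = [0, 1, 1, 0, 1, 0, 0, 1]
        panel = pd.DataFrame({"a": col, "b": col, "c": col})
        stats = {(s.rsid_a, s.rsid_b): s for s in ld_matrix(panel)}
        for key in [("a", "b"), ("a", "c"), ("b", "c")]:
            assert stats[key].r2 == pytest.approx(1.0)
            assert stats[key].d_prime == pytest.approx(1.0)

    def test_worked_2x2_table(self):
        # 20 haplotypes: AB=6, Ab=4, aB=4, ab=6 -> D=0.05, r2=0.04, D'=0.2
        a = [1] * 6 + [1] * 4 + [0] * 4 + [0] * 6
        b = [1] * 6 + [0] * 4 + [1] * 4 + [0] * 6
        stats = ld_matrix(pd.DataFrame({"a": a, "b": b}))
        s = next(x for x in stats if x.rsid_a == "a" and x.rsid_b == "b")
        assert s.r2 == pytest.approx(0.04, abs=1e-12)
        assert s.d_prime == pytest.approx(0.2, abs=1e-12)
        oracle_r2, oracle_dp = ld_from_counts(6, 4, 4, 6)
        assert s.r2 == pytest.approx(oracle_r2) and s.d_prime == pytest.approx(oracle_dp)

    def test_equilibrium_zero(self):
        # pAB = pA*pB exactly: independence
        a = [1, 1, 0, 0]
        b = [1, 0, 1, 0]
        s = next(
            x for x in ld_matrix(pd.DataFrame({"a": a, "b": b}))
            if x.rsid_a == "a" and x.rsid_b == "b"
        )
        assert s.r2 == pytest.approx(0.0) and s.d_prime == 0.0

    def test_diagonal_r2_one(self):
        panel = pd.DataFrame({"a": [0, 1, 1, 0]})
        s = ld_matrix(panel)[0]
        assert s.rsid_a == s.rsid_b == "a" and s.r2 == 1.0 and s.d_prime == 1.0

    def test_monomorphic_named_in_error(self):
        panel = pd.DataFrame({"a": [0, 1], "mono": [1, 1]})
        with pytest.raises(ValueError, match="mono"):
            ld_matrix(panel)

    def test_allele_relabel_invariance(self, rng):
        for _ in range(20):
            a = rng.integers(0, 2, size=30)
            b = rng.integers(0, 2, size=30)
            if a.min() == a.max() or b.min() == b.max():
                continue
            base = ld_matrix(pd.DataFrame({"a": a, "b": b}))[1]
            flipped = ld_matrix(pd.DataFrame({"a": 1 - a, "b": b}))[1]
            both = ld_matrix(pd.DataFrame({"a": 1 - a, "b": 1 - b}))[1]
            for other in (flipped, both):
                assert base.r2 == pytest.approx(other.r2, abs=1e-12)
                assert base.d_prime == pytest.approx(other.d_prime, abs=1e-12)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            ld_matrix(pd.DataFrame({"a": [0, 2, 1]}))

    def test_missing_variant_rejected(self):
        with pytest.raises(KeyError):
            ld_matrix(pd.DataFrame({"a": [0, 1]}), ["a", "zz"])

    def test_planted_blocks(self, planted_dataset):
        ds = planted_dataset
        for block in ds.manifest.ld_blocks:
            stats = ld_matrix(ds.haplotypes, block)
            assert all(s.r2 == pytest.approx(1.0) for s in stats)


class TestIO:
    def test_marks_roundtrip(self, tmp_path):
        marks = [HistoneMarkRecord("chr1", 5, 10, "adipose", "H3K27ac")]
        write_marks_tsv(marks, tmp_path / "m.tsv")
        assert read_marks_tsv(tmp_path / "m.tsv") == marks

    def test_pwm_roundtrip(self, tmp_path):
        pwms = [SINGLE, UNIFORM]
        write_pwms(pwms, tmp_path / "p.txt")
        back = read_pwms(tmp_path / "p.txt")
        assert [p.motif_name for p in back] == ["single", "uniform"]
        assert np.allclose(back[0].probs, SINGLE.probs)

    def test_pwm_bad_row_rejected(self, tmp_path):
        (tmp_path / "bad.txt").write_text(">m\n0.5 0.5\n")
        with pytest.raises(ValueError, match="4 probabilities"):
            read_pwms(tmp_path / "bad.txt")

    def test_haplotypes_roundtrip(self, tmp_path):
        panel = pd.DataFrame({"rs1": [0, 1], "rs2": [1, 0]})
        panel.to_csv(tmp_path / "h.tsv", sep="\t", index=False)
        assert read_haplotypes_tsv(tmp_path / "h.tsv").equals(panel)
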