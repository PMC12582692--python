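import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protmr.gwas_io import LDMatrix
from protmr.instruments import (clump, harmonize, is_palindromic,
                                select_significant)

from conftest import make_record


class TestSelectSignificant:
    def test_strict_inequality_at_threshold(self):
        recs = [make_record(snp_id=f"rs{i}", pval=p)
                for i, p in enumerate([1e-9, 5e-8, 1e-7])]
        kept = select_significant(recs, 5e-8)
        assert [r.snp_id for r in kept] == ["rs0"]

    def test_all_null_gives_empty(self):
        recs = [make_record(snp_id=f"rs{i}", pval=0.5) for i in range(5)]
        assert select_significant(recs) == []

    def test_order_preserved(self):
        recs = [make_record(snp_id=f"rs{i}", pval=1e-9 * (5 - i)) for i in range(5)]
        assert [r.snp_id for r in select_significant(recs)] == [r.snp_id for r in recs]


def _ar1_ld(ids, rho):
    n = len(ids)
    return LDMatrix(list(ids), rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n))))


def _brute_force_clump(records, ld, r2_threshold, window_bp):
    """Independent reference: iterative best-p selection with set arithmetic."""
    remaining = sorted(records, key=lambda r: (r.pval, r.chrom, r.pos))
    kept = []
    while remaining:
        best = remaining[0]
        kept.append(best)
        remaining = [
            r for r in remaining[1:]
            if not (r.chrom == best.chrom and abs(r.pos - best.pos) <= window_bp
                    and ld.r2(best.snp_id, r.snp_id) > r2_threshold)
        ]
    return sorted(kept, key=lambda r: (r.chrom, r.pos))


class TestClump:
    def test_single_clump_keeps_best_p(self):
        recs = [make_record(snp_id=f"rs{i}", pos=1000 + i, pval=p)
                for i, p in enumerate([1e-10, 1e-9, 1e-8])]
        ld = _ar1_ld([r.snp_id for r in recs], 0.95)  # pairwise r2 ~ 0.9
        kept = clump(recs, ld, r2_threshold=0.001, window_kb=10_000)
        assert [r.snp_id for r in kept] == ["rs0"]

    def test_independent_snps_all_kept(self):
        recs = [make_record(snp_id=f"rs{i}", pos=1000 * i + 1, pval=1e-9)
                for i in range(4)]
        kept = clump(recs, _ar1_ld([r.snp_id for r in recs], 0.0), 0.001, 10_000)
        assert len(kept) == 4

    def test_outside_window_not_clumped(self):
        recs = [make_record(snp_id="rs0", pos=1, pval=1e-10),
                make_record(snp_id="rs1", pos=20_000_001, pval=1e-9)]
        kept = clump(recs, _ar1_ld(["rs0", "rs1"], 0.99), 0.001, 10_000)
        assert len(kept) == 2  # r2 high but 20 Mb apart

    def test_missing_snp_is_fatal(self):
        recs = [make_record(snp_id="rsX")]
        with pytest.raises(ValueError, match="rsX"):
            clump(recs, _ar1_ld(["rs1"], 0.0), 0.001, 10_000)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_ar1_region(self, seed):
        rng = np.random.default_rng(seed)
        recs = [make_record(snp_id=f"rs{i}", pos=1000 + 500 * i,
                            pval=float(rng.uniform(1e-12, 1e-6)))
                for i in range(10)]
        ld = _ar1_ld([r.snp_id for r in recs], 0.8)
        kept = clump(recs, ld, r2_threshold=0.1, window_kb=10_000)
        oracle = _brute_force_clump(recs, ld, 0.1, 10_000 * 1000)
        assert [r.snp_id for r in kept] == [r.snp_id for r in oracle]

    @pytest.mark.parametrize("seed", range(3))
    def test_row_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        recs = [make_record(snp_id=f"rs{i}", pos=1000 + 500 * i,
                            pval=float(rng.uniform(1e-12, 1e-6)))
                for i in range(8)]
        ld = _ar1_ld([r.snp_id for r in recs], 0.7)
        kept = clump(recs, ld, 0.2, 10_000)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        kept2 = clump(shuffled, ld, 0.2, 10_000)
        assert [r.snp_id for r in kept] == [r.snp_id for r in kept2]


class TestHarmonize:
    def test_swapped_alleles_flip_beta(self):
        x = make_record(ea="A", oa="G", beta=0.1, eaf=0.3)
        y = make_record(ea="G", oa="A", beta=0.2, eaf=0.7)
        s = harmonize([x], [y])
        assert s.beta_y[0] == -0.2
        assert np.isclose(s.eaf_y[0], 0.3)

    def test_strand_flip_resolved(self):
        x = make_record(ea="A", oa="G", beta=0.1)
        y = make_record(ea="T", oa="C", beta=0.2)  # same SNP, other strand
        s = harmonize([x], [y])
        assert s.beta_y[0] == 0.2

    def test_ambiguous_palindrome_dropped(self):
        x = make_record(snp_id="rs1", ea="A", oa="T", eaf=0.50)
        y = make_record(snp_id="rs1", ea="A", oa="T", eaf=0.50)
        ok_x = make_record(snp_id="rs2", pos=2000, ea="A", oa="G")
        ok_y = make_record(snp_id="rs2", pos=2000, ea="A", oa="G")
        s = harmonize([x, ok_x], [y, ok_y])
        assert list(s.snp_ids) == ["rs2"]

    def test_palindrome_eaf_discordance_flips(self):
        # C/G SNP with eaf 0.10 vs 0.88: the outcome is strand-flipped
        x = make_record(ea="C", oa="G", beta=0.1, eaf=0.10)
        y = make_record(ea="C", oa="G", beta=0.2, eaf=0.88)
        s = harmonize([x], [y])
        assert s.beta_y[0] == -0.2
        assert np.isclose(s.eaf_y[0], 0.12)

    def test_palindrome_eaf_concordance_keeps(self):
        x = make_record(ea="C", oa="G", beta=0.1, eaf=0.10)
        y = make_record(ea="C", oa="G", beta=0.2, eaf=0.15)
        s = harmonize([x], [y])
        assert s.beta_y[0] == 0.2

    def test_irreconcilable_alleles_dropped(self):
        x = make_record(snp_id="rs1", ea="A", oa="G")
        y = make_record(snp_id="rs1", ea="A", oa="C")
        ok_x = make_record(snp_id="rs2", pos=2000)
        ok_y = make_record(snp_id="rs2", pos=2000)
        s = harmonize([x, ok_x], [y, ok_y])
        assert list(s.snp_ids) == ["rs2"]

    def test_empty_intersection_fatal(self):
        with pytest.raises(ValueError, match="no SNPs shared"):
            harmonize([make_record(snp_id="rs1")], [make_record(snp_id="rs2")])


def _random_record_pairs(seed, k=12):
    """Exposure/outcome record pairs with random strand, swaps, palindromes."""
    rng = np.random.default_rng(seed)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    pairs = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G")]
    xs, ys = [], []
    for i in range(k):
        ea, oa = pairs[rng.integers(0, len(pairs))]
        eaf = float(rng.uniform(0.05, 0.95))
        x = make_record(snp_id=f"rs{i}", pos=1000 * i + 1, ea=ea, oa=oa, eaf=eaf,
                        beta=float(rng.normal(0, 0.2)), pval=float(rng.uniform(1e-12, 0.9)))
        yea, yoa, ybeta, yeaf = ea, oa, float(rng.normal(0, 0.1)), eaf
        if rng.random() < 0.5:  # swap alleles, flip effect
            yea, yoa, ybeta, yeaf = yoa, yea, -ybeta, 1 - yeaf
        if rng.random() < 0.5:  # strand flip
            yea, yoa = comp[yea], comp[yoa]
        ys.append(make_record(snp_id=f"rs{i}", pos=1000 * i + 1, ea=yea, oa=yoa,
                              eaf=yeaf, beta=ybeta, pval=float(rng.uniform(1e-6, 0.9))))
        xs.append(x)
    return xs, ys


class TestHarmonizeProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_idempotence(self, seed):
        xs, ys = _random_record_pairs(seed)
        s1 = harmonize(xs, ys)
        ex, out = s1.to_records()
        s2 = harmonize(ex, out, exposure=s1.exposure, outcome=s1.outcome)
        np.testing.assert_array_equal(s1.snp_ids, s2.snp_ids)
        np.testing.assert_allclose(s1.beta_y, s2.beta_y)
        np.testing.assert_allclose(s1.eaf_y, s2.eaf_y)

    @pytest.mark.parametrize("seed", range(5))
    def test_allele_swap_invariance(self, seed):
        """Swapping an outcome record's alleles while negating its beta (and
        complementing its EAF) must leave the harmonized set unchanged."""
        xs, ys = _random_record_pairs(seed)
        swapped = [make_record(snp_id=y.snp_id, pos=y.pos, ea=y.other_allele,
                               oa=y.effect_allele, eaf=1 - y.eaf, beta=-y.beta,
                               se=y.se, pval=y.pval, n=y.n) for y in ys]
        s1 = harmonize(xs, ys)
        s2 = harmonize(xs, swapped)
        np.testing.assert_array_equal(s1.snp_ids, s2.snp_ids)
        np.testing.assert_allclose(s1.beta_y, s2.beta_y, atol=1e-15)
        np.testing.assert_allclose(s1.eaf_y, s2.eaf_y, atol=1e-15)


@given(st.sampled_from(["A", "C", "G", "T"]), st.sampled_from(["A", "C", "G", "T"]))
@settings(derandomize=True, deadline=None)
def test_palindrome_detection(ea, oa):
    if ea == oa:
        return
    assert is_palindromic(ea, oa) == ({ea, oa} in ({"A", "T"}, {"C", "G"}))
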