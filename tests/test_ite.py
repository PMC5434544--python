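"""Codon usage parsing, family partitions, adaptedness weights and scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribosignal.ite import (
    ALL_CODONS,
    CodonUsageTable,
    FamilyMode,
    cai_score,
    codon_usage_from_cds,
    ite_score,
    partition_codon_families,
    read_codon_usage_table,
    relative_adaptedness,
)
from ribosignal.simulate import generate_biased_cds_set

# synthetic stand-in for a distributed codon usage file; the GCR counts are
# the E. coli HEG values discussed in the module docstring
SYNTHETIC_CUT = """# Synthetic codon usage fixture (.cut dialect)
# Codon AA Fraction /1000 Number
GCA A 0.230 21.1 1973
GCG A 0.310 28.4 2654
GCC A 0.160 14.6 1362
GCT A 0.300 27.5 2571
TTA L 0.050 3.1 291
TTG L 0.050 3.2 297
"""


class TestReadCodonUsageTable:
    def test_counts_from_last_column(self, tmp_path):
        p = tmp_path / "fix.cut"
        p.write_text(SYNTHETIC_CUT)
        with pytest.warns(UserWarning):
            table = read_codon_usage_table(p)
        assert table["GCA"] == 1973
        assert table["GCG"] == 2654
        assert table["AAA"] == 0  # absent -> zero-filled

    def test_comment_only_file_warns_all_zero(self, tmp_path):
        p = tmp_path / "empty.cut"
        p.write_text("# nothing\n# here\n")
        with pytest.warns(UserWarning):
            table = read_codon_usage_table(p)
        assert all(v == 0 for v in table.counts.values())

    def test_bad_codon_and_duplicates_raise(self, tmp_path):
        p = tmp_path / "bad.cut"
        p.write_text("GCAA A 0.2 21 100\n")
        with pytest.raises(ValueError):
            read_codon_usage_table(p)
        p.write_text("GCA A 0.2 21 100\nGCA A 0.2 21 100\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_codon_usage_table(p)


class TestCodonUsageFromCds:
    def test_direct_count(self):
        t = codon_usage_from_cds(["ATGGCAGCGTAA"])
        assert (t["ATG"], t["GCA"], t["GCG"], t["TAA"]) == (1, 1, 1, 1)

    def test_additivity(self):
        one = codon_usage_from_cds(["ATGGCAGCGTAA"])
        two = codon_usage_from_cds(["ATGGCAGCGTAA"] * 2)
        assert all(two[c] == 2 * one[c] for c in ALL_CODONS)

    def test_frame_truncation_warns(self):
        with pytest.warns(UserWarning):
            t = codon_usage_from_cds(["ATGGCAG"])
        assert t["ATG"] == 1 and t["GCA"] == 1
        assert sum(t.counts.values()) == 2  # trailing G dropped

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            codon_usage_from_cds([])


class TestPartitions:
    def test_box_split_serine_four_plus_two(self):
        part = partition_codon_families(11, FamilyMode.BOX_SPLIT)
        ser = [f for f in part.families if f & {"TCA", "AGC"}]
        sizes = sorted(len(f) for f in ser)
        assert sizes == [2, 4]
        assert frozenset({"AGC", "AGT"}) in part.families
        assert frozenset({"TCA", "TCC", "TCG", "TCT"}) in part.families

    def test_box_split_leucine_four_plus_two(self):
        part = partition_codon_families(11, "box")
        assert frozenset({"CTA", "CTC", "CTG", "CTT"}) in part.families
        assert frozenset({"TTA", "TTG"}) in part.families

    def test_aa_lump_leucine_six(self):
        part = partition_codon_families(11, FamilyMode.AA_LUMP)
        leu = next(f for f in part.families if "CTA" in f)
        assert leu == {"CTA", "CTC", "CTG", "CTT", "TTA", "TTG"}

    def test_ry_split_glycine(self):
        part = partition_codon_families(11, FamilyMode.RY_SPLIT)
        assert frozenset({"GGA", "GGG"}) in part.families
        assert frozenset({"GGC", "GGT"}) in part.families

    def test_r_only_alanine_gcr(self):
        part = partition_codon_families(11, FamilyMode.R_ONLY)
        assert frozenset({"GCA", "GCG"}) in part.families
        assert "GCC" not in part.countable and "GCT" not in part.countable

    def test_stops_excluded_and_single_codon_families_uncountable(self):
        part = partition_codon_families(11, "box")
        all_members = {c for f in part.families for c in f}
        assert not all_members & {"TAA", "TAG", "TGA"}
        assert "ATG" not in part.countable and "TGG" not in part.countable

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            partition_codon_families(11, "bogus")


class TestRelativeAdaptedness:
    def setup_method(self):
        self.part = partition_codon_families(11, "box")
        self.heg = CodonUsageTable({"GCA": 1973, "GCG": 2654})
        self.bg = CodonUsageTable({"GCA": 1000, "GCG": 3000})

    def test_background_correction_flips_preference(self):
        # r_GCA = 1973.5/1000.5, r_GCG = 2654.5/3000.5; selection favours GCA
        wt = relative_adaptedness(self.heg, self.bg, self.part, 0.5)
        assert wt.w["GCA"] == 1.0
        expected = (2654.5 / 3000.5) / (1973.5 / 1000.5)
        assert math.isclose(wt.w["GCG"], expected, rel_tol=1e-12)
        assert math.isclose(wt.w["GCG"], 0.44851, abs_tol=5e-6)

    def test_uniform_background_gives_cai_weights(self):
        wt = relative_adaptedness(self.heg, None, self.part, 0.5)
        assert wt.w["GCG"] == 1.0
        assert math.isclose(wt.w["GCA"], 1973.5 / 2654.5, rel_tol=1e-12)
        assert math.isclose(wt.w["GCA"], 0.74345, abs_tol=5e-6)

    def test_uniform_heg_and_background_all_ones(self):
        wt = relative_adaptedness(
            CodonUsageTable.uniform(), CodonUsageTable.uniform(), self.part
        )
        assert all(v == 1.0 for v in wt.w.values())

    def test_family_maximum_is_one(self):
        rng = np.random.default_rng(5)
        heg = CodonUsageTable({c: int(n) for c, n in zip(ALL_CODONS, rng.integers(0, 500, 64))})
        bg = CodonUsageTable({c: int(n) for c, n in zip(ALL_CODONS, rng.integers(1, 500, 64))})
        wt = relative_adaptedness(heg, bg, self.part)
        for fam in self.part.families:
            if len(fam) >= 2:
                assert math.isclose(max(wt.w[c] for c in fam), 1.0)
        assert all(0 < v <= 1 for v in wt.w.values())

    def test_scale_invariance_without_pseudocount(self):
        heg = CodonUsageTable({c: i + 1 for i, c in enumerate(ALL_CODONS)})
        bg = CodonUsageTable({c: 2 * i + 3 for i, c in enumerate(ALL_CODONS)})
        w1 = relative_adaptedness(heg, bg, self.part, pseudocount=0).w
        heg10 = CodonUsageTable({c: 10 * (i + 1) for i, c in enumerate(ALL_CODONS)})
        bg10 = CodonUsageTable({c: 10 * (2 * i + 3) for i, c in enumerate(ALL_CODONS)})
        w2 = relative_adaptedness(heg10, bg10, self.part, pseudocount=0).w
        assert all(math.isclose(w1[c], w2[c], rel_tol=1e-12) for c in w1)

    def test_scale_near_invariance_with_default_pseudocount(self):
        # additive pseudocount breaks exact scale invariance; at counts in
        # the thousands the effect is negligible
        w1 = relative_adaptedness(self.heg, self.bg, self.part, 0.5).w
        heg10 = CodonUsageTable({"GCA": 19730, "GCG": 26540})
        bg10 = CodonUsageTable({"GCA": 10000, "GCG": 30000})
        w2 = relative_adaptedness(heg10, bg10, self.part, 0.5).w
        assert math.isclose(w1["GCG"], w2["GCG"], rel_tol=1e-3)

    def test_zero_counts_without_pseudocount_raise(self):
        heg = CodonUsageTable({})  # all zero
        with pytest.raises(ValueError):
            relative_adaptedness(heg, None, self.part, pseudocount=0)


class TestScores:
    def setup_method(self):
        self.part = partition_codon_families(11, "box")
        self.heg = CodonUsageTable({"GCA": 1973, "GCG": 2654})
        self.bg = CodonUsageTable({"GCA": 1000, "GCG": 3000})
        self.wt = relative_adaptedness(self.heg, self.bg, self.part, 0.5)

    def test_all_maximal_codons_score_one(self):
        s = ite_score("ATGGCAGCAGCATAA", self.wt)
        assert s.score == 1.0 and s.n_codons == 3

    def test_two_codon_geometric_mean(self):
        s = ite_score("ATGGCAGCGTAA", self.wt)
        assert math.isclose(s.score, math.sqrt(1.0 * self.wt.w["GCG"]), rel_tol=1e-12)
        assert math.isclose(s.score, 0.6697, abs_tol=5e-5)
        assert s.n_codons == 2

    def test_start_stop_and_noncountable_excluded(self):
        # ATG start, ATG+TGG internal (single-codon families), stop: only the
        # two Ala codons count
        a = ite_score("ATGGCAATGTGGGCGTAA", self.wt)
        b = ite_score("ATGGCAGCGTAA", self.wt)
        assert a.n_codons == b.n_codons == 2
        assert a.score == b.score

    def test_single_countable_codon(self):
        heg = CodonUsageTable(dict({c: 100 for c in ALL_CODONS}, TTG=50))
        wt = relative_adaptedness(heg, None, self.part, 0)
        s = cai_score("ATGTTGTAA", heg, self.part, 0)
        assert math.isclose(s.score, 0.5) and s.n_codons == 1
        assert math.isclose(wt.w["TTG"], 0.5)

    def test_no_countable_codons_raises(self):
        with pytest.raises(ValueError):
            ite_score("ATGTGGTAA", self.wt)  # only Trp inside

    def test_uniform_background_equals_cai_exactly(self):
        seqs, truth, usage = generate_biased_cds_set(
            100, np.linspace(0, 1, 100), seed=21, n_codons=60
        )
        wt_uniform = relative_adaptedness(usage, None, self.part, 0.5)
        for seq in seqs:
            assert (
                ite_score(seq, wt_uniform).score
                == cai_score(seq, usage, self.part, 0.5).score
            )

    def test_r_only_score_blind_to_y_ending_codons(self):
        part = partition_codon_families(11, FamilyMode.R_ONLY)
        heg = CodonUsageTable({"GCA": 1973, "GCG": 2654, "GCC": 10, "GCT": 2000})
        wt = relative_adaptedness(heg, None, part, 0.5)
        base = "ATGGCAGCGGCCTAA"
        swapped = "ATGGCAGCGGCTTAA"  # GCC -> GCT (both Y-ending)
        assert ite_score(base, wt) == ite_score(swapped, wt)

    def test_bias_rank_recovery(self):
        """I_TE rank-correlates with the planted codon-bias strength."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(9)
        b = rng.uniform(0, 1, 80)
        seqs, truth, usage = generate_biased_cds_set(80, b, seed=9, n_codons=300)
        heg_seqs, _, _ = generate_biased_cds_set(30, 0.95, seed=10, n_codons=300)
        heg = codon_usage_from_cds(heg_seqs, label="heg")
        wt = relative_adaptedness(heg, usage, self.part, 0.5)
        scores = [ite_score(s, wt).score for s in seqs]
        rho = spearmanr(truth.b, scores).statistic
        assert rho > 0.95

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_scores_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        seqs, _, usage = generate_biased_cds_set(3, rng.uniform(0, 1, 3),
                                                 seed=seed % 2**31, n_codons=50)
        wt = relative_adaptedness(usage, None, self.part)
        for s in seqs:
            val = ite_score(s, wt).score
            assert 0 < val <= 1
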