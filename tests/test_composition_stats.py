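import itertools
import random

import numpy as np
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from oracles import kruskal_wallis_by_formula
from tandemscope.composition_stats import (NON_REPEAT, REPEAT, aa_enrichment,
                                           absent_codons, benjamini_yekutieli,
                                           codon_usage, kruskal_wallis,
                                           partition_substrings,
                                           positional_nt_frequency,
                                           snp_bias_summary,
                                           substitution_fraction,
                                           tr_composition_test)
from tandemscope.core_io import GenomeRecord, ProteinRecord, VariantRecord
from tandemscope.repeat_finder import AATR, TRRegion


def _region(start, unit, copies):
    return TRRegion(contig_id="g", start=start, end=start + copies * len(unit),
                    unit=unit, copies=copies)


class TestPartition:
    def test_120bp_region_gives_two_repeat_samples(self):
        rng = random.Random(0)
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        region = _region(100, "ACGTTA", 20)  # 120 bp
        samples = partition_substrings(GenomeRecord(id="g", sequence=seq), [region])
        reps = [s for s in samples if s.class_label == REPEAT]
        assert len(reps) == 2

    def test_49bp_segment_gives_nothing(self):
        seq = "A" * 49
        samples = partition_substrings(GenomeRecord(id="g", sequence=seq), [])
        assert samples == []

    def test_counts_match_arithmetic_oracle(self):
        rng = random.Random(3)
        seq = "".join(rng.choice("ACGT") for _ in range(5000))
        regions = [_region(500, "ACGTTAC", 10), _region(2000, "GGATC", 30)]
        samples = partition_substrings(GenomeRecord(id="g", sequence=seq), regions)
        # oracle: floor(len/50) per segment
        seg_lens_rep = [70, 150]
        seg_lens_non = [500, 2000 - 570, 5000 - 2150]
        assert sum(1 for s in samples if s.class_label == REPEAT) == \
            sum(l // 50 for l in seg_lens_rep)
        assert sum(1 for s in samples if s.class_label == NON_REPEAT) == \
            sum(l // 50 for l in seg_lens_non)
        assert sum(s.width for s in samples) <= 5000
        for s in samples:
            assert s.width == 50

    def test_vector_counts_are_real_base_counts(self):
        seq = "ACGT" * 25
        samples = partition_substrings(GenomeRecord(id="g", sequence=seq), [])
        for s in samples:
            assert s.vector == (13, 12, 13, 12) or sum(s.vector) == 50

    def test_width_error(self):
        with pytest.raises(ValueError):
            partition_substrings(GenomeRecord(id="g", sequence="ACGT" * 30), [], width=0)


class TestKruskalWallis:
    def test_reference_example(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.8571, abs=1e-4)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_identical_groups(self):
        h, p = kruskal_wallis([1, 2], [1, 2])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_all_values_identical(self):
        assert kruskal_wallis([5, 5, 5], [5, 5]) == (0.0, 1.0)

    def test_matches_scipy_on_100_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g1 = rng.integers(0, 20, size=rng.integers(2, 30)).astype(float)
            g2 = rng.integers(0, 20, size=rng.integers(2, 30)).astype(float)
            if np.all(g1 == g1[0]) and np.all(g2 == g2[0]) and g1[0] == g2[0]:
                continue
            h, p = kruskal_wallis(g1, g2)
            ref = scipy.stats.kruskal(g1, g2)
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_hand_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            g1 = rng.integers(0, 8, size=12).tolist()
            g2 = rng.integers(0, 8, size=9).tolist()
            h, _ = kruskal_wallis(g1, g2)
            assert h == pytest.approx(kruskal_wallis_by_formula(g1, g2), abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([], [1.0])


class TestBenjaminiYekutieli:
    def test_single_p_unchanged(self):
        assert benjamini_yekutieli([0.03]) == pytest.approx([0.03])

    def test_hand_computed_example(self):
        adj = benjamini_yekutieli([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.08333] * 4, abs=1e-5)

    def test_output_at_least_input(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 40)
        adj = benjamini_yekutieli(p)
        assert np.all(np.asarray(adj) >= p)
        assert np.all(np.asarray(adj) <= 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 25)
        adj = np.array(benjamini_yekutieli(p))
        perm = rng.permutation(25)
        adj_perm = np.array(benjamini_yekutieli(p[perm]))
        assert np.allclose(adj[perm], adj_perm)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 50))
            ours = benjamini_yekutieli(p)
            ref = multipletests(p, method="fdr_by")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            benjamini_yekutieli([0.5, 1.5])


class TestTrCompositionTest:
    def test_identical_substrings_give_p1(self):
        block = "ACGTTGCAAT" * 5  # one 50-mer
        seq = block * 8
        region = _region(0, block, 2)  # first two blocks are "repeat"
        tests = tr_composition_test(GenomeRecord(id="g", sequence=seq), [region])
        assert len(tests) == 4
        for t in tests:
            assert t.p_adj == pytest.approx(1.0)
            assert t.H == pytest.approx(0.0, abs=1e-12)

    def test_a_rich_repeat_detected(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ATGC"))
        bg = "".join(rng.choice(bases, p=[0.384, 0.288, 0.203, 0.125], size=4000))
        tr = "".join(rng.choice(bases, p=[0.484, 0.237, 0.171, 0.108], size=600))
        seq = bg[:2000] + tr + bg[2000:]
        region = _region(2000, tr[:100], 6)  # mark the A-rich block as repeat
        tests = tr_composition_test(GenomeRecord(id="g", sequence=seq), [region])
        a_test = next(t for t in tests if t.nucleotide == "A")
        assert a_test.p_adj < 0.05
        assert a_test.mean_repeat > a_test.mean_nonrepeat

    def test_class_too_small_skipped(self):
        seq = "ACGT" * 100
        region = _region(0, "ACGT" * 15, 2)  # 120bp repeat -> 2 samples; but non-repeat 280bp -> 5
        small = _region(0, "ACGT" * 25, 2)  # leaves < 2 repeat samples? 200bp -> 4; use tiny genome
        genome = GenomeRecord(id="g", sequence="ACGT" * 30)  # 120bp
        with pytest.warns(UserWarning):
            out = tr_composition_test(genome, [_region(0, "ACGT", 15)])
        assert out == []


class TestCodonUsage:
    def test_toy_orf(self):
        seq = "ATG" + "CCA" * 3 + "AAA" + "TAA"
        table = codon_usage([seq], [[(1, 4)]])
        assert table.loc["CCA", "freq_in"] == pytest.approx(1.0)
        assert table.loc["AAA", "ratio"] == 0.0
        absent = absent_codons(table)
        assert {"AAA", "ATG", "TAA"} <= set(absent)

    def test_whitelist_planting(self):
        whitelist = ["CCA", "ACA", "GAA", "AAA", "GAT", "ACT", "CCT", "GAG", "AAG", "ACC"]
        rng = random.Random(0)
        inside = [rng.choice(whitelist) for _ in range(300)]
        outside = [c for c in map("".join, itertools.product("ACGT", repeat=3))
                   for _ in range(2)]
        seq = "".join(inside) + "".join(outside)
        intervals = [[(0, 300)]]
        table = codon_usage([seq], intervals)
        absent = set(absent_codons(table))
        assert absent == set(map("".join, itertools.product("ACGT", repeat=3))) - set(inside)
        assert len(absent) >= 64 - len(whitelist)

    def test_frequencies_normalized(self):
        rng = random.Random(4)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        table = codon_usage([seq], [[(10, 40)]])
        assert table["freq_in"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["freq_out"].sum() == pytest.approx(1.0, abs=1e-12)
        # ratio reproduces the frequency quotient
        for codon, row in table.iterrows():
            if row["freq_out"] > 0:
                assert row["ratio"] == pytest.approx(
                    row["freq_in"] / row["freq_out"], abs=1e-12)

    def test_alignment_errors(self):
        with pytest.raises(ValueError):
            codon_usage(["ATGC"], [[]])
        with pytest.raises(ValueError):
            codon_usage(["ATGCCATAA"], [[(0, 5)]])

    def test_g_test_alternative(self):
        seq = "ATG" + "CCA" * 10 + "AAA" * 10 + "TAA"
        t1 = codon_usage([seq], [[(1, 11)]], test="fisher")
        t2 = codon_usage([seq], [[(1, 11)]], test="g")
        assert (t1["count_in_aaTR"] == t2["count_in_aaTR"]).all()


class TestPositionalFrequency:
    def test_all_cca(self):
        tables = positional_nt_frequency(["CCA"] * 5, ["ATG"] * 3)
        assert tables["aaTR"].loc["C", 1] == 1.0
        assert tables["aaTR"].loc["A", 3] == 1.0

    def test_columns_sum_to_one(self):
        rng = random.Random(1)
        codons = ["".join(rng.choice("ACGT") for _ in range(3)) for _ in range(50)]
        tables = positional_nt_frequency(codons, codons[:10])
        for table in tables.values():
            assert np.allclose(table.sum(axis=0), 1.0)

    def test_matches_tally_oracle(self):
        rng = random.Random(2)
        codons = ["".join(rng.choice("ACGT") for _ in range(3)) for _ in range(1000)]
        tables = positional_nt_frequency(codons, ["AAA"])
        for pos in (1, 2, 3):
            for base in "ACGT":
                expect = sum(1 for c in codons if c[pos - 1] == base) / len(codons)
                assert tables["aaTR"].loc[base, pos] == pytest.approx(expect)


class TestAaEnrichment:
    def test_proteome_fully_covered(self):
        proteome = [ProteinRecord(id="p", sequence="PPPP")]
        aatrs = [AATR(protein_id="p", start=0, end=4, unit="P", copies=4)]
        table = aa_enrichment(aatrs, proteome)
        assert table.loc["P", "ratio"] == pytest.approx(1.0)
        others = table.drop("P")
        assert others["ratio"].isna().all()

    def test_planted_2x_enrichment(self):
        # aaTR is 40% K; proteome overall exactly 20% K
        proteome = [ProteinRecord(id="p", sequence="KAAAA" * 40)]
        aatrs = [AATR(protein_id="p", start=0, end=20, unit="KAKAA", copies=4)]
        table = aa_enrichment(aatrs, proteome)
        assert table.loc["K", "ratio"] == pytest.approx(2.0)

    def test_freq_in_sums_to_one(self):
        proteome = [ProteinRecord(id="p", sequence="KEQPTA" * 30)]
        aatrs = [AATR(protein_id="p", start=0, end=18, unit="KEQPTA", copies=3)]
        table = aa_enrichment(aatrs, proteome)
        assert table["freq_in_aaTR"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_ordered_by_disorder_propensity(self):
        proteome = [ProteinRecord(id="p", sequence="KEQPTA" * 30)]
        aatrs = [AATR(protein_id="p", start=0, end=18, unit="KEQPTA", copies=3)]
        table = aa_enrichment(aatrs, proteome)
        props = table["disorder_propensity"].to_numpy()
        assert np.all(np.diff(props) <= 0)
        assert table.index[0] == "P"  # most disorder-promoting first


class TestSnpBias:
    def test_single_variant_in_region(self):
        region = _region(100, "GATTAG", 10)
        variant = VariantRecord("g", 110, "G", "A")
        mats = snp_bias_summary([variant], [region])
        assert mats["TR"].loc["G", "A"] == 1
        assert mats["TR"].to_numpy().sum() == 1
        assert mats["non_TR"].to_numpy().sum() == 0

    def test_empty_table(self):
        mats = snp_bias_summary([], [_region(0, "GATTAG", 10)])
        assert mats["TR"].to_numpy().sum() == 0
        assert mats["non_TR"].to_numpy().sum() == 0

    def test_14_of_18_fraction(self):
        region = _region(0, "G" * 10, 10)  # [0, 100)
        variants = [VariantRecord("g", i, "G", "A") for i in range(14)]
        variants += [VariantRecord("g", 20 + i, "C", "A") for i in range(4)]
        # C positions don't exist in a G homopolymer, but the summary is
        # position-based, not sequence-checked
        mats = snp_bias_summary(variants, [region])
        frac = substitution_fraction(mats["TR"], "G", "A")
        assert frac == pytest.approx(14 / 18)

    def test_out_of_bounds_skipped(self):
        with pytest.warns(UserWarning):
            mats = snp_bias_summary([VariantRecord("g", 500, "G", "A")],
                                    [_region(0, "GATTAG", 10)],
                                    contig_lengths={"g": 100})
        assert mats["non_TR"].to_numpy().sum() == 0
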