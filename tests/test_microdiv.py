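"""SNV calling, N/S classification, diversity statistics, Hudson FST, screens."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from plumeomics import microdiv
from plumeomics.microdiv import (FstResult, GeneModel, call_snvs,
                                 classify_snv_effect, gene_group_stats,
                                 genome_fst, hudson_fst, linkage_r2,
                                 profile_genome, screen_high_fst_genes,
                                 screen_sulfur_gene_fixation,
                                 site_diversity_stats)
from conftest import make_matrix


class TestCallSnvs:
    def test_low_coverage_not_callable(self):
        m = make_matrix([(1, "env1", (4, 0, 0, 0))])
        calls = call_snvs(m, min_cov=5)
        assert not calls["callable"].iloc[0]
        assert calls["n_snv"].iloc[0] == 0

    def test_threshold_variant(self):
        # A:95 G:5 -> variant G at freq 0.05, consensus A, con_freq 0.95
        m = make_matrix([(1, "env1", (95, 0, 5, 0))])
        calls = call_snvs(m)
        row = calls.iloc[0]
        assert row["consensus"] == "A"
        assert row["variants"] == "G"
        assert row["con_freq"] == pytest.approx(0.95)

    def test_monomorphic(self):
        m = make_matrix([(1, "env1", (100, 0, 0, 0))])
        row = call_snvs(m).iloc[0]
        assert row["n_snv"] == 0 and row["con_freq"] == 1.0

    def test_count_threshold(self):
        # freq 0.05 but count 1 of 20: fails min_count=2
        m = make_matrix([(1, "env1", (19, 1, 0, 0))])
        assert call_snvs(m)["n_snv"].iloc[0] == 0

    def test_consensus_tie_alphabetical(self):
        m = make_matrix([(1, "env1", (0, 10, 10, 0))])
        assert call_snvs(m)["consensus"].iloc[0] == "C"


class TestClassifySnvEffect:
    GENE_F = GeneModel("genome", "g", 1, 6, "+")

    def test_synonymous_third_position(self):
        # GAA -> GAG : Glu -> Glu
        assert classify_snv_effect(3, "G", self.GENE_F, "GAAGAA") == "S"

    def test_nonsynonymous_first_position(self):
        # GAA -> AAA : Glu -> Lys
        assert classify_snv_effect(1, "A", self.GENE_F, "GAAGAA") == "N"

    def test_minus_strand_synonymous(self):
        # genomic TTCTTC on minus strand codes GAA GAA; genomic change at
        # pos 4 T->C reverse-complements to GAA -> GAG (synonymous)
        gene = GeneModel("genome", "g", 1, 6, "-")
        assert classify_snv_effect(4, "C", gene, "TTCTTC") == "S"

    def test_outside_gene_noncoding(self):
        assert classify_snv_effect(9, "A", self.GENE_F, "GAAGAAGGG") == "noncoding"

    def test_stop_to_sense_counts_as_n(self):
        # TAA (stop) -> CAA (Gln)
        gene = GeneModel("genome", "g", 1, 3, "+")
        assert classify_snv_effect(1, "C", gene, "TAA") == "N"


class TestSiteDiversity:
    def test_monomorphic_site(self):
        m = make_matrix([(1, "env1", (50, 0, 0, 0))])
        row = site_diversity_stats(m, "env1").iloc[0]
        assert row["pi"] == 0.0 and row["con_freq"] == 1.0

    def test_balanced_biallelic(self):
        m = make_matrix([(1, "env1", (25, 25, 0, 0))])
        row = site_diversity_stats(m, "env1").iloc[0]
        assert row["pi"] == pytest.approx(0.5)
        assert row["con_freq"] == pytest.approx(0.5)

    def test_triallelic_hand_value(self):
        # 60/30/10 -> pi = 1 - (0.36 + 0.09 + 0.01) = 0.54
        m = make_matrix([(1, "env1", (60, 30, 10, 0))])
        assert site_diversity_stats(m, "env1")["pi"].iloc[0] == pytest.approx(0.54)


class TestLinkage:
    def _pairs(self, ab, a_b, aB, _ab):
        return pd.DataFrame([{"n_AB": ab, "n_Ab": a_b, "n_aB": aB, "n_ab": _ab}])

    def test_perfect_coupling(self):
        _, mean = linkage_r2(self._pairs(50, 0, 0, 50))
        assert mean == pytest.approx(1.0)

    def test_independence(self):
        _, mean = linkage_r2(self._pairs(25, 25, 25, 25))
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # AB=40 Ab=10 aB=10 ab=40 -> r^2 = 0.36
        _, mean = linkage_r2(self._pairs(40, 10, 10, 40))
        assert mean == pytest.approx(0.36)

    def test_monomorphic_pair_skipped(self):
        pairs = pd.DataFrame([
            {"n_AB": 50, "n_Ab": 0, "n_aB": 0, "n_ab": 0},   # monomorphic
            {"n_AB": 40, "n_Ab": 10, "n_aB": 10, "n_ab": 40},
        ])
        table, mean = linkage_r2(pairs)
        assert math.isnan(table["r2"].iloc[0])
        assert mean == pytest.approx(0.36)


class TestGenomeProfile:
    def test_full_breadth(self):
        rows = [(p, "env1", (50, 0, 0, 0)) for p in range(1, 11)]
        prof = profile_genome(make_matrix(rows), [], "env1", "A" * 10, 10)
        assert prof.breadth_mincov == 1.0
        assert not prof.excluded

    def test_snv_rate_formula(self):
        # 8 callable of 10 sites (breadth 0.8), 2 SNVs -> 2 / (0.8 * 10) = 0.25
        rows = [(p, "env1", (50, 0, 0, 0)) for p in range(1, 7)]
        rows += [(7, "env1", (40, 10, 0, 0)), (8, "env1", (30, 20, 0, 0))]
        rows += [(p, "env1", (2, 0, 0, 0)) for p in (9, 10)]
        prof = profile_genome(make_matrix(rows), [], "env1", "A" * 10, 10)
        assert prof.snv_count == 2
        assert prof.snv_rate == pytest.approx(0.25)

    def test_breadth_below_half_excluded(self):
        rows = [(p, "env1", (50, 0, 0, 0)) for p in range(1, 5)]  # 4 of 10
        prof = profile_genome(make_matrix(rows), [], "env1", "A" * 10, 10)
        assert prof.breadth_mincov == pytest.approx(0.4)
        assert prof.excluded

    def test_zero_length_genome_rejected(self):
        with pytest.raises(microdiv.DataError):
            profile_genome(make_matrix([(1, "env1", (9, 0, 0, 0))]),
                           [], "env1", "A", 0)


class TestHudsonFst:
    GENE = GeneModel("genome", "g", 1, 3, "+")

    def test_worked_example(self):
        # n1 = n2 = 10, p1 = 0.9, p2 = 0.1:
        # num = 0.64 - 0.01 - 0.01 = 0.62; den = 0.82; FST = 0.7561
        m = make_matrix([(1, "env1", (1, 9, 0, 0)), (1, "env2", (9, 1, 0, 0))])
        fst, n = hudson_fst(m, self.GENE)
        assert n == 1
        assert fst == pytest.approx(0.62 / 0.82, abs=1e-12)

    def test_identical_groups_near_zero(self):
        m = make_matrix([(1, "env1", (30, 30, 0, 0)), (1, "env2", (30, 30, 0, 0))])
        fst, _ = hudson_fst(m, self.GENE)
        assert fst <= 0.0  # unbiased estimator is negative at equal frequencies

    def test_fixed_difference_limit(self):
        m = make_matrix([(1, "env1", (1000, 0, 0, 0)), (1, "env2", (0, 1000, 0, 0))])
        fst, _ = hudson_fst(m, self.GENE)
        assert fst == pytest.approx(1.0, abs=1e-6)

    def test_monomorphic_gene_is_nan(self):
        m = make_matrix([(1, "env1", (50, 0, 0, 0)), (1, "env2", (50, 0, 0, 0))])
        fst, n = hudson_fst(m, self.GENE)
        assert math.isnan(fst) and n == 0

    def test_low_coverage_site_skipped(self):
        m = make_matrix([(1, "env1", (2, 2, 0, 0)), (1, "env2", (30, 30, 0, 0))])
        _, n = hudson_fst(m, self.GENE)  # env1 coverage 4 < min_cov 5
        assert n == 0

    def test_ratio_of_sums_not_mean_of_ratios(self):
        m = make_matrix([
            (1, "env1", (10, 40, 0, 0)), (1, "env2", (40, 10, 0, 0)),
            (2, "env1", (25, 25, 0, 0)), (2, "env2", (25, 25, 0, 0)),
        ])
        fst, n = hudson_fst(m, self.GENE)
        assert n == 2
        nums, dens = [], []
        for p1, p2, n1, n2 in ((0.8, 0.2, 50, 50), (0.5, 0.5, 50, 50)):
            nums.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                        - p2 * (1 - p2) / (n2 - 1))
            dens.append(p1 * (1 - p2) + p2 * (1 - p1))
        assert fst == pytest.approx(sum(nums) / sum(dens), abs=1e-12)


def _stats(rows):
    return pd.DataFrame(rows, columns=["gene_id", "coverage", "n_callable",
                                       "pi", "n_snv", "n_N", "n_S", "ns_ratio"])


def _fst_result(values, mean=None, std=None):
    per_gene = pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(values))],
                             "fst": values,
                             "n_sites": [5] * len(values)})
    defined = per_gene["fst"].dropna()
    return FstResult(per_gene=per_gene,
                     mean=float(defined.mean()) if mean is None else mean,
                     std=float(defined.std(ddof=1)) if std is None else std,
                     n_genes=len(values),
                     n_undefined=int(per_gene["fst"].isna().sum()))


class TestScreens:
    SWEPT = "g20"

    def _passing_inputs(self):
        # 20 background genes with near-zero FST keep the genome-wide
        # mean + 2.5 sd threshold well below the swept gene's FST of 0.8
        background = [0.02, 0.0] * 10
        fst = _fst_result(background + [0.8])
        stats1 = _stats([(f"g{i}", 50.0, 300, 0.01, 10, 2, 8, 0.25)
                         for i in range(20)]
                        + [(self.SWEPT, 50.0, 300, 0.001, 2, 2, 0, math.inf)])
        stats2 = _stats([(f"g{i}", 50.0, 300, 0.01, 10, 2, 8, 0.25)
                         for i in range(20)]
                        + [(self.SWEPT, 50.0, 300, 0.02, 10, 5, 5, 1.0)])
        return fst, stats1, stats2

    def test_constructed_sweep_flagged(self):
        fst, s1, s2 = self._passing_inputs()
        calls, skipped = screen_high_fst_genes(fst, s1, s2,
                                               genome_pi1=0.01, genome_ns1=0.3)
        assert not skipped
        assert list(calls["gene_id"]) == [self.SWEPT]

    def test_low_env2_coverage_blocks_call(self):
        # identical to the passing fixture except cov_env2 = 4x (< 5x rule)
        fst, s1, s2 = self._passing_inputs()
        s2.loc[s2["gene_id"] == self.SWEPT, "coverage"] = 4.0
        calls, _ = screen_high_fst_genes(fst, s1, s2,
                                         genome_pi1=0.01, genome_ns1=0.3)
        assert calls.empty

    def test_genome_skipped_when_half_fst_undefined(self):
        values = [0.1] * 40 + [math.nan] * 60
        fst = _fst_result(values)
        stats = _stats([(f"g{i}", 50.0, 300, 0.01, 10, 2, 8, 0.25)
                        for i in range(100)])
        calls, skipped = screen_high_fst_genes(fst, stats, stats.copy(),
                                               genome_pi1=0.02, genome_ns1=0.1)
        assert skipped and calls.empty

    def test_monotone_in_fst(self):
        # raising a gene's FST (mean/std held fixed) never un-flags it
        fst, s1, s2 = self._passing_inputs()
        base, _ = screen_high_fst_genes(fst, s1, s2, 0.01, 0.3)
        assert self.SWEPT in set(base["gene_id"])
        for higher in (0.9, 1.0, 5.0):
            raised = _fst_result([0.02, 0.0] * 10 + [higher],
                                 mean=fst.mean, std=fst.std)
            calls, _ = screen_high_fst_genes(raised, s1, s2, 0.01, 0.3)
            assert self.SWEPT in set(calls["gene_id"])

    def test_sulfur_requires_strictly_above_mean(self):
        genes = [GeneModel("genome", "g0", 1, 300, "+", ("sdo",))]
        fst = _fst_result([0.3, 0.3, 0.3])  # g0 FST equals the mean
        s1 = _stats([("g0", 50.0, 300, 0.001, 2, 2, 0, math.inf),
                     ("g1", 50.0, 300, 0.01, 10, 2, 8, 0.25),
                     ("g2", 50.0, 300, 0.01, 10, 2, 8, 0.25)])
        s2 = _stats([("g0", 50.0, 300, 0.02, 10, 5, 5, 1.0),
                     ("g1", 50.0, 300, 0.01, 10, 2, 8, 0.25),
                     ("g2", 50.0, 300, 0.01, 10, 2, 8, 0.25)])
        assert screen_sulfur_gene_fixation(fst, s1, s2, genes).empty

    def test_negative_genome_mean_blocks_sulfur_calls(self):
        genes = [GeneModel("genome", "g0", 1, 300, "+", ("soxB",))]
        fst = _fst_result([0.5, -0.6, -0.6])  # mean < 0
        s1 = _stats([("g0", 50.0, 300, 0.001, 2, 2, 0, math.inf),
                     ("g1", 50.0, 300, 0.01, 10, 2, 8, 0.25),
                     ("g2", 50.0, 300, 0.01, 10, 2, 8, 0.25)])
        s2 = _stats([("g0", 50.0, 300, 0.02, 10, 5, 5, 1.0),
                     ("g1", 50.0, 300, 0.01, 10, 2, 8, 0.25),
                     ("g2", 50.0, 300, 0.01, 10, 2, 8, 0.25)])
        assert screen_sulfur_gene_fixation(fst, s1, s2, genes).empty

    def test_sulfur_catches_subthreshold_gene_missed_by_part1(self):
        # sulfur gene passes the fixation screen but stays below mean + 2.5 sd
        genes = [GeneModel("genome", f"g{i}", 1 + 300 * i, 300 * (i + 1), "+",
                           ("aprA",) if i == 0 else ())
                 for i in range(6)]
        fst = _fst_result([0.25, 0.05, 0.02, 0.0, 0.9, 0.01])
        s1 = _stats([("g0", 50.0, 300, 0.001, 2, 2, 0, math.inf)]
                    + [(f"g{i}", 50.0, 300, 0.01, 10, 2, 8, 0.25)
                       for i in range(1, 6)])
        s2 = _stats([("g0", 50.0, 300, 0.02, 10, 5, 5, 1.0)]
                    + [(f"g{i}", 50.0, 300, 0.01, 10, 2, 8, 0.25)
                       for i in range(1, 6)])
        part1, _ = screen_high_fst_genes(fst, s1, s2, 0.01, 0.3)
        part2 = screen_sulfur_gene_fixation(fst, s1, s2, genes)
        assert "g0" not in set(part1["gene_id"])
        assert list(part2["gene_id"]) == ["g0"]


class TestNSOracleSpotChecks:
    """Exhaustive oracle runs in the acceptance suite; spot-check both strands."""

    @pytest.mark.parametrize("codon", ["ATG", "TTA", "CGA", "GGG"])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_against_biopython_translation(self, codon, strand):
        ref = codon if strand == "+" else str(Seq(codon).reverse_complement())
        gene = GeneModel("genome", "g", 1, 3, strand)
        for within in range(3):
            pos = within + 1 if strand == "+" else 3 - within
            for alt in "ACGT":
                coding_alt = alt if strand == "+" else \
                    str(Seq(alt).reverse_complement())
                if codon[within] == coding_alt:
                    continue
                mutated = codon[:within] + coding_alt + codon[within + 1:]
                expected = "S" if str(Seq(codon).translate()) == \
                    str(Seq(mutated).translate()) else "N"
                assert classify_snv_effect(pos, alt, gene, ref) == expected


def test_gene_models_roundtrip(tmp_path, pileups):
    path = tmp_path / "genes.tsv"
    microdiv.write_gene_models(pileups.genes, path)
    back = microdiv.read_gene_models(path)
    assert back == pileups.genes


def test_gff3_import(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "genome\ttest\tgene\t10\t309\t.\t+\t.\tID=geneA\n"
        "genome\ttest\tgene\t400\t699\t.\t-\t.\tID=geneB\n")
    genes = microdiv.read_gene_models_gff3(gff)
    assert [(g.gene_id, g.start, g.end, g.strand) for g in genes] == \
        [("geneA", 10, 309, "+"), ("geneB", 400, 699, "-")]
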