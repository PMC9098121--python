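"""Motif counting, U1/PAS ratios, feature comparisons, ORF readthrough
translation and tryptic digestion."""

import re

import numpy as np
import pytest

from conftest import make_toy_gene
from ttquant.seqfeatures import (
    compare_down_vs_rest,
    count_motif_occurrences,
    gc_fraction,
    gene_feature_table,
    logfc_vs_width_trend,
    orf_readthrough_translate,
    peptide_library,
    tryptic_digest,
    u1_pas_ratio,
)
from ttquant.synthetic_data import SyntheticConfig, make_gene_set, reverse_complement

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _oracle_translate(seq):
    """Brute-force codon-by-codon translation to the first stop."""
    aa = []
    for i in range(0, len(seq) - 2, 3):
        c = CODON_TABLE[seq[i:i + 3]]
        if c == "*":
            return "".join(aa), True
        aa.append(c)
    return "".join(aa), False


class TestMotifCounting:
    def test_overlapping_occurrences_counted(self):
        counts = count_motif_occurrences("GGTGAGT")
        assert counts["GGTGAG"] == 1 and counts["GTGAGT"] == 1

    def test_overlapping_pas_brute_force(self):
        seq = "AATAAATAAA"
        counts = count_motif_occurrences(seq)
        brute = sum(seq[i:i + 6] == "AATAAA" for i in range(len(seq) - 5))
        assert counts["AATAAA"] == brute == 2

    def test_empty_sequence_all_zero(self):
        assert all(v == 0 for v in count_motif_occurrences("").values())

    def test_non_iupac_character_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            count_motif_occurrences("ACGXACGT")

    def test_matches_sliding_window_oracle_on_random_sequences(self):
        rng = np.random.default_rng(50)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 500))
            counts = count_motif_occurrences(seq)
            for motif, n in counts.items():
                brute = sum(seq[i:i + len(motif)] == motif
                            for i in range(len(seq) - len(motif) + 1))
                assert n == brute

    def test_n_never_matches(self):
        assert count_motif_occurrences("AATAANAATAAA")["AATAAA"] == 1


class TestU1PasRatio:
    def test_balanced_counts_give_one(self):
        seq = "GGTGAG" + "C" * 10 + "GGTAAG" + "C" * 10 + "GTGAGT" + \
              ("C" * 10 + "AATAAA") * 3
        out = u1_pas_ratio(seq)
        assert out["ratio"] == pytest.approx(1.0)

    def test_zero_pas_excluded_with_flag(self):
        out = u1_pas_ratio("GGTGAG" + "C" * 20)
        assert out["ratio"] is None and out["excluded"]

    def test_planted_design_value_recovered(self, gene_set, small_config):
        genes, _, truth = gene_set
        expect = sum(small_config.planted_u1_per_gene) / small_config.planted_pas_per_gene
        for g in genes[:4]:
            out = u1_pas_ratio(truth["genes"][g.gene_id]["genic_sequence"])
            assert out["ratio"] == pytest.approx(expect)


class TestFeatureTable:
    def test_gc_fraction_all_gc(self):
        assert gc_fraction("GGCC") == 1.0

    def test_wilcoxon_flags_designed_width_difference(self, gene_set):
        genes, chrom_seqs, _ = gene_set
        # mark the widest half as down-regulated by design
        widths = sorted(g.width for g in genes)
        cut = widths[len(widths) // 2]
        status = {g.gene_id: ("down" if g.width >= cut else "unchanged") for g in genes}
        table = gene_feature_table(genes, chrom_seqs, status)
        cmp = compare_down_vs_rest(table, features=("width",))
        assert cmp.iloc[0]["pvalue"] < 0.01

    def test_null_wilcoxon_p_uniform(self):
        """Rank-sum p-values are uniform under the null (calibration at
        n=50/50 over repeated simulations)."""
        from scipy import stats

        rng = np.random.default_rng(51)
        ps = []
        for _ in range(500):
            a, b = rng.normal(size=50), rng.normal(size=50)
            ps.append(stats.ranksums(a, b).pvalue)
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_width_trend_binned_medians(self):
        import pandas as pd

        rng = np.random.default_rng(52)
        widths = pd.Series(rng.uniform(5e3, 2e5, 300))
        logfc = pd.Series(-widths / 1e5 + rng.normal(0, 0.05, 300))
        trend = logfc_vs_width_trend(widths, logfc, n_bins=5)
        assert np.all(np.diff(trend["median_logfc"]) < 0)


class TestOrfTranslation:
    def _gene(self, sense_seq, strand="+", exon_bounds=None, start=2000):
        width = len(sense_seq)
        gene = make_toy_gene("G", start=start, width=width, strand=strand,
                             exon_bounds=exon_bounds or [(0, 12), (30, width)])
        genomic = sense_seq if strand == "+" else reverse_complement(sense_seq)
        chrom_seqs = {"chrT": "T" * start + genomic + "T" * 1000}
        return gene, chrom_seqs

    def test_stop_in_intron_first_codon(self):
        # exon1 = ATGGCT + filler, ATG at 0; intron starts at 12 with TAA in frame
        seq = "ATGGCTGCTGCT" + "TAA" + "G" * 50
        gene, chrom_seqs = self._gene(seq, exon_bounds=[(0, 12), (30, len(seq))])
        orf = orf_readthrough_translate(gene, chrom_seqs, canonical_atg=0)
        assert orf.peptide == "MAAA" and orf.stop_found

    def test_frame_continues_across_exon_intron_boundary(self):
        """Translation of the readthrough product equals a brute-force
        translation of the concatenated genomic sequence."""
        rng = np.random.default_rng(53)
        for trial in range(5):
            body = "".join(rng.choice(list("ACGT"), 300))
            seq = "ATG" + body
            gene, chrom_seqs = self._gene(seq, exon_bounds=[(0, 10), (40, len(seq))])
            orf = orf_readthrough_translate(gene, chrom_seqs, canonical_atg=0)
            coding = seq[: len(seq) - len(seq) % 3]
            want, stop = _oracle_translate(coding)
            assert orf.peptide == want
            assert orf.stop_found == stop

    def test_minus_strand_twin_gives_identical_peptide(self):
        seq = "ATGGCTAAAGGGTTTCCC" + "TGA" + "C" * 30
        plus_gene, plus_seqs = self._gene(seq, strand="+")
        minus_gene, minus_seqs = self._gene(seq, strand="-")
        a = orf_readthrough_translate(plus_gene, plus_seqs, canonical_atg=0)
        b = orf_readthrough_translate(minus_gene, minus_seqs, canonical_atg=0)
        assert a.peptide == b.peptide and a.stop_found == b.stop_found

    def test_atg_not_at_position_errors(self):
        seq = "CCCGCTGCTGCT" + "G" * 60
        gene, chrom_seqs = self._gene(seq)
        with pytest.raises(ValueError, match="no ATG"):
            orf_readthrough_translate(gene, chrom_seqs, canonical_atg=0)

    def test_atg_outside_exon1_errors(self):
        seq = "ATGGCTGCTGCT" + "G" * 60
        gene, chrom_seqs = self._gene(seq)
        with pytest.raises(ValueError, match="not within exon 1"):
            orf_readthrough_translate(gene, chrom_seqs, canonical_atg=40)

    def test_no_stop_truncates_with_flag(self):
        seq = "ATG" + "GCA" * 40  # alanine run, no stop anywhere
        gene, chrom_seqs = self._gene(seq, exon_bounds=[(0, 12), (30, len(seq))])
        orf = orf_readthrough_translate(gene, chrom_seqs, canonical_atg=0)
        assert not orf.stop_found
        assert orf.peptide == "M" + "A" * 40

    def test_stop_position_length_relation(self):
        rng = np.random.default_rng(54)
        for _ in range(10):
            seq = "ATG" + "".join(rng.choice(list("ACGT"), 120))
            gene, chrom_seqs = self._gene(seq, exon_bounds=[(0, 12), (30, len(seq))])
            orf = orf_readthrough_translate(gene, chrom_seqs, canonical_atg=0)
            if orf.stop_found:
                stop_offset = orf.tx_span[1] - orf.tx_span[0] - 3
                assert len(orf.peptide) == stop_offset // 3


class TestTrypticDigest:
    def test_basic_cleavage(self):
        assert tryptic_digest("MAAAAAAKGGGGGGR") == ["MAAAAAAK", "GGGGGGR"]

    def test_kp_not_cleaved(self):
        assert tryptic_digest("MAKPLLLLLLR") == ["MAKPLLLLLLR"]

    def test_min_length_filter(self):
        assert tryptic_digest("MAKGGGGGGR") == ["GGGGGGR"]  # "MAK" dropped

    def test_fragments_concatenate_to_peptide(self):
        rng = np.random.default_rng(55)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            pep = "".join(rng.choice(aas, 80))
            frags = tryptic_digest(pep, min_length=0)
            assert "".join(frags) == pep

    def test_matches_regex_oracle(self):
        rng = np.random.default_rng(56)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            pep = "".join(rng.choice(aas, 60))
            want = [f for f in re.split(r"(?<=[KR])(?!P)", pep) if len(f) >= 7]
            assert tryptic_digest(pep, min_length=7) == want

    def test_missed_cleavages_add_merged_fragments(self):
        frags = tryptic_digest("MAAAAAAKGGGGGGR", missed_cleavages=1)
        assert "MAAAAAAKGGGGGGR" in frags and "MAAAAAAK" in frags


def test_peptide_library_covers_gene_set(gene_set):
    genes, chrom_seqs, truth = gene_set
    atg = {g: truth["genes"][g]["atg_offset"] for g in truth["genes"]}
    lib = peptide_library(genes, chrom_seqs, atg)
    assert set(lib.columns) == {"gene_id", "fragment_index", "peptide", "stop_found"}
    assert (lib["peptide"].str.len() >= 7).all()
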