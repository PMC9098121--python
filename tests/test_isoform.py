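"""First-exon enrichment statistic, its test, and 3'-half DE calling."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_toy_gene
from ttquant.genome_model import GenomicInterval
from ttquant.isoform import (
    assign_reads_to_exons,
    de_counts_and_call,
    first_exon_enrichment,
    recode_first_vs_remaining,
    summarize_first_exon_shift,
)
from ttquant.synthetic_data import SyntheticConfig, make_count_gene_set, simulate_exon_count_matrix


def _brute_force_exon_counts(reads, exons):
    """Oracle: count a read for an exon iff it overlaps that exon and no other."""
    counts = np.zeros(len(exons), dtype=int)
    for r in reads:
        hits = [i for i, e in enumerate(exons) if r.start < e.end and e.start < r.end]
        if len(hits) == 1:
            counts[hits[0]] += 1
    return counts


class TestReadAssignment:
    def _tx_gene(self):
        return make_toy_gene("G", start=0, width=10_000,
                             exon_bounds=[(0, 1000), (4000, 5000), (9000, 10_000)])

    def test_read_in_single_exon_counts(self):
        gene = self._tx_gene()
        reads = [GenomicInterval("chrT", 4100, 4200, "+")]
        counts = assign_reads_to_exons(reads, gene.transcripts[0])
        assert counts.tolist() == [0, 1, 0]

    def test_junction_read_discarded(self):
        gene = self._tx_gene()
        reads = [GenomicInterval("chrT", 900, 4100, "+")]  # spans exons 1 and 2
        assert assign_reads_to_exons(reads, gene.transcripts[0]).sum() == 0

    def test_intronic_and_wrong_strand_reads_discarded(self):
        gene = self._tx_gene()
        reads = [GenomicInterval("chrT", 2000, 2100, "+"),
                 GenomicInterval("chrT", 4100, 4200, "-")]
        assert assign_reads_to_exons(reads, gene.transcripts[0]).sum() == 0

    def test_randomised_reads_match_brute_force_oracle(self):
        rng = np.random.default_rng(44)
        gene = self._tx_gene()
        tx = gene.transcripts[0]
        for _ in range(10):
            starts = rng.integers(0, 10_000, 200)
            lens = rng.integers(30, 1500, 200)
            reads = [GenomicInterval("chrT", int(s), int(s + l), "+")
                     for s, l in zip(starts, lens)]
            got = assign_reads_to_exons(reads, tx)
            want = _brute_force_exon_counts(reads, tx.exons_in_transcription_order())
            assert np.array_equal(got, want)

    def test_minus_strand_first_exon_is_rightmost(self):
        gene = make_toy_gene("G", start=0, width=10_000, strand="-",
                             exon_bounds=[(0, 1000), (9000, 10_000)])
        # first exon in tx order sits at genomic [9000, 10000)
        reads = [GenomicInterval("chrT", 9500, 9600, "-")]
        counts = assign_reads_to_exons(reads, gene.transcripts[0])
        assert counts.tolist() == [1, 0]


class TestRecoding:
    def _matrix(self):
        idx = pd.MultiIndex.from_tuples(
            [("g1", 1), ("g1", 2), ("g1", 3), ("g2", 1)],
            names=["gene_id", "exon_index"],
        )
        return pd.DataFrame({"s1": [5, 3, 2, 9], "s2": [1, 1, 1, 4]}, index=idx)

    def test_first_vs_remaining_sums(self):
        out = recode_first_vs_remaining(self._matrix())
        assert out.loc["g1", ("s1", "first")] == 5
        assert out.loc["g1", ("s1", "remaining")] == 5

    def test_single_exon_gene_dropped(self):
        out = recode_first_vs_remaining(self._matrix())
        assert list(out.index) == ["g1"]

    def test_count_conservation(self):
        m = self._matrix()
        out = recode_first_vs_remaining(m)
        for s in ["s1", "s2"]:
            assert out.loc["g1", (s, "first")] + out.loc["g1", (s, "remaining")] == \
                m.loc["g1"][s].sum()


def _recoded_frame(first, remaining, samples):
    cols = pd.MultiIndex.from_product([samples, ["first", "remaining"]],
                                      names=["sample", "part"])
    data = np.empty((len(first), 2 * len(samples)))
    for j, s in enumerate(samples):
        data[:, 2 * j] = first[:, j]
        data[:, 2 * j + 1] = remaining[:, j]
    return pd.DataFrame(data, columns=cols,
                        index=[f"g{i}" for i in range(len(first))]).rename_axis("gene_id")


class TestFirstExonEnrichment:
    samples = ["c0", "c1", "c2", "h0", "h1", "h2"]
    condition = {s: ("hs" if s.startswith("h") else "ctrl") for s in samples}
    sf = {s: 1.0 for s in samples}

    def test_worked_logfc_example(self):
        """HS (first 8, remaining 2) vs ctrl (first 2, remaining 2):
        log2((8/2)/(2/2)) = 2 with the pseudocount off."""
        first = np.array([[2, 2, 2, 8, 8, 8]], float)
        rem = np.array([[2, 2, 2, 2, 2, 2]], float)
        res = first_exon_enrichment(_recoded_frame(first, rem, self.samples),
                                    self.sf, self.condition, pseudocount=0.0)
        assert res["logfc"].iloc[0] == pytest.approx(2.0)

    def test_null_gives_zero_logfc(self):
        first = np.full((3, 6), 5.0)
        rem = np.full((3, 6), 7.0)
        res = first_exon_enrichment(_recoded_frame(first, rem, self.samples),
                                    self.sf, self.condition)
        assert np.allclose(res["logfc"], 0.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        first = rng.poisson(20, (10, 6)).astype(float) + 1
        rem = rng.poisson(30, (10, 6)).astype(float) + 1
        frame = _recoded_frame(first, rem, self.samples)
        res = first_exon_enrichment(frame, self.sf, self.condition)
        swapped = {s: ("ctrl" if c == "hs" else "hs") for s, c in self.condition.items()}
        res2 = first_exon_enrichment(frame, self.sf, swapped)
        assert np.allclose(res["logfc"], -res2["logfc"])

    def test_size_factor_invariance(self):
        """Multiplying one sample's counts by its own size factor leaves the
        normalised statistic unchanged."""
        rng = np.random.default_rng(4)
        first = rng.poisson(20, (8, 6)).astype(float) + 1
        rem = rng.poisson(30, (8, 6)).astype(float) + 1
        res1 = first_exon_enrichment(_recoded_frame(first, rem, self.samples),
                                     self.sf, self.condition, pseudocount=0.0)
        f2, r2 = first.copy(), rem.copy()
        f2[:, 2] *= 3.0
        r2[:, 2] *= 3.0
        sf2 = dict(self.sf, c2=3.0)
        res2 = first_exon_enrichment(_recoded_frame(f2, r2, self.samples),
                                     sf2, self.condition, pseudocount=0.0)
        assert np.allclose(res1["logfc"], res2["logfc"])

    def test_expression_filter_excludes_zero_cells(self):
        first = np.array([[0, 2, 2, 8, 8, 8], [2, 2, 2, 8, 8, 8]], float)
        rem = np.full((2, 6), 2.0)
        res = first_exon_enrichment(_recoded_frame(first, rem, self.samples),
                                    self.sf, self.condition)
        assert list(res.index) == ["g1"]

    def test_theta_recovery_and_shift_fraction(self):
        """theta=4 with 3 vs 3 replicates over 200 genes: mean logFC near 2
        and >90% of genes shift positive."""
        cfg = SyntheticConfig(seed=41, first_exon_effect=4.0)
        genes = make_count_gene_set(cfg, 200)
        counts, truth = simulate_exon_count_matrix(genes, cfg, n_reps=3)
        recoded = recode_first_vs_remaining(counts)
        res = first_exon_enrichment(
            recoded, {s: 1.0 for s in counts.columns}, truth["condition"],
            rng=np.random.default_rng(1),
        )
        assert 1.8 <= res["logfc"].mean() <= 2.2
        s = summarize_first_exon_shift(res)
        assert s["fraction_positive"] > 0.9

    def test_null_shift_fraction_near_half(self):
        cfg = SyntheticConfig(seed=42, first_exon_effect=1.0)
        genes = make_count_gene_set(cfg, 200)
        counts, truth = simulate_exon_count_matrix(genes, cfg, n_reps=3)
        res = first_exon_enrichment(
            recode_first_vs_remaining(counts), {s: 1.0 for s in counts.columns},
            truth["condition"], rng=np.random.default_rng(1),
        )
        assert summarize_first_exon_shift(res)["fraction_positive"] == pytest.approx(0.5, abs=0.08)


def test_summarize_fraction_positive():
    res = pd.DataFrame(dict(logfc=[1.0, -1.0, 2.0], padj=[1, 1, 1]))
    assert summarize_first_exon_shift(res)["fraction_positive"] == pytest.approx(2 / 3)


class TestDECall:
    def _counts(self, ratio=0.25, n=6, base=400.0):
        rng = np.random.default_rng(7)
        samples = [f"c{i}" for i in range(n)] + [f"h{i}" for i in range(n)]
        ctrl = rng.poisson(base, (50, n))
        hs = rng.poisson(base * ratio, (50, n))
        df = pd.DataFrame(np.hstack([ctrl, hs]), columns=samples,
                          index=[f"g{i}" for i in range(50)])
        cond = {s: ("hs" if s.startswith("h") else "ctrl") for s in samples}
        return df, cond

    def test_four_fold_drop_called_down(self):
        counts, cond = self._counts(ratio=0.25)
        res = de_counts_and_call(counts, cond)
        assert (res["status"] == "down").mean() > 0.9

    def test_base_mean_filter_blocks_low_expression(self):
        counts, cond = self._counts(ratio=0.25, base=8.0)
        res = de_counts_and_call(counts, cond, base_mean_min=10.0)
        assert (res["status"] == "unchanged").all()

    def test_null_mostly_unchanged(self):
        counts, cond = self._counts(ratio=1.0)
        res = de_counts_and_call(counts, cond)
        assert (res["status"] == "unchanged").mean() > 0.95
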