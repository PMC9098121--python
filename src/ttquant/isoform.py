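"""First-exon enrichment (short-isoform shift) and 3'-half differential
expression calling.

The isoform-shift statistic compares the share of reads on the first exon
vs the remaining exons between conditions as a log2 ratio-of-ratios:
log2[(HS first / HS remaining) / (ctrl first / ctrl remaining)].  A
positive value means a shift toward shorter isoforms under heat shock.
Inference defaults to a label-permutation test on the per-replicate
first/remaining log-ratio, with a Welch t alternative; p-values are
Benjamini-Hochberg adjusted across genes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import CoverageTrack, GeneModel, GenomicInterval, TranscriptModel
from .pausing import _tx_interval, _interval_count


def assign_reads_to_exons(reads: list[GenomicInterval], transcript: TranscriptModel) -> np.ndarray:
    """Count reads per exon under the inter-feature rule: a read counts for
    an exon only if it overlaps exactly one exon of the transcript; reads
    overlapping two or more exons (junction reads) or none are discarded.

    Returns counts indexed by exon in transcription order (position 0 =
    first exon).
    """
    exons = transcript.exons_in_transcription_order()
    counts = np.zeros(len(exons), dtype=int)
    for read in reads:
        if read.chrom != transcript.interval.chrom or read.strand != transcript.strand:
            continue
        hits = [
            i for i, ex in enumerate(exons)
            if read.start < ex.end and ex.start < read.end
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
    return counts


def recode_first_vs_remaining(counts: pd.DataFrame) -> pd.DataFrame:
    """Recode a per-exon count matrix into two paired columns per sample:
    first-exon counts and the sum over exons 2..n.

    ``counts`` is indexed by (gene_id, exon_index) with exon_index 1..n in
    transcription order.  Single-exon genes are dropped.  Output is indexed
    by gene_id with columns MultiIndex (sample, {'first', 'remaining'}).
    """
    n_exons = counts.groupby(level="gene_id").size()
    multi = n_exons[n_exons >= 2].index
    sub = counts.loc[counts.index.get_level_values("gene_id").isin(multi)]
    first = sub.xs(1, level="exon_index")
    rest = sub[sub.index.get_level_values("exon_index") >= 2].groupby(level="gene_id").sum()
    out = pd.concat({"first": first, "remaining": rest.loc[first.index]}, axis=1)
    out.columns = out.columns.swaplevel(0, 1)
    out.columns.names = ["sample", "part"]
    return out.sort_index(axis=1)


def _permutation_contrasts(labels: np.ndarray, max_exact: int = 200_000,
                           n_mc: int = 2000, rng=None):
    """All (or sampled) reassignments of condition labels as contrast
    matrices W so that T = r @ W.T gives mean(hs) - mean(ctrl) per
    reassignment.  Row 0 is the observed labelling."""
    n = len(labels)
    hs_idx = np.flatnonzero(labels)
    n_hs = len(hs_idx)
    from math import comb

    rows = []

    def contrast(idx_set):
        w = np.full(n, -1.0 / (n - n_hs))
        w[list(idx_set)] = 1.0 / n_hs
        return w

    if comb(n, n_hs) <= max_exact:
        combos = [set(c) for c in combinations(range(n), n_hs)]
        combos.sort(key=lambda c: c != set(hs_idx))  # observed first
        rows = [contrast(c) for c in combos]
    else:
        rng = np.random.default_rng(rng)
        rows = [contrast(set(hs_idx))]
        for _ in range(n_mc):
            rows.append(contrast(rng.choice(n, size=n_hs, replace=False)))
    return np.asarray(rows)


def first_exon_enrichment(
    recoded: pd.DataFrame,
    size_factors: dict[str, float],
    condition: dict[str, str],
    pseudocount: float = 0.5,
    test: str = "permutation",
    rng=None,
) -> pd.DataFrame:
    """Per-gene first-exon enrichment log2 ratio-of-ratios with a test.

    The same per-sample size factor is applied to both of a sample's paired
    columns.  Genes failing the expression filter — a count of at least 1
    in the first exon and in the remaining exons across every sample — are
    excluded.  ``test`` is 'permutation' (default; exact enumeration of
    label reassignments when feasible) or 'welch'.
    """
    samples = recoded.columns.get_level_values("sample").unique().tolist()
    sf = np.array([size_factors[s] for s in samples], float)
    is_hs = np.array([condition[s] == "hs" for s in samples])
    F = recoded.xs("first", level="part", axis=1)[samples].to_numpy(float)
    R = recoded.xs("remaining", level="part", axis=1)[samples].to_numpy(float)
    keep = (F >= 1).all(axis=1) & (R >= 1).all(axis=1)
    if not keep.any():
        raise ValueError("expression filter removed every gene")
    genes = recoded.index[keep]
    Fn, Rn = F[keep] / sf, R[keep] / sf

    mHSf = Fn[:, is_hs].mean(axis=1) + pseudocount
    mHSr = Rn[:, is_hs].mean(axis=1) + pseudocount
    mCf = Fn[:, ~is_hs].mean(axis=1) + pseudocount
    mCr = Rn[:, ~is_hs].mean(axis=1) + pseudocount
    logfc = np.log2((mHSf / mHSr) / (mCf / mCr))

    # per-replicate first/remaining log-ratio carries the inference
    r = np.log2((Fn + pseudocount) / (Rn + pseudocount))
    if test == "permutation":
        W = _permutation_contrasts(is_hs.astype(int), rng=rng)
        T = r @ W.T                      # genes x reassignments; col 0 observed
        obs = T[:, 0]
        p = (np.abs(T) >= np.abs(obs)[:, None] - 1e-12).mean(axis=1)
    elif test == "welch":
        obs, p = stats.ttest_ind(r[:, is_hs], r[:, ~is_hs], axis=1, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        dict(gene_id=genes, logfc=logfc, stat=obs, pvalue=p, padj=padj)
    ).set_index("gene_id")


def summarize_first_exon_shift(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Fraction of genes with a positive first-exon logFC (shift toward
    shorter isoforms), over all tested genes and, separately flagged, over
    the significant subset only."""
    if len(results) == 0:
        raise ValueError("no results to summarise")
    pos = results["logfc"] > 0
    sig = results["padj"] <= alpha
    return dict(
        n=len(results),
        fraction_positive=float(pos.mean()),
        n_significant=int(sig.sum()),
        fraction_positive_significant=(float(pos[sig].mean()) if sig.any() else np.nan),
        median_logfc=float(results["logfc"].median()),
    )


# ---------------------------------------------------------------------------
# 3'-half differential expression
# ---------------------------------------------------------------------------

def gene_3prime_half_counts(track: CoverageTrack, genes: list[GeneModel]) -> pd.Series:
    """Summed sense signal over the 3' 50% of each gene interval
    (transcription direction)."""
    out = {}
    for gene in genes:
        iv = _tx_interval(gene, gene.width / 2, gene.width)
        out[gene.gene_id] = _interval_count(track, iv, gene.strand)
    return pd.Series(out)


def de_counts_and_call(
    counts: pd.DataFrame,
    condition: dict[str, str],
    size_factors: dict[str, float] | None = None,
    fc_threshold: float = 2.0,
    fdr: float = 0.01,
    base_mean_min: float = 10.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential-expression call on 3'-half gene counts.

    logFC is computed on size-factor-normalised means (+pseudocount); the
    p-value is a normal-approximation Wald test on per-replicate log2
    normalised counts, BH-adjusted.  Status is 'up'/'down' only when
    |FC| >= fc_threshold, adjusted p <= fdr and base mean >= base_mean_min.
    """
    samples = list(counts.columns)
    sf = np.array([1.0 if size_factors is None else size_factors[s] for s in samples])
    is_hs = np.array([condition[s] == "hs" for s in samples])
    if is_hs.sum() < 2 or (~is_hs).sum() < 2:
        raise ValueError("need >= 2 replicates per condition")
    norm = counts.to_numpy(float) / sf
    base_mean = norm.mean(axis=1)
    m_hs = norm[:, is_hs].mean(axis=1)
    m_ctrl = norm[:, ~is_hs].mean(axis=1)
    logfc = np.log2((m_hs + pseudocount) / (m_ctrl + pseudocount))
    x = np.log2(norm + pseudocount)
    n1, n0 = is_hs.sum(), (~is_hs).sum()
    v1 = x[:, is_hs].var(axis=1, ddof=1) / n1
    v0 = x[:, ~is_hs].var(axis=1, ddof=1) / n0
    se = np.sqrt(v1 + v0)
    delta = x[:, is_hs].mean(axis=1) - x[:, ~is_hs].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]
    lfc_cut = np.log2(fc_threshold)
    status = np.where(
        (padj <= fdr) & (base_mean >= base_mean_min) & (logfc >= lfc_cut), "up",
        np.where(
            (padj <= fdr) & (base_mean >= base_mean_min) & (logfc <= -lfc_cut), "down",
            "unchanged",
        ),
    )
    return pd.DataFrame(
        dict(base_mean=base_mean, logfc=logfc, pvalue=p, padj=padj, status=status),
        index=counts.index,
    )
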