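"""Travel ratios, 3'/5' processivity ratio-of-ratios, and terminator
readthrough ratios.

All intervals are measured along the gene in transcription direction;
signal is sense-strand only.  The travel ratio uses a +1 pseudocount on
the raw promoter and body counts to keep ratios finite; the processivity
statistic instead discards genes with a zero-count interval, mirroring
how each quantity is conventionally defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    query_coverage,
    select_representative_transcript,
)
from .synthetic_data import WIDTH_STRATA_KB

logger = logging.getLogger(__name__)


@dataclass
class TravelRatioResult:
    gene_id: str
    promoter_density: float
    body_density: float
    ratio: float
    clipped: bool = False


@dataclass
class ProcessivityResult:
    gene_id: str
    width: int
    ctrl_ratio: float      # ctrl 3'/5' density ratio
    hs_ratio: float        # HS 3'/5' density ratio
    ratio_of_ratios: float  # HS(3'/5') / ctrl(3'/5'); < 1 = 3' loss under HS


@dataclass
class ReadthroughResult:
    gene_id: str
    terminal_exon_density: float
    downstream_density: float
    ratio: float
    downstream_overlaps_gene: bool = False


def _tx_interval(gene: GeneModel, tx_lo: float, tx_hi: float) -> GenomicInterval:
    """Genomic interval for transcription coordinates [tx_lo, tx_hi) from the
    TSS; fractional boundaries are rounded toward the inside of the range."""
    lo, hi = int(np.ceil(tx_lo - 1e-9)), int(np.floor(tx_hi + 1e-9))
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.tss + lo, gene.tss + hi, "+")
    return GenomicInterval(gene.chrom, gene.tss - hi, gene.tss - lo, "-")


def _interval_count(track: CoverageTrack, iv: GenomicInterval, sense: str) -> float:
    """Summed signal (depth x bin_size) over the interval, sense strand."""
    return float(np.sum(query_coverage(track, iv, sense)) * track.bin_size)


def travel_ratio(
    track: CoverageTrack,
    gene: GeneModel,
    promoter_up: int = 30,
    promoter_down: int = 300,
    pseudocount: float = 1.0,
) -> TravelRatioResult | None:
    """Promoter-proximal density (TSS-30 .. TSS+300) over gene-body density
    (+300 .. TES), each with ``pseudocount`` added to the raw count.

    Genes shorter than the promoter bin are excluded (returns None).
    The promoter bin is clipped at the chromosome start if needed and the
    result flagged.
    """
    if gene.width <= promoter_down + 30:
        logger.info("travel_ratio: %s too short (%d bp), excluded", gene.gene_id, gene.width)
        return None
    clipped = False
    chrom_len = track.chrom_length(gene.chrom)
    lo, hi = -promoter_up, promoter_down
    if gene.strand == "+" and gene.tss - promoter_up < 0:
        lo, clipped = -gene.tss, True
    if gene.strand == "-" and gene.tss + promoter_up > chrom_len:
        lo, clipped = -(chrom_len - gene.tss), True
    prom_iv = _tx_interval(gene, lo, hi)
    body_iv = _tx_interval(gene, promoter_down, gene.width)
    prom_count = _interval_count(track, prom_iv, gene.strand) + pseudocount
    body_count = _interval_count(track, body_iv, gene.strand) + pseudocount
    prom_density = prom_count / prom_iv.width
    body_density = body_count / body_iv.width
    return TravelRatioResult(
        gene_id=gene.gene_id,
        promoter_density=prom_density,
        body_density=body_density,
        ratio=prom_density / body_density,
        clipped=clipped,
    )


def processivity_ratio_of_ratios(
    ctrl_track: CoverageTrack,
    hs_track: CoverageTrack,
    gene: GeneModel,
    five_prime_frac: float = 0.05,
    three_prime_frac: float = 0.25,
) -> tuple[ProcessivityResult | None, str | None]:
    """3'/5' density ratio-of-ratios between conditions.

    5' interval = first ``five_prime_frac`` of the gene width from the TSS;
    3' interval = final ``three_prime_frac`` up to the TES.  Genes with a
    zero count in any of the four (interval, condition) cells are discarded;
    returns (result, discard_reason), exactly one of which is None.
    """
    w = gene.width
    five_iv = _tx_interval(gene, 0, five_prime_frac * w)
    three_iv = _tx_interval(gene, (1 - three_prime_frac) * w, w)
    counts = {}
    for cond, track in (("ctrl", ctrl_track), ("hs", hs_track)):
        for name, iv in (("five", five_iv), ("three", three_iv)):
            c = _interval_count(track, iv, gene.strand)
            if c <= 0:
                return None, f"zero_count_{cond}_{name}"
            counts[(cond, name)] = c / iv.width
    ctrl_ratio = counts[("ctrl", "three")] / counts[("ctrl", "five")]
    hs_ratio = counts[("hs", "three")] / counts[("hs", "five")]
    return (
        ProcessivityResult(
            gene_id=gene.gene_id, width=w,
            ctrl_ratio=ctrl_ratio, hs_ratio=hs_ratio,
            ratio_of_ratios=hs_ratio / ctrl_ratio,
        ),
        None,
    )


def processivity_table(ctrl_track, hs_track, genes, **kw) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the ratio-of-ratios over a gene set.

    Returns (results, discards); the two gene-id sets partition the input.
    """
    rows, discards = [], []
    for gene in genes:
        res, reason = processivity_ratio_of_ratios(ctrl_track, hs_track, gene, **kw)
        if res is None:
            discards.append(dict(gene_id=gene.gene_id, discard_reason=reason))
        else:
            rows.append(res.__dict__)
    return (
        pd.DataFrame(rows, columns=["gene_id", "width", "ctrl_ratio", "hs_ratio", "ratio_of_ratios"]),
        pd.DataFrame(discards, columns=["gene_id", "discard_reason"]),
    )


def width_stratum(width_bp: float) -> int:
    """Index of the width stratum (<15, 15-30, 30-60, 60-90, 90-120, >=120 kb),
    half-open boundaries [lo, hi)."""
    kb = width_bp / 1e3
    bounds = [15, 30, 60, 90, 120]
    for i, b in enumerate(bounds):
        if kb < b:
            return i
    return len(bounds)


STRATUM_LABELS = ["<15kb", "15-30kb", "30-60kb", "60-90kb", "90-120kb", ">=120kb"]


def stratified_reduction_counts(results: pd.DataFrame, fold: float = 1.5) -> pd.DataFrame:
    """Per width stratum, the number and fraction of genes whose 3'/5'
    ratio-of-ratios shows at least a ``fold``-fold reduction
    (ratio_of_ratios <= 1/fold)."""
    df = results.copy()
    df["stratum"] = df["width"].map(width_stratum)
    df["reduced"] = df["ratio_of_ratios"] <= 1.0 / fold
    out = []
    for i, label in enumerate(STRATUM_LABELS):
        sub = df[df["stratum"] == i]
        n = len(sub)
        k = int(sub["reduced"].sum())
        out.append(dict(stratum=label, n_genes=n, n_reduced=k,
                        fraction=(k / n if n else np.nan)))
    return pd.DataFrame(out)


def readthrough_ratio(
    track: CoverageTrack,
    gene: GeneModel,
    all_genes: list[GeneModel] | None = None,
    downstream_bp: int = 20_000,
) -> ReadthroughResult:
    """Terminal-exon density over the density in the ``downstream_bp`` region
    past the TES (transcription direction).  The ratio falls as readthrough
    rises.  If the downstream window overlaps another same-strand gene the
    result is flagged, not excluded."""
    tx = select_representative_transcript(gene)
    terminal_exon = tx.exons_in_transcription_order()[-1]
    w = gene.width
    down_iv = _tx_interval(gene, w, w + downstream_bp)
    chrom_len = track.chrom_length(gene.chrom)
    if down_iv.start < 0 or down_iv.end > chrom_len:
        raise ValueError(
            f"{gene.gene_id}: downstream {downstream_bp} bp runs off {gene.chrom}"
        )
    term_density = _interval_count(track, terminal_exon, gene.strand) / terminal_exon.width
    down_density = _interval_count(track, down_iv, gene.strand) / down_iv.width
    overlaps = False
    if all_genes:
        for other in all_genes:
            if other.gene_id == gene.gene_id or other.strand != gene.strand:
                continue
            oi = other.interval
            if oi.chrom == down_iv.chrom and oi.start < down_iv.end and down_iv.start < oi.end:
                overlaps = True
                break
    ratio = term_density / down_density if down_density > 0 else np.inf
    return ReadthroughResult(
        gene_id=gene.gene_id,
        terminal_exon_density=term_density,
        downstream_density=down_density,
        ratio=ratio,
        downstream_overlaps_gene=overlaps,
    )
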