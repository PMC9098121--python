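"""Sequence features of heat-shock-sensitive genes and the ORF-readthrough
peptide library.

Features: counts of U1 5'-splice-site motifs (GGTGAG, GGTAAG, GTGAGT) and
the polyadenylation signal hexamer (AATAAA) within the genic interval
(TSS..TES, sense strand), their ratio (low U1/PAS marks genes prone to
premature cleavage and polyadenylation), GC content and intron geometry.

The peptide library translates each gene from its canonical ATG through
the first exon into the adjacent intron up to the first stop codon —
the proteome-wide readout expected if intron-1-terminated transcripts are
translated — then digests the products with trypsin rules for matching
against mass-spectrometry data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .genome_model import GeneModel, TranscriptModel
from .synthetic_data import PAS_MOTIF, U1_MOTIFS, reverse_complement

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


def _validate_sequence(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")


def count_motif_occurrences(sequence: str, motifs=U1_MOTIFS + (PAS_MOTIF,)) -> dict[str, int]:
    """Overlapping occurrence counts per motif (sliding window, step 1).
    'N' never matches.  Sequence must be uppercase ACGTN."""
    _validate_sequence(sequence)
    counts = {}
    for motif in motifs:
        n = 0
        start = 0
        while True:
            i = sequence.find(motif, start)
            if i < 0:
                break
            n += 1
            start = i + 1  # overlapping matches count
        counts[motif] = n
    return counts


def u1_pas_ratio(sequence: str) -> dict:
    """U1/PAS ratio: (GGTGAG + GGTAAG + GTGAGT) / AATAAA over the genic
    sequence.  Genes with zero PAS count get ratio None and are flagged for
    exclusion from ratio summaries."""
    counts = count_motif_occurrences(sequence)
    n_u1 = sum(counts[m] for m in U1_MOTIFS)
    n_pas = counts[PAS_MOTIF]
    return dict(
        n_u1=n_u1,
        n_pas=n_pas,
        ratio=(n_u1 / n_pas if n_pas > 0 else None),
        excluded=n_pas == 0,
    )


def gc_fraction(sequence: str) -> float:
    _validate_sequence(sequence)
    acgt = sum(sequence.count(b) for b in "ACGT")
    return (sequence.count("G") + sequence.count("C")) / acgt if acgt else np.nan


def gene_sense_sequence(chrom_seqs: dict[str, str], gene: GeneModel) -> str:
    """Sense-strand genic sequence TSS..TES (reverse complement for '-')."""
    raw = chrom_seqs[gene.chrom][gene.interval.start:gene.interval.end].upper()
    return reverse_complement(raw) if gene.strand == "-" else raw


def gene_feature_table(
    genes: list[GeneModel],
    chrom_seqs: dict[str, str],
    de_status: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene sequence/structure features, with DE status attached."""
    rows = []
    for gene in genes:
        seq = gene_sense_sequence(chrom_seqs, gene)
        up = u1_pas_ratio(seq)
        tx = gene.transcripts[0]
        introns = tx.introns()
        rows.append(dict(
            gene_id=gene.gene_id,
            width=gene.width,
            n_u1=up["n_u1"],
            n_pas=up["n_pas"],
            u1_pas_ratio=up["ratio"],
            u1_pas_excluded=up["excluded"],
            gc_fraction=gc_fraction(seq),
            n_introns=len(introns),
            intron_length=sum(iv.width for iv in introns),
            de_status=(de_status or {}).get(gene.gene_id, "unchanged"),
        ))
    return pd.DataFrame(rows).set_index("gene_id")


def compare_down_vs_rest(table: pd.DataFrame, features=("width", "u1_pas_ratio", "gc_fraction", "intron_length")) -> pd.DataFrame:
    """Wilcoxon rank-sum test of each feature: HS-downregulated genes vs all
    others.  Groups with fewer than 2 genes are skipped."""
    down = table["de_status"] == "down"
    out = []
    for feat in features:
        a = table.loc[down, feat].dropna()
        b = table.loc[~down, feat].dropna()
        if len(a) < 2 or len(b) < 2:
            logger.info("compare_down_vs_rest: skipping %s (group too small)", feat)
            continue
        res = stats.ranksums(a, b)
        out.append(dict(feature=feat, n_down=len(a), n_rest=len(b),
                        statistic=res.statistic, pvalue=res.pvalue,
                        median_down=float(np.median(a)), median_rest=float(np.median(b))))
    return pd.DataFrame(out)


def logfc_vs_width_trend(widths: pd.Series, logfc: pd.Series, n_bins: int = 10) -> pd.DataFrame:
    """Monotone summary of the logFC-vs-gene-width trend: median logFC in
    width-quantile bins (the robust analogue of a smoothed trend line)."""
    df = pd.DataFrame(dict(width=widths, logfc=logfc)).dropna()
    df["bin"] = pd.qcut(df["width"], q=n_bins, duplicates="drop")
    g = df.groupby("bin", observed=True)
    return pd.DataFrame(dict(
        median_width=g["width"].median(),
        median_logfc=g["logfc"].median(),
        n=g.size(),
    )).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ORF readthrough translation + tryptic digestion
# ---------------------------------------------------------------------------

@dataclass
class ReadthroughORF:
    gene_id: str
    peptide: str          # amino acids from the canonical Met, no stop char
    stop_found: bool
    tx_span: tuple[int, int]   # translated span in transcript (sense genic) coords
    source: str = "exon1+intron1 readthrough"


def orf_readthrough_translate(
    gene: GeneModel,
    chrom_seqs: dict[str, str],
    canonical_atg: int,
    transcript: TranscriptModel | None = None,
) -> ReadthroughORF:
    """Translate from the canonical ATG through exon 1, into intron 1 and
    onward to the first stop codon.

    ``canonical_atg`` is the offset of the A of the ATG in sense genic
    coordinates (bp from the TSS) and must lie within the first exon.  If
    no stop occurs, the search is capped at the transcript's last exon end
    and ``stop_found`` is False.  Translation runs across the exon/intron
    boundary in frame (the readthrough pre-mRNA is the template).
    """
    tx = transcript or gene.transcripts[0]
    exons = tx.exons_in_transcription_order()
    first = exons[0]
    # first-exon span in sense genic coordinates
    if gene.strand == "+":
        ex1_lo, ex1_hi = first.start - gene.interval.start, first.end - gene.interval.start
    else:
        ex1_lo, ex1_hi = gene.interval.end - first.end, gene.interval.end - first.start
    if not (ex1_lo <= canonical_atg <= ex1_hi - 3):
        raise ValueError(
            f"{gene.gene_id}: canonical ATG at {canonical_atg} not within exon 1 "
            f"[{ex1_lo},{ex1_hi})"
        )
    sense = gene_sense_sequence(chrom_seqs, gene)
    if sense[canonical_atg:canonical_atg + 3] != "ATG":
        raise ValueError(f"{gene.gene_id}: no ATG at stated position {canonical_atg}")
    cap = gene.width  # last exon ends at the TES in these models
    coding = sense[canonical_atg:cap]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop = aa.find("*")
    if stop >= 0:
        peptide, stop_found = aa[:stop], True
        end = canonical_atg + 3 * (stop + 1)
    else:
        peptide, stop_found = aa, False
        end = canonical_atg + len(coding)
    return ReadthroughORF(
        gene_id=gene.gene_id, peptide=peptide, stop_found=stop_found,
        tx_span=(canonical_atg, end),
    )


def tryptic_digest(peptide: str, min_length: int = 7, missed_cleavages: int = 0) -> list[str]:
    """Trypsin/LysC in-silico digestion: cleave C-terminal to K or R except
    when the next residue is P; keep fragments of at least ``min_length``
    residues.  ``missed_cleavages`` > 0 additionally yields merged runs of
    up to that many skipped sites."""
    if any(ch == "*" for ch in peptide):
        raise ValueError("peptide contains a stop symbol")
    cuts = [0]
    for i, ch in enumerate(peptide[:-1]):
        if ch in "KR" and peptide[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(peptide))
    pieces = [peptide[a:b] for a, b in zip(cuts[:-1], cuts[1:]) if b > a]
    out = []
    for k in range(missed_cleavages + 1):
        for i in range(len(pieces) - k):
            frag = "".join(pieces[i:i + k + 1])
            if len(frag) >= min_length:
                out.append(frag)
    return out


def peptide_library(
    genes: list[GeneModel],
    chrom_seqs: dict[str, str],
    atg_offsets: dict[str, int],
    min_length: int = 7,
) -> pd.DataFrame:
    """Build the virtual readthrough peptide library for a gene set:
    one readthrough ORF per gene (genes whose ATG is not in exon 1 are
    skipped with a log entry), tryptically digested."""
    rows = []
    for gene in genes:
        try:
            orf = orf_readthrough_translate(gene, chrom_seqs, atg_offsets[gene.gene_id])
        except ValueError as e:
            logger.info("peptide_library: skipping %s", e)
            continue
        for j, frag in enumerate(tryptic_digest(orf.peptide, min_length=min_length)):
            rows.append(dict(gene_id=gene.gene_id, fragment_index=j, peptide=frag,
                             stop_found=orf.stop_found))
    return pd.DataFrame(rows, columns=["gene_id", "fragment_index", "peptide", "stop_found"])
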