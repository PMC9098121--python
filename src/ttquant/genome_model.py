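"""Coordinate-safe gene/transcript/coverage data model and standard-format I/O.

All internal coordinates are 0-based half-open; conversion to/from the
1-based closed GTF convention happens only at the I/O edge.  Every statistic
downstream of this module works on sense-strand signal in transcription
orientation (5'->3' of the owning gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: default allow-list of "standard" chromosomes (autosomes + X + Y, with and
#: without the "chr" prefix).  The set is configurable in every reader.
STANDARD_CHROMOSOMES = frozenset(
    [str(i) for i in range(1, 23)]
    + ["X", "Y"]
    + [f"chr{i}" for i in range(1, 23)]
    + ["chrX", "chrY"]
)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One transcript: its genomic span, ordered exons and annotation support.

    ``support_level`` follows the Ensembl transcript-support-level convention:
    a lower integer means better experimental support.
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    support_level: int = 5
    biotype: str = "protein_coding"

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"exon [{ex.start},{ex.end}) outside transcript "
                    f"[{self.interval.start},{self.interval.end}) of {self.transcript_id}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = ex.end

    @property
    def width(self) -> int:
        return self.interval.width

    @property
    def strand(self) -> str:
        return self.interval.strand

    def exons_in_transcription_order(self) -> list[GenomicInterval]:
        """Exons ordered 5'->3' along the direction of transcription."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> list[GenomicInterval]:
        """Introns between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons[:-1], self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class GeneModel:
    """A gene locus with its transcripts.

    TSS/TES follow the strand convention: on '+' the TSS is ``start``; on
    '-' the TSS is ``end`` and the TES is ``start``.
    """

    gene_id: str
    interval: GenomicInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def width(self) -> int:
        return self.interval.width

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


def select_representative_transcript(gene: GeneModel) -> TranscriptModel:
    """Pick one transcript per gene: best (lowest) support level, then
    largest genomic width, then lexicographically smallest transcript id.

    The result is deterministic and invariant to the input order of the
    transcript list.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return min(
        gene.transcripts,
        key=lambda t: (t.support_level, -t.width, t.transcript_id),
    )


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect)
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path) -> None:
    """Cheap structural pass so malformed records are rejected with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF record at line {lineno}")
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as e:
                raise ValueError(f"{path}: non-integer coordinate at line {lineno}") from e
            if fields[6] not in ("+", "-") or start1 < 1 or end1 < start1:
                raise ValueError(f"{path}: malformed interval/strand at line {lineno}")


def read_gene_annotation(
    path,
    *,
    biotypes: set[str] | None = frozenset({"protein_coding"}),
    min_width: int | None = None,
    max_width: int | None = None,
    chromosomes: frozenset[str] | None = STANDARD_CHROMOSOMES,
) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into GeneModel objects (via gffutils).

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open here, at the I/O edge.  Filters (biotype, width in bp,
    chromosome allow-list) are applied after parsing; pass ``None`` to
    disable a filter.  Output is ordered by (chrom, start, gene_id).
    """
    import gffutils

    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )

    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, dict] = {}

    def _attr(feat, key, default=None):
        vals = feat.attributes.get(key)
        return vals[0] if vals else default

    for feat in db.all_features():
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "gene":
            gid = _attr(feat, "gene_id")
            genes[gid] = GeneModel(
                gene_id=gid,
                interval=iv,
                biotype=_attr(feat, "gene_biotype", "protein_coding"),
            )
        elif feat.featuretype == "transcript":
            tid = _attr(feat, "transcript_id")
            tsl_raw = _attr(feat, "transcript_support_level", "5") or "5"
            try:
                tsl = int(tsl_raw.split()[0])
            except ValueError:
                tsl = 5  # "NA" and friends sort worst
            tx_meta[tid] = dict(
                gene_id=_attr(feat, "gene_id"), interval=iv, support_level=tsl,
                biotype=_attr(feat, "transcript_biotype", _attr(feat, "gene_biotype", "protein_coding")),
            )
            exons.setdefault(tid, [])
        elif feat.featuretype == "exon":
            exons.setdefault(_attr(feat, "transcript_id"), []).append(iv)

    bad_genes: set[str] = set()
    for tid, meta in tx_meta.items():
        try:
            transcripts[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=meta["gene_id"],
                interval=meta["interval"],
                exons=exons.get(tid, []),
                support_level=meta["support_level"],
                biotype=meta["biotype"],
            )
        except ValueError as e:
            logger.warning("rejecting gene %s: %s", meta["gene_id"], e)
            bad_genes.add(meta["gene_id"])

    for tid, tx in transcripts.items():
        if tx.gene_id in genes:
            genes[tx.gene_id].transcripts.append(tx)

    out = []
    for gid, gene in genes.items():
        if gid in bad_genes:
            continue
        if biotypes is not None and gene.biotype not in biotypes:
            continue
        if chromosomes is not None and gene.chrom not in chromosomes:
            continue
        if min_width is not None and gene.width < min_width:
            continue
        if max_width is not None and gene.width > max_width:
            continue
        gene.transcripts.sort(key=lambda t: t.transcript_id)
        out.append(gene)
    out.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return out


def write_gene_annotation(genes: list[GeneModel], path) -> None:
    """Write GeneModels as Ensembl-dialect GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for gene in genes:
            gi = gene.interval
            fh.write(
                f"{gi.chrom}\tttquant\tgene\t{gi.start + 1}\t{gi.end}\t.\t{gi.strand}\t.\t"
                f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";\n'
            )
            for tx in gene.transcripts:
                ti = tx.interval
                fh.write(
                    f"{ti.chrom}\tttquant\ttranscript\t{ti.start + 1}\t{ti.end}\t.\t{ti.strand}\t.\t"
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'transcript_support_level "{tx.support_level}"; '
                    f'gene_biotype "{gene.biotype}";\n'
                )
                for ex in tx.exons:
                    fh.write(
                        f"{ex.chrom}\tttquant\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t"
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";\n'
                    )


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Strand-specific binned read-depth vectors per chromosome.

    ``data`` maps (chrom, strand) -> float array of per-bin depths at
    ``bin_size`` bp resolution.  ``scale_factor`` records a between-sample
    factor that has already been divided out (None = raw).
    """

    def __init__(
        self,
        data: dict[tuple[str, str], np.ndarray],
        bin_size: int = 1,
        label: str = "",
        scale_factor: float | None = None,
    ):
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for key, depths in data.items():
            depths = np.asarray(depths, dtype=float)
            if not np.all(np.isfinite(depths)) or np.any(depths < 0):
                raise ValueError(f"depths for {key} must be finite and >= 0")
            data[key] = depths
        self.data = data
        self.bin_size = int(bin_size)
        self.label = label
        self.scale_factor = scale_factor

    def chrom_length(self, chrom: str) -> int:
        for (c, s), v in self.data.items():
            if c == chrom:
                return len(v) * self.bin_size
        raise KeyError(f"chromosome {chrom!r} not in track {self.label!r}")

    def total_signal(self) -> float:
        """Genome-wide sum of depth x bin_size (both strands)."""
        return float(sum(v.sum() for v in self.data.values()) * self.bin_size)

    def copy(self, **overrides) -> "CoverageTrack":
        kw = dict(
            data={k: v.copy() for k, v in self.data.items()},
            bin_size=self.bin_size,
            label=self.label,
            scale_factor=self.scale_factor,
        )
        kw.update(overrides)
        return CoverageTrack(**kw)


def query_coverage(track: CoverageTrack, interval: GenomicInterval, sense: str | None = None) -> np.ndarray:
    """Depth vector over ``interval`` from the sense strand only, oriented
    5'->3' in the direction of transcription (reversed for '-' genes).

    ``sense`` defaults to the interval's own strand.  Querying a strand the
    track does not carry returns zeros (strand-specific contract).
    """
    strand = sense if sense is not None else interval.strand
    chroms = {c for c, _ in track.data}
    if interval.chrom not in chroms:
        raise KeyError(f"chromosome {interval.chrom!r} not in track {track.label!r}")
    b = track.bin_size
    lo = interval.start // b
    hi = -(-interval.end // b)  # ceil
    key = (interval.chrom, strand)
    if key not in track.data:
        vec = np.zeros(hi - lo)
    else:
        arr = track.data[key]
        if hi > len(arr):
            raise IndexError(
                f"interval [{interval.start},{interval.end}) beyond {interval.chrom} "
                f"length {len(arr) * b}"
            )
        vec = arr[lo:hi].astype(float, copy=True)
    return vec[::-1] if strand == "-" else vec


def mean_depth(track: CoverageTrack, interval: GenomicInterval, sense: str | None = None) -> float:
    """Mean per-bp depth over the interval on the sense strand."""
    return float(np.mean(query_coverage(track, interval, sense)))


def raw_count(track: CoverageTrack, interval: GenomicInterval, sense: str | None = None) -> float:
    """Approximate read-count signal = sum(depth) x bin_size over the interval."""
    return float(np.sum(query_coverage(track, interval, sense)) * track.bin_size)


# ---------------------------------------------------------------------------
# bedGraph I/O (one file per strand: <stem>.plus.bedgraph / <stem>.minus.bedgraph)
# ---------------------------------------------------------------------------

_STRAND_SUFFIX = {"+": "plus", "-": "minus"}


def write_bedgraph(track: CoverageTrack, stem) -> list[str]:
    """Write one bedGraph per strand; adjacent equal-value bins are merged
    (run-length encoding); zero runs and empty chromosomes are omitted.
    Returns the paths written."""
    stem = str(stem)
    paths = []
    for strand in ("+", "-"):
        path = f"{stem}.{_STRAND_SUFFIX[strand]}.bedgraph"
        with open(path, "w") as fh:
            for (chrom, s), depths in sorted(track.data.items()):
                if s != strand or len(depths) == 0:
                    continue
                b = track.bin_size
                # run-length encode
                change = np.flatnonzero(np.diff(depths)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(depths)]))
                for i0, i1 in zip(starts, ends):
                    val = depths[i0]
                    if val == 0:
                        continue
                    fh.write(f"{chrom}\t{i0 * b}\t{i1 * b}\t{val:g}\n")
        paths.append(path)
    return paths


def read_bedgraph(
    stem,
    chrom_lengths: dict[str, int],
    bin_size: int = 1,
    label: str = "",
    scale_factor: float | None = None,
) -> CoverageTrack:
    """Read a .plus/.minus bedGraph pair back into a CoverageTrack.

    bedGraph intervals must align to the bin grid and must not overlap.
    """
    data: dict[tuple[str, str], np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        nbins = -(-length // bin_size)
        for strand in ("+", "-"):
            data[(chrom, strand)] = np.zeros(nbins)
    for strand in ("+", "-"):
        path = f"{stem}.{_STRAND_SUFFIX[strand]}.bedgraph"
        seen: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                chrom, start_s, end_s, val_s = line.split()
                start, end, val = int(start_s), int(end_s), float(val_s)
                if start % bin_size or end % bin_size:
                    raise ValueError(f"{path}:{lineno}: interval not aligned to bin_size {bin_size}")
                if start < seen.get(chrom, 0):
                    raise ValueError(f"{path}:{lineno}: overlapping or unsorted bedGraph intervals")
                seen[chrom] = end
                data[(chrom, strand)][start // bin_size:end // bin_size] = val
    return CoverageTrack(data, bin_size=bin_size, label=label, scale_factor=scale_factor)
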