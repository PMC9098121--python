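"""Metagene and TSS-anchored average read-depth profiles.

Two geometries, mirroring standard nascent-RNA practice:

* scaled-regions: fixed upstream/downstream flanks plus the gene body
  width-normalised into a fixed number of bins;
* reference-point: a fixed window around the TSS, with genes shorter than
  the window contributing only to the bins they cover.

The per-bin statistic is a trimmed mean across genes (default: 5% most
extreme values removed, 2.5% per tail).  All profiles are oriented
5'->3' in transcription direction regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import trim_mean

from .genome_model import CoverageTrack, GeneModel, GenomicInterval, query_coverage


@dataclass
class MetaProfile:
    """Average profile across genes: per-bin trimmed-mean depth."""

    positions: np.ndarray          # bin start coordinate on the profile axis
    means: np.ndarray              # trimmed-mean depth per bin
    n_per_bin: np.ndarray          # genes contributing to each bin
    bin_size: int
    geometry: dict = field(default_factory=dict)
    segments: dict = field(default_factory=dict)   # name -> slice into the arrays

    @property
    def n_genes(self) -> int:
        return int(self.geometry.get("n_genes", 0))


def resample_mean(vec: np.ndarray, n_out: int) -> np.ndarray:
    """Width-normalised rebinning: means of a piecewise-constant signal over
    ``n_out`` equal fractions of its span (exact via the cumulative integral).
    Output bins touching any NaN source bin are NaN."""
    vec = np.asarray(vec, float)
    n = len(vec)
    missing = ~np.isfinite(vec)
    cum = np.concatenate(([0.0], np.cumsum(np.where(missing, 0.0, vec))))
    edges = np.linspace(0, n, n_out + 1)
    integ = np.interp(edges, np.arange(n + 1), cum)
    out = np.diff(integ) / np.diff(edges)
    if missing.any():
        cum_m = np.concatenate(([0.0], np.cumsum(missing.astype(float))))
        m = np.diff(np.interp(edges, np.arange(n + 1), cum_m))
        out[m > 1e-12] = np.nan
    return out


def _trimmed_col_mean(matrix: np.ndarray, trim: float, mode: str = "symmetric"):
    """Missing-aware per-column trimmed mean and contributor counts."""
    n_bins = matrix.shape[1]
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for j in range(n_bins):
        col = matrix[:, j]
        col = col[np.isfinite(col)]
        counts[j] = len(col)
        if len(col) == 0:
            continue
        if trim <= 0:
            means[j] = col.mean()
        elif mode == "symmetric":
            means[j] = trim_mean(col, trim / 2)
        elif mode == "top":
            k = int(np.floor(len(col) * trim))
            means[j] = np.sort(col)[: len(col) - k].mean() if len(col) > k else np.nan
        else:
            raise ValueError(f"unknown trim mode {mode!r}")
    return means, counts


def _window_coverage(track: CoverageTrack, gene: GeneModel, tx_lo: int, tx_hi: int) -> np.ndarray:
    """Sense coverage for transcription coordinates [tx_lo, tx_hi) relative to
    the TSS (negative = upstream), NaN-padded where the window runs off the
    chromosome.  Length = (tx_hi - tx_lo) / track.bin_size bins."""
    b = track.bin_size
    if gene.strand == "+":
        g_lo, g_hi = gene.tss + tx_lo, gene.tss + tx_hi
    else:
        g_lo, g_hi = gene.tss - tx_hi, gene.tss - tx_lo
    chrom_len = track.chrom_length(gene.chrom)
    c_lo, c_hi = max(g_lo, 0), min(g_hi, chrom_len)
    n = (tx_hi - tx_lo) // b
    out = np.full(n, np.nan)
    if c_lo < c_hi:
        vec = query_coverage(
            track, GenomicInterval(gene.chrom, c_lo, c_hi, gene.strand), gene.strand
        )
        if gene.strand == "+":
            off = (c_lo - g_lo) // b
        else:
            off = (g_hi - c_hi) // b
        # windows need not align to the bin grid; clamp the copied slice
        k = min(len(vec), n - off)
        if k > 0:
            out[off:off + k] = vec[:k]
    return out


def metagene_scaled_regions(
    track: CoverageTrack,
    genes: list[GeneModel],
    up: int = 5000,
    body_bins: int = 100,
    down: int = 5000,
    bin_size: int = 100,
    trim: float = 0.05,
    trim_mode: str = "symmetric",
) -> MetaProfile:
    """Scaled-regions metagene: ``up`` bp upstream of the TSS, the gene body
    width-normalised into ``body_bins`` bins, and ``down`` bp downstream of
    the TES; trimmed mean across genes per bin."""
    if not genes:
        raise ValueError("empty gene set")
    n_up, n_down = up // bin_size, down // bin_size
    total = n_up + body_bins + n_down
    mat = np.full((len(genes), total), np.nan)
    for i, gene in enumerate(genes):
        w = gene.width
        upstream = _window_coverage(track, gene, -up, 0)
        body = query_coverage(track, gene.interval, gene.strand)
        downstream = _window_coverage(track, gene, w, w + down)
        mat[i, :n_up] = resample_mean(upstream, n_up)
        mat[i, n_up:n_up + body_bins] = resample_mean(body, body_bins)
        mat[i, n_up + body_bins:] = resample_mean(downstream, n_down)
    means, counts = _trimmed_col_mean(mat, trim, trim_mode)
    positions = np.arange(total) * bin_size - up
    return MetaProfile(
        positions=positions, means=means, n_per_bin=counts, bin_size=bin_size,
        geometry=dict(mode="scaled_regions", up=up, body_bins=body_bins,
                      down=down, n_genes=len(genes), trim=trim),
        segments=dict(upstream=slice(0, n_up),
                      body=slice(n_up, n_up + body_bins),
                      downstream=slice(n_up + body_bins, total)),
    )


def tss_reference_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    downstream: int = 120_000,
    upstream: int = 2000,
    bin_size: int = 100,
    start_offset: int = 0,
    trim: float = 0.05,
    trim_mode: str = "symmetric",
    clip_at_tes: bool = True,
) -> MetaProfile:
    """Reference-point profile around the TSS: ``upstream`` bp before to
    ``downstream`` bp after, in transcription orientation.

    Genes shorter than the downstream window contribute nothing beyond
    their TES (missing-aware mean); ``start_offset`` masks the first bins
    after the TSS (e.g. +500 bp for PRO-seq style profiles).
    """
    if downstream <= 0:
        raise ValueError("downstream extent must be > 0")
    if upstream < 0:
        raise ValueError("upstream extent must be >= 0")
    if not genes:
        raise ValueError("empty gene set")
    n_bins = (upstream + downstream) // bin_size
    mat = np.full((len(genes), n_bins), np.nan)
    offsets = np.arange(n_bins) * bin_size - upstream  # bin start, tx coords
    for i, gene in enumerate(genes):
        vec = _window_coverage(track, gene, -upstream, downstream)
        binned = resample_mean(vec, n_bins)
        mask = np.ones(n_bins, bool)
        if clip_at_tes:
            mask &= offsets < gene.width
        if start_offset:
            mask &= ~((offsets >= 0) & (offsets < start_offset))
        mat[i, mask] = binned[mask]
    means, counts = _trimmed_col_mean(mat, trim, trim_mode)
    return MetaProfile(
        positions=offsets, means=means, n_per_bin=counts, bin_size=bin_size,
        geometry=dict(mode="reference_point", upstream=upstream,
                      downstream=downstream, start_offset=start_offset,
                      n_genes=len(genes), trim=trim),
        segments=dict(upstream=slice(0, upstream // bin_size),
                      downstream=slice(upstream // bin_size, n_bins)),
    )


def promoter_background_rescale(profile: MetaProfile, upstream_window: int | None = None) -> MetaProfile:
    """Divide every bin by the summed signal upstream of the TSS, aligning
    curves on their promoter-upstream background.  Idempotent (the rescaled
    upstream sum is 1)."""
    upstream = profile.segments.get("upstream")
    if upstream is None:
        raise ValueError("profile has no upstream segment")
    sl = upstream
    if upstream_window is not None:
        n_keep = upstream_window // profile.bin_size
        sl = slice(max(sl.stop - n_keep, sl.start), sl.stop)
    total = np.nansum(profile.means[sl])
    if not total > 0:
        raise ValueError(
            "upstream signal sums to zero; add a pseudocount or widen the window"
        )
    return MetaProfile(
        positions=profile.positions.copy(),
        means=profile.means / total,
        n_per_bin=profile.n_per_bin.copy(),
        bin_size=profile.bin_size,
        geometry={**profile.geometry, "promoter_rescaled": True},
        segments=dict(profile.segments),
    )
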