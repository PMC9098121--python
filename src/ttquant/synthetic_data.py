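"""Synthetic annotations, sequences, coverage tracks and count matrices.

The generators emulate the signal structure that the downstream statistics
assume, with ground truth recorded for every dataset:

* gene-body coverage with distance-dependent attrition after heat shock
  (a constant per-kb premature-termination hazard beyond an onset distance),
* transcription waves advancing from the TSS at a known speed after release
  from a CDK9 inhibitor block (DRB washout),
* receding clearance waves after blocking pause release (flavopiridol),
* spike-in count matrices with known between-sample library factors,
* negative-binomial exon count matrices with a known first-exon enrichment,
* gene sequences with planted U1 5'-splice-site and polyadenylation-signal
  motifs and a known ORF/intron structure.

All generators are deterministic under ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .genome_model import CoverageTrack, GeneModel, GenomicInterval, TranscriptModel

#: width strata (kb) used throughout: <15, 15-30, 30-60, 60-90, 90-120, >=120
WIDTH_STRATA_KB: list[tuple[float, float]] = [
    (5, 15), (15, 30), (30, 60), (60, 90), (90, 120), (120, 200),
]

U1_MOTIFS = ("GGTGAG", "GGTAAG", "GTGAGT")
PAS_MOTIF = "AATAAA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Defaults reflect the regime the analysis targets: a basal nascent-RNA
    depth of 10 reads/bp, Poisson counting noise per coverage bin, a
    premature-termination hazard of 5%/kb beyond 10 kb after heat shock,
    transcription waves at 2 kb/min smeared by a 2 kb front and 10%
    cell-to-cell rate variability, and a 4-fold first-exon boost under HS.
    """

    seed: int = 0
    n_genes_per_stratum: int = 2
    basal_depth: float = 10.0          # reads per bp
    bin_size: int = 50                 # bp per coverage bin
    noise: bool = True                 # Poisson noise on binned depth
    # heat-shock attrition
    termination_hazard: float = 0.05   # per-kb premature-termination probability
    onset_distance_kb: float = 10.0    # attrition starts beyond this distance
    # wavefront kinetics
    wave_speed: float = 2.0            # kb/min
    front_sd_kb: float = 2.0           # smearing of the wavefront (kb)
    rate_cv: float = 0.10              # cell-to-cell sd of speed / speed
    pulse_amplitude: float = 4.0       # released-cohort peak, x basal
    # spike-ins
    spikein_true_factors: tuple[float, ...] = (1.0, 2.0, 0.5, 1.25)
    n_spikein_genes: int = 60
    spikein_mean_count: float = 500.0
    # exon count matrices
    first_exon_effect: float = 4.0     # theta: HS fold-boost of first-exon mean
    nb_dispersion: float = 0.05        # NB variance = mu + dispersion * mu^2
    exon_mean_count: float = 100.0     # ctrl mean count per exon
    # gene structure
    exon_length_range: tuple[int, int] = (150, 400)
    n_exons_range: tuple[int, int] = (3, 8)
    planted_u1_per_gene: tuple[int, int, int] = (2, 2, 2)  # per U1 motif
    planted_pas_per_gene: int = 3
    intergenic_gap: int = 30_000
    flank: int = 10_000

    def __post_init__(self):
        if self.termination_hazard < 0 or self.wave_speed <= 0:
            raise ValueError("rates must be >= 0 and wave_speed > 0")
        if self.first_exon_effect <= 0 or self.nb_dispersion < 0:
            raise ValueError("first_exon_effect must be > 0 and dispersion >= 0")

    def rng(self, tag: str) -> np.random.Generator:
        """Independent, reproducible stream per generator stage."""
        import zlib

        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(tag.encode()) % (2**31)])
        )


# ---------------------------------------------------------------------------
# gene set + sequences
# ---------------------------------------------------------------------------

def _scrub_motifs(seq: list[str], motifs: tuple[str, ...], rng,
                  keep_spans: list[tuple[int, int]] | None = None) -> None:
    """Mutate bases in-place until each motif occurs only at kept spans.

    ``keep_spans`` are half-open intervals (planted motifs) whose bases must
    not be touched; any other occurrence — including ones straddling a kept
    span — has one of its free bases mutated.  Loops until clean.
    """
    keep_spans = keep_spans or []
    kept_starts = {(a) for a, _ in keep_spans}

    def _protected(j):
        return any(a <= j < b for a, b in keep_spans)

    for _ in range(10_000):
        s = "".join(seq)
        dirty = False
        for motif in motifs:
            start = 0
            while True:
                i = s.find(motif, start)
                if i < 0:
                    break
                if i in kept_starts:
                    start = i + 1
                    continue
                free = [j for j in range(i, i + len(motif)) if not _protected(j)]
                j = int(rng.choice(free))
                seq[j] = str(rng.choice([b for b in "ACGT" if b != seq[j]]))
                dirty = True
                s = "".join(seq)
                start = i
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")


def make_gene_set(config: SyntheticConfig):
    """Build a stratified gene set with sequences and planted motifs.

    Returns ``(genes, chrom_seqs, truth)`` where ``chrom_seqs`` maps
    chromosome name to its sequence and ``truth`` records, per gene, the
    planted motif counts/positions (in sense-strand genic coordinates),
    the exon/intron structure and the canonical ATG offset.
    """
    rng = config.rng("gene_set")
    genes: list[GeneModel] = []
    truth: dict = {"genes": {}}
    chrom = "chr1"
    cursor = config.flank
    chrom_parts: list[str] = []
    all_motifs = U1_MOTIFS + (PAS_MOTIF,)

    gene_widths = []
    for si, (lo, hi) in enumerate(WIDTH_STRATA_KB):
        if config.n_genes_per_stratum < 1:
            continue
        widths = rng.uniform(lo * 1e3, hi * 1e3, size=config.n_genes_per_stratum)
        gene_widths += [(si, int(w)) for w in widths]

    def _random_seq(n):
        return rng.choice(list("ACGT"), size=n).tolist()

    for gi, (si, width) in enumerate(gene_widths):
        gene_id = f"SYNG{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        start = cursor
        end = start + width
        iv = GenomicInterval(chrom, start, end, strand)

        # exon/intron structure in transcription coordinates [0, width)
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
        remaining = width - int(exon_lens.sum())
        cuts = np.sort(rng.uniform(0, 1, size=n_exons - 2)) if n_exons > 2 else np.array([])
        intron_lens = np.diff(np.concatenate(([0.0], cuts, [1.0]))) * remaining
        intron_lens = np.maximum(intron_lens.astype(int), 50)
        # exons in transcription order, starting at the TSS
        tx_bounds = []
        pos = 0
        for k in range(n_exons):
            tx_bounds.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        # stretch last exon to end at the TES
        tx_bounds[-1] = (tx_bounds[-1][0], width)

        # sense-strand genic sequence with planted motifs and nothing else
        sense = _random_seq(width)
        intron1 = (tx_bounds[0][1], tx_bounds[1][0])
        atg_offset = 30
        sense[atg_offset:atg_offset + 3] = list("ATG")

        planted: dict[str, list[int]] = {m: [] for m in all_motifs}
        plant_jobs = [(PAS_MOTIF, config.planted_pas_per_gene)] + [
            (m, config.planted_u1_per_gene[k]) for k, m in enumerate(U1_MOTIFS)
        ]
        lo_plant, hi_plant = intron1[0] + 10, width - 16
        slots = rng.choice(
            np.arange(lo_plant, hi_plant, 12),
            size=sum(n for _, n in plant_jobs), replace=False,
        )
        si_slot = 0
        keep_spans = [(atg_offset, atg_offset + 3)]
        for motif, n in plant_jobs:
            for _ in range(n):
                p = int(slots[si_slot]); si_slot += 1
                sense[p:p + 6] = list(motif)
                planted[motif].append(p)
                keep_spans.append((p, p + 6))
        _scrub_motifs(sense, all_motifs, rng, keep_spans=keep_spans)

        genomic_seq = "".join(sense) if strand == "+" else reverse_complement("".join(sense))
        # exon intervals in genomic coordinates
        exon_ivs = []
        for (a, b) in tx_bounds:
            if strand == "+":
                exon_ivs.append(GenomicInterval(chrom, start + a, start + b, strand))
            else:
                exon_ivs.append(GenomicInterval(chrom, end - b, end - a, strand))
        tx = TranscriptModel(
            transcript_id=f"SYNT{gi:04d}", gene_id=gene_id, interval=iv,
            exons=exon_ivs, support_level=1,
        )
        gene = GeneModel(gene_id=gene_id, interval=iv, transcripts=[tx])
        genes.append(gene)
        truth["genes"][gene_id] = {
            "stratum": si,
            "width": width,
            "strand": strand,
            "planted_motifs": {m: sorted(p) for m, p in planted.items()},
            "exon_bounds_tx": tx_bounds,
            "atg_offset": atg_offset,
            "genic_sequence": "".join(sense),
        }
        truth["genes"][gene_id]["genomic_span"] = [start, end]
        chrom_parts.append((start, genomic_seq))
        cursor = end + config.intergenic_gap

    # assemble the chromosome: random filler + genic sequences at their spans
    total_len = cursor + config.flank
    backbone = rng.choice(list("ACGT"), size=total_len)
    for start, gseq in [p for p in chrom_parts if p]:
        backbone[start:start + len(gseq)] = list(gseq)
    chrom_seqs = {chrom: "".join(backbone)}
    truth["chrom_lengths"] = {chrom: total_len}
    return genes, chrom_seqs, truth


def make_count_gene_set(config: SyntheticConfig, n_genes: int) -> list[GeneModel]:
    """Light-weight multi-exon gene models (no sequences) for count-matrix
    studies: exon counts and lengths drawn from the config distributions."""
    rng = config.rng("count_genes")
    genes = []
    chrom = "chrC"
    cursor = config.flank
    for gi in range(n_genes):
        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
        intron_lens = rng.integers(500, 2000, size=max(n_exons - 1, 0))
        strand = "+" if gi % 2 == 0 else "-"
        pos = cursor
        bounds = []
        for k in range(n_exons):
            bounds.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        iv = GenomicInterval(chrom, cursor, pos, strand)
        exons = [GenomicInterval(chrom, a, b, strand) for a, b in bounds]
        tx = TranscriptModel(
            transcript_id=f"CNTT{gi:04d}", gene_id=f"CNTG{gi:04d}",
            interval=iv, exons=exons, support_level=1,
        )
        genes.append(GeneModel(gene_id=f"CNTG{gi:04d}", interval=iv, transcripts=[tx]))
        cursor = pos + config.intergenic_gap
    return genes


def make_wave_gene_set(config: SyntheticConfig, n_genes: int = 3, width: int = 220_000):
    """Long genes (>=200 kb) for wavefront analyses; no sequence needed."""
    genes = []
    chrom = "chrW"
    cursor = config.flank
    for gi in range(n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        iv = GenomicInterval(chrom, cursor, cursor + width, strand)
        tx = TranscriptModel(
            transcript_id=f"WAVT{gi:02d}", gene_id=f"WAVG{gi:02d}", interval=iv,
            exons=[iv], support_level=1,
        )
        genes.append(GeneModel(gene_id=f"WAVG{gi:02d}", interval=iv, transcripts=[tx]))
        cursor += width + config.intergenic_gap
    chrom_lengths = {chrom: cursor + config.flank}
    return genes, chrom_lengths


# ---------------------------------------------------------------------------
# coverage-track generators
# ---------------------------------------------------------------------------

def _empty_data(chrom_lengths: dict[str, int], bin_size: int):
    return {
        (c, s): np.zeros(-(-length // bin_size))
        for c, length in chrom_lengths.items()
        for s in ("+", "-")
    }


def _gene_bin_distances_kb(gene: GeneModel, bin_size: int) -> tuple[slice, np.ndarray]:
    """Slice of the chromosome bin array covered by the gene and the distance
    (kb) of each bin centre from the TSS, in transcription direction."""
    lo = gene.interval.start // bin_size
    hi = -(-gene.interval.end // bin_size)
    centers = (np.arange(lo, hi) + 0.5) * bin_size
    d = (centers - gene.interval.start) if gene.strand == "+" else (gene.interval.end - centers)
    return slice(lo, hi), d / 1e3


def _deposit(data, gene, bin_size, depths, noise, rng):
    sl, _ = _gene_bin_distances_kb(gene, bin_size)
    if noise:
        lam = np.maximum(depths, 0) * bin_size
        depths = rng.poisson(lam) / bin_size
    data[(gene.chrom, gene.strand)][sl] = np.maximum(depths, 0)


def simulate_hs_attrition_tracks(genes, chrom_lengths, config: SyntheticConfig, replicate: int = 0):
    """Paired control / heat-shock tracks with distance-dependent attrition.

    Control depth is basal over the gene body.  Under HS the expected depth
    at distance d (kb) beyond the onset is basal * (1 - h)^(d - onset): each
    kb transited carries hazard h of premature termination, so coverage
    decays geometrically toward the 3' end and long genes lose most of
    their 3' signal.
    """
    rng = config.rng(f"attrition_{replicate}")
    ctrl_data = _empty_data(chrom_lengths, config.bin_size)
    hs_data = _empty_data(chrom_lengths, config.bin_size)
    h = config.termination_hazard
    for gene in genes:
        sl, d_kb = _gene_bin_distances_kb(gene, config.bin_size)
        ctrl = np.full(d_kb.shape, config.basal_depth)
        excess = np.maximum(d_kb - config.onset_distance_kb, 0.0)
        hs = config.basal_depth * (1.0 - h) ** excess
        _deposit(ctrl_data, gene, config.bin_size, ctrl, config.noise, rng)
        _deposit(hs_data, gene, config.bin_size, hs, config.noise, rng)
    ctrl_track = CoverageTrack(ctrl_data, config.bin_size, label="ctrl")
    hs_track = CoverageTrack(hs_data, config.bin_size, label="hs")
    truth = {
        "termination_hazard": h,
        "onset_distance_kb": config.onset_distance_kb,
        "expected_rr": {
            g.gene_id: expected_attrition_ratio_of_ratios(g.width / 1e3, config)
            for g in genes
        },
    }
    return ctrl_track, hs_track, truth


def expected_attrition_ratio_of_ratios(width_kb: float, config: SyntheticConfig) -> float:
    """Closed-form expected HS(3'/5')/ctrl(3'/5') under the attrition model,
    using the same intervals as the processivity statistic (first 5% of the
    gene vs final 25%)."""
    h, onset = config.termination_hazard, config.onset_distance_kb
    if h == 0:
        return 1.0

    def mean_decay(a_kb, b_kb):
        # mean of (1-h)^max(d-onset, 0) for d uniform on (a, b)
        xs = np.linspace(a_kb, b_kb, 2001)
        return float(np.trapezoid((1 - h) ** np.maximum(xs - onset, 0), xs) / (b_kb - a_kb))

    five = mean_decay(0.0, 0.05 * width_kb)
    three = mean_decay(0.75 * width_kb, width_kb)
    return three / five


def _front_sd_kb(config: SyntheticConfig, t_min: float) -> float:
    """Front smearing grows with distance travelled: a rate CV across cells
    spreads the cohort by cv * v * t on top of the base front width."""
    return config.front_sd_kb + config.rate_cv * config.wave_speed * t_min


def simulate_drb_wave_tracks(genes, chrom_lengths, config: SyntheticConfig, timepoints):
    """Advancing transcription waves after release from a DRB block.

    The released paused cohort travels as a Gaussian pulse centred at v*t
    (the wave peak a spline maximum tracks); behind it the gene body refills
    toward basal with a smeared edge trailing the pulse.  At t=0 the pulse
    sits at the promoter.  Returns ``(tracks, truth)`` with tracks keyed by
    timepoint (min) and true front positions v*t (kb) in the truth dict.
    """
    rng = config.rng("drb")
    v = config.wave_speed
    tracks = {}
    for t in timepoints:
        data = _empty_data(chrom_lengths, config.bin_size)
        sd = max(_front_sd_kb(config, t), 1e-9)
        for gene in genes:
            _, d_kb = _gene_bin_distances_kb(gene, config.bin_size)
            front = v * t
            body = config.basal_depth * norm.cdf((front - 2 * sd - d_kb) / sd)
            pulse = config.pulse_amplitude * config.basal_depth * np.exp(
                -0.5 * ((d_kb - front) / sd) ** 2
            )
            _deposit(data, gene, config.bin_size, body + pulse, config.noise, rng)
        tracks[t] = CoverageTrack(data, config.bin_size, label=f"drb_t{t}")
    truth = {"wave_speed": v, "front_kb": {float(t): v * t for t in timepoints}}
    return tracks, truth


def simulate_fp_clearance_tracks(genes, chrom_lengths, config: SyntheticConfig, timepoints):
    """Receding waves after blocking pause release (flavopiridol).

    Elongating polymerases vacate the 5' end, so depth(d, t) =
    basal * Phi((d - v*t) / front_sd): a cleared region grows from the TSS
    and the rear edge's half-height sits at v*t.
    """
    rng = config.rng("fp")
    v = config.wave_speed
    tracks = {}
    for t in timepoints:
        data = _empty_data(chrom_lengths, config.bin_size)
        sd = max(_front_sd_kb(config, t), 1e-9)
        for gene in genes:
            _, d_kb = _gene_bin_distances_kb(gene, config.bin_size)
            depth = config.basal_depth * norm.cdf((d_kb - v * t) / sd)
            _deposit(data, gene, config.bin_size, depth, config.noise, rng)
        tracks[t] = CoverageTrack(data, config.bin_size, label=f"fp_t{t}")
    truth = {"wave_speed": v, "rear_kb": {float(t): v * t for t in timepoints}}
    return tracks, truth


# ---------------------------------------------------------------------------
# count-matrix generators
# ---------------------------------------------------------------------------

def simulate_spikein_counts(config: SyntheticConfig):
    """Spike-in ('yeast') count matrix: constant true abundance per gene,
    multiplied by the per-sample library factors to be recovered.

    Returns ``(counts, truth)``; counts is a genes x samples int DataFrame.
    """
    import pandas as pd

    rng = config.rng("spikein")
    factors = np.asarray(config.spikein_true_factors, float)
    mu = rng.lognormal(mean=np.log(config.spikein_mean_count), sigma=0.8,
                       size=config.n_spikein_genes)
    lam = np.outer(mu, factors)
    counts = rng.poisson(lam)
    df = pd.DataFrame(
        counts,
        index=[f"SPIKE{i:03d}" for i in range(config.n_spikein_genes)],
        columns=[f"sample_{j}" for j in range(len(factors))],
    )
    truth = {"true_factors": factors.tolist()}
    return df, truth


def _nb_draw(rng, mu, dispersion):
    """NB with variance mu + dispersion*mu^2 (Poisson when dispersion=0)."""
    mu = np.asarray(mu, float)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_exon_count_matrix(genes, config: SyntheticConfig, n_reps: int = 3):
    """Per-exon NB counts for ctrl and HS replicates.

    Under HS the first-exon mean is multiplied by theta
    (``first_exon_effect``); remaining-exon means are unchanged, so the true
    per-gene log2 first-vs-remaining ratio-of-ratios is log2(theta).
    Single-exon genes are generated too (downstream code must drop them).
    """
    import pandas as pd

    rng = config.rng("exons")
    theta = config.first_exon_effect
    rows, data = [], []
    samples = [f"ctrl_{r}" for r in range(n_reps)] + [f"hs_{r}" for r in range(n_reps)]
    for gene in genes:
        tx = gene.transcripts[0]
        n_exons = len(tx.exons)
        base = rng.lognormal(np.log(config.exon_mean_count), 0.4)
        for idx in range(1, n_exons + 1):
            mu_ctrl = base
            mu_hs = base * theta if idx == 1 else base
            row = np.concatenate([
                _nb_draw(rng, np.full(n_reps, mu_ctrl), config.nb_dispersion),
                _nb_draw(rng, np.full(n_reps, mu_hs), config.nb_dispersion),
            ])
            rows.append((gene.gene_id, idx))
            data.append(row)
    counts = pd.DataFrame(
        np.asarray(data, dtype=int),
        index=pd.MultiIndex.from_tuples(rows, names=["gene_id", "exon_index"]),
        columns=samples,
    )
    condition = {s: ("hs" if s.startswith("hs") else "ctrl") for s in samples}
    truth = {"log2_theta": float(np.log2(theta)), "condition": condition}
    return counts, truth
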