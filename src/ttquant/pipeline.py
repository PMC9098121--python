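"""End-to-end orchestration: fixture generation, stage running, provenance
and report collation.

Each stage writes TSV/JSON outputs plus a provenance manifest recording
the package version, the global seed and SHA-256 hashes of the files, so
a rerun with the same configuration is verifiably identical for
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome_model import read_bedgraph, write_bedgraph, write_gene_annotation
from .synthetic_data import (
    SyntheticConfig,
    make_gene_set,
    make_wave_gene_set,
    simulate_drb_wave_tracks,
    simulate_exon_count_matrix,
    simulate_fp_clearance_tracks,
    simulate_hs_attrition_tracks,
    simulate_spikein_counts,
)

PRESETS = ("attrition", "drb", "fp", "isoform", "motifs")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, seed: int, files: list[Path], extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "version": __version__,
        "seed": seed,
        "files": {str(Path(f).name): _sha256(f) for f in files},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def validate_manifest(out_dir: Path) -> bool:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return all(
        _sha256(out_dir / name) == digest for name, digest in manifest["files"].items()
    )


def _write_fasta(chrom_seqs: dict[str, str], path: Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=c, description="") for c, s in sorted(chrom_seqs.items())]
    seqio_write(records, str(path), "fasta")


def generate_fixtures(preset: str, seed: int, out_dir) -> dict:
    """Write one preset's synthetic dataset (GTF + FASTA + bedGraph pairs +
    TSV matrices + ground-truth JSON) under ``out_dir``.  Returns the truth
    dictionary."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(seed=seed)
    files: list[Path] = []
    truth: dict = {"preset": preset, "seed": seed}

    if preset in ("attrition", "isoform", "motifs"):
        genes, chrom_seqs, gene_truth = make_gene_set(config)
        truth["gene_set"] = {
            g: {k: v for k, v in d.items() if k != "genic_sequence"}
            for g, d in gene_truth["genes"].items()
        }
        gtf = out_dir / "genes.gtf"
        write_gene_annotation(genes, gtf)
        fasta = out_dir / "genome.fa"
        _write_fasta(chrom_seqs, fasta)
        files += [gtf, fasta]
        chrom_lengths = gene_truth["chrom_lengths"]
        truth["chrom_lengths"] = chrom_lengths

        if preset == "attrition":
            ctrl, hs, att_truth = simulate_hs_attrition_tracks(genes, chrom_lengths, config)
            files += [Path(p) for p in write_bedgraph(ctrl, out_dir / "ctrl")]
            files += [Path(p) for p in write_bedgraph(hs, out_dir / "hs")]
            truth["attrition"] = att_truth
            spike, spike_truth = simulate_spikein_counts(config)
            spike_path = out_dir / "spikein_counts.tsv"
            spike.to_csv(spike_path, sep="\t")
            files.append(spike_path)
            truth["spikein"] = spike_truth
        elif preset == "isoform":
            counts, iso_truth = simulate_exon_count_matrix(genes, config)
            counts_path = out_dir / "exon_counts.tsv"
            counts.to_csv(counts_path, sep="\t")
            files.append(counts_path)
            truth["isoform"] = iso_truth
    else:  # drb / fp: long genes, wave tracks per timepoint
        genes, chrom_lengths = make_wave_gene_set(config)
        gtf = out_dir / "genes.gtf"
        write_gene_annotation(genes, gtf)
        files.append(gtf)
        truth["chrom_lengths"] = chrom_lengths
        timepoints = [0, 10, 20, 30, 40]
        sim = simulate_drb_wave_tracks if preset == "drb" else simulate_fp_clearance_tracks
        tracks, wave_truth = sim(genes, chrom_lengths, config, timepoints)
        for t, track in tracks.items():
            files += [Path(p) for p in write_bedgraph(track, out_dir / f"{preset}_t{t}")]
        truth["wave"] = wave_truth
        truth["timepoints"] = timepoints

    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True, default=float) + "\n")
    files.append(truth_path)
    write_manifest(out_dir, seed, files, extra={"preset": preset})
    return truth


STAGE_ORDER = ["fixtures", "normalization", "processivity", "first_exon", "report"]


def run_pipeline(seed: int, out_dir, stages: list[str] | None = None) -> dict:
    """Run an ordered subset of the attrition/isoform demonstration pipeline.

    Stage dependencies are checked (normalization and processivity need
    fixtures; report needs at least one upstream output); outputs land in
    per-stage TSVs under ``out_dir``.
    """
    from .isoform import first_exon_enrichment, recode_first_vs_remaining, summarize_first_exon_shift
    from .normalization import median_of_ratios_size_factors
    from .pausing import processivity_table, stratified_reduction_counts

    stages = stages or STAGE_ORDER
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def _need(dep: str):
        if dep not in results and not (out_dir / dep).exists():
            raise RuntimeError(f"stage dependency not satisfied: {dep}")

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        if stage == "fixtures":
            results["fixtures"] = {
                "attrition": generate_fixtures("attrition", seed, out_dir / "fixtures"),
                "isoform": generate_fixtures("isoform", seed, out_dir / "fixtures_isoform"),
            }
        elif stage == "normalization":
            _need("fixtures")
            spike = pd.read_csv(out_dir / "fixtures" / "spikein_counts.tsv", sep="\t", index_col=0)
            sf = median_of_ratios_size_factors(spike, reference="synthetic spike-in set")
            (out_dir / "size_factors.json").write_text(
                json.dumps({"method": sf.method, "factors": sf.factors}, indent=2) + "\n"
            )
            results["normalization"] = sf
        elif stage == "processivity":
            _need("fixtures")
            fx = out_dir / "fixtures"
            truth = json.loads((fx / "truth.json").read_text())
            from .genome_model import read_gene_annotation

            genes = read_gene_annotation(fx / "genes.gtf", chromosomes=None)
            lengths = {k: int(v) for k, v in truth["chrom_lengths"].items()}
            bin_size = SyntheticConfig(seed=seed).bin_size
            ctrl = read_bedgraph(fx / "ctrl", lengths, bin_size=bin_size, label="ctrl")
            hs = read_bedgraph(fx / "hs", lengths, bin_size=bin_size, label="hs")
            table, discards = processivity_table(ctrl, hs, genes)
            strata = stratified_reduction_counts(table)
            table.to_csv(out_dir / "processivity.tsv", sep="\t", index=False)
            discards.to_csv(out_dir / "processivity_discards.tsv", sep="\t", index=False)
            strata.to_csv(out_dir / "processivity_strata.tsv", sep="\t", index=False)
            results["processivity"] = strata
        elif stage == "first_exon":
            _need("fixtures")
            counts = pd.read_csv(
                out_dir / "fixtures_isoform" / "exon_counts.tsv", sep="\t", index_col=[0, 1]
            )
            recoded = recode_first_vs_remaining(counts)
            condition = {s: ("hs" if s.startswith("hs") else "ctrl") for s in counts.columns}
            size_factors = {s: 1.0 for s in counts.columns}
            res = first_exon_enrichment(recoded, size_factors, condition,
                                        rng=np.random.default_rng(seed))
            res.to_csv(out_dir / "first_exon.tsv", sep="\t")
            results["first_exon"] = summarize_first_exon_shift(res)
        elif stage == "report":
            if not results:
                raise RuntimeError("report needs at least one upstream stage output")
            results["report"] = generate_report(results, out_dir)
    return results


def generate_report(results: dict, out_dir) -> Path:
    """Collate stage summaries into one markdown report + TSV."""
    out_dir = Path(out_dir)
    lines = ["# ttquant pipeline report", ""]
    rows = []
    if "processivity" in results:
        lines.append("## Processivity: >=1.5-fold 3'/5' reductions per width stratum")
        lines.append(results["processivity"].to_string(index=False))
        lines.append("")
        for _, r in results["processivity"].iterrows():
            rows.append(("processivity_fraction_" + r["stratum"], r["fraction"]))
    if "first_exon" in results:
        s = results["first_exon"]
        lines.append("## First-exon shift")
        lines.append(f"fraction of genes with positive logFC: {s['fraction_positive']:.3f} "
                     f"(n={s['n']}; median logFC {s['median_logfc']:.2f})")
        lines.append("")
        rows.append(("first_exon_fraction_positive", s["fraction_positive"]))
    if "fp_rates" in results:
        from .wavefront import mean_rate_one_decimal

        rates = results["fp_rates"]
        lines.append("## FP per-gene elongation rates (kb/min)")
        lines.append(", ".join(f"{r:.2f}" for r in rates)
                     + f"; mean {mean_rate_one_decimal(rates)}")
        lines.append("")
        rows.append(("fp_mean_rate_kb_min", mean_rate_one_decimal(rates)))
    if "normalization" in results:
        sf = results["normalization"]
        lines.append("## Size factors (" + sf.method + ")")
        lines.append(", ".join(f"{k}={v:.4f}" for k, v in sf.factors.items()))
        lines.append("")
        for k, v in sf.factors.items():
            rows.append((f"size_factor_{k}", v))
    md = out_dir / "report.md"
    md.write_text("\n".join(lines) + "\n")
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
        out_dir / "report.tsv", sep="\t", index=False
    )
    return md
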