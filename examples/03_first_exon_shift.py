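"""Detect the shift toward short isoforms via first-exon enrichment.

Simulates exon-level NB counts where heat shock boosts the first-exon mean
4-fold, recodes each gene into first vs remaining exon counts, and tests
the log2 ratio-of-ratios per gene with a label-permutation test.
"""

import numpy as np

from ttquant.isoform import (
    first_exon_enrichment,
    recode_first_vs_remaining,
    summarize_first_exon_shift,
)
from ttquant.synthetic_data import SyntheticConfig, make_count_gene_set, simulate_exon_count_matrix

cfg = SyntheticConfig(seed=0, first_exon_effect=4.0)
genes = make_count_gene_set(cfg, 200)
counts, truth = simulate_exon_count_matrix(genes, cfg, n_reps=3)

recoded = recode_first_vs_remaining(counts)
res = first_exon_enrichment(
    recoded,
    size_factors={s: 1.0 for s in counts.columns},
    condition=truth["condition"],
    rng=np.random.default_rng(0),
)
summary = summarize_first_exon_shift(res)
print(res.head().round(3))
print(f"\nmean logFC: {res['logfc'].mean():.2f} (true log2(theta) = {truth['log2_theta']:.1f})")
print(f"fraction of genes shifting to shorter isoforms: {summary['fraction_positive']:.2f}")
print("A positive logFC means the first exon gains share under heat shock — "
      "the signature of premature termination producing short transcripts.")
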