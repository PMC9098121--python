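"""Sequence features of premature-cleavage-prone genes and the readthrough
peptide library.

Builds genes with planted U1 5'-splice-site and PAS motifs, scores the
U1/PAS ratio (telescripting protection), and translates each gene from its
canonical ATG through intron 1 to build tryptic peptides for proteomic
matching.
"""

from ttquant.seqfeatures import gene_feature_table, peptide_library, u1_pas_ratio
from ttquant.synthetic_data import SyntheticConfig, make_gene_set

cfg = SyntheticConfig(seed=0)
genes, chrom_seqs, truth = make_gene_set(cfg)

table = gene_feature_table(genes, chrom_seqs)
print(table[["width", "n_u1", "n_pas", "u1_pas_ratio", "gc_fraction"]].head().round(3))
print("\nLow U1/PAS means few protective U1 sites per cryptic poly(A) signal: "
      "such genes are prone to premature cleavage and polyadenylation.")

atg = {g: truth["genes"][g]["atg_offset"] for g in truth["genes"]}
lib = peptide_library(genes, chrom_seqs, atg)
print(f"\npeptide library: {len(lib)} tryptic fragments (>=7 aa) "
      f"from {lib['gene_id'].nunique()} readthrough ORFs")
print(lib.head().to_string(index=False))
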