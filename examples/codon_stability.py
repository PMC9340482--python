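"""Codon stabilization coefficients on a synthetic genome.

Generates 300 genes whose content of four 'stabilizing' codons predicts
mRNA half-life (population correlation 0.7), computes the per-codon CSC
table and gene-level metrics, and profiles one gene's sliding-window CSC
against a codon-order permutation null.
"""

import numpy as np

import sacquant as sq
from sacquant.synthetic_data import gen_cds_with_planted_stability

STAB = ("GCT", "GAA", "AAG", "TTC")

genes, half_lives = gen_cds_with_planted_stability(
    n_genes=300, stabilizing_codons=STAB, planted_r=0.7, seed=42
)
table = sq.compute_csc(sq.frequency_matrix(genes), half_lives, source="synthetic")

print(f"CSC computed from {table.n_genes_used} genes")
for codon in STAB:
    print(f"  CSC({codon}) = {table[codon]:+.3f}   (planted stabilizing)")
others = table.values.drop(list(STAB)).dropna()
print(f"  mean CSC of the other codons = {others.mean():+.3f} "
      "(they anti-correlate because frequencies sum to 1)")

gm = sq.gene_metrics(genes[0], table)
print(f"\n{gm.gene_id}: CSC_g = {gm.csc_g:+.3f} over {gm.n_codons} codons")

profile = sq.permutation_null(genes[0], table, window=9, n_perm=2000, seed=7)
n_above = (profile.flags == "above").sum()
n_below = (profile.flags == "below").sum()
print(f"9-codon sliding window: {n_above} positions above and {n_below} below "
      "the 2-SD permutation band")
print("(positions outside the band mark local clusters of stabilizing or "
      "destabilizing codons)")
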