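"""Chord-PCA, Bray-Curtis PCoA, Hill diversity and UPGMA on simulated samples.

Simulates a small rearing study, computes both ordinations of the community
matrix, the effective number of phylotypes per sample (^2D), and a UPGMA
dendrogram from Bray-Curtis dissimilarities.
"""

import numpy as np

from melibiome import (
    SimulationConfig,
    bray_curtis,
    chord_transform,
    hill_diversity,
    pca,
    pcoa,
    rarefy,
    relative_abundance,
    simulate_study,
    upgma,
)

study = simulate_study(SimulationConfig(seed=4, n_caterpillars=60))
table = rarefy(study.otu_table, depth=500, seed=0).table
rel = relative_abundance(table)

pca_res = pca(chord_transform(rel), n_axes=2, sample_ids=table.sample_ids)
print("chord-PCA variance explained:", np.round(pca_res.explained, 3).tolist())

bc = bray_curtis(rel, labels=table.sample_ids)
pcoa_res = pcoa(bc, n_axes=2)
print("Bray-Curtis PCoA explained (of positive eigenvalues):",
      np.round(pcoa_res.explained, 3).tolist())
r = np.corrcoef(pca_res.scores[:, 0], pcoa_res.scores[:, 0])[0, 1]
print(f"|r| between PC1 and PCO1 scores: {abs(r):.3f}  "
      "(the two ordinations usually agree closely)")

d2 = hill_diversity(rel, q=2, sample_ids=table.sample_ids)
print(f"^2D (effective phylotypes): mean {d2.values.mean():.2f}, "
      f"range [{d2.values.min():.2f}, {d2.values.max():.2f}]")

dend = upgma(bc)
print("UPGMA root height (half the average inter-cluster Bray-Curtis):",
      round(dend.merges[-1, 2], 3))
print("newick (first 80 chars):", dend.newick[:80], "...")
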