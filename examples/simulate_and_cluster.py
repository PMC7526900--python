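"""Simulate a small single-cell Hi-C study, fit LDA, and cluster cell types.

Cells are drawn from a planted topic model (2 shared contact-decay topics
plus 2 specific topics for each of 3 cell types), converted to a binarized
cell-by-locus-pair matrix, and decomposed by collapsed Gibbs sampling.  The
normalized cell-topic matrix is then embedded in 2-D and scored by the
silhouette of the true cell-type labels.
"""

import warnings

import numpy as np

import hictopics as ht
from hictopics import synthdata as sd

truth, cells, labels = sd.default_study(seed=1)
print(f"simulated {len(cells)} cells over {len(truth.vocab)} locus pairs, "
      f"{truth.topics.shape[0]} planted topics")

mat, report = ht.build_cell_lp_matrix(cells, truth.vocab, truth.bins)
print(f"matrix {mat.matrix.shape[0]} x {mat.matrix.shape[1]}, "
      f"mean {mat.token_counts().mean():.0f} distinct LPs per cell, "
      f"capture {report.capture_fraction:.2f} of cis contacts")

model = ht.train_lda(mat, n_topics=8, alpha=1.0, seed=7, init="kmeans")
print(f"LDA trained: final log-likelihood {model.loglik_trace[-1]:,.0f}")

# which topics mark which cell types? (one-sided rank-sum + BH + ratio filter)
asg = ht.assign_topics_to_cell_types(
    ht.normalize_cell_topics(model.C_ct), [labels[c] for c in model.cell_ids]
)
print("cell-type-specific topics:", asg.assigned())

# embed and evaluate cluster separation by cell type
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    emb = ht.embed_2d(
        model.C_ct / model.C_ct.sum(axis=1, keepdims=True), "umap", seed=3
    )
sil = ht.silhouette(emb, [labels[c] for c in model.cell_ids])
print(f"average silhouette over cell types: {sil.overall:.2f}")
for ct, s in sil.per_type.items():
    print(f"  {ct}: {s:.2f}")
# values near 1 mean cells of a type sit in a tight, isolated cluster;
# near 0 means overlapping clusters
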