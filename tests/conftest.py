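"""Shared fixtures: the default synthetic study and a trained model.

The study is generated once per session at its default scale (3 cell types
x 100 cells, V = 4380) and the LDA model trained once; recovery,
clustering, and enrichment tests all read from these.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import hictopics as ht
from hictopics import synthdata as sd

STUDY_SEED = 0
TRAIN_SEED = 7


@pytest.fixture(scope="session")
def study():
    """Default synthetic study plus its binarized cell-LP matrix."""
    truth, cells, labels = sd.default_study(seed=STUDY_SEED)
    mat, report = ht.build_cell_lp_matrix(cells, truth.vocab, truth.bins)
    return truth, cells, labels, mat, report


@pytest.fixture(scope="session")
def study_model(study):
    """LDA fit of the default study at the planted T with the recovery
    protocol (sparse-mixture prior, cluster-informed chain start,
    post-burn-in averaging)."""
    truth, cells, labels, mat, _ = study
    return ht.train_lda(
        mat,
        truth.topics.shape[0],
        alpha=1.0,
        seed=TRAIN_SEED,
        average=True,
        init="kmeans",
    )


@pytest.fixture(scope="session")
def study_umap(study, study_model):
    """2-D UMAP embedding of the study's normalized cell-topic matrix."""
    model = study_model
    norm = model.C_ct / model.C_ct.sum(axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ht.embed_2d(norm, "umap", seed=3)


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-chromosome genome (V = 690) for cheap unit tests."""
    return sd.make_toy_genome(2, 20_000_000, 500_000, 5_000_000)
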