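"""Shared fixtures: planted corpora, fitted models, and a hand-built
three-level model whose usage distributions are computable by hand."""

from __future__ import annotations

import numpy as np
import pytest

import domainmap as dm
from domainmap.sbm_inference import (
    DomainTopicModel,
    FitConfig,
    NestedPartition,
    description_length,
)


def make_planted_doc_model(graph, truth, n_domains=3, n_topics=4
                           ) -> DomainTopicModel:
    """Wrap the planted ground-truth assignment as a two-level model."""
    b0 = np.empty(graph.n_nodes, dtype=np.int64)
    b0[:graph.n_left] = truth.doc_domain
    b0[graph.n_left:] = n_domains + truth.term_topic
    top = np.zeros(n_domains + n_topics, dtype=np.int64)
    top[n_domains:] = 1
    part = NestedPartition([b0, top])
    return DomainTopicModel(graph, part, FitConfig(),
                            description_length(graph, part))


@pytest.fixture(scope="session")
def planted():
    """Strong-signal benchmark corpus (300 docs, 60 terms, 3x4 blocks)."""
    corpus, truth = dm.generate(dm.PlantedSpec(seed=1))
    graph = dm.build_doc_term_graph(corpus)
    return corpus, truth, graph


@pytest.fixture(scope="session")
def planted_model(planted):
    _, _, graph = planted
    return dm.fit(graph, dm.FitConfig(seed=5, n_restarts=2))


@pytest.fixture(scope="session")
def toy_model():
    """Three-level model with hand-computable usage distributions.

    Documents: d0 = {a1, a2, x1, x2}, d1 = {x3..x6}, d2 = {y1..y8}.
    Level 1: each document its own domain; topics A = {a1, a2} and
    B = everything else. Level 2 groups {d0, d1}; level 3 is the top.
    p(A|d0) = 1/2, p(A|{d0,d1}) = 1/4, p(A|top) = 1/8.
    """
    docs = [
        dm.Document("d0", ["a1", "a2", "x1", "x2"]),
        dm.Document("d1", ["x3", "x4", "x5", "x6"]),
        dm.Document("d2", [f"y{i}" for i in range(1, 9)]),
    ]
    graph = dm.build_doc_term_graph(dm.Corpus(docs))
    b0 = np.empty(graph.n_nodes, dtype=np.int64)
    b0[:3] = [0, 1, 2]
    for j, t in enumerate(graph.right_labels):
        b0[3 + j] = 3 if t.startswith("a") else 4
    l2 = np.array([0, 0, 1, 2, 2])
    l3 = np.array([0, 0, 1])
    part = NestedPartition([b0, l2, l3])
    return DomainTopicModel(graph, part, FitConfig(),
                            description_length(graph, part))


@pytest.fixture(scope="session")
def drift_chained():
    """Year-drift corpus chained against its planted document hierarchy."""
    spec = dm.year_drift_spec(seed=2024)
    corpus, truth = dm.generate(spec)
    graph = dm.build_doc_term_graph(corpus)
    doc_model = make_planted_doc_model(graph, truth)
    meta_graph = dm.build_doc_metadata_graph(corpus, "year")
    chained = dm.fit_chained(meta_graph, doc_model,
                             dm.FitConfig(seed=11, n_restarts=2))
    return corpus, truth, doc_model, chained
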