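"""Inference engine: description length, fitting, refinement."""

import itertools
import json
import math

import numpy as np
import pytest

import domainmap as dm
from domainmap.sbm_inference import (
    DomainTopicModel,
    NestedPartition,
    description_length,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def set_partitions(n):
    """All partitions of range(n), as assignment arrays."""
    def rec(i, assign, nb):
        if i == n:
            yield np.array(assign, dtype=np.int64)
            return
        for b in range(nb):
            yield from rec(i + 1, assign + [b], nb)
        yield from rec(i + 1, assign + [nb], nb + 1)
    yield from rec(0, [], 0)


def flat_partition(graph, bl, br):
    D = int(bl.max()) + 1
    b0 = np.concatenate([bl, D + br])
    top = np.zeros(D + int(br.max()) + 1, dtype=np.int64)
    top[D:] = 1
    return NestedPartition([b0, top])


def exhaustive_flat_min(graph):
    """Exact minimum DL over every type-pure flat partition."""
    best = np.inf
    best_part = None
    for bl in set_partitions(graph.n_left):
        for br in set_partitions(graph.n_right):
            part = flat_partition(graph, bl, br)
            dl = description_length(graph, part).total
            if dl < best:
                best, best_part = dl, part
    return best, best_part


def hand_flat_dl(graph, bl, br):
    """Direct transcription of the flat DL formula with math.lgamma.

    Likelihood ln prod e_r! - ln prod e_rs! - ln prod k_i!, degree prior
    sum_r ln multiset(n_r, e_r), per-type partition prior, and the
    single-level edge-matrix closure ln multiset(B_d * B_t, E).
    """
    lf = lambda x: math.lgamma(x + 1)

    def lbin(n, k):
        return lf(n) - lf(k) - lf(n - k)

    def lms(n, m):
        return lbin(n + m - 1, m) if n > 0 else 0.0

    nl = graph.n_left
    D, T = int(bl.max()) + 1, int(br.max()) + 1
    e = [[0] * T for _ in range(D)]
    for u, v in graph.edges:
        e[bl[u]][br[v - nl]] += 1
    e_rd = [sum(e[r]) for r in range(D)]
    e_rt = [sum(e[r][s] for r in range(D)) for s in range(T)]
    k = graph.degrees()
    s = sum(lf(x) for x in e_rd) + sum(lf(x) for x in e_rt)
    s -= sum(lf(e[r][t]) for r in range(D) for t in range(T))
    s -= sum(lf(int(x)) for x in k)
    n_rd = [int(np.sum(bl == r)) for r in range(D)]
    n_rt = [int(np.sum(br == t)) for t in range(T)]
    s += sum(lms(n, m) for n, m in zip(n_rd, e_rd))
    s += sum(lms(n, m) for n, m in zip(n_rt, e_rt))
    for n_obj, B, sizes in ((nl, D, n_rd), (graph.n_right, T, n_rt)):
        s += lbin(n_obj - 1, B - 1) + lf(n_obj) - sum(lf(x) for x in sizes)
    s += lms(D * T, graph.n_edges)
    return s


def random_bipartite(rng, nl, nr, p=0.5):
    while True:
        mask = rng.random((nl, nr)) < p
        if mask.sum() > 0 and mask.any(axis=1).all():
            break
    edges = np.argwhere(mask)
    edges[:, 1] += nl
    return dm.BipartiteGraph([f"d{i}" for i in range(nl)],
                             [f"t{i}" for i in range(nr)], edges)


# ---------------------------------------------------------------------------
# Description length
# ---------------------------------------------------------------------------

class TestDescriptionLength:
    def test_matches_hand_transcription(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            g = random_bipartite(rng, 5, 4)
            for bl, br in [(np.array([0, 0, 1, 1, 2]),
                            np.array([0, 1, 1, 0])),
                           (np.array([0, 1, 0, 1, 0]),
                            np.array([0, 0, 0, 0]))]:
                part = flat_partition(g, bl, br)
                assert description_length(g, part).total == pytest.approx(
                    hand_flat_dl(g, bl, br), abs=1e-9)

    def test_label_invariance(self):
        rng = np.random.default_rng(3)
        g = random_bipartite(rng, 6, 5)
        bl = np.array([0, 1, 0, 2, 1, 0])
        br = np.array([0, 1, 1, 0, 2])
        dl1 = description_length(g, flat_partition(g, bl, br)).total
        # relabel blocks: 0<->2 on the left, 0<->1 on the right
        perm_l = np.array([2, 1, 0])
        perm_r = np.array([1, 0, 2])
        dl2 = description_length(
            g, flat_partition(g, perm_l[bl], perm_r[br])).total
        assert dl1 == pytest.approx(dl2, abs=1e-9)

    def test_components_sum_to_total(self):
        rng = np.random.default_rng(5)
        g = random_bipartite(rng, 5, 5)
        dl = description_length(
            g, flat_partition(g, np.array([0, 0, 1, 1, 1]),
                              np.array([0, 1, 0, 1, 1])))
        assert dl.total == pytest.approx(
            dl.graph_likelihood + dl.degree_sequence
            + sum(dl.partition_levels) + sum(dl.edge_matrix_levels))

    def test_planted_beats_single_block(self):
        rng = np.random.default_rng(1)
        # 8 docs, 8 terms in 2x2 planted blocks, within 0.9 / cross 0.05
        probs = np.where(
            (np.arange(8)[:, None] < 4) == (np.arange(8)[None, :] < 4),
            0.9, 0.05)
        mask = rng.random((8, 8)) < probs
        mask[~mask.any(axis=1), 0] = True
        edges = np.argwhere(mask)
        edges[:, 1] += 8
        g = dm.BipartiteGraph([f"d{i}" for i in range(8)],
                              [f"t{i}" for i in range(8)], edges)
        planted = flat_partition(
            g, (np.arange(8) >= 4).astype(np.int64),
            (np.arange(8) >= 4).astype(np.int64))
        single = flat_partition(g, np.zeros(8, dtype=np.int64),
                                np.zeros(8, dtype=np.int64))
        assert description_length(g, planted).total < \
            description_length(g, single).total

    def test_mismatched_partition_errors(self):
        g = random_bipartite(np.random.default_rng(0), 4, 4)
        with pytest.raises(ValueError):
            description_length(
                g, NestedPartition([np.zeros(5, dtype=np.int64)]))

    def test_mixed_type_block_errors(self):
        g = random_bipartite(np.random.default_rng(0), 3, 3)
        b0 = np.array([0, 0, 1, 1, 2, 2])  # block 1 mixes doc and term
        with pytest.raises(ValueError, match="mixes"):
            description_length(g, NestedPartition([b0, np.array([0, 1, 1])]))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class TestFit:
    def test_degenerate_single_pair(self):
        g = dm.BipartiteGraph(["d0"], ["t0"], np.array([[0, 1]]))
        m = dm.fit(g, dm.FitConfig(seed=0, n_restarts=1))
        assert m.n_levels == 1
        assert m.n_side_blocks("doc", 1) == 1
        assert m.n_side_blocks("right", 1) == 1

    def test_empty_graph_errors(self):
        g = dm.BipartiteGraph([], [], np.zeros((0, 2)))
        with pytest.raises(ValueError):
            dm.fit(g)

    def test_attains_exhaustive_minimum(self):
        g = random_bipartite(np.random.default_rng(17), 4, 3)
        oracle, _ = exhaustive_flat_min(g)
        m = dm.fit(g, dm.FitConfig(seed=0, n_restarts=8))
        assert m.dl.total == pytest.approx(oracle, abs=1e-9)

    def test_planted_recovery_single_seed(self, planted, planted_model):
        from sklearn.metrics import adjusted_rand_score

        _, truth, _ = planted
        ari_d = adjusted_rand_score(truth.doc_domain,
                                    planted_model.side_assignment("doc", 1))
        ari_t = adjusted_rand_score(truth.term_topic,
                                    planted_model.side_assignment("right", 1))
        assert ari_d >= 0.95
        assert ari_t >= 0.95

    def test_partition_validates_and_is_type_pure(self, planted_model):
        planted_model.partition.validate(planted_model.graph)
        btypes = planted_model.partition.block_types(
            planted_model.graph.node_type())
        for bt in btypes:
            assert set(bt) <= {0, 1}

    def test_dl_consistent_with_recompute(self, planted_model):
        dl = description_length(planted_model.graph, planted_model.partition)
        assert dl.total == pytest.approx(planted_model.dl.total, abs=1e-8)

    def test_seed_reproducible(self):
        corpus, _ = dm.generate(dm.PlantedSpec(n_docs=60, n_terms=24,
                                               n_domains=2, n_topics=2,
                                               mean_terms=10, seed=7))
        g = dm.build_doc_term_graph(corpus)
        cfg = dm.FitConfig(seed=13, n_restarts=2)
        m1 = dm.fit(g, cfg)
        m2 = dm.fit(g, cfg)
        assert m1.to_json() == m2.to_json()

    def test_duplicate_document_robustness(self):
        """Duplicating an existing document never adds more than one
        level-1 domain."""
        corpus, _ = dm.generate(dm.PlantedSpec(n_docs=90, n_terms=30,
                                               n_domains=3, n_topics=3,
                                               mean_terms=12, seed=21))
        g = dm.build_doc_term_graph(corpus)
        base = dm.fit(g, dm.FitConfig(seed=2, n_restarts=2))
        docs = corpus.documents + [
            dm.Document("dup", list(corpus.documents[0].tokens))]
        g2 = dm.build_doc_term_graph(dm.Corpus(docs))
        again = dm.fit(g2, dm.FitConfig(seed=2, n_restarts=2))
        assert again.n_side_blocks("doc", 1) <= \
            base.n_side_blocks("doc", 1) + 1


class TestRefine:
    def test_monotone(self, planted, planted_model):
        _, _, g = planted
        refined = dm.refine(planted_model,
                            dm.FitConfig(seed=99, n_restarts=1, sweeps=3))
        assert refined.dl.total <= planted_model.dl.total + 1e-9

    def test_zero_sweeps_is_identity(self, planted_model):
        refined = dm.refine(planted_model,
                            dm.FitConfig(seed=0, n_restarts=1, sweeps=0))
        assert refined is planted_model

    def test_optimum_is_fixed_point(self):
        g = random_bipartite(np.random.default_rng(23), 4, 4)
        oracle, _ = exhaustive_flat_min(g)
        m = dm.fit(g, dm.FitConfig(seed=1, n_restarts=8))
        assert m.dl.total == pytest.approx(oracle, abs=1e-9)
        refined = dm.refine(m, dm.FitConfig(seed=7, n_restarts=1, sweeps=5))
        assert refined.dl.total == pytest.approx(oracle, abs=1e-9)


class TestSerialization:
    def test_roundtrip(self, planted_model, tmp_path):
        path = str(tmp_path / "model.json")
        planted_model.save(path)
        loaded = DomainTopicModel.load(path)
        assert loaded.to_json() == planted_model.to_json()
        assert np.array_equal(loaded.side_assignment("doc", 1),
                              planted_model.side_assignment("doc", 1))

    def test_json_contains_components(self, planted_model):
        d = json.loads(planted_model.to_json())
        assert d["format"] == "domainmap-model/1"
        assert "description_length" in d and "levels" in d
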