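"""Domain-chained models: clustering metadata against frozen domains.

A chained model takes the document hierarchy inferred by a domain-topic
model, transposes it onto a document-metadata bipartite graph (documents
linked to, e.g., their publication year) and keeps it immutable at every
level; only the metadata nodes are partitioned, by the same MDL objective.
Year blocks obtained this way are called periods; their chronological
contiguity is emergent, never enforced. Metadata values are treated as
categorical. The metadata hierarchy has the same depth as the document
hierarchy, with collapsed (single-block) levels allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_prep import BipartiteGraph
from .sbm_inference import (
    BlockModel,
    DomainTopicModel,
    FitConfig,
    NestedPartition,
    _BaseState,
    _descend,
    _grow_hierarchy,
    _polish,
    description_length,
)


class ChainedModel(BlockModel):
    """A metadata graph co-blocked with a frozen document hierarchy.

    The document side reproduces the source domain-topic model's blocks at
    every level (restricted to the documents present in the metadata graph);
    ``doc_block_origin[l]`` maps this model's level-(l+1) document block
    indices back to the source model's within-side domain indices.
    """

    kind = "chained"

    def __init__(self, graph, partition, config, dl,
                 doc_block_origin: list[np.ndarray],
                 doc_chains: np.ndarray):
        super().__init__(graph, partition, config, dl)
        self.doc_block_origin = [np.asarray(a, dtype=np.int64)
                                 for a in doc_block_origin]
        self.doc_chains = np.asarray(doc_chains, dtype=np.int64)

    def docs_in_source_domain(self, level: int, index: int) -> np.ndarray:
        """Mask over this graph's documents for a source-model domain."""
        return self.doc_chains[:, level - 1] == index

    def docs_in_period(self, level: int, index: int) -> np.ndarray:
        """Mask over this graph's documents linked to metadata block
        ``index`` at ``level`` (within the metadata side)."""
        a = self.side_assignment("right", level)
        g = self.graph
        mask = np.zeros(g.n_left, dtype=bool)
        sel = a[g.edges[:, 1] - g.n_left] == index
        mask[g.edges[sel, 0]] = True
        return mask

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["doc_block_origin"] = [a.tolist() for a in self.doc_block_origin]
        d["doc_chains"] = self.doc_chains.tolist()
        return d

    @classmethod
    def load(cls, path: str) -> "ChainedModel":
        import json

        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("format") != cls.FORMAT or d.get("kind") != "chained":
            raise ValueError("not a chained model file")
        g = d["graph"]
        graph = BipartiteGraph(g["left_labels"], g["right_labels"],
                               np.array(g["edges"], dtype=np.int64)
                               .reshape(-1, 2), right_type=g["right_type"])
        partition = NestedPartition([np.array(l, dtype=np.int64)
                                     for l in d["levels"]])
        config = FitConfig.from_dict(d["config"])
        from .sbm_inference import DescriptionLength

        dlc = d["description_length"]
        dl = DescriptionLength(dlc["total"], dlc["graph_likelihood"],
                               dlc["degree_sequence"], dlc["partition_levels"],
                               dlc["edge_matrix_levels"])
        return cls(graph, partition, config, dl,
                   [np.array(a, dtype=np.int64)
                    for a in d["doc_block_origin"]],
                   np.array(d["doc_chains"], dtype=np.int64))


def _frozen_doc_structure(doc_model: DomainTopicModel, left_labels: list[str]
                          ) -> tuple[np.ndarray, list[np.ndarray],
                                     list[np.ndarray], np.ndarray]:
    """Restrict the source document hierarchy to ``left_labels``.

    Returns the level-1 frozen assignment (contiguous ids), the per-level
    parent maps imposed on the document side, the per-level origin arrays
    (chained block -> source within-side index), and the full per-document
    chain of source indices.
    """
    index = {lab: i for i, lab in enumerate(doc_model.graph.left_labels)}
    try:
        rows = np.array([index[lab] for lab in left_labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"document {exc.args[0]!r} not in the domain-topic "
                         "model") from None
    M = doc_model.n_levels
    chains = np.empty((len(rows), M), dtype=np.int64)
    for lev in range(1, M + 1):
        chains[:, lev - 1] = doc_model.side_assignment("doc", lev)[rows]
    origins: list[np.ndarray] = []
    remaps: list[dict] = []
    for lev in range(M):
        present = np.unique(chains[:, lev])
        origins.append(present)
        remaps.append({int(o): j for j, o in enumerate(present)})
    b0 = np.array([remaps[0][int(c)] for c in chains[:, 0]], dtype=np.int64)
    parent_maps: list[np.ndarray] = []
    for lev in range(1, M):
        pm_src = doc_model.parent_map("doc", lev)
        pm = np.array([remaps[lev][int(pm_src[int(o)])]
                       for o in origins[lev - 1]], dtype=np.int64)
        parent_maps.append(pm)
    return b0, parent_maps, origins, chains


def fit_chained(
    graph: BipartiteGraph,
    doc_model: DomainTopicModel,
    config: FitConfig | None = None,
) -> ChainedModel:
    """Fit a metadata partition against the frozen document hierarchy.

    Every document of ``graph`` must appear in ``doc_model`` (unknown
    documents are an error). Document blocks are held immutable at all
    levels and contribute no partition cost; only the metadata side is
    clustered, to the same depth as the document hierarchy, allowing
    collapsed levels.
    """
    if config is None:
        config = FitConfig()
    if graph.n_edges == 0:
        raise ValueError("cannot chain an empty graph")
    b0_doc, parent_maps, origins, chains = _frozen_doc_structure(
        doc_model, graph.left_labels)

    master = np.random.default_rng(config.seed)
    best = None
    for _ in range(config.n_restarts):
        rng = np.random.default_rng(int(master.integers(2 ** 31)))
        state = _BaseState(graph, frozen_b=b0_doc)
        b_flat, dl_flat = _descend(state, config, rng)
        state.b[:] = b_flat
        state._rebuild()
        _polish(state, config, rng)
        if state.flat_dl() < dl_flat - 1e-9:
            b_flat = state.compact_assignment()
        levels = _grow_hierarchy(graph, b_flat, config, rng,
                                 frozen_parent_maps=parent_maps)
        partition = NestedPartition(levels)
        dl = description_length(graph, partition, frozen_types=(0,))
        if best is None or dl.total < best[1].total - 1e-9:
            best = (partition, dl)
    return ChainedModel(graph, best[0], config, best[1], origins, chains)


# ---------------------------------------------------------------------------
# Period summaries
# ---------------------------------------------------------------------------

@dataclass
class PeriodSummary:
    """Ordered listing of metadata blocks per level with contiguity flags."""

    table: pd.DataFrame
    highest_distinguishing_level: int


def _sort_key(label: str):
    try:
        return (0, float(label))
    except ValueError:
        return (1, label)


def period_summary(chained: ChainedModel) -> PeriodSummary:
    """List metadata blocks per level with their member values.

    Members are sorted (numerically when possible); a block is flagged
    chronologically contiguous when its members form an unbroken interval of
    the observed value sequence. Also reports the highest level at which the
    metadata side still distinguishes more than one block (levels above are
    collapsed, hence equivalent).
    """
    labels = chained.graph.right_labels
    order = sorted(range(len(labels)), key=lambda i: _sort_key(labels[i]))
    pos = {i: p for p, i in enumerate(order)}
    rows = []
    highest = 1
    for level in range(1, chained.n_levels + 1):
        a = chained.side_assignment("right", level)
        nb = chained.n_side_blocks("right", level)
        if nb > 1:
            highest = level
        blocks = [np.flatnonzero(a == j) for j in range(nb)]
        blocks.sort(key=lambda idx: min(pos[int(i)] for i in idx))
        for j, idx in enumerate(blocks):
            positions = sorted(pos[int(i)] for i in idx)
            contiguous = positions == list(range(positions[0],
                                                 positions[-1] + 1))
            members = sorted((labels[int(i)] for i in idx), key=_sort_key)
            rows.append({"level": level, "period": j, "members": members,
                         "contiguous": bool(contiguous)})
    return PeriodSummary(pd.DataFrame(rows), highest)


def domain_document_ids(model: DomainTopicModel, level: int, index: int
                        ) -> list[str]:
    """Document ids of one domain — the sub-corpus selector used to re-chain
    a restricted document set (e.g., periods or countries of one domain)."""
    a = model.side_assignment("doc", level)
    return [model.graph.left_labels[i] for i in np.flatnonzero(a == index)]
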