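"""Nested degree-corrected stochastic block model inference by MDL.

Fits a nested, degree-corrected, non-overlapping stochastic block model to a
bipartite document-term graph by minimizing the total description length
(DL): the information cost of the graph given the model plus the cost of the
partitions and parameters. Blocks are constrained to be type-pure, so the fit
simultaneously yields a hierarchy of domains (document blocks) and topics
(term blocks). Both the number of blocks per level and the number of levels
are inferred; the search returns the single best-known fit.

Description length variant
--------------------------
All quantities are in nats. For the base level the microcanonical
degree-corrected likelihood of a simple graph is used,

    -ln P(A | k, e, b) = sum_r ln e_r! - sum_{r<s} ln e_rs!
                         - sum_r ln e_rr!! - sum_i ln k_i!,

(the within-block double-factorial term vanishes for type-pure bipartite
partitions). Degrees are encoded by a uniform prior over degree sequences
compatible with the block degree totals, sum_r ln multiset(n_r, e_r) with
multiset(n, m) = C(n+m-1, m). Each level's partition costs, per node type,
ln C(n-1, B-1) + ln n! - sum_r ln n_r!. The level-l block multigraph is
itself modeled by a (non-degree-corrected) SBM at level l+1: its edge matrix
costs sum_{r<s} ln multiset(n_r n_s, e_rs) over block pairs of the level
above, closing at the top with the single-block-per-type multigraph cost.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln

from .corpus_prep import BipartiteGraph

logger = logging.getLogger("domainmap")

_EPS = 1e-9


def _lnfact(x) -> np.ndarray:
    return gammaln(np.asarray(x, dtype=np.float64) + 1.0)


def _lnbinom(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _lnmultiset(n, m):
    """ln of the number of multisets of size m from n elements, C(n+m-1, m)."""
    n = np.asarray(n, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    out = np.where(n > 0, _lnbinom(np.maximum(n + m - 1.0, 0.0), m), 0.0)
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Search parameters for the MDL fit.

    seed fixes the full random stream; n_restarts independent agglomerative
    runs are performed and the best final state kept. sigma is the shrink
    factor of the agglomerative schedule (block count divided by sigma per
    round), sweeps the number of single-node move sweeps per round. beta is
    the inverse temperature of the move-acceptance rule: infinite beta (the
    default) always takes the best candidate move, finite beta samples
    candidates proportionally to exp(-beta * dDL). max_levels caps hierarchy
    depth.
    """

    seed: int = 0
    n_restarts: int = 3
    sweeps: int = 5
    sigma: float = 1.5
    beta: float = float("inf")
    max_levels: int = 10

    def __post_init__(self) -> None:
        if self.n_restarts < 1 or self.sweeps < 0 or self.max_levels < 1:
            raise ValueError("n_restarts, max_levels must be >= 1; sweeps >= 0")
        if self.sigma <= 1.0:
            raise ValueError("sigma must be > 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = "inf" if np.isinf(self.beta) else self.beta
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        if d.get("beta") == "inf":
            d["beta"] = float("inf")
        return cls(**d)


# ---------------------------------------------------------------------------
# Nested partitions
# ---------------------------------------------------------------------------

class NestedPartition:
    """A nesting-consistent, type-pure hierarchy of block assignments.

    ``levels[0]`` maps each graph node to its level-1 block; ``levels[j]``
    for ``j >= 1`` maps level-j blocks to level-(j+1) blocks. The image of
    the last map has exactly one block per node type (the top level). Block
    ids are contiguous per level, document blocks first.
    """

    def __init__(self, levels: list[np.ndarray]):
        if not levels:
            raise ValueError("empty partition")
        self.levels = [np.asarray(l, dtype=np.int64) for l in levels]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def n_blocks(self, level: int) -> int:
        """Total blocks (both types) at 1-based ``level``."""
        return int(self.levels[level - 1].max()) + 1

    def assignment(self, level: int) -> np.ndarray:
        """Composed node -> level-``level`` block assignment (1-based level)."""
        a = self.levels[0]
        for j in range(1, level):
            a = self.levels[j][a]
        return a

    def block_types(self, node_types: np.ndarray) -> list[np.ndarray]:
        """Per-level array of block types (0 = document side)."""
        out = []
        t = node_types.astype(np.int64)
        for lev in self.levels:
            bt = np.full(int(lev.max()) + 1, -1, dtype=np.int64)
            for blk, typ in zip(lev, t):
                if bt[blk] == -1:
                    bt[blk] = typ
                elif bt[blk] != typ:
                    raise ValueError("block mixes node types")
            t = bt
            out.append(bt)
        return out

    def validate(self, graph: BipartiteGraph) -> None:
        if len(self.levels[0]) != graph.n_nodes:
            raise ValueError("partition does not match graph size")
        for j in range(1, len(self.levels)):
            if len(self.levels[j]) != int(self.levels[j - 1].max()) + 1:
                raise ValueError(f"level {j + 1} does not nest level {j}")
        bt = self.block_types(graph.node_type())
        top = bt[-1]
        if not (np.sum(top == 0) == 1 and np.sum(top == 1) == 1):
            raise ValueError("top level must have exactly one block per type")

    def canonicalized(self, node_types: np.ndarray) -> "NestedPartition":
        """Relabel blocks per level: document blocks first, then by first
        occurrence in node order. Description length is label-invariant."""
        return _canonicalize(self, node_types)

    def copy(self) -> "NestedPartition":
        return NestedPartition([l.copy() for l in self.levels])


def _canonicalize(partition: NestedPartition, node_types: np.ndarray
                  ) -> NestedPartition:
    tvec = node_types.astype(np.int64)
    new_levels: list[np.ndarray] = []
    # remap level by level, propagating the relabeling downward
    remap_prev: np.ndarray | None = None
    cur_types = tvec
    for j, lev in enumerate(partition.levels):
        lev = lev.copy() if remap_prev is None else lev[_inverse_perm(remap_prev)]
        nb = int(lev.max()) + 1
        # order: type of block, then first occurrence among objects
        first = np.full(nb, np.iinfo(np.int64).max, dtype=np.int64)
        btyp = np.zeros(nb, dtype=np.int64)
        for idx, blk in enumerate(lev):
            if first[blk] == np.iinfo(np.int64).max:
                first[blk] = idx
                btyp[blk] = cur_types[idx]
        order = np.lexsort((first, btyp))
        remap = np.empty(nb, dtype=np.int64)
        remap[order] = np.arange(nb)
        new_levels.append(remap[lev])
        remap_prev = remap
        cur_types = btyp[order]
    return NestedPartition(new_levels)


def _inverse_perm(remap: np.ndarray) -> np.ndarray:
    inv = np.empty_like(remap)
    inv[remap] = np.arange(len(remap))
    return inv


# ---------------------------------------------------------------------------
# Description length
# ---------------------------------------------------------------------------

@dataclass
class DescriptionLength:
    """Total nested DL in nats and its additive components."""

    total: float
    graph_likelihood: float
    degree_sequence: float
    partition_levels: list[float]
    edge_matrix_levels: list[float]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BlockState:
    """Summary statistics of one level of a blocked graph."""

    e_rs: np.ndarray   # cross-type block edge counts (doc rows, term cols)
    e_r_doc: np.ndarray
    e_r_term: np.ndarray
    n_r_doc: np.ndarray
    n_r_term: np.ndarray


def _level_matrices(graph: BipartiteGraph, partition: NestedPartition
                    ) -> list[dict]:
    """Per level: cross-type edge-count matrix with per-type reindex maps."""
    tvec = graph.node_type()
    btypes = partition.block_types(tvec)
    out = []
    for level in range(1, partition.n_levels + 1):
        a = partition.assignment(level)
        bt = btypes[level - 1]
        doc_ids = np.flatnonzero(bt == 0)
        term_ids = np.flatnonzero(bt == 1)
        dmap = np.full(len(bt), -1, dtype=np.int64)
        dmap[doc_ids] = np.arange(len(doc_ids))
        tmap = np.full(len(bt), -1, dtype=np.int64)
        tmap[term_ids] = np.arange(len(term_ids))
        mat = np.zeros((len(doc_ids), len(term_ids)), dtype=np.int64)
        u = dmap[a[graph.edges[:, 0]]]
        v = tmap[a[graph.edges[:, 1]]]
        np.add.at(mat, (u, v), 1)
        sizes = np.bincount(partition.levels[level - 1],
                            minlength=len(bt)).astype(np.int64) \
            if level > 1 else np.bincount(partition.levels[0],
                                          minlength=len(bt)).astype(np.int64)
        out.append({
            "mat": mat, "doc_ids": doc_ids, "term_ids": term_ids,
            "sizes_doc": sizes[doc_ids], "sizes_term": sizes[term_ids],
            "bt": bt,
        })
    return out


def description_length(
    graph: BipartiteGraph,
    partition: NestedPartition,
    frozen_types: tuple[int, ...] = (),
) -> DescriptionLength:
    """Exact nested DC-SBM description length of ``partition`` for ``graph``.

    ``frozen_types`` lists node types whose partition is conditioned upon
    rather than inferred (used by chained models); those types contribute no
    partition cost. Deterministic and invariant under block relabeling.
    """
    partition.validate(graph)
    k = graph.degrees()
    E = graph.n_edges
    tvec = graph.node_type()
    infos = _level_matrices(graph, partition)

    m1 = infos[0]["mat"]
    e_r_doc = m1.sum(axis=1)
    e_r_term = m1.sum(axis=0)
    s_lik = float(
        _lnfact(e_r_doc).sum() + _lnfact(e_r_term).sum()
        - _lnfact(m1).sum() - _lnfact(k).sum()
    )
    n_r_doc = infos[0]["sizes_doc"]
    n_r_term = infos[0]["sizes_term"]
    s_deg = float(_lnmultiset(n_r_doc, e_r_doc).sum()
                  + _lnmultiset(n_r_term, e_r_term).sum())

    s_part_levels: list[float] = []
    for level in range(1, partition.n_levels + 1):
        info = infos[level - 1]
        if level == 1:
            n_doc = int(np.sum(tvec == 0))
            n_term = int(np.sum(tvec == 1))
        else:
            prev = infos[level - 2]
            n_doc = len(prev["doc_ids"])
            n_term = len(prev["term_ids"])
        s = 0.0
        for typ, n_obj, sizes in ((0, n_doc, info["sizes_doc"]),
                                  (1, n_term, info["sizes_term"])):
            if typ in frozen_types:
                continue
            B = len(sizes)
            s += float(_lnbinom(n_obj - 1, B - 1) + _lnfact(n_obj)
                       - _lnfact(sizes).sum())
        s_part_levels.append(s)

    s_mat_levels: list[float] = []
    for level in range(1, partition.n_levels):
        lower = infos[level - 1]
        upper_map = partition.levels[level]
        bt_lower = lower["bt"]
        up_doc = upper_map[lower["doc_ids"]]
        up_term = upper_map[lower["term_ids"]]
        upper = infos[level]
        dmap = np.full(int(upper_map.max()) + 1, -1, dtype=np.int64)
        dmap[upper["doc_ids"]] = np.arange(len(upper["doc_ids"]))
        tmap = np.full(int(upper_map.max()) + 1, -1, dtype=np.int64)
        tmap[upper["term_ids"]] = np.arange(len(upper["term_ids"]))
        W = np.zeros((len(upper["doc_ids"]), len(upper["term_ids"])),
                     dtype=np.int64)
        rows = dmap[up_doc]
        np.add.at(W, (rows[:, None].repeat(len(up_term), 1),
                      tmap[up_term][None, :].repeat(len(up_doc), 0)),
                  lower["mat"])
        nL = np.bincount(dmap[up_doc], minlength=W.shape[0])
        nR = np.bincount(tmap[up_term], minlength=W.shape[1])
        s_mat_levels.append(float(
            _lnmultiset(nL[:, None] * nR[None, :], W).sum()))
    # top closure: the top-level 1x1 cross matrix holds E edges; its multiset
    # cost ln multiset(1, E) is zero, so nothing further is added.
    total = s_lik + s_deg + sum(s_part_levels) + sum(s_mat_levels)
    return DescriptionLength(total, s_lik, s_deg, s_part_levels, s_mat_levels)


def block_state(graph: BipartiteGraph, partition: NestedPartition,
                level: int = 1) -> BlockState:
    info = _level_matrices(graph, partition)[level - 1]
    m = info["mat"]
    return BlockState(m, m.sum(axis=1), m.sum(axis=0),
                      info["sizes_doc"], info["sizes_term"])


# ---------------------------------------------------------------------------
# Base-level optimizer (degree-corrected, incremental)
# ---------------------------------------------------------------------------

class _BaseState:
    """Incremental flat partition of the base graph under the closure DL.

    The objective is the nested DL of the two-level hierarchy (this partition
    plus the trivial top): likelihood + degree prior + partition prior +
    ln multiset(B_doc * B_term, E). Moves and merges are evaluated by local
    deltas against lookup tables of log-factorials; the exact DL can always
    be recomputed from scratch for verification.
    """

    def __init__(self, graph: BipartiteGraph, frozen_b: np.ndarray | None = None):
        self.graph = graph
        n = graph.n_nodes
        self.n = n
        self.E = graph.n_edges
        self.tvec = graph.node_type().astype(np.int64)
        self.k = graph.degrees().astype(np.int64)
        # CSR adjacency, both directions
        both = np.concatenate([graph.edges, graph.edges[:, ::-1]])
        order = np.lexsort((both[:, 1], both[:, 0]))
        both = both[order]
        self.indptr = np.searchsorted(both[:, 0], np.arange(n + 1))
        self.indices = both[:, 1].copy()
        # log-factorial table over 0..(2E + n)
        self.lf = gammaln(np.arange(2 * self.E + n + 4, dtype=np.float64) + 1.0)

        self.b = np.arange(n, dtype=np.int64)
        self.frozen = np.zeros(n, dtype=bool)
        self.part_types = {0, 1}
        if frozen_b is not None:
            docs = self.tvec == 0
            if len(frozen_b) != int(docs.sum()):
                raise ValueError("frozen assignment does not match doc count")
            nb_frozen = int(frozen_b.max()) + 1
            self.b[docs] = frozen_b
            self.b[~docs] = nb_frozen + np.arange(int((~docs).sum()))
            self.frozen[docs] = True
            self.part_types = {1}
        self._rebuild()

    # -- bookkeeping --------------------------------------------------------

    def _rebuild(self) -> None:
        nb = int(self.b.max()) + 1
        cap = max(nb + 8, self.n + 8)
        self.cap = cap
        self.n_r = np.bincount(self.b, minlength=cap).astype(np.int64)
        self.e_r = np.zeros(cap, dtype=np.int64)
        np.add.at(self.e_r, self.b, self.k)
        self.btype = np.full(cap, -1, dtype=np.int64)
        self.btype[self.b] = self.tvec
        self.e = np.zeros((cap, cap), dtype=np.int64)
        bu = self.b[self.graph.edges[:, 0]]
        bv = self.b[self.graph.edges[:, 1]]
        np.add.at(self.e, (bu, bv), 1)
        self.e += self.e.T.copy()
        self.free_ids = [i for i in range(cap) if self.n_r[i] == 0][::-1]

    def active(self, typ: int) -> np.ndarray:
        return np.flatnonzero((self.n_r > 0) & (self.btype == typ))

    def n_blocks(self, typ: int) -> int:
        return len(self.active(typ))

    def n_type(self, typ: int) -> int:
        return int(np.sum(self.tvec == typ))

    # -- exact objective ----------------------------------------------------

    def flat_dl(self) -> float:
        act = np.flatnonzero(self.n_r > 0)
        docs = act[self.btype[act] == 0]
        terms = act[self.btype[act] == 1]
        s = float(self.lf[self.e_r[act]].sum())
        s -= float(self.lf[self.e[np.ix_(docs, terms)]].sum())
        s -= float(self.lf[self.k].sum())
        s += float(_lnmultiset(self.n_r[act], self.e_r[act]).sum())
        for typ in self.part_types:
            blocks = docs if typ == 0 else terms
            n_obj = self.n_type(typ)
            B = len(blocks)
            s += float(_lnbinom(n_obj - 1, B - 1) + _lnfact(n_obj)
                       - _lnfact(self.n_r[blocks]).sum())
        s += float(_lnmultiset(len(docs) * len(terms), self.E))
        return s

    def _closure_delta_b(self, typ: int, db: int) -> float:
        """Delta of (partition binomial + closure) when B_typ changes by db."""
        bd, bt = self.n_blocks(0), self.n_blocks(1)
        bd2, bt2 = (bd + db, bt) if typ == 0 else (bd, bt + db)
        d = float(_lnmultiset(bd2 * bt2, self.E) - _lnmultiset(bd * bt, self.E))
        if typ in self.part_types:
            n_obj = self.n_type(typ)
            b_old = bd if typ == 0 else bt
            d += float(_lnbinom(n_obj - 1, b_old + db - 1)
                       - _lnbinom(n_obj - 1, b_old - 1))
        return d

    # -- single-node moves --------------------------------------------------

    def move_deltas(self, i: int, allow_new: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Candidate target blocks and their DL deltas for node ``i``.

        Includes every active same-type block plus (when ``allow_new`` and
        the node is not alone in its block) a fresh empty block. The entry
        for the current block is exactly zero.
        """
        lf = self.lf
        typ = int(self.tvec[i])
        r = int(self.b[i])
        ki = int(self.k[i])
        nbr = self.indices[self.indptr[i]:self.indptr[i + 1]]
        T_arr, m = np.unique(self.b[nbr], return_counts=True)
        cands = self.active(typ)

        er_c = self.e_r[cands]
        nr_c = self.n_r[cands]
        d = lf[er_c + ki] - lf[er_c]
        E_sub = self.e[np.ix_(cands, T_arr)]
        d -= (lf[E_sub + m[None, :]] - lf[E_sub]).sum(axis=1)
        d += _lnmultiset(nr_c + 1, er_c + ki) - _lnmultiset(nr_c, er_c)
        if typ in self.part_types:
            d -= lf[nr_c + 1] - lf[nr_c]

        er_r, nr_r = int(self.e_r[r]), int(self.n_r[r])
        row = self.e[r, T_arr]
        ds = float(lf[er_r - ki] - lf[er_r])
        ds -= float((lf[row - m] - lf[row]).sum())
        ds += float(_lnmultiset(nr_r - 1, er_r - ki) - _lnmultiset(nr_r, er_r))
        if typ in self.part_types:
            ds -= float(lf[nr_r - 1] - lf[nr_r])
        empties = nr_r == 1
        if empties:
            ds += self._closure_delta_b(typ, -1)
        d += ds
        d[cands == r] = 0.0

        if not empties and allow_new:
            # fresh block candidate
            dn = float(lf[ki] - (lf[m] - 0.0).sum())
            dn += 0.0  # multiset(1, k) = 0; size term lf[1]-lf[0] = 0
            dn += self._closure_delta_b(typ, +1)
            cands = np.append(cands, -1)
            d = np.append(d, dn + ds)
        return cands, d

    def apply_move(self, i: int, s: int) -> None:
        r = int(self.b[i])
        if s == -1:
            s = self.free_ids.pop()
            self.btype[s] = self.tvec[i]
        if s == r:
            return
        ki = int(self.k[i])
        nbr = self.indices[self.indptr[i]:self.indptr[i + 1]]
        T_arr, m = np.unique(self.b[nbr], return_counts=True)
        self.e[r, T_arr] -= m
        self.e[T_arr, r] -= m
        self.e[s, T_arr] += m
        self.e[T_arr, s] += m
        self.e_r[r] -= ki
        self.e_r[s] += ki
        self.n_r[r] -= 1
        self.n_r[s] += 1
        self.b[i] = s
        if self.n_r[r] == 0:
            self.btype[r] = -1
            self.free_ids.append(r)

    def sweep(self, rng: np.random.Generator, beta: float = float("inf"),
              allow_new: bool = True) -> int:
        moved = 0
        movable = np.flatnonzero(~self.frozen & (self.k > 0))
        for i in rng.permutation(movable):
            cands, d = self.move_deltas(int(i), allow_new=allow_new)
            if np.isinf(beta):
                j = int(np.argmin(d))
                if d[j] < -_EPS:
                    self.apply_move(int(i), int(cands[j]))
                    moved += 1
            else:
                w = np.exp(-beta * (d - d.min()))
                j = int(rng.choice(len(cands), p=w / w.sum()))
                if cands[j] != self.b[i]:
                    self.apply_move(int(i), int(cands[j]))
                    moved += 1
        return moved

    # -- merges -------------------------------------------------------------

    def merge_deltas(self, typ: int) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise DL deltas for merging same-type block pairs.

        Returns (active block ids R, delta matrix |R| x |R|); entry [i, j]
        is the delta for absorbing R[i] into R[j]. The shared B-change term
        is included; stacked merges within a round use slightly stale deltas.
        """
        lf = self.lf
        R = self.active(typ)
        T = self.active(1 - typ)
        er = self.e_r[R]
        nr = self.n_r[R]
        M = self.e[np.ix_(R, T)]
        d = lf[er[:, None] + er[None, :]] - lf[er][:, None] - lf[er][None, :]
        # chunk the D x D x T sum to bound memory
        chunk = max(1, int(4e6 // max(1, len(R) * len(T))))
        for lo in range(0, len(R), chunk):
            hi = min(len(R), lo + chunk)
            cross = lf[M[lo:hi, None, :] + M[None, :, :]]
            d[lo:hi] -= (cross - lf[M[lo:hi, None, :]]
                         - lf[M][None, :, :]).sum(axis=2)
        d += (_lnmultiset(nr[:, None] + nr[None, :], er[:, None] + er[None, :])
              - _lnmultiset(nr, er)[:, None] - _lnmultiset(nr, er)[None, :])
        if typ in self.part_types:
            d -= (lf[nr[:, None] + nr[None, :]]
                  - lf[nr][:, None] - lf[nr][None, :])
        d += self._closure_delta_b(typ, -1)
        np.fill_diagonal(d, np.inf)
        return R, d

    def apply_merge(self, r: int, s: int) -> None:
        """Absorb block r into block s (same type)."""
        self.e[s, :] += self.e[r, :]
        self.e[:, s] += self.e[:, r]
        self.e[r, :] = 0
        self.e[:, r] = 0
        self.e[s, s] = 0
        self.e_r[s] += self.e_r[r]
        self.e_r[r] = 0
        self.n_r[s] += self.n_r[r]
        self.n_r[r] = 0
        self.b[self.b == r] = s
        self.btype[r] = -1
        self.free_ids.append(r)

    def merge_round(self, typ: int, n_merges: int) -> int:
        if n_merges <= 0 or self.n_blocks(typ) <= 1:
            return 0
        R, d = self.merge_deltas(typ)
        order = np.argsort(d, axis=None, kind="stable")
        consumed: set[int] = set()
        done = 0
        for flat in order:
            if done >= n_merges:
                break
            i, j = divmod(int(flat), len(R))
            r, s = int(R[i]), int(R[j])
            if r in consumed or s in consumed or r == s:
                continue
            self.apply_merge(r, s)
            consumed.add(r)
            consumed.add(s)
            done += 1
        return done

    def compact_assignment(self) -> np.ndarray:
        """Contiguous relabeling of the current assignment, docs first."""
        act_d = self.active(0)
        act_t = self.active(1)
        remap = np.full(self.cap, -1, dtype=np.int64)
        remap[act_d] = np.arange(len(act_d))
        remap[act_t] = len(act_d) + np.arange(len(act_t))
        return remap[self.b]


# ---------------------------------------------------------------------------
# Upper-level optimizer (small block multigraphs, full evaluation)
# ---------------------------------------------------------------------------

def _grouped_cost(W: np.ndarray, bl: np.ndarray, br: np.ndarray,
                  part_left: bool, part_right: bool, E: int) -> float:
    """Conditional DL of one upper level: edge-matrix cost of the lower
    multigraph under this grouping + partition priors + top closure."""
    BL = int(bl.max()) + 1
    BR = int(br.max()) + 1
    W2 = np.zeros((BL, BR), dtype=np.int64)
    np.add.at(W2, (bl[:, None].repeat(W.shape[1], 1),
                   br[None, :].repeat(W.shape[0], 0)), W)
    nL = np.bincount(bl, minlength=BL)
    nR = np.bincount(br, minlength=BR)
    s = float(_lnmultiset(nL[:, None] * nR[None, :], W2).sum())
    if part_left:
        s += float(_lnbinom(len(bl) - 1, BL - 1) + _lnfact(len(bl))
                   - _lnfact(nL).sum())
    if part_right:
        s += float(_lnbinom(len(br) - 1, BR - 1) + _lnfact(len(br))
                   - _lnfact(nR).sum())
    s += float(_lnmultiset(BL * BR, E))
    return s


def _compact_labels(b: np.ndarray) -> np.ndarray:
    _, inv = np.unique(b, return_inverse=True)
    return inv.astype(np.int64)


def _fit_block_level(
    W: np.ndarray,
    E: int,
    rng: np.random.Generator,
    frozen_left: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Group the rows/columns of a lower-level block multigraph.

    Greedy agglomeration from singletons down to one group per side with
    full objective evaluation, followed by single-object reassignment passes;
    the best state seen is returned. If ``frozen_left`` is given the row
    grouping is fixed (chained models) and only columns are clustered.
    """
    D, T = W.shape
    part_left = frozen_left is None
    bl = np.arange(D, dtype=np.int64) if part_left else frozen_left.copy()
    br = np.arange(T, dtype=np.int64)

    def cost(bl_, br_):
        return _grouped_cost(W, _compact_labels(bl_), _compact_labels(br_),
                             part_left, True, E)

    best = (bl.copy(), br.copy(), cost(bl, br))
    cur = best[2]
    while True:
        sides = []
        if part_left and len(np.unique(bl)) > 1:
            sides.append("L")
        if len(np.unique(br)) > 1:
            sides.append("R")
        if not sides:
            break
        best_merge = None
        for side in sides:
            vec = bl if side == "L" else br
            groups = np.unique(vec)
            for ai in range(len(groups)):
                for aj in range(ai + 1, len(groups)):
                    trial = vec.copy()
                    trial[trial == groups[aj]] = groups[ai]
                    c = cost(trial, br) if side == "L" else cost(bl, trial)
                    if best_merge is None or c < best_merge[0] - _EPS:
                        best_merge = (c, side, trial)
        cur = best_merge[0]
        if best_merge[1] == "L":
            bl = best_merge[2]
        else:
            br = best_merge[2]
        if cur < best[2] - _EPS:
            best = (bl.copy(), br.copy(), cur)
    # local refinement sweeps on the best state
    bl, br, cur = best[0].copy(), best[1].copy(), best[2]
    for _ in range(10):
        improved = False
        for side in (["L", "R"] if part_left else ["R"]):
            vec = bl if side == "L" else br
            groups = list(np.unique(vec))
            for i in rng.permutation(len(vec)):
                orig = vec[i]
                for g in groups + [max(groups) + 1]:
                    if g == orig:
                        continue
                    vec[i] = g
                    c = cost(bl, br)
                    if c < cur - _EPS:
                        cur = c
                        orig = g
                        improved = True
                        groups = list(np.unique(vec))
                    else:
                        vec[i] = orig
        if not improved:
            break
    if cur < best[2] - _EPS:
        best = (bl, br, cur)
    return (_compact_labels(best[0]), _compact_labels(best[1]), best[2])


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class BlockModel:
    """A bipartite graph with a fitted nested partition: common base for
    domain-topic and chained models. Exposes per-side, per-level block views
    and cached block-to-block edge counts."""

    FORMAT = "domainmap-model/1"
    kind = "domain-topic"

    def __init__(self, graph: BipartiteGraph, partition: NestedPartition,
                 config: FitConfig, dl: DescriptionLength):
        self.graph = graph
        self.partition = partition
        self.config = config
        self.dl = dl
        self._cache: dict = {}
        self._btypes = partition.block_types(graph.node_type())

    # -- side/level helpers -------------------------------------------------

    @property
    def n_levels(self) -> int:
        return self.partition.n_levels

    def side_index(self, side: str) -> int:
        if side in ("doc", "left", "domain"):
            return 0
        return 1

    def side_blocks(self, side: str, level: int) -> np.ndarray:
        """Global block ids of ``side`` at 1-based ``level``."""
        bt = self._btypes[level - 1]
        return np.flatnonzero(bt == self.side_index(side))

    def n_side_blocks(self, side: str, level: int) -> int:
        return len(self.side_blocks(side, level))

    def side_assignment(self, side: str, level: int) -> np.ndarray:
        """Within-side block index for each base node of ``side``."""
        a = self.partition.assignment(level)
        tvec = self.graph.node_type()
        si = self.side_index(side)
        blocks = self.side_blocks(side, level)
        remap = np.full(int(a.max()) + 1, -1, dtype=np.int64)
        remap[blocks] = np.arange(len(blocks))
        return remap[a[tvec == si]]

    def parent_map(self, side: str, level: int) -> np.ndarray:
        """Within-side index map: level blocks -> level+1 blocks."""
        lev = self.partition.levels[level]
        blocks = self.side_blocks(side, level)
        up_blocks = self.side_blocks(side, level + 1)
        remap = np.full(int(lev.max()) + 1, -1, dtype=np.int64)
        remap[up_blocks] = np.arange(len(up_blocks))
        return remap[lev[blocks]]

    def ancestry(self, side: str, level: int, index: int) -> list[int]:
        """Within-side indices of the strict ancestors, one per upper level."""
        out = []
        cur = index
        for lev in range(level, self.n_levels):
            cur = int(self.parent_map(side, lev)[cur])
            out.append(cur)
        return out

    def children(self, side: str, level: int, index: int) -> np.ndarray:
        """Within-side indices of the level-1 below children (level >= 2)."""
        pm = self.parent_map(side, level - 1)
        return np.flatnonzero(pm == index)

    def edge_counts(self, level_left: int = 1, level_right: int = 1
                    ) -> np.ndarray:
        """Edge counts between left blocks at one level and right blocks at
        another (rows = left/document side)."""
        key = ("ec", level_left, level_right)
        if key not in self._cache:
            al = self.side_assignment("doc", level_left)
            ar = self.side_assignment("right", level_right)
            nl = self.n_side_blocks("doc", level_left)
            nr = self.n_side_blocks("right", level_right)
            mat = np.zeros((nl, nr), dtype=np.int64)
            u = al[self.graph.edges[:, 0]]
            v = ar[self.graph.edges[:, 1] - self.graph.n_left]
            np.add.at(mat, (u, v), 1)
            self._cache[key] = mat
        return self._cache[key]

    def element_counts(self, side: str, level: int) -> np.ndarray:
        """Edge counts between ``side`` blocks at ``level`` and the
        individual base nodes of the opposite side."""
        key = ("el", side, level)
        if key not in self._cache:
            si = self.side_index(side)
            a = self.side_assignment(side, level)
            nb = self.n_side_blocks(side, level)
            if si == 0:
                own = a[self.graph.edges[:, 0]]
                other = self.graph.edges[:, 1] - self.graph.n_left
                n_other = self.graph.n_right
            else:
                own = a[self.graph.edges[:, 1] - self.graph.n_left]
                other = self.graph.edges[:, 0]
                n_other = self.graph.n_left
            mat = np.zeros((nb, n_other), dtype=np.int64)
            np.add.at(mat, (own, other), 1)
            self._cache[key] = mat
        return self._cache[key]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": self.FORMAT,
            "kind": self.kind,
            "graph": {
                "left_labels": self.graph.left_labels,
                "right_labels": self.graph.right_labels,
                "right_type": self.graph.right_type,
                "edges": self.graph.edges.tolist(),
            },
            "levels": [l.tolist() for l in self.partition.levels],
            "description_length": self.dl.to_dict(),
            "config": self.config.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True,
                          separators=(",", ":"))

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "BlockModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("format") != cls.FORMAT:
            raise ValueError("unrecognized model format")
        g = d["graph"]
        graph = BipartiteGraph(g["left_labels"], g["right_labels"],
                               np.array(g["edges"], dtype=np.int64)
                               .reshape(-1, 2),
                               right_type=g["right_type"])
        partition = NestedPartition([np.array(l, dtype=np.int64)
                                     for l in d["levels"]])
        config = FitConfig.from_dict(d["config"])
        dlc = d["description_length"]
        dl = DescriptionLength(dlc["total"], dlc["graph_likelihood"],
                               dlc["degree_sequence"], dlc["partition_levels"],
                               dlc["edge_matrix_levels"])
        target = DomainTopicModel if d.get("kind") == "domain-topic" else cls
        return target(graph, partition, config, dl)


class DomainTopicModel(BlockModel):
    """A fitted domain-topic model: document-term graph + nested partition.

    Level-1 topic usage distributions p(t|d) are available through
    :meth:`edge_counts` and the measures module.
    """

    kind = "domain-topic"


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _descend(state: _BaseState, config: FitConfig, rng: np.random.Generator
             ) -> tuple[np.ndarray, float]:
    """Agglomerative descent tracking the best flat state seen."""
    movable_types = sorted(state.part_types)
    best_b = state.compact_assignment()
    best_dl = state.flat_dl()
    while any(state.n_blocks(t) > 1 for t in movable_types):
        for typ in movable_types:
            B = state.n_blocks(typ)
            target = max(1, int(np.floor(B / config.sigma)))
            state.merge_round(typ, B - target)
        # fresh-block moves are disabled during forced agglomeration: a
        # split undone by the next merge round would cycle forever
        for _ in range(config.sweeps):
            if state.sweep(rng, config.beta, allow_new=False) == 0:
                break
        dl = state.flat_dl()
        if dl < best_dl - _EPS:
            best_dl = dl
            best_b = state.compact_assignment()
    return best_b, best_dl


def _polish(state: _BaseState, config: FitConfig, rng: np.random.Generator,
            max_rounds: int = 60) -> None:
    """Hill-climb from the current state: sweeps to convergence, then the
    single best merge if it lowers DL, repeated until neither helps."""
    movable_types = sorted(state.part_types)
    for _ in range(max_rounds):
        for _ in range(max(1, config.sweeps)):
            if state.sweep(rng, config.beta) == 0:
                break
        best_merge = None
        for typ in movable_types:
            if state.n_blocks(typ) <= 1:
                continue
            R, d = state.merge_deltas(typ)
            i, j = divmod(int(np.argmin(d)), len(R))
            if best_merge is None or d[i, j] < best_merge[0]:
                best_merge = (float(d[i, j]), int(R[i]), int(R[j]))
        if best_merge is None or best_merge[0] >= -_EPS:
            break
        state.apply_merge(best_merge[1], best_merge[2])


def _grow_hierarchy(
    graph: BipartiteGraph,
    b0: np.ndarray,
    config: FitConfig,
    rng: np.random.Generator,
    frozen_parent_maps: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Stack upper levels on a base assignment while DL decreases.

    Each added level groups the current block multigraph; the trivial
    grouping reproduces the current closure cost, so total DL never worsens.
    With ``frozen_parent_maps`` (chained models) the document-side grouping
    at each level is imposed and only the right side is clustered; levels are
    then added up to the frozen hierarchy's depth even when collapsed.
    """
    tvec = graph.node_type()
    levels = [b0.copy()]
    # current per-side structure
    nb = int(b0.max()) + 1
    bt = np.full(nb, -1, dtype=np.int64)
    bt[b0] = tvec
    doc_ids = np.flatnonzero(bt == 0)
    term_ids = np.flatnonzero(bt == 1)
    dmap = np.full(nb, -1, dtype=np.int64)
    dmap[doc_ids] = np.arange(len(doc_ids))
    tmap = np.full(nb, -1, dtype=np.int64)
    tmap[term_ids] = np.arange(len(term_ids))
    W = np.zeros((len(doc_ids), len(term_ids)), dtype=np.int64)
    np.add.at(W, (dmap[b0[graph.edges[:, 0]]],
                  tmap[b0[graph.edges[:, 1]]]), 1)
    E = graph.n_edges

    depth = 1
    while depth < config.max_levels:
        frozen_left = None
        if frozen_parent_maps is not None:
            if depth > len(frozen_parent_maps):
                break
            frozen_left = frozen_parent_maps[depth - 1]
        elif W.shape[0] <= 1 and W.shape[1] <= 1:
            break
        bl, br, _ = _fit_block_level(W, E, rng, frozen_left=frozen_left)
        trivial = (int(bl.max()) == 0 and int(br.max()) == 0)
        if trivial and frozen_parent_maps is None:
            break
        # map per-side labels back to a joint level array (docs first)
        D2, T2 = int(bl.max()) + 1, int(br.max()) + 1
        joint = np.empty(nb, dtype=np.int64)
        joint[doc_ids] = bl
        joint[term_ids] = D2 + br
        levels.append(joint)
        # regroup W
        W2 = np.zeros((D2, T2), dtype=np.int64)
        np.add.at(W2, (bl[:, None].repeat(W.shape[1], 1),
                       br[None, :].repeat(W.shape[0], 0)), W)
        W = W2
        nb = D2 + T2
        doc_ids = np.arange(D2)
        term_ids = D2 + np.arange(T2)
        dmap = np.full(nb, -1, dtype=np.int64)
        dmap[doc_ids] = np.arange(D2)
        tmap = np.full(nb, -1, dtype=np.int64)
        tmap[term_ids] = np.arange(T2)
        depth += 1
        if frozen_parent_maps is None and D2 == 1 and T2 == 1:
            break
    # ensure the hierarchy closes with one block per type
    top_docs = len(doc_ids)
    top_terms = len(term_ids)
    if top_docs > 1 or top_terms > 1:
        lev = np.empty(top_docs + top_terms, dtype=np.int64)
        lev[:top_docs] = 0
        lev[top_docs:] = 1
        levels.append(lev)
    return levels


def fit(graph: BipartiteGraph, config: FitConfig | None = None
        ) -> DomainTopicModel:
    """Fit the nested degree-corrected SBM by MDL minimization.

    Runs ``config.n_restarts`` independent agglomerative searches (merges
    interleaved with single-node sweeps, shrink factor ``config.sigma``),
    grows the hierarchy while description length decreases, and returns the
    single best-known fit. Fully reproducible given ``config.seed``; the
    number of blocks and of levels are inferred, never taken as input.
    """
    if config is None:
        config = FitConfig()
    if graph.n_nodes == 0 or graph.n_edges == 0:
        raise ValueError("cannot fit an empty graph")
    master = np.random.default_rng(config.seed)
    best: tuple[NestedPartition, DescriptionLength] | None = None
    for _ in range(config.n_restarts):
        rng = np.random.default_rng(int(master.integers(2 ** 31)))
        state = _BaseState(graph)
        b0, dl0 = _descend(state, config, rng)
        state.b[:] = b0
        state._rebuild()
        _polish(state, config, rng)
        if state.flat_dl() < dl0 - _EPS:
            b0 = state.compact_assignment()
        levels = _grow_hierarchy(graph, b0, config, rng)
        partition = _canonicalize(NestedPartition(levels), graph.node_type())
        dl = description_length(graph, partition)
        if best is None or dl.total < best[1].total - _EPS:
            best = (partition, dl)
    return DomainTopicModel(graph, best[0], config, best[1])


def refine(model: DomainTopicModel, config: FitConfig | None = None
           ) -> DomainTopicModel:
    """Continue the search from an existing state.

    Runs additional single-node sweeps on the base level and regrows the
    hierarchy; the better of the refined and original states (by exact DL)
    is returned, so the result never has a larger description length. With
    ``sweeps == 0`` the input model is returned unchanged.
    """
    if config is None:
        config = model.config
    if config.sweeps == 0:
        return model
    rng = np.random.default_rng(config.seed)
    state = _BaseState(model.graph)
    state.b = model.partition.assignment(1).copy()
    state._rebuild()
    for _ in range(config.sweeps):
        if state.sweep(rng, config.beta) == 0:
            break
    levels = _grow_hierarchy(model.graph, state.compact_assignment(),
                             config, rng)
    partition = _canonicalize(NestedPartition(levels),
                              model.graph.node_type())
    dl = description_length(model.graph, partition)
    if dl.total < model.dl.total - _EPS:
        return DomainTopicModel(model.graph, partition, config, dl)
    return model
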