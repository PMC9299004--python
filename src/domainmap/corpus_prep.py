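"""Corpus preprocessing and bipartite graph construction.

Preprocessing is deliberately minimal and language independent: lowercasing
tokenization, statistical bigram merging, and per-document deduplication of
terms. No stop-word lists, frequency cuts, stemming or lemmatization are
applied — separating function words from content words is left to the block
model, which isolates them in their own topics.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("domainmap")

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)

DOC_SIDE = "doc"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Document:
    """A document: an id, an ordered token list, and categorical metadata.

    Metadata maps a field name (e.g. ``"year"``, ``"country"``) to a list of
    opaque categorical values; multi-valued fields (several countries, several
    authors) are allowed and yield one graph edge per value.
    """

    doc_id: str
    tokens: list[str]
    metadata: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class Corpus:
    """A list of documents plus the vocabulary of distinct terms."""

    documents: list[Document]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doc_id in corpus")

    @property
    def vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for d in self.documents:
            vocab.update(d.tokens)
        return vocab

    def __len__(self) -> int:
        return len(self.documents)


@dataclass
class CollocationTable:
    """Bigram statistics and the set of accepted (merged) bigrams.

    ``counts`` are corpus-wide: ``unigram[a]`` occurrences of token ``a``,
    ``bigram[(a, b)]`` adjacent ordered occurrences within documents, and
    ``n_tokens`` the total token count N. A bigram is accepted when its
    discounted normalized score ``N * (c_ab - delta) / (c_a * c_b)`` reaches
    ``threshold`` (and ``c_ab > delta``).
    """

    unigram: Counter
    bigram: Counter
    n_tokens: int
    delta: float
    threshold: float
    merged: set[tuple[str, str]]

    def score(self, a: str, b: str) -> float:
        c_ab = self.bigram.get((a, b), 0)
        c_a, c_b = self.unigram.get(a, 0), self.unigram.get(b, 0)
        if c_a == 0 or c_b == 0:
            return 0.0
        return self.n_tokens * (c_ab - self.delta) / (c_a * c_b)


class BipartiteGraph:
    """A simple bipartite graph between documents and terms (or metadata).

    Left nodes are documents, right nodes are terms or metadata values of a
    single field. Edges are unweighted and deduplicated. Nodes are indexed
    contiguously: left nodes ``0..n_left-1``, right nodes
    ``n_left..n_left+n_right-1``.
    """

    def __init__(
        self,
        left_labels: list[str],
        right_labels: list[str],
        edges: np.ndarray,
        right_type: str = "term",
    ) -> None:
        self.left_labels = list(left_labels)
        self.right_labels = list(right_labels)
        self.right_type = right_type
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        # simple graph: deduplicate, sort for determinism
        if len(edges):
            edges = np.unique(edges, axis=0)
        self.edges = edges
        self._validate()

    # -- basic properties ---------------------------------------------------

    @property
    def n_left(self) -> int:
        return len(self.left_labels)

    @property
    def n_right(self) -> int:
        return len(self.right_labels)

    @property
    def n_nodes(self) -> int:
        return self.n_left + self.n_right

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_type(self) -> np.ndarray:
        """0 for left (document) nodes, 1 for right nodes."""
        t = np.zeros(self.n_nodes, dtype=np.int8)
        t[self.n_left:] = 1
        return t

    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    def _validate(self) -> None:
        if len(self.edges):
            u, v = self.edges[:, 0], self.edges[:, 1]
            if (u < 0).any() or (u >= self.n_left).any():
                raise ValueError("left endpoint out of range")
            if (v < self.n_left).any() or (v >= self.n_nodes).any():
                raise ValueError("right endpoint out of range (not bipartite)")

    # -- conversion / serialization -----------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, lab in enumerate(self.left_labels):
            g.add_node(i, label=lab, kind=DOC_SIDE, bipartite=0)
        for j, lab in enumerate(self.right_labels):
            g.add_node(self.n_left + j, label=lab, kind=self.right_type,
                       bipartite=1)
        g.add_edges_from(map(tuple, self.edges))
        return g

    def write_graphml(self, path: str) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, path: str) -> None:
        """Portable node-table + edge-list text serialization."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# nodes\tid\ttype\tlabel\n")
            for i, lab in enumerate(self.left_labels):
                fh.write(f"n\t{i}\t{DOC_SIDE}\t{lab}\n")
            for j, lab in enumerate(self.right_labels):
                fh.write(f"n\t{self.n_left + j}\t{self.right_type}\t{lab}\n")
            fh.write("# edges\tsource\ttarget\n")
            for u, v in self.edges:
                fh.write(f"e\t{u}\t{v}\n")

    @classmethod
    def read_edgelist(cls, path: str) -> "BipartiteGraph":
        left: list[str] = []
        right: list[str] = []
        right_type = "term"
        raw_edges: list[tuple[int, int]] = []
        node_index: dict[int, tuple[str, str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "n":
                    node_index[int(parts[1])] = (parts[2], parts[3])
                elif parts[0] == "e":
                    raw_edges.append((int(parts[1]), int(parts[2])))
        for idx in sorted(node_index):
            kind, lab = node_index[idx]
            if kind == DOC_SIDE:
                left.append(lab)
            else:
                right.append(lab)
                right_type = kind
        return cls(left, right, np.array(raw_edges, dtype=np.int64).reshape(-1, 2),
                   right_type=right_type)


# ---------------------------------------------------------------------------
# Tokenization and collocations
# ---------------------------------------------------------------------------

def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric boundaries.

    Underscores are preserved (they mark previously merged bigrams such as
    ``stem_cells``). Deterministic; empty input yields an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


def detect_collocations(
    corpus: Corpus, delta: float = 5.0, threshold: float = 10.0
) -> CollocationTable:
    """Detect frequent adjacent bigrams with a discounted normalized score.

    ``score(a, b) = N * (c_ab - delta) / (c_a * c_b)`` where counts are taken
    over the tokenized corpus; pairs with ``score >= threshold`` and
    ``c_ab > delta`` are accepted. Single pass: only bigrams of original
    tokens, no higher n-grams.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    unigram: Counter = Counter()
    bigram: Counter = Counter()
    n_tokens = 0
    for doc in corpus.documents:
        toks = doc.tokens
        unigram.update(toks)
        n_tokens += len(toks)
        bigram.update(zip(toks, toks[1:]))
    merged = set()
    for (a, b), c_ab in bigram.items():
        if c_ab <= delta:
            continue
        score = n_tokens * (c_ab - delta) / (unigram[a] * unigram[b])
        if score >= threshold:
            merged.add((a, b))
    return CollocationTable(unigram, bigram, n_tokens, delta, threshold, merged)


def apply_collocations(document: Document, table: CollocationTable) -> Document:
    """Greedy left-to-right non-overlapping replacement of accepted bigrams."""
    toks = document.tokens
    out: list[str] = []
    i = 0
    while i < len(toks):
        if i + 1 < len(toks) and (toks[i], toks[i + 1]) in table.merged:
            out.append(f"{toks[i]}_{toks[i + 1]}")
            i += 2
        else:
            out.append(toks[i])
            i += 1
    return Document(document.doc_id, out, document.metadata)


def preprocess_corpus(
    corpus: Corpus,
    delta: float = 5.0,
    threshold: float = 10.0,
    merge_bigrams: bool = True,
) -> tuple[Corpus, CollocationTable]:
    """Tokenize-level pipeline: collocation detection plus replacement."""
    table = detect_collocations(corpus, delta=delta, threshold=threshold)
    if merge_bigrams and table.merged:
        docs = [apply_collocations(d, table) for d in corpus.documents]
        corpus = Corpus(docs)
    return corpus, table


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_doc_term_graph(corpus: Corpus) -> BipartiteGraph:
    """One edge per (document, distinct term); local frequency is discarded.

    Documents with zero tokens are dropped with a logged warning — the model
    requires connected documents.
    """
    kept: list[Document] = []
    for d in corpus.documents:
        if d.tokens:
            kept.append(d)
        else:
            logger.warning("dropping empty document %r from doc-term graph",
                           d.doc_id)
    vocab = sorted({t for d in kept for t in d.tokens})
    term_index = {t: i for i, t in enumerate(vocab)}
    n_left = len(kept)
    edges = []
    for i, d in enumerate(kept):
        for t in sorted(set(d.tokens)):
            edges.append((i, n_left + term_index[t]))
    return BipartiteGraph(
        [d.doc_id for d in kept], vocab,
        np.array(edges, dtype=np.int64).reshape(-1, 2), right_type="term",
    )


def build_doc_metadata_graph(corpus: Corpus, fieldname: str) -> BipartiteGraph:
    """One edge per (document, metadata value) of one field.

    Documents lacking the field are omitted from this graph (logged); a field
    present in no document is an error.
    """
    kept: list[Document] = []
    for d in corpus.documents:
        if d.metadata.get(fieldname):
            kept.append(d)
        else:
            logger.info("document %r lacks field %r; omitted from that graph",
                        d.doc_id, fieldname)
    if not kept:
        raise ValueError(f"metadata field {fieldname!r} present in no document")
    values = sorted({v for d in kept for v in d.metadata[fieldname]})
    val_index = {v: i for i, v in enumerate(values)}
    n_left = len(kept)
    edges = []
    for i, d in enumerate(kept):
        for v in sorted(set(d.metadata[fieldname])):
            edges.append((i, n_left + val_index[v]))
    return BipartiteGraph(
        [d.doc_id for d in kept], values,
        np.array(edges, dtype=np.int64).reshape(-1, 2), right_type=fieldname,
    )


# ---------------------------------------------------------------------------
# Corpus IO
# ---------------------------------------------------------------------------

def _as_values(value) -> list[str]:
    if value is None:
        return []
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value]
    return [str(value)]


def read_jsonl(
    path_or_buffer, text_field: str = "text", id_field: str = "id"
) -> Corpus:
    """Read a JSON-lines corpus; every non-text field becomes metadata."""
    if isinstance(path_or_buffer, (str, bytes)):
        fh = open(path_or_buffer, encoding="utf-8")
        close = True
    else:
        fh, close = path_or_buffer, False
    docs = []
    try:
        for lineno, line in enumerate(fh):
            if not line.strip():
                continue
            rec = json.loads(line)
            doc_id = str(rec.get(id_field, lineno))
            text = rec.get(text_field, "")
            meta = {k: _as_values(v) for k, v in rec.items()
                    if k not in (text_field, id_field)}
            docs.append(Document(doc_id, tokenize(text), meta))
    finally:
        if close:
            fh.close()
    return Corpus(docs)


def read_delimited(
    path_or_buffer, text_field: str = "text", id_field: str = "id",
    sep: str = ",",
) -> Corpus:
    """Read a CSV/TSV corpus with a designated text column."""
    if isinstance(path_or_buffer, (str, bytes)):
        fh = open(path_or_buffer, encoding="utf-8", newline="")
        close = True
    else:
        fh, close = path_or_buffer, False
    docs = []
    try:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None or text_field not in reader.fieldnames:
            raise ValueError(f"text column {text_field!r} not found")
        for lineno, rec in enumerate(reader):
            doc_id = str(rec.get(id_field) or lineno)
            meta = {k: _as_values(v) for k, v in rec.items()
                    if k not in (text_field, id_field) and v not in (None, "")}
            docs.append(Document(doc_id, tokenize(rec[text_field] or ""), meta))
    finally:
        if close:
            fh.close()
    return Corpus(docs)


def write_jsonl(corpus: Corpus, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            rec = {"id": d.doc_id, "text": " ".join(d.tokens)}
            rec.update({k: v for k, v in d.metadata.items()})
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
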