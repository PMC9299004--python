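"""Planted-structure corpus generation.

Generates corpora with known ground truth for testing every stage of the
pipeline without an external dataset: documents are drawn from planted
domain blocks, each domain with a characteristic mixture over planted topic
blocks of terms, contaminated by a uniform background noise component that
mimics the stop-word structure real corpora exhibit (the model is expected
to isolate those background terms in their own topics). Optional metadata
(e.g. years) drifts across domains, so chained fits can recover planted
eras. Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_prep import Corpus, Document


@dataclass
class MetadataSpec:
    """Categorical metadata values with per-domain sampling weights."""

    values: list[str]
    weights: np.ndarray     # (n_domains, n_values) rows sum to 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape[1] != len(self.values):
            raise ValueError("weights do not match values")
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            raise ValueError("weight rows must sum to 1")


@dataclass
class GroundTruth:
    doc_domain: np.ndarray
    term_topic: np.ndarray
    domain_level2: np.ndarray | None = None
    topic_level2: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "doc_domain": self.doc_domain.tolist(),
            "term_topic": self.term_topic.tolist(),
            "domain_level2": (None if self.domain_level2 is None
                              else self.domain_level2.tolist()),
            "topic_level2": (None if self.topic_level2 is None
                             else self.topic_level2.tolist()),
        }


@dataclass
class PlantedSpec:
    """Parameters of the planted generative process.

    Defaults describe the strong-signal benchmark regime: 300 documents over
    3 domains, 60 terms over 4 topics, each domain concentrating 80% of its
    term draws on its characteristic topic, a mean of 20 term draws per
    document, and a 5% uniform background noise weight.
    """

    n_docs: int = 300
    n_terms: int = 60
    n_domains: int = 3
    n_topics: int = 4
    mixture: np.ndarray | None = None     # (n_domains, n_topics)
    mean_terms: float = 20.0
    dispersion: float | None = None       # None = Poisson; else gamma-Poisson
    epsilon: float = 0.05
    domain_level2: list[int] | None = None
    topic_level2: list[int] | None = None
    metadata: dict[str, MetadataSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_docs, self.n_terms, self.n_domains, self.n_topics) < 1:
            raise ValueError("all counts must be positive")
        if self.n_topics > self.n_terms:
            raise ValueError("more topics than terms is infeasible")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must be in [0, 1)")
        if self.mixture is None:
            mix = np.full((self.n_domains, self.n_topics),
                          0.2 / max(1, self.n_topics - 1))
            for i in range(self.n_domains):
                mix[i, i % self.n_topics] = 0.8
            if self.n_topics == 1:
                mix[:] = 1.0
            self.mixture = mix
        else:
            self.mixture = np.asarray(self.mixture, dtype=np.float64)
        if self.mixture.shape != (self.n_domains, self.n_topics):
            raise ValueError("mixture shape mismatch")
        if not np.allclose(self.mixture.sum(axis=1), 1.0):
            raise ValueError("mixture rows must sum to 1")


def generate(spec: PlantedSpec) -> tuple[Corpus, GroundTruth]:
    """Draw a corpus from the planted process.

    Documents are assigned to domains in round-robin order; each document
    draws term slots from its domain's topic mixture (a slot is replaced by
    a uniform background draw with probability epsilon) and terms uniformly
    within the chosen topic; the resulting term set is deduplicated,
    matching the binary document-term incidence the model consumes.
    """
    rng = np.random.default_rng(spec.seed)
    term_topic = np.arange(spec.n_terms) % spec.n_topics
    term_names = [f"w{j:04d}" for j in range(spec.n_terms)]
    topic_members = [np.flatnonzero(term_topic == t)
                     for t in range(spec.n_topics)]
    doc_domain = np.arange(spec.n_docs) % spec.n_domains

    docs = []
    for i in range(spec.n_docs):
        dom = int(doc_domain[i])
        if spec.dispersion is None:
            n_slots = max(1, int(rng.poisson(spec.mean_terms)))
        else:
            shape = spec.dispersion
            lam = rng.gamma(shape, spec.mean_terms / shape)
            n_slots = max(1, int(rng.poisson(lam)))
        tokens: list[str] = []
        seen: set[str] = set()
        for _ in range(n_slots):
            if spec.epsilon > 0 and rng.random() < spec.epsilon:
                term = int(rng.integers(spec.n_terms))
            else:
                topic = int(rng.choice(spec.n_topics, p=spec.mixture[dom]))
                members = topic_members[topic]
                term = int(members[rng.integers(len(members))])
            name = term_names[term]
            if name not in seen:
                seen.add(name)
                tokens.append(name)
        meta: dict[str, list[str]] = {}
        for fname, mspec in spec.metadata.items():
            v = int(rng.choice(len(mspec.values), p=mspec.weights[dom]))
            meta[fname] = [mspec.values[v]]
        docs.append(Document(f"d{i:05d}", tokens, meta))
    truth = GroundTruth(
        doc_domain, term_topic,
        None if spec.domain_level2 is None
        else np.asarray(spec.domain_level2),
        None if spec.topic_level2 is None
        else np.asarray(spec.topic_level2),
    )
    return Corpus(docs), truth


def year_drift_spec(
    n_docs: int = 300,
    n_years: int = 10,
    drift: float = 0.9,
    seed: int = 0,
    **kwargs,
) -> PlantedSpec:
    """Benchmark spec with two planted eras.

    Domains are split into an early and a late group; documents of the early
    group draw their year from the first half of the year range with total
    probability ``drift`` (uniform within each half), and symmetrically for
    the late group. Chained fits should recover the two halves as periods.
    """
    spec = PlantedSpec(n_docs=n_docs, seed=seed, **kwargs)
    years = [str(1995 + y) for y in range(n_years)]
    half = n_years // 2
    w_early = np.concatenate([
        np.full(half, drift / half),
        np.full(n_years - half, (1 - drift) / (n_years - half)),
    ])
    w_late = np.concatenate([
        np.full(half, (1 - drift) / half),
        np.full(n_years - half, drift / (n_years - half)),
    ])
    n_early = (spec.n_domains + 1) // 2
    weights = np.vstack([w_early if d < n_early else w_late
                         for d in range(spec.n_domains)])
    spec.metadata = {"year": MetadataSpec(years, weights)}
    return spec
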