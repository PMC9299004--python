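"""Block characterization measures.

A domain (or any block) induces a probability distribution over the level-1
blocks of the opposite side — for domains, the topic-usage distribution
p(t|d), the fraction of the domain's document-term edges landing in each
level-1 topic. Comparing these distributions along the block's ladder of
ancestors yields two pointwise relative-entropy (KL) measures:

* nested specificity — the expectation-weighted pointwise relative entropy
  of a unit between a block and each of its strict ancestors, averaged over
  the ancestor ladder. Always finite (ancestor counts aggregate descendant
  counts, so p_d > 0 implies p_ancestor > 0) and sums to a nonnegative value
  over units.
* nested commonality — the unweighted pointwise relative entropy between
  each immediate subblock and each ancestor, averaged over both, then
  expectation-weighted by the mean subblock probability. It is positive when
  a unit is overrepresented in *all* subblocks and reaches minus infinity as
  soon as the unit is missing from any subblock with nonzero mean weight;
  when the mean weight is itself zero the measure is defined as zero.

Both measures transpose to any pair of block types (characteristic domains
for a topic or a metadata block) and to elements (characteristic terms
instead of topics). Natural logarithms throughout; no smoothing or
pseudocounts are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chained_model import ChainedModel
from .sbm_inference import BlockModel


@dataclass
class TopicUsage:
    """Distribution of a block's edges over opposite-side level-1 blocks."""

    side: str
    level: int
    index: int
    probs: np.ndarray
    granularity: str = "blocks"


@dataclass
class BlockScore:
    """A (block, counterpart) characterization score in nats."""

    side: str
    level: int
    index: int
    counterpart: int
    value: float
    kind: str
    granularity: str = "blocks"


# ---------------------------------------------------------------------------
# Usage distributions
# ---------------------------------------------------------------------------

def _counts_matrix(model: BlockModel, side: str, level: int,
                   granularity: str) -> np.ndarray:
    if granularity == "elements":
        return model.element_counts(side, level)
    if model.side_index(side) == 0:
        return model.edge_counts(level, 1)
    return model.edge_counts(1, level).T


def topic_usage(model: BlockModel, level: int, index: int, side: str = "doc",
                granularity: str = "blocks") -> TopicUsage:
    """p(t|d): the fraction of the block's edges landing in each opposite
    level-1 block (or individual element). Errors on a block with no edges."""
    counts = _counts_matrix(model, side, level, granularity)
    if index < 0 or index >= counts.shape[0]:
        raise ValueError(f"no block {index} at level {level} on side {side!r}")
    row = counts[index].astype(np.float64)
    tot = row.sum()
    if tot == 0:
        raise ValueError("block has no edges")
    return TopicUsage(side, level, index, row / tot, granularity)


def _ladder(model: BlockModel, side: str, level: int, index: int,
            granularity: str) -> np.ndarray:
    """Stack of ancestor distributions, one row per level strictly above."""
    ancestors = model.ancestry(side, level, index)
    if not ancestors:
        raise ValueError("top-level block has no ancestors")
    rows = []
    for off, a in enumerate(ancestors, start=1):
        rows.append(topic_usage(model, level + off, a, side, granularity).probs)
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Nested specificity and commonality
# ---------------------------------------------------------------------------

def specificity_profile(model: BlockModel, level: int, index: int,
                        side: str = "doc", granularity: str = "blocks"
                        ) -> np.ndarray:
    """Nested specificity of every opposite-side unit for one block:
    mean over ancestors a of p_d * ln(p_d / p_a), with 0 ln 0 = 0."""
    p_d = topic_usage(model, level, index, side, granularity).probs
    P_a = _ladder(model, side, level, index, granularity)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p_d[None, :] * (np.log(p_d)[None, :] - np.log(P_a))
    terms[:, p_d == 0] = 0.0
    return terms.mean(axis=0)


def commonality_profiles(model: BlockModel, level: int, index: int,
                         side: str = "doc", granularity: str = "blocks"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted and expectation-weighted nested commonality profiles.

    Requires a block with at least one strict ancestor and one subblock
    (level >= 2, below the top). Returns (C_star, C); entries are -inf
    exactly when some subblock lacks the unit while the mean subblock
    probability is positive, and 0 when that mean weight is zero.
    """
    if level < 2:
        raise ValueError("commonality needs subblocks: level must be >= 2")
    P_a = _ladder(model, side, level, index, granularity)
    children = model.children(side, level, index)
    P_s = np.vstack([
        topic_usage(model, level - 1, int(c), side, granularity).probs
        for c in children])
    w = P_s.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_star = np.log(P_s).mean(axis=0) - np.log(P_a).mean(axis=0)
        c = w * c_star
    zero = w == 0
    c_star[zero] = 0.0
    c[zero] = 0.0
    return c_star, c


def nested_specificity(model: BlockModel, domain: tuple[int, int],
                       topic: int, side: str = "doc",
                       granularity: str = "blocks") -> BlockScore:
    level, index = domain
    value = float(specificity_profile(model, level, index, side,
                                      granularity)[topic])
    return BlockScore(side, level, index, topic, value, "specificity",
                      granularity)


def nested_commonality(model: BlockModel, domain: tuple[int, int],
                       topic: int, side: str = "doc",
                       granularity: str = "blocks") -> BlockScore:
    level, index = domain
    _, c = commonality_profiles(model, level, index, side, granularity)
    return BlockScore(side, level, index, topic, float(c[topic]),
                      "commonality", granularity)


def element_scores(model: BlockModel, domain: tuple[int, int],
                   side: str = "doc", kind: str = "specificity",
                   granularity: str = "elements") -> list[BlockScore]:
    """Ranked characterization scores of one block over opposite units.

    ``granularity='elements'`` scores individual opposite-side nodes
    (characteristic terms for a domain); ``'blocks'`` scores opposite
    level-1 blocks. The transposed use — characteristic domains for a topic
    or a metadata block — is the same call with ``side`` swapped.
    """
    level, index = domain
    if kind == "specificity":
        prof = specificity_profile(model, level, index, side, granularity)
    elif kind == "commonality":
        prof = commonality_profiles(model, level, index, side, granularity)[1]
    else:
        raise ValueError(f"unknown score kind {kind!r}")
    order = sorted(range(len(prof)),
                   key=lambda u: (-prof[u] if np.isfinite(prof[u])
                                  else np.inf, u))
    return [BlockScore(side, level, index, u, float(prof[u]), kind,
                       granularity) for u in order]


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------

def prevalence_change(chained: ChainedModel, domain: tuple[int, int],
                      periods: tuple[int, int], period_level: int = 1
                      ) -> float:
    """Shift of a domain's prevalence between two periods.

    Prevalence in a period is the domain's share of the period's documents;
    the change is the share in the second period minus the share in the
    first. ``domain`` is (level, within-side index) in the source
    domain-topic model; ``periods`` are metadata block indices of the
    chained model at ``period_level``.
    """
    d_mask = chained.docs_in_source_domain(*domain)
    shares = []
    for p in periods:
        p_mask = chained.docs_in_period(period_level, p)
        n = int(p_mask.sum())
        if n == 0:
            raise ValueError(f"period {p} at level {period_level} is empty")
        shares.append(float((p_mask & d_mask).sum()) / n)
    return shares[1] - shares[0]
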