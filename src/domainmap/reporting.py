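"""Interpretive artifacts: block labels, domain-topic tables, map exports
and bump-chart data.

Labels follow the ``L{level}{kind}{index}`` convention: ``L2T29`` is topic
29 at level 2, ``L3D40`` domain 40 at level 3. Within a level, topic indices
start at 0 and domain indices start from the highest topic index, so the two
kinds never collide; period (metadata) blocks are labeled ``P`` and printed
1-based.

The domain-topic table lists, for each domain above level 1, the topics
common to its immediate subdomains and, for each level-1 domain, its
specific topics; topics are retained until they account for half the sum of
the positive scores, and each topic's terms are retained when their value
exceeds half the topic's highest value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chained_model import ChainedModel
from .measures import (
    commonality_profiles,
    specificity_profile,
    topic_usage,
)
from .sbm_inference import BlockModel, DomainTopicModel


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def block_label(model: BlockModel, side: str, level: int, index: int) -> str:
    """Render a block as L{level}{D|T|P}{index}."""
    if model.side_index(side) == 0:
        if model.graph.right_type == "term":
            offset = model.n_side_blocks("right", level)
        else:
            offset = 0
        return f"L{level}D{offset + index}"
    if model.graph.right_type == "term":
        return f"L{level}T{index}"
    return f"L{level}P{index + 1}"


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------

def select_topics(scores, half_rule: str = "ge") -> list[int]:
    """Indices of the highest scores accounting for half the positive sum.

    Scores are ranked descending (ties broken by index); the smallest prefix
    whose cumulative score reaches half the sum of the positive scores is
    returned. ``half_rule='gt'`` requires strictly exceeding the half sum.
    All-nonpositive input selects nothing. Input order is irrelevant.
    """
    scores = np.asarray(scores, dtype=np.float64)
    finite_pos = np.where(np.isfinite(scores) & (scores > 0), scores, 0.0)
    possum = finite_pos.sum()
    if possum <= 0:
        return []
    half = possum / 2.0
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores[i] if np.isfinite(scores[i])
                                  else np.inf, i))
    out: list[int] = []
    cum = 0.0
    for i in order:
        if not np.isfinite(scores[i]) or scores[i] <= 0:
            break
        out.append(i)
        cum += scores[i]
        if (cum >= half - 1e-12) if half_rule == "ge" else (cum > half + 1e-12):
            break
    return out


def select_terms(values, strict: bool = True) -> list[int]:
    """Indices of values higher than half the highest value.

    The comparison is strict by default (a value exactly equal to half the
    maximum is excluded); the argmax itself is always included. Returned in
    descending value order, ties broken by index.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) == 0:
        return []
    vmax = np.max(values[np.isfinite(values)]) if np.isfinite(values).any() \
        else -np.inf
    half = vmax / 2.0
    keep = []
    for i, v in enumerate(values):
        if not np.isfinite(v):
            continue
        if (v > half if strict else v >= half) or v == vmax:
            keep.append(i)
    keep.sort(key=lambda i: (-values[i], i))
    return keep


# ---------------------------------------------------------------------------
# Domain-topic tables
# ---------------------------------------------------------------------------

@dataclass
class TopicEntry:
    index: int
    label: str
    score: float
    terms: list[tuple[str, float]]


@dataclass
class TableRow:
    level: int
    index: int
    label: str
    kind: str                       # "common" or "specific"
    topics: list[TopicEntry]
    children: list["TableRow"] = field(default_factory=list)


@dataclass
class DomainTopicTable:
    focal: TableRow

    def to_frame(self) -> pd.DataFrame:
        rows: list[dict] = []

        def walk(node: TableRow) -> None:
            for t in node.topics:
                rows.append({
                    "domain": node.label, "level": node.level,
                    "kind": node.kind, "topic": t.label,
                    "score": t.score,
                    "terms": ", ".join(lab for lab, _ in t.terms),
                })
            if not node.topics:
                rows.append({"domain": node.label, "level": node.level,
                             "kind": node.kind, "topic": "", "score": np.nan,
                             "terms": ""})
            for c in node.children:
                walk(c)

        walk(self.focal)
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines: list[str] = []

        def walk(node: TableRow, depth: int) -> None:
            pad = "  " * depth
            lines.append(f"{pad}- **{node.label}** ({node.kind} topics)")
            for t in node.topics:
                terms = ", ".join(lab for lab, _ in t.terms)
                lines.append(f"{pad}  - {t.label} ({t.score:.3f}): {terms}")
            for c in node.children:
                walk(c, depth + 1)

        walk(self.focal, 0)
        return "\n".join(lines) + "\n"


def _topic_entries(model: BlockModel, level: int, index: int, side: str,
                   kind: str, opp: str) -> list[TopicEntry]:
    if kind == "specific":
        prof = specificity_profile(model, level, index, side)
        el_prof = specificity_profile(model, level, index, side,
                                      granularity="elements")
    else:
        prof = commonality_profiles(model, level, index, side)[1]
        el_prof = commonality_profiles(model, level, index, side,
                                       granularity="elements")[1]
    opp_assign = model.side_assignment(opp, 1)
    opp_labels = (model.graph.right_labels if model.side_index(opp) == 1
                  else model.graph.left_labels)
    entries = []
    for t in select_topics(prof):
        members = np.flatnonzero(opp_assign == t)
        vals = el_prof[members]
        chosen = select_terms(vals)
        terms = [(opp_labels[int(members[i])], float(vals[i]))
                 for i in chosen]
        entries.append(TopicEntry(t, block_label(model, opp, 1, t),
                                  float(prof[t]), terms))
    return entries


def domain_topic_table(model: BlockModel, level: int, index: int,
                       side: str = "doc") -> DomainTopicTable:
    """Recursive topic listing for a focal block at level >= 2.

    Blocks above level 1 get the topics common to their immediate
    subblocks (when they have an ancestor to compare against); level-1
    blocks get their specific topics. Constructible for any block pair —
    e.g. country-domain tables — by passing the appropriate ``side``.
    """
    if level < 2:
        raise ValueError("focal block must be at level >= 2")
    if level > model.n_levels:
        raise ValueError(f"model has only {model.n_levels} level(s)")
    if not (0 <= index < model.n_side_blocks(side, level)):
        raise ValueError(f"no block {index} at level {level}")
    opp = "right" if model.side_index(side) == 0 else "doc"

    def build(lev: int, idx: int) -> TableRow:
        if lev == 1:
            entries = _topic_entries(model, lev, idx, side, "specific", opp)
            return TableRow(lev, idx, block_label(model, side, lev, idx),
                            "specific", entries)
        has_ancestor = lev < model.n_levels
        entries = (_topic_entries(model, lev, idx, side, "common", opp)
                   if has_ancestor else [])
        children = [build(lev - 1, int(c))
                    for c in model.children(side, lev, idx)]
        return TableRow(lev, idx, block_label(model, side, lev, idx),
                        "common", entries, children)

    return DomainTopicTable(build(level, index))


# ---------------------------------------------------------------------------
# Map export
# ---------------------------------------------------------------------------

def _side_volumes(model: BlockModel, side: str, level: int) -> np.ndarray:
    """Domains are sized by document count, topics (and metadata) by edge
    count (term usage)."""
    if model.side_index(side) == 0:
        a = model.side_assignment(side, level)
        return np.bincount(a, minlength=model.n_side_blocks(side, level)
                           ).astype(np.float64)
    return model.edge_counts(model.n_levels, level).sum(axis=0
                                                        ).astype(np.float64)


def _normalize(v: np.ndarray) -> list[float]:
    m = v.max() if len(v) else 0.0
    return [float(x / m) if m > 0 else 0.0 for x in v]


def map_export(model: BlockModel, selection: dict | None = None,
               corpus=None, year_field: str = "year") -> dict:
    """Two facing hierarchies with volumes and per-level relevance colors.

    Without a selection, relevance defaults to the fraction of the corpus a
    domain contains and the fraction of term usage a topic originates.
    With ``selection={"side":..., "level":..., "index":...}``, the opposite
    side is recolored by its usage with respect to the selected block
    (edges shared with the selection over the block's own edges). Relevance
    is normalized so each level's greatest value is 1. Includes per-domain
    document id lists, a per-year histogram (restricted to the selected
    domain, when one is selected) and a term search index.
    """
    if selection is not None:
        s_side = selection["side"]
        s_level, s_index = int(selection["level"]), int(selection["index"])
        if not (1 <= s_level <= model.n_levels) or not (
                0 <= s_index < model.n_side_blocks(s_side, s_level)):
            raise ValueError("unknown selection block")
    sides_out = {}
    for side in ("doc", "right"):
        kind = ("domain" if model.side_index(side) == 0 else
                ("topic" if model.graph.right_type == "term"
                 else model.graph.right_type))
        levels_out = []
        for level in range(1, model.n_levels + 1):
            vol = _side_volumes(model, side, level)
            if selection is not None and \
                    model.side_index(s_side) != model.side_index(side):
                if model.side_index(side) == 0:
                    shared = model.edge_counts(level, s_level)[:, s_index]
                else:
                    shared = model.edge_counts(s_level, level)[s_index, :]
                own = model.edge_counts(level, 1).sum(axis=1) \
                    if model.side_index(side) == 0 \
                    else model.edge_counts(1, level).sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    rel = np.where(own > 0, shared / own, 0.0)
            else:
                rel = vol / vol.sum() if vol.sum() > 0 else vol
            parent = (model.parent_map(side, level)
                      if level < model.n_levels else None)
            blocks = []
            for j in range(len(vol)):
                blocks.append({
                    "index": j,
                    "id": block_label(model, side, level, j),
                    "volume": float(vol[j]),
                    "relevance": _normalize(rel)[j],
                    "parent": int(parent[j]) if parent is not None else None,
                })
            levels_out.append(blocks)
        sides_out[("left" if model.side_index(side) == 0 else "right")] = {
            "kind": kind, "levels": levels_out}

    a1 = model.side_assignment("doc", 1)
    documents = {
        block_label(model, "doc", 1, j):
            [model.graph.left_labels[i] for i in np.flatnonzero(a1 == j)]
        for j in range(model.n_side_blocks("doc", 1))
    }
    histogram = None
    if corpus is not None:
        doc_filter = None
        if selection is not None and model.side_index(s_side) == 0:
            keep = np.flatnonzero(
                model.side_assignment("doc", s_level) == s_index)
            doc_filter = {model.graph.left_labels[i] for i in keep}
        counts: dict[str, int] = {}
        for d in corpus.documents:
            if doc_filter is not None and d.doc_id not in doc_filter:
                continue
            for y in d.metadata.get(year_field, []):
                counts[y] = counts.get(y, 0) + 1
        histogram = dict(sorted(counts.items()))
    search_index = None
    if model.graph.right_type == "term":
        ar = model.side_assignment("right", 1)
        search_index = {lab: int(ar[j])
                        for j, lab in enumerate(model.graph.right_labels)}
    return {
        "format": "domainmap-map/1",
        "sides": sides_out,
        "selection": selection,
        "documents": documents,
        "histogram": histogram,
        "search_index": search_index,
    }


def map_to_json(map_doc: dict) -> str:
    return json.dumps(map_doc, sort_keys=True, separators=(",", ":"))


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>domain-topic map</title>
<style>
body {{ font-family: sans-serif; margin: 0; display: flex; }}
#left, #right {{ flex: 1; height: 95vh; }}
.block {{ stroke: #fff; cursor: pointer; }}
#info {{ position: fixed; bottom: 0; left: 0; right: 0; height: 5vh;
         background: #eee; padding: 2px 8px; font-size: 12px;
         overflow: hidden; }}
#search {{ position: fixed; top: 2px; right: 8px; }}
</style></head>
<body>
<svg id="left"></svg><svg id="right"></svg>
<input id="search" placeholder="search term"/>
<div id="info">hover a block; click to select; type a term to find its
topic</div>
<script>
const DATA = {data};
function draw(svgId, sideKey, color) {{
  const svg = document.getElementById(svgId);
  const W = svg.clientWidth, H = svg.clientHeight;
  const side = DATA.sides[sideKey];
  const L = side.levels.length;
  side.levels.forEach((blocks, li) => {{
    const lvl = sideKey === 'left' ? L - 1 - li : li;
    const total = blocks.reduce((s, b) => s + b.volume, 0);
    let y = 0;
    blocks.forEach(b => {{
      const h = H * b.volume / total;
      const r = document.createElementNS('http://www.w3.org/2000/svg','rect');
      r.setAttribute('x', lvl * W / L); r.setAttribute('y', y);
      r.setAttribute('width', W / L - 1); r.setAttribute('height', h - 1);
      r.setAttribute('class', 'block');
      r.setAttribute('fill', color);
      r.setAttribute('fill-opacity', 0.15 + 0.85 * b.relevance);
      r.addEventListener('mouseover', () =>
        document.getElementById('info').textContent =
          b.id + '  volume=' + b.volume + '  relevance=' +
          b.relevance.toFixed(3));
      svg.appendChild(r);
      y += h;
    }});
  }});
}}
draw('left', 'left', '#c03');
draw('right', 'right', '#06c');
document.getElementById('search').addEventListener('change', (e) => {{
  const t = DATA.search_index && DATA.search_index[e.target.value];
  document.getElementById('info').textContent = t === undefined ?
    'term not found' : 'term "' + e.target.value + '" is in topic L1T' + t;
}});
</script></body></html>
"""


def render_map_html(map_doc: dict) -> str:
    """Self-contained static viewer embedding the map JSON (best effort;
    the JSON document is the artifact of record)."""
    return _HTML_TEMPLATE.format(data=map_to_json(map_doc))


# ---------------------------------------------------------------------------
# Bump charts
# ---------------------------------------------------------------------------

def bump_chart(chained: ChainedModel, domain_level: int,
               period_level: int = 1, domains: list[int] | None = None,
               doc_model: DomainTopicModel | None = None) -> pd.DataFrame:
    """Per (domain, period) volumes and ranks for an area bump chart.

    Absolute volume is the domain's documents in the period averaged per
    year (count divided by the number of years in the period); relative
    volume is the domain's share of the period's documents. Ranks order
    domains within each period by absolute volume, ties broken by domain
    index. Domains are given as source-model within-side indices at
    ``domain_level`` (default: all domains present in the chained graph).
    """
    from .chained_model import period_summary

    summary = period_summary(chained).table
    periods = summary[summary.level == period_level].reset_index(drop=True)
    if len(periods) == 0:
        raise ValueError("no periods at the requested level")
    if domains is None:
        domains = [int(d)
                   for d in chained.doc_block_origin[domain_level - 1]]
    rows = []
    for p_i, prow in periods.iterrows():
        p_mask = chained.docs_in_period(period_level, int(prow["period"]))
        n_period = int(p_mask.sum())
        if n_period == 0:
            raise ValueError(f"period {p_i} is empty")
        n_years = len(prow["members"])
        for d in domains:
            d_mask = chained.docs_in_source_domain(domain_level, d)
            n = int((p_mask & d_mask).sum())
            label = (block_label(doc_model, "doc", domain_level, d)
                     if doc_model is not None
                     else f"L{domain_level}D{d}")
            rows.append({
                "period": p_i,
                "period_members": ",".join(prow["members"]),
                "domain": d,
                "domain_label": label,
                "n_docs": n,
                "absolute_volume": n / n_years,
                "relative_volume": n / n_period,
            })
    df = pd.DataFrame(rows)
    df["rank"] = 0
    for p_i in df["period"].unique():
        sub = df[df.period == p_i].sort_values(
            ["absolute_volume", "domain"], ascending=[False, True])
        df.loc[sub.index, "rank"] = np.arange(1, len(sub) + 1)
    return df


def specificity_edge_list(model: BlockModel, domain_level: int,
                          topic_level: int = 1) -> pd.DataFrame:
    """Positive domain-topic specificity links (the underlying data of a
    domain-topic network drawing)."""
    rows = []
    for d in range(model.n_side_blocks("doc", domain_level)):
        prof = specificity_profile(model, domain_level, d, "doc")
        for t in np.flatnonzero(prof > 0):
            rows.append({
                "domain": block_label(model, "doc", domain_level, d),
                "topic": block_label(model, "right", topic_level, int(t)),
                "specificity": float(prof[t]),
            })
    return pd.DataFrame(rows)
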