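# Methods

## Model

A corpus is represented as a simple bipartite graph: one node per document,
one per distinct term, and an edge whenever the term occurs in the
document. Local term frequency is discarded (binary incidence), which
weights thematic features over stylistic ones. The graph is fitted with a
nested, degree-corrected, non-overlapping stochastic block model under the
constraint that blocks are type-pure: document blocks are *domains*, term
blocks *topics*. Degree correction matters because term degrees are
fat-tailed while document degrees are narrow; a single model that captures
general connectivity patterns handles both sides, and later also metadata.

The fit minimizes the total description length (all quantities in nats):

- **Graph likelihood** (microcanonical degree-corrected, simple graph):
  `−ln P(A|k,e,b) = Σ_r ln e_r! − Σ_{r<s} ln e_rs! − Σ_r ln e_rr!! − Σ_i ln k_i!`.
  For type-pure bipartite partitions all within-block terms vanish and
  only cross-type block pairs contribute.
- **Degree prior**: uniform over degree sequences given the block degree
  totals, `Σ_r ln multiset(n_r, e_r)` with `multiset(n, m) = C(n+m−1, m)`.
- **Partition prior**, per node type and per level:
  `ln C(n−1, B−1) + ln n! − Σ_r ln n_r!`.
- **Nested edge-matrix prior**: the level-l block multigraph is itself
  modeled by a (non-degree-corrected) SBM at level l+1; its edge matrix
  costs `Σ_{(R,S)} ln multiset(n_R·n_S, e_RS)` over cross-type block pairs
  of the level above, with `n_R` counting level-l blocks. The hierarchy
  closes at a top level with one block per type, whose single-cell matrix
  costs nothing beyond the (constant) edge total.

This is a standard, self-consistent microcanonical MDL formulation; the
two-level special case (a flat partition plus the trivial top) replaces the
nested prior by `ln multiset(B_d·B_t, E)`, which is exactly what the
exhaustive-enumeration oracle in the test suite evaluates. Appending a
trivial level never changes the total, so flat and nested states are
compared on one scale. DL is invariant under block relabeling; fitted
partitions are canonicalized (documents first, then first occurrence).

Two deliberate restrictions simplify interpretation: a single best-known
fit rather than posterior averaging, and non-overlapping blocks, so each
document belongs to exactly one domain.

## Search

`fit()` runs `n_restarts` independent searches and keeps the lowest-DL
state found:

1. **Agglomerative descent.** Starting from one block per node, each round
   merges blocks down by the shrink factor `sigma` (best candidate merges
   by exact pairwise DL delta, stale within a round) and then runs up to
   `sweeps` single-node move sweeps; the best flat state along the descent
   is recorded. Fresh-block moves are disabled here: a split that the next
   forced merge round undoes would cycle.
2. **Polish.** From the best recorded state, sweeps (now allowing moves to
   a fresh block) alternate with the single best merge for as long as
   either strictly lowers DL. Every applied action strictly decreases DL,
   so this terminates.
3. **Hierarchy growth.** The block multigraph of the current level is
   itself grouped (greedy merges plus reassignment passes under the
   conditional DL of that level); since the trivial grouping reproduces
   the current closure cost exactly, adding a level never worsens the
   total, and growth stops at the first trivial level (cap `max_levels`).

Moves are greedy by default (`beta = ∞`); a finite `beta` samples
candidates by `exp(−β·ΔDL)`. Equal-DL states resolve to the first found
under the seeded stream; a single `seed` fixes the full random stream, and
all serialized artifacts are byte-reproducible. Single-node deltas and
merge deltas are computed incrementally against integer log-factorial
tables; final states are always re-scored by the exact from-scratch
evaluator, which the tests compare against an independent hand
transcription.

## Chained models

`fit_chained()` transposes the fitted document hierarchy onto a
document–metadata graph and keeps it immutable at **all** levels (the
hierarchy is conditioned on in full, not just its base level, matching the
nested-blocks semantics of the construction); only metadata nodes are
moved, merged, and charged a partition prior. The metadata hierarchy has
the same depth as the document hierarchy, with collapsed (single-block)
levels allowed; metadata values are categorical — years carry no ordinal
prior, so chronological contiguity of recovered periods is a finding, not
a constraint. Sub-corpus re-chaining (periods or countries of one domain)
is the same operation on a filtered graph via `domain_document_ids`.

## Measures

Each block induces a distribution over opposite-side level-1 blocks (or
individual elements): the fraction of its edges landing in each unit;
ancestor distributions aggregate descendant counts, so a unit present in a
block is present in every ancestor (dominance), making nested specificity
always finite. The superdomain ladder excludes the block itself and
includes every level strictly above, up to the top. Conventions chosen
where the formulas leave limits open:

- specificity uses `0·ln(0/q) = 0`;
- commonality is −∞ whenever some subdomain lacks the unit while the mean
  subdomain probability is positive, and defined as 0 when that mean
  weight is itself zero (the `0·(−∞)` case);
- natural logarithms throughout — the base only rescales ranks, and
  ranking is what tables and maps consume;
- no smoothing or pseudocounts: raw frequencies, embracing −∞.

Prevalence of a domain in a period is its **share of the period's
documents** (not its absolute count): corpus volume typically grows
strongly over time, and shares are what make periods comparable.
Prevalence change is the share in the later period minus the earlier one.

## Tables, maps, labels

Blocks render as `L{level}{D|T|P}{index}`; topic indices start at 0 and
domain indices start from the highest topic index of the same level, so
the two kinds never collide; periods print 1-based. Domain-topic tables
list common topics (commonality-scored) for rows above level 1 and
specific topics (specificity-scored) for level-1 rows — the half-sum rule
keeps topics until their cumulative score reaches half the positive total
(boundary: reaching exactly half stops, configurable), and the half-max
rule keeps terms strictly above half the topic's best value (the argmax is
always kept; configurable to non-strict). Maps size domains by document
count and topics by edge count, normalize relevance per level to a maximum
of 1, and on selection recolor the opposite side by shared-edge fraction
`e(x, s)/e(x)`. The JSON map document is the artifact of record; the
bundled HTML viewer is a best-effort convenience.

## Synthetic data

The generator plants the structure the model assumes: documents assigned
round-robin to domains; each document draws term slots (Poisson with mean
`mean_terms`, or gamma-Poisson when `dispersion` is set) from its domain's
topic mixture, replaced with probability `epsilon` by a uniform draw over
all terms — a background component mimicking the stop-word structure of
real corpora — and the slot sequence is deduplicated to match the binary
incidence the model consumes. Metadata values are drawn from per-domain
weight vectors; `year_drift_spec` splits domains into an early and a late
group drawing 90% of their years from opposite halves of the range.

Benchmark conditions (also the generator defaults): 300 documents, 60
terms, 3 domains, 4 topics, mixture concentration 0.8 on the
characteristic topic, mean 20 term draws per document, ε = 0.05. These
sizes keep a single fit in seconds while leaving the planted structure
~1000 nats below the one-block state. What passing them does **not** show:
real corpora have fat-tailed vocabularies (hundreds of thousands of
terms), multi-valued and missing metadata, and vocabulary drift over time;
the generator's terms are exchangeable within a topic and its documents
within a domain, so the benchmarks validate correctness of inference and
measures, not retrieval quality on real text.

## Numerical choices and limitations

- Integer log-factorial lookup tables back all incremental deltas; exact
  totals are recomputed with `scipy.special.gammaln`. Improvement
  thresholds use an absolute 1e-9 guard.
- The block edge-count matrix is dense, so memory grows with the square of
  the node count; desk-scale corpora (up to a few thousand documents) are
  the intended regime of this implementation.
- Collocation defaults δ = 5, θ = 10 are the conventional values of the
  discounted score; both are exposed, as is the tokenizer's behavior
  (lowercase, split on non-alphanumeric, underscores preserved). One pass
  only: bigrams, not higher n-grams.
- Empty documents are dropped (the model needs connected documents);
  documents lacking a metadata field are kept in the doc-term graph but
  omitted from that field's chained graph.
- The search is a heuristic: restarts bound, but do not eliminate, the
  chance of a local optimum (exhaustive optimality is verified on small
  graphs only). Term-side recovery occasionally merges two planted topics
  in a minority of seeds; the benchmarks assert medians.
- Out of scope by design: overlapping blocks, posterior averaging over
  partitions, weighted or layered graph variants, and joint re-inference
  of documents with metadata.
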