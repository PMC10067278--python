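# Methods

## The audit model

The object of study is a pair: a directed systems map `G = (V, E)` of
factors, and a binary coverage coding `cov : V × S → {0, 1}` over a set of
data sources `S`, where `cov(n, s) = 1` means source `s` contains at least
one question or indicator that could measure factor `n`. The coding is
deliberately binary — one face-valid question suffices — and carries no
judgment of measurement quality.

Three descriptive summaries are computed, all exact counts with percentages
`100·count/total` rounded half-away-from-zero to two decimals:

- **Node coverage.** Per-source counts, the count covered by no source, by
  exactly one, and by at least k for k = 1..|S|. `covered_by_none +
  at_least_1 = |V|` by construction, and `at_least_k` is non-increasing in k.
- **Edge coverage.** Direction is ignored: the question is whether data on
  *both* endpoints can come from one place. For each edge (u, v):
  *within source s* iff `cov(u,s) ∧ cov(v,s)`; *within any one* iff some s
  qualifies; otherwise *cross-source only* if both endpoints are covered
  somewhere, *one endpoint only* if exactly one is, *neither* otherwise.
  The four top-level categories are mutually exclusive and exhaustive, so
  their counts must sum to the deduplicated edge count; the report raises a
  visible diagnostic if an input coding ever breaks that accounting (which
  can happen when a published coding and map version have drifted apart —
  precisely what an audit must surface rather than absorb). A self-loop is
  retained with a warning and categorized by its single endpoint (within a
  source iff that source covers the node).
- **Level coverage.** Factors are tagged with one or more social-ecological
  levels (individual, relationship, community, societal). A multi-level
  factor contributes to each of its levels, so per-level map counts may sum
  to more than |V|. The gradient check asks whether percent coverage
  strictly decreases along the outward order; a tie fails it.

## Rounding

One rounding rule is used throughout: half-away-from-zero at two decimals,
implemented with `decimal.Decimal` to avoid binary-float artifacts.
Published tables of this kind are not always internally consistent (some
cells appear truncated rather than rounded), so comparisons against printed
values should allow ±0.01.

## Codebook matching

The matcher mechanizes a human codebook scan. Text normalization is
lowercasing, punctuation stripping and whitespace tokenization — no
stemming, and stop-word removal only behind a flag, because the audit
favours reproducibility over recall. The default match mode requires every
token of a search term to occur in the item's token set, order-free; a
verbatim-substring mode and a `difflib`-based fuzzy token mode (similarity
threshold, default 0.88) exist behind flags. Search terms per node are the
node's own label, lexicon synonyms, and — only when neighbor expansion is
switched on — the labels of in- and out-neighbors, each hit tagged with the
neighbor it came through. Neighbor-derived cells are written with a
`needs_review` flag and are never meant to be auto-accepted: edge-following
is a search aid; the final yes/no coding is a human judgment. Every emitted
record carries provenance (term, term type, item) sufficient to re-verify
the match, and the record list is stably ordered by (source, variable id,
node id), so identical inputs give identical output bytes.

## Synthetic data: what it emulates and what it does not

The generator exists so that every stage has a testable ground truth.
Defaults describe a study-scale audit of an adolescent-suicide map:

- **Map.** 364 factors (123/117/80/44 primary assignments across
  individual/relationship/community/societal, proportional to a real map's
  level profile) and 946 directed edges sampled uniformly without
  self-loops. Each node gains a second level with probability 0.24, so the
  expected sum of per-level assignments (~451) exceeds the node count, as
  real multi-level tagging does.
- **Coverage.** Each (node, source) cell is an independent coin flip at the
  node's level probability (a multi-level node takes the maximum of its
  levels' probabilities — any fixed rule would do for testing; max keeps the
  gradient interpretable). Default per-source probabilities
  {individual 0.335, relationship 0.30, community 0.235, societal 0.12}
  were calibrated once from the closed form `1 − (1 − p)^5` so that
  five-source any-coverage reproduces the decreasing per-level gradient
  observed in real audits (~87/83/74/47%).
- **Codebooks.** For every planted "yes" cell, one item embeds a term from
  the node's search set inside filler text; each source also receives 100
  pure-filler distractor items by default. Label, synonym and filler
  vocabularies are token-disjoint by construction (labels are two-token
  combinations with pairwise-distinct token sets; synonyms are globally
  unique suffixed tokens), which makes draft-vs-planted precision and recall
  exactly 1.0 — the recovery guarantee the matcher tests rely on.

Reproducibility: each generator stage draws from `numpy`'s PCG64 seeded with
`[master_seed, stage_offset]`, so regenerating a later stage never perturbs
an earlier one.

What the generator does **not** emulate, and therefore what passing tests do
not show about real data: per-cell coin flips are independent, whereas real
questionnaire coverage is strongly clustered within a source (a survey that
asks about one endpoint of a mechanism often asks about the other). As a
result the synthetic share of edges coverable within a single source
(~31% under the defaults) is far below what real audits report (~80%);
node- and level-coverage rates are comparable, edge-level joint coverage is
conservative. Question text is vocabulary sampling, not language, so the
matcher's perfect recovery on synthetic codebooks says nothing about recall
on real question rewordings — on real data the drafted matrix is a
recall-oriented candidate set for human review, not a finished coding.

At study scale, adjacent levels' expected coverages (e.g. ~87% vs ~83% on
~120–150 nodes) differ by about one standard error, so a *strict* decrease
of empirical percentages is not guaranteed on every seed; the generator's
tests assert the strict decrease of the closed-form targets and that
realizations stay within 99% binomial bounds of them. Relatedly, at
saturating probabilities (any-coverage ≥ 99.7%) two levels will often tie at
100% observed coverage at a few hundred nodes per level, defeating a strict
gradient check regardless of sample.

## Numerical and design choices

- Duplicate edge rows collapse to one edge with a logged warning; the
  reverse orientation is a distinct edge, but edge categorization depends
  only on the endpoint set, so both orientations always land in the same
  category.
- Unknown node ids in a coverage file are a hard error; map nodes missing
  from the file are filled all-absent with a warning. The asymmetry is
  deliberate: extra rows mean version drift, missing rows mean incomplete
  coding.
- Cell vocabulary is strict ({yes,no}, {y,n}, {1,0}, {true,false},
  case-insensitive); anything else is a format error naming the cell.
- Summaries over an empty universe (an edgeless map) report 0.00% rather
  than failing; `percent_of` itself refuses a zero denominator.
- The audit CLI has no randomness; `synth` takes an explicit seed. With
  `--no-provenance`, repeated runs on identical inputs are byte-identical.

## Problem sizes

The test suite runs the partition invariant on 1,000 fuzzed maps (up to ~14
nodes), brute-force oracle equivalence on several hundred random maps of ≤ 8
nodes × ≤ 3 sources plus every coverage matrix on fixed 3- and 4-node maps,
planted-match recovery at 50 nodes × 3 sources × 100 distractors per source,
and gradient recovery at 400 nodes × 5 sources; the whole suite completes in
a few seconds.

## Known limitations

- Binary presence only: no notion of whether a question supports a desired
  analysis (age ranges, wording, periodicity).
- The matcher drafts; it does not replicate any particular published manual
  coding, whose face-validity threshold for "yes" is a human judgment.
- No statistical inference on coverage proportions — the summaries are
  descriptive, as coverage is a census of the map, not a sample.
- Edge direction is preserved in I/O but unused analytically; analyses that
  distinguish drivers from consequences would need a different edge summary.
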