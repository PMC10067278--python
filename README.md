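# mapgap

Data-gap audits of causal systems maps against surveillance data sources.

## The problem

Systems maps of public-health problems — here, adolescent suicide — encode
expert knowledge as a directed graph: each node is a factor (bullying,
hopelessness, housing stability, economic policy ...) and each edge states
that one factor contributes to another. Turning such a map into quantitative
models requires data, and national surveys were never designed against the
map. `mapgap` audits that mismatch. Given

1. a map (nodes with social-ecological level tags; directed edges), and
2. a binary node × source coverage coding — does source *s* contain at least
   one question measuring factor *n*? —

it computes where data exists and where it is missing, at three grains:

- **Factors (nodes).** For each source the covered share
  `pct(s) = 100·|{n : cov(n,s)}| / N`, plus the share covered by no source,
  by exactly one, and by ≥ k sources.
- **Causal mechanisms (edges).** An edge (u, v) is quantitatively studiable
  *within* a source s only if cov(u,s) ∧ cov(v,s). Every edge falls in
  exactly one of four categories: coverable within some single source;
  coverable only by combining different sources (both endpoints covered
  somewhere, but never together); one endpoint covered; neither covered.
  These four categories partition the edge set — the audit verifies that
  accounting on every run and reports any discrepancy loudly.
- **Social-ecological levels.** The same per-factor coverage stratified by
  level (individual, relationship, community, societal; a multi-level factor
  counts in each of its levels), with a check whether coverage strictly
  decreases as one moves outward from the individual.

Percentages are reported on the 0–100 scale, rounded half-away-from-zero to
two decimals.

A codebook matcher drafts the coverage coding from raw data dictionaries:
for each node it searches every item's question text for the node's label,
curated synonyms (e.g. "homeless", "eviction" for a housing-stability
factor), and optionally the labels of adjacent nodes, and emits a full
provenance record per hit so a human reviewer can accept or overrule each
drafted cell. A synthetic generator produces maps, codings and codebooks
with known planted structure so the whole pipeline is testable end to end.

## Worked example

```python
from mapgap import (SyntheticConfig, generate_map, generate_coverage,
                    node_coverage, edge_coverage, level_coverage, gradient_check)

cfg = SyntheticConfig(seed=1)          # study-scale defaults: 364 nodes, 946 edges
smap = generate_map(cfg)
cm = generate_coverage(smap, cfg)

ns = node_coverage(smap, cm)
es = edge_coverage(smap, cm)
ls = level_coverage(smap, cm)
print(smap)
print("factors with no data:", ns.covered_by_none)
print("mechanisms within one source:", es.within_any_one)
print({l: ls.percent_covered[l] for l in ls.levels})
print("strictly decreasing:", gradient_check(ls))
```

prints

```
SystemsMap(n_nodes=364, n_edges=946)
factors with no data: CountPercent(count=79, percent=21.7)
mechanisms within one source: CountPercent(count=297, percent=31.4)
{'individual': 85.51, 'relationship': 83.7, 'community': 72.38, 'societal': 60.61}
strictly decreasing: True
```

So on this synthetic audit roughly 1 in 5 factors has no supporting data in
any source, less than a third of causal mechanisms can be studied inside a
single source, and coverage falls from the individual level outward — the
qualitative signature such audits show on real surveillance data.

The same pipeline runs from the shell:

```
mapgap synth --out fixtures --seed 1
mapgap audit --nodes fixtures/nodes.csv --edges fixtures/edges.csv \
             --coverage fixtures/coverage.csv --out report --format markdown
mapgap match --codebook fixtures/codebook_S1.csv --nodes fixtures/nodes.csv \
             --edges fixtures/edges.csv --lexicon fixtures/lexicon.csv \
             --out draft.csv
```

`mapgap audit` accepts real inputs in the same CSV dialects: nodes
(`id,label,levels` with semicolon-separated levels), edges
(`source,target`), coverage (`node_id,<one column per source>` with yes/no
cells). A YAML file passed as `--config` may override any flag; its keys are
the long option names (e.g. `format: json`, `levels_order: "individual,relationship,community,societal"`,
or for `synth` any generator field such as `n_edges: 500`).

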