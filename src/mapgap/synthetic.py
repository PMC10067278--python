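"""Synthetic maps, coverage codings, lexicons and codebooks with planted truth.

The generator emulates the structure of a real audit so every pipeline stage
is testable without any download: a leveled map whose social-ecological
profile mirrors an actual factor map, a coverage coding whose per-level
probability falls off from individual to societal (the gradient observed in
real surveillance data), and per-source codebooks in which every planted
"yes" cell is backed by a question embedding one of the node's search terms
inside filler text.  Node-label, synonym and filler vocabularies are
token-disjoint by construction, so the codebook matcher can be scored
exactly against the planted coverage matrix.

Each generator draws from its own random stream derived from the master seed
by a fixed offset; regenerating the codebook therefore never perturbs the
map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np

from .coverage import CoverageMatrix, write_coverage
from .errors import ConfigurationError
from .map_io import LEVELS, Edge, Node, SystemsMap, write_map
from .matching import CodebookItem, Lexicon, expand_terms
import csv

# Three pairwise token-disjoint vocabularies.  Node labels draw on factor
# words, codebook filler on survey-administration words, synonyms on suffixed
# construct words — disjointness is what makes planted-match recovery exact.
NODE_VOCAB = (
    "bullying isolation depression anxiety hopelessness impulsivity aggression "
    "neglect abuse poverty unemployment housing instability stigma firearm "
    "access alcohol substance misuse trauma discrimination connectedness "
    "belonging supervision conflict divorce incarceration violence "
    "victimization harassment insomnia rumination perfectionism shame grief "
    "bereavement delinquency truancy homelessness eviction religiosity "
    "spirituality resilience coping therapy counseling medication "
    "hospitalization stressors burdensomeness entrapment defeat loneliness "
    "rejection exclusion cyberbullying gambling debt inequality segregation"
).split()

DISTRACTOR_VOCAB = (
    "respondent questionnaire interview module section item scale frequency "
    "weekly monthly yearly baseline followup wave cohort sample weight stratum "
    "cluster missing refused skipped coded categorical numeric integer boolean "
    "response option answer prompt card booklet proxy household roster "
    "screener eligibility consent administered computer telephone mailed "
    "school grade classroom district county region state national survey "
    "census record linkage identifier version revision release archive"
).split()

_SYN_BASE = (
    "suicidality morbidity psychopathology adversity vulnerability exposure "
    "riskfactor protectivefactor wellbeing psychdistress"
).split()

# Study-scale defaults: 364 factors split across levels in proportion to an
# actual adolescent-suicide map's per-level tallies (152/145/99/55), with a
# second level added to roughly a quarter of nodes so that the expected sum
# of per-level assignments (~451) exceeds the node count, as real maps do.
_DEFAULT_NODES_PER_LEVEL = {
    "individual": 123,
    "relationship": 117,
    "community": 80,
    "societal": 44,
}

# Per-(level, source) coin probabilities calibrated so that with five sources
# the chance a factor is covered anywhere, 1-(1-p)^5, reproduces the observed
# per-level coverage gradient (~87/83/74/47%).
_DEFAULT_COVERAGE_PROB = {
    "individual": 0.335,
    "relationship": 0.30,
    "community": 0.235,
    "societal": 0.12,
}


@dataclass
class SyntheticConfig:
    """Parameters of the generator; ``seed`` fully determines all outputs."""

    nodes_per_level: dict = field(default_factory=lambda: dict(_DEFAULT_NODES_PER_LEVEL))
    multi_level_prob: float = 0.24
    n_edges: int = 946
    n_sources: int = 5
    source_names: Optional[tuple] = None
    coverage_prob: dict = field(default_factory=lambda: dict(_DEFAULT_COVERAGE_PROB))
    synonyms_per_node: int = 2
    distractors_per_source: int = 100
    filler_tokens: tuple = (4, 9)  # inclusive range of filler tokens per item
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.multi_level_prob <= 1.0):
            raise ConfigurationError("multi_level_prob must be in [0, 1]")
        for level, p in self.coverage_prob.items():
            values = p.values() if isinstance(p, dict) else [p]
            if not all(0.0 <= v <= 1.0 for v in values):
                raise ConfigurationError(f"coverage_prob[{level!r}] outside [0, 1]")
        unknown = set(self.nodes_per_level) - set(LEVELS)
        if unknown:
            raise ConfigurationError(f"unknown level(s) in nodes_per_level: {sorted(unknown)}")

    @property
    def sources(self) -> tuple:
        if self.source_names is not None:
            return tuple(self.source_names)
        return tuple(f"S{i + 1}" for i in range(self.n_sources))

    def node_probability(self, levels) -> float:
        """A multi-level node takes the maximum of its levels' probabilities."""
        ps = []
        for level in levels:
            p = self.coverage_prob.get(level, 0.0)
            if isinstance(p, dict):
                ps.extend(p.values())
            else:
                ps.append(p)
        return max(ps) if ps else 0.0

    def rng(self, stream: int) -> np.random.Generator:
        # one stream per generator stage, at a fixed offset from the master seed
        return np.random.default_rng([int(self.seed), stream])


_STREAM_MAP, _STREAM_COVERAGE, _STREAM_LEXICON, _STREAM_CODEBOOK = range(4)


def _label_pool(n_needed: int):
    """Distinct two-token labels with pairwise-distinct token *sets*.

    Distinct token sets (not just distinct strings) keep the order-free token
    matcher free of cross-label collisions.  The vocabulary is extended with
    suffixed variants when more labels are needed than the base list allows.
    """
    vocab = list(NODE_VOCAB)
    suffix = 2
    while len(vocab) * (len(vocab) - 1) // 2 < n_needed:
        vocab += [f"{w}{suffix}" for w in NODE_VOCAB]
        suffix += 1
    return list(combinations(vocab, 2))


def generate_map(config: SyntheticConfig) -> SystemsMap:
    """A leveled map with ``nodes_per_level`` primary nodes per level.

    Each node may gain one extra level with probability ``multi_level_prob``;
    ``n_edges`` distinct ordered pairs are sampled uniformly, self-loops
    excluded.
    """
    rng = config.rng(_STREAM_MAP)
    n_total = sum(config.nodes_per_level.values())
    if n_total == 0:
        raise ConfigurationError("no nodes requested")
    max_edges = n_total * (n_total - 1)
    if config.n_edges > max_edges:
        raise ConfigurationError(
            f"n_edges={config.n_edges} infeasible for {n_total} nodes (max {max_edges})"
        )
    pool = _label_pool(n_total)
    picks = rng.choice(len(pool), size=n_total, replace=False)
    nodes: list[Node] = []
    idx = 0
    for level in LEVELS:
        for _ in range(config.nodes_per_level.get(level, 0)):
            levels = {level}
            if rng.random() < config.multi_level_prob:
                extra = [l for l in LEVELS if l != level]
                levels.add(extra[rng.integers(len(extra))])
            a, b = pool[picks[idx]]
            nodes.append(Node(id=f"n{idx:04d}", label=f"{a} {b}", levels=frozenset(levels)))
            idx += 1
    # sample ordered pairs without replacement by indexing the off-diagonal cells
    flat = rng.choice(max_edges, size=config.n_edges, replace=False)
    edges = []
    for f in np.sort(flat):
        a, r = divmod(int(f), n_total - 1)
        b = r if r < a else r + 1
        edges.append(Edge(nodes[a].id, nodes[b].id))
    return SystemsMap(nodes, edges)


def generate_coverage(smap: SystemsMap, config: SyntheticConfig) -> CoverageMatrix:
    """Independent coin flips per (node, source) at the node's level probability."""
    rng = config.rng(_STREAM_COVERAGE)
    sources = config.sources
    entries = {}
    for node in smap.nodes:
        p = config.node_probability(node.levels)
        draws = rng.random(len(sources)) < p
        for source, hit in zip(sources, draws):
            entries[(node.id, source)] = bool(hit)
    return CoverageMatrix.from_dict(entries, smap.node_ids, sources)


def generate_lexicon(smap: SystemsMap, config: SyntheticConfig) -> Lexicon:
    """Single-token synonyms, globally unique, disjoint from all other vocabularies."""
    rng = config.rng(_STREAM_LEXICON)
    lex = Lexicon()
    counter = 0
    for node in smap.nodes:
        for _ in range(config.synonyms_per_node):
            base = _SYN_BASE[int(rng.integers(len(_SYN_BASE)))]
            lex.add(node.id, f"{base}{counter:04d}")
            counter += 1
    return lex


def generate_codebook(
    smap: SystemsMap,
    cm: CoverageMatrix,
    lexicon: Lexicon,
    config: SyntheticConfig,
) -> list[CodebookItem]:
    """Codebooks realizing a planted coverage matrix.

    For every (node, source) cell coded present, one item embeds a term from
    the node's search-term set (label or synonym) inside filler text drawn
    only from the distractor vocabulary; each source additionally receives
    ``distractors_per_source`` pure-filler items.  Matching the result
    reconstructs ``cm`` exactly.
    """
    term_tokens = set()
    for node in smap.nodes:
        term_tokens.update(node.label.split())
    for node_id in lexicon.node_ids():
        for term in lexicon.synonyms(node_id):
            term_tokens.update(term.split())
    overlap = term_tokens & set(DISTRACTOR_VOCAB)
    if overlap:
        raise ConfigurationError(
            f"term and distractor vocabularies overlap: {sorted(overlap)[:5]}"
        )

    rng = config.rng(_STREAM_CODEBOOK)
    lo, hi = config.filler_tokens
    counters = dict.fromkeys(cm.sources, 0)
    items: list[CodebookItem] = []

    def filler(k: int) -> list[str]:
        picks = rng.integers(len(DISTRACTOR_VOCAB), size=k)
        return [DISTRACTOR_VOCAB[int(i)] for i in picks]

    for node in smap.nodes:
        terms = sorted(
            exp.term for exp in expand_terms(node.id, smap, lexicon, include_neighbors=False)
        )
        for source in cm.sources:
            if not cm.is_present(node.id, source):
                continue
            term = terms[int(rng.integers(len(terms)))]
            words = filler(int(rng.integers(lo, hi + 1)))
            pos = int(rng.integers(len(words) + 1))
            text_tokens = words[:pos] + term.split() + words[pos:]
            counters[source] += 1
            items.append(
                CodebookItem(
                    source=source,
                    variable_id=f"{source}_V{counters[source]:05d}",
                    text=" ".join(text_tokens).capitalize() + "?",
                    category="planted",
                )
            )
    for source in cm.sources:
        for _ in range(config.distractors_per_source):
            counters[source] += 1
            items.append(
                CodebookItem(
                    source=source,
                    variable_id=f"{source}_V{counters[source]:05d}",
                    text=" ".join(filler(int(rng.integers(lo, hi + 1)))).capitalize() + "?",
                    category="distractor",
                )
            )
    return items


def write_fixture_set(config: SyntheticConfig, outdir) -> dict:
    """Generate and write the full fixture set; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    smap = generate_map(config)
    cm = generate_coverage(smap, config)
    lex = generate_lexicon(smap, config)
    codebook = generate_codebook(smap, cm, lex, config)

    paths = {
        "nodes": outdir / "nodes.csv",
        "edges": outdir / "edges.csv",
        "coverage": outdir / "coverage.csv",
        "lexicon": outdir / "lexicon.csv",
    }
    write_map(smap, paths["nodes"], paths["edges"])
    write_coverage(cm, paths["coverage"])
    with paths["lexicon"].open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "term"])
        for node_id in lex.node_ids():
            for term in lex.synonyms(node_id):
                writer.writerow([node_id, term])
    for source in cm.sources:
        path = outdir / f"codebook_{source}.csv"
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "variable_id", "text", "category"])
            for item in codebook:
                if item.source == source:
                    writer.writerow([item.source, item.variable_id, item.text, item.category])
        paths[f"codebook_{source}"] = path
    return paths
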