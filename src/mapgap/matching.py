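"""Draft a coverage matrix from raw codebooks by term search.

The search mechanizes how an analyst scans a data dictionary for a map
factor: look for the factor's own label, for curated synonyms (e.g. a
"housing stability" factor is searched as "homeless" and "eviction"), and —
optionally — for the labels of adjacent factors, on the reasoning that a
question about a driver or consequence of a factor can point a reviewer at
relevant content.  Every hit is recorded with full provenance (which term,
which type of term, which neighbor it came through) so a human can audit and
overrule each drafted "yes".  Neighbor-derived cells are flagged for
mandatory review rather than silently accepted: edge-following is a search
aid, not a coding criterion.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .coverage import CoverageMatrix
from .errors import FormatError
from .map_io import SystemsMap

#: Small built-in stop-word list; applied only when the config flag is set.
STOP_WORDS = frozenset(
    "a an and are as at be by for from has have in is it of on or that the to was with".split()
)

_PUNCT_TABLE = str.maketrans({c: " " for c in r"""!"#$%&'()*+,-./:;<=>?@[\]^_`{|}~"""})

#: Match-type precedence when one normalized term arises in several ways.
_TYPE_RANK = {"exact_label": 0, "synonym": 1, "neighbor": 2}


def normalize_text(s: str, remove_stopwords: bool = False) -> tuple[str, ...]:
    """Lowercase, strip punctuation, split on whitespace.  No stemming."""
    tokens = s.lower().translate(_PUNCT_TABLE).split()
    if remove_stopwords:
        tokens = [t for t in tokens if t not in STOP_WORDS]
    return tuple(tokens)


@dataclass(frozen=True)
class CodebookItem:
    """One variable of a data source's codebook / data dictionary."""

    source: str
    variable_id: str
    text: str
    category: Optional[str] = None


class Lexicon:
    """Synonym sets per node id; a node absent from the lexicon matches on its label only."""

    def __init__(self, terms: Optional[dict] = None):
        self._terms: dict[str, tuple[str, ...]] = {}
        for node_id, synonyms in (terms or {}).items():
            self.add(node_id, *synonyms)

    def add(self, node_id: str, *synonyms: str) -> None:
        cleaned = [s.strip() for s in synonyms if s.strip()]
        existing = list(self._terms.get(node_id, ()))
        for s in cleaned:
            if s not in existing:
                existing.append(s)
        self._terms[node_id] = tuple(existing)

    def synonyms(self, node_id: str) -> tuple[str, ...]:
        return self._terms.get(node_id, ())

    def node_ids(self) -> tuple[str, ...]:
        return tuple(self._terms)

    def __len__(self) -> int:
        return len(self._terms)


@dataclass(frozen=True)
class TermExpansion:
    """One search term for a node: the term, how it arose, and via which neighbor."""

    term: str
    match_type: str  # exact_label | synonym | neighbor
    neighbor_via: Optional[str] = None


@dataclass(frozen=True)
class MatchRecord:
    """Provenance of one (node, codebook item) hit."""

    node_id: str
    item: CodebookItem
    matched_term: str
    match_type: str
    neighbor_via: Optional[str] = None


@dataclass
class MatchConfig:
    """Knobs of the codebook search.

    mode : ``"tokens"`` (default) requires every normalized token of the term
        to occur in the item's normalized token set, order-free — this is how
        a human scans a codebook and survives question rewordings.
        ``"substring"`` requires the normalized term phrase to occur verbatim
        in the normalized item text.
    include_neighbors : follow map edges and also search on neighbor labels
        (off by default; such hits are review-flagged).
    remove_stopwords : drop stop words during normalization.
    fuzzy / fuzzy_threshold : allow near-miss token matches by sequence
        similarity (off by default — the audit favours reproducibility over
        recall).
    """

    mode: str = "tokens"
    include_neighbors: bool = False
    remove_stopwords: bool = False
    fuzzy: bool = False
    fuzzy_threshold: float = 0.88

    def __post_init__(self):
        if self.mode not in ("tokens", "substring"):
            raise ValueError(f"unknown match mode {self.mode!r}")


def expand_terms(
    node_id: str,
    smap: SystemsMap,
    lexicon: Lexicon,
    include_neighbors: bool = False,
) -> frozenset:
    """The search-term set for one node.

    Contains the node's own label (``exact_label``), each lexicon synonym
    (``synonym``) and, when ``include_neighbors``, the label of every in- and
    out-neighbor (``neighbor``, tagged with that neighbor's id).  When the
    same normalized term arises more than once, the strongest type wins
    (exact_label > synonym > neighbor).
    """
    node = smap[node_id]  # raises KeyError for unknown ids
    best: dict[tuple[str, ...], TermExpansion] = {}

    def offer(exp: TermExpansion) -> None:
        key = normalize_text(exp.term)
        if not key:
            return
        incumbent = best.get(key)
        if incumbent is None or _TYPE_RANK[exp.match_type] < _TYPE_RANK[incumbent.match_type]:
            best[key] = exp

    offer(TermExpansion(node.label, "exact_label"))
    for synonym in lexicon.synonyms(node_id):
        offer(TermExpansion(synonym, "synonym"))
    if include_neighbors:
        for other_id in smap.neighbors(node_id):
            offer(TermExpansion(smap[other_id].label, "neighbor", neighbor_via=other_id))
    return frozenset(best.values())


def _tokens_fuzzy_contained(
    term_tokens: Sequence[str], item_tokens: Sequence[str], threshold: float
) -> bool:
    item_set = set(item_tokens)
    for t in term_tokens:
        if t in item_set:
            continue
        if not any(difflib.SequenceMatcher(None, t, u).ratio() >= threshold for u in item_set):
            return False
    return True


def term_matches(term: str, text: str, config: MatchConfig) -> bool:
    """Does ``term`` occur in ``text`` under the configured match mode?"""
    term_tokens = normalize_text(term, config.remove_stopwords)
    item_tokens = normalize_text(text, config.remove_stopwords)
    if not term_tokens:
        return False
    if config.mode == "substring":
        return " ".join(term_tokens) in " ".join(item_tokens)
    if config.fuzzy:
        return _tokens_fuzzy_contained(term_tokens, item_tokens, config.fuzzy_threshold)
    return set(term_tokens) <= set(item_tokens)


def match_codebook(
    codebook: Iterable[CodebookItem],
    smap: SystemsMap,
    lexicon: Lexicon,
    config: Optional[MatchConfig] = None,
):
    """Search every codebook item for every node's terms.

    Returns ``(records, draft)``: the full provenance record list, stably
    ordered by (source, variable_id, node id), and a draft
    :class:`~mapgap.coverage.CoverageMatrix` coding (node, source) present iff
    at least one record exists for that pair.  One item matching several nodes
    emits one record per node; the per-(node, source) matrix absorbs the
    multiplicity.
    """
    config = config or MatchConfig()
    items = sorted(codebook, key=lambda i: (i.source, i.variable_id))
    sources: dict[str, None] = {}
    for item in items:
        sources.setdefault(item.source)

    expansions = {
        node_id: sorted(
            expand_terms(node_id, smap, lexicon, config.include_neighbors),
            key=lambda e: (_TYPE_RANK[e.match_type], e.term, e.neighbor_via or ""),
        )
        for node_id in smap.node_ids
    }

    records: list[MatchRecord] = []
    for item in items:
        for node_id in smap.node_ids:
            for exp in expansions[node_id]:
                if term_matches(exp.term, item.text, config):
                    records.append(
                        MatchRecord(node_id, item, exp.term, exp.match_type, exp.neighbor_via)
                    )
                    break  # strongest term type suffices; one record per (node, item)

    entries = {(r.node_id, r.item.source): True for r in records}
    draft = CoverageMatrix.from_dict(entries, smap.node_ids, tuple(sources))
    return records, draft


# ---------------------------------------------------------------------------
# CSV interfaces


def read_codebook(path) -> list[CodebookItem]:
    """Read one source's codebook: columns ``source,variable_id,text[,category]``."""
    path = Path(path)
    items: list[CodebookItem] = []
    seen: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = ("source", "variable_id", "text")
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            key = (row["source"].strip(), row["variable_id"].strip())
            if key in seen:
                raise FormatError(f"{path}: duplicate (source, variable_id) {key} at line {lineno}")
            seen.add(key)
            items.append(
                CodebookItem(
                    source=key[0],
                    variable_id=key[1],
                    text=row["text"],
                    category=(row.get("category") or None),
                )
            )
    return items


def read_lexicon(path) -> Lexicon:
    """Read a synonym lexicon: columns ``node_id,term``, one term per row."""
    path = Path(path)
    lex = Lexicon()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("node_id", "term") if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for row in reader:
            lex.add(row["node_id"].strip(), row["term"])
    return lex


def write_match_records(records: Iterable[MatchRecord], path) -> None:
    """Export the provenance records for human review."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["node_id", "source", "variable_id", "matched_term", "match_type", "neighbor_via", "text"]
        )
        for r in records:
            writer.writerow(
                [r.node_id, r.item.source, r.item.variable_id, r.matched_term,
                 r.match_type, r.neighbor_via or "", r.item.text]
            )


def write_draft_coverage(
    draft: CoverageMatrix, records: Iterable[MatchRecord], path
) -> None:
    """Write the draft matrix in the coverage dialect plus a review-flag column.

    The trailing ``needs_review`` column lists (semicolon-joined) the sources
    whose "yes" for that node rests *only* on neighbor-derived matches; drop
    the column before feeding the file back through ``read_coverage``.
    """
    strong: set[tuple[str, str]] = set()
    weak: set[tuple[str, str]] = set()
    for r in records:
        pair = (r.node_id, r.item.source)
        (weak if r.match_type == "neighbor" else strong).add(pair)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", *draft.sources, "needs_review"])
        for node_id in draft.node_ids:
            flags = [
                s for s in draft.sources
                if (node_id, s) in weak and (node_id, s) not in strong
            ]
            writer.writerow(
                [node_id,
                 *("yes" if draft.is_present(node_id, s) else "no" for s in draft.sources),
                 ";".join(flags)]
            )
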