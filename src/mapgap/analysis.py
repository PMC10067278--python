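"""The three coverage summaries of a gap audit.

Node level: how many factors each source covers, how many no source covers,
and how many are covered by at least k sources.  Edge level: a causal
mechanism (an edge) is quantitatively studiable within one source only if
that source measures both endpoint factors; edges fall into exactly one of
four categories — coverable within a single source, coverable only by
combining different sources, one endpoint covered, neither covered.  Level
stratification: the same per-factor coverage grouped by social-ecological
level (individual, relationship, community, societal), where a multi-level
factor counts toward each of its levels.

All percentages are on the 0-100 scale, rounded half-away-from-zero to two
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd

from .coverage import CoverageMatrix
from .errors import IntegrityError, ValidationError
from .map_io import LEVELS, SystemsMap


def percent_of(count: int, total: int) -> float:
    """``100 * count / total`` rounded half-away-from-zero to 2 decimals."""
    if total == 0:
        raise ZeroDivisionError("percent_of: total is zero (undefined ratio)")
    if count < 0 or total < 0:
        raise ValueError("percent_of: counts must be non-negative")
    if count > total:
        raise ValueError(f"percent_of: count {count} exceeds total {total}")
    ratio = Decimal(100) * Decimal(count) / Decimal(total)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountPercent:
    count: int
    percent: float

    def __iter__(self):
        return iter((self.count, self.percent))


def _cp(count: int, total: int) -> CountPercent:
    # summaries over an empty universe report 0.00% instead of failing,
    # so an empty or edgeless map still renders
    return CountPercent(count, percent_of(count, total) if total else 0.0)


def _check_aligned(smap: SystemsMap, cm: CoverageMatrix) -> None:
    if set(cm.node_ids) != set(smap.node_ids):
        extra = set(cm.node_ids) - set(smap.node_ids)
        missing = set(smap.node_ids) - set(cm.node_ids)
        raise IntegrityError(
            f"coverage matrix misaligned with map (extra: {sorted(extra)[:5]}, "
            f"missing: {sorted(missing)[:5]})"
        )


def _markdown_table(header: Sequence[str], rows: Sequence[Sequence], footnote: str = "") -> str:
    lines = ["| " + " | ".join(str(c) for c in header) + " |",
             "|" + "|".join(" --- " for _ in header) + "|"]
    lines += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
    if footnote:
        lines += ["", footnote]
    return "\n".join(lines) + "\n"


_NOT_EXCLUSIVE = "Categories are not mutually exclusive, hence totals exceed 100%"


@dataclass(frozen=True)
class NodeCoverageSummary:
    """Per-factor availability across the data sources."""

    total_nodes: int
    per_source: dict  # source -> CountPercent
    covered_by_none: CountPercent
    exactly_one: CountPercent
    at_least: dict  # k (1..n_sources) -> CountPercent

    @property
    def all_sources(self) -> CountPercent:
        return self.at_least[max(self.at_least)]

    def to_frame(self) -> pd.DataFrame:
        rows = [("total factors", self.total_nodes, 100.0)]
        rows += [(s, cp.count, cp.percent) for s, cp in self.per_source.items()]
        rows.append(("covered by no data source", *self.covered_by_none))
        rows.append(("in only one data source", *self.exactly_one))
        rows += [(f"in >= {k} data sources", *cp) for k, cp in sorted(self.at_least.items())]
        return pd.DataFrame(rows, columns=["category", "count", "percent"])

    def to_markdown(self) -> str:
        df = self.to_frame()
        rows = [(c, n, f"{p:.2f}%") for c, n, p in df.itertuples(index=False)]
        return _markdown_table(
            ["Data source and coverage", "n", "% of factors"], rows, _NOT_EXCLUSIVE
        )


@dataclass(frozen=True)
class EdgeCoverageSummary:
    """Per-mechanism (edge) availability; the four top categories partition the edges."""

    total_edges: int
    within_any_one: CountPercent
    within_source: dict  # source -> CountPercent
    cross_source_only: CountPercent
    one_endpoint_only: CountPercent
    neither_endpoint: CountPercent

    @property
    def partition_sum(self) -> int:
        return (self.within_any_one.count + self.cross_source_only.count
                + self.one_endpoint_only.count + self.neither_endpoint.count)

    @property
    def partition_discrepancy(self) -> int:
        """Partition sum minus edge count; non-zero indicates an inconsistent coding."""
        return self.partition_sum - self.total_edges

    def to_frame(self) -> pd.DataFrame:
        rows = [("within any one data source", *self.within_any_one)]
        rows += [(f"within {s} only", *cp) for s, cp in self.within_source.items()]
        rows += [
            ("only covered by using different data sources", *self.cross_source_only),
            ("only one endpoint of the edge has data", *self.one_endpoint_only),
            ("no data on either endpoint", *self.neither_endpoint),
        ]
        return pd.DataFrame(rows, columns=["category", "count", "percent"])

    def to_markdown(self) -> str:
        df = self.to_frame()
        rows = [(c, n, f"{p:.2f}") for c, n, p in df.itertuples(index=False)]
        return _markdown_table(
            ["Coverage", f"Edges covered (n = {self.total_edges})", "% of edges"],
            rows, _NOT_EXCLUSIVE,
        )


@dataclass(frozen=True)
class LevelCoverageSummary:
    """Coverage stratified by social-ecological level (multi-level nodes count in each)."""

    nodes_in_map: dict  # level -> int
    nodes_covered: dict  # level -> int
    percent_covered: dict  # level -> float

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.nodes_in_map)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "nodes_in_map": [self.nodes_in_map[l] for l in self.levels],
                "nodes_covered": [self.nodes_covered[l] for l in self.levels],
                "percent_covered": [self.percent_covered[l] for l in self.levels],
            }
        )

    def to_markdown(self) -> str:
        header = ["", *self.levels]
        rows = [
            ["In systems map", *(self.nodes_in_map[l] for l in self.levels)],
            ["In at least one data source", *(self.nodes_covered[l] for l in self.levels)],
            ["Coverage of the map (%)", *(f"{self.percent_covered[l]:.2f}" for l in self.levels)],
        ]
        return _markdown_table(header, rows)


def node_coverage(smap: SystemsMap, cm: CoverageMatrix) -> NodeCoverageSummary:
    """Tally factor availability per source, by no source, and by >= k sources."""
    _check_aligned(smap, cm)
    total = smap.n_nodes
    counts = {n: cm.n_sources_covering(n) for n in smap.node_ids}
    per_source = {
        s: _cp(sum(cm.is_present(n, s) for n in smap.node_ids), total) for s in cm.sources
    }
    n_sources = len(cm.sources)
    at_least = {
        k: _cp(sum(c >= k for c in counts.values()), total) for k in range(1, n_sources + 1)
    }
    return NodeCoverageSummary(
        total_nodes=total,
        per_source=per_source,
        covered_by_none=_cp(sum(c == 0 for c in counts.values()), total),
        exactly_one=_cp(sum(c == 1 for c in counts.values()), total),
        at_least=at_least,
    )


def edge_coverage(smap: SystemsMap, cm: CoverageMatrix) -> EdgeCoverageSummary:
    """Categorize every edge by endpoint coverage, direction-insensitively.

    For edge (u, v): *within source s* iff s covers both u and v; *within any
    one* iff some single source does; *cross-source only* iff both endpoints
    are covered somewhere but no single source covers both; *one endpoint
    only* iff exactly one endpoint is covered by any source; *neither*
    otherwise.  The last four categories partition the (deduplicated) edge
    set.
    """
    _check_aligned(smap, cm)
    total = smap.n_edges
    any_cov = {n: cm.covered_any(n) for n in smap.node_ids}
    within_any = 0
    cross_only = 0
    one_end = 0
    neither = 0
    per_source = dict.fromkeys(cm.sources, 0)
    for edge in smap.edges:
        u, v = edge.source, edge.target
        in_some_single = False
        for s in cm.sources:
            if cm.is_present(u, s) and cm.is_present(v, s):
                per_source[s] += 1
                in_some_single = True
        n_cov_endpoints = int(any_cov[u]) + int(any_cov[v])
        if u == v:
            n_cov_endpoints = 2 if any_cov[u] else 0
        if in_some_single:
            within_any += 1
        elif n_cov_endpoints == 2:
            cross_only += 1
        elif n_cov_endpoints == 1:
            one_end += 1
        else:
            neither += 1
    return EdgeCoverageSummary(
        total_edges=total,
        within_any_one=_cp(within_any, total),
        within_source={s: _cp(c, total) for s, c in per_source.items()},
        cross_source_only=_cp(cross_only, total),
        one_endpoint_only=_cp(one_end, total),
        neither_endpoint=_cp(neither, total),
    )


def level_coverage(
    smap: SystemsMap, cm: CoverageMatrix, order: Sequence[str] = LEVELS
) -> LevelCoverageSummary:
    """Per-level factor counts and coverage; a multi-level node counts in each level."""
    _check_aligned(smap, cm)
    in_map = dict.fromkeys(order, 0)
    covered = dict.fromkeys(order, 0)
    for node in smap.nodes:
        if not node.levels:
            raise ValidationError(f"node {node.id!r}: empty level set")
        is_cov = cm.covered_any(node.id)
        for level in node.levels:
            if level not in in_map:
                continue  # level outside the requested order is not tallied
            in_map[level] += 1
            covered[level] += int(is_cov)
    percent = {
        l: percent_of(covered[l], in_map[l]) if in_map[l] else 0.0 for l in order
    }
    return LevelCoverageSummary(dict(in_map), dict(covered), percent)


def gradient_check(
    summary: LevelCoverageSummary, order: Optional[Sequence[str]] = None
) -> bool:
    """True iff percent covered strictly decreases along the level order.

    The default order walks outward from the person: individual →
    relationship → community → societal.
    """
    order = tuple(order or LEVELS)
    if sorted(order) != sorted(summary.levels):
        raise ValueError(f"order {order} is not a permutation of {summary.levels}")
    values = [summary.percent_covered[l] for l in order]
    return all(a > b for a, b in zip(values, values[1:]))
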