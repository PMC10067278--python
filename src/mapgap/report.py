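"""Orchestrate a full gap audit and render its report.

An audit reads the map and the coverage coding, computes the three summaries
(node, edge, social-ecological level), checks the coverage gradient, and
collects the concrete gap lists: factors no source covers and mechanisms
(edges) no single source can study.  The edge categories must partition the
edge set; if a coding ever breaks that accounting the report carries a loud
diagnostic rather than absorbing the discrepancy.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import analysis
from .analysis import EdgeCoverageSummary, LevelCoverageSummary, NodeCoverageSummary
from .coverage import CoverageMatrix, read_coverage
from .map_io import LEVELS, SystemsMap, ValidationReport, read_map, validate_map

__version__ = "0.1.0"


@dataclass
class GapReport:
    node_summary: NodeCoverageSummary
    edge_summary: EdgeCoverageSummary
    level_summary: LevelCoverageSummary
    gradient_decreasing: bool
    uncovered_nodes: list  # node ids covered by no source
    uncovered_edges: list  # (source, target) with no single source covering both
    validation: ValidationReport
    diagnostics: list = field(default_factory=list)
    provenance: Optional[dict] = None


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_report(
    smap: SystemsMap,
    cm: CoverageMatrix,
    levels_order: Sequence[str] = LEVELS,
    provenance: Optional[dict] = None,
) -> GapReport:
    """Compute all summaries and gap lists for an in-memory map + coding."""
    node_summary = analysis.node_coverage(smap, cm)
    edge_summary = analysis.edge_coverage(smap, cm)
    level_summary = analysis.level_coverage(smap, cm, order=levels_order)
    gradient = analysis.gradient_check(level_summary, order=levels_order)

    uncovered_nodes = [n for n in smap.node_ids if not cm.covered_any(n)]
    covered_pairs = {
        (e.source, e.target)
        for e in smap.edges
        if any(cm.is_present(e.source, s) and cm.is_present(e.target, s) for s in cm.sources)
    }
    uncovered_edges = [
        (e.source, e.target) for e in smap.edges if (e.source, e.target) not in covered_pairs
    ]

    diagnostics = []
    if edge_summary.partition_discrepancy != 0:
        diagnostics.append(
            f"EDGE PARTITION DISCREPANCY: the four edge categories sum to "
            f"{edge_summary.partition_sum} but the deduplicated edge count is "
            f"{edge_summary.total_edges}; the coding and the map are inconsistent."
        )
    return GapReport(
        node_summary=node_summary,
        edge_summary=edge_summary,
        level_summary=level_summary,
        gradient_decreasing=gradient,
        uncovered_nodes=uncovered_nodes,
        uncovered_edges=uncovered_edges,
        validation=validate_map(smap),
        diagnostics=diagnostics,
        provenance=provenance,
    )


def run_audit(
    nodes_path,
    edges_path,
    coverage_path,
    levels_order: Sequence[str] = LEVELS,
    with_provenance: bool = True,
) -> GapReport:
    """Load inputs from disk and build the full gap report."""
    smap = read_map(nodes_path, edges_path)
    cm = read_coverage(coverage_path, smap)
    provenance = None
    if with_provenance:
        provenance = {
            "tool": f"mapgap {__version__}",
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "inputs": {
                "nodes": {"path": str(nodes_path), "sha256": _digest(nodes_path)},
                "edges": {"path": str(edges_path), "sha256": _digest(edges_path)},
                "coverage": {"path": str(coverage_path), "sha256": _digest(coverage_path)},
            },
        }
    return build_report(smap, cm, levels_order=levels_order, provenance=provenance)


def report_to_dict(report: GapReport) -> dict:
    """Lossless JSON-ready view of a report."""
    ns, es, ls = report.node_summary, report.edge_summary, report.level_summary
    payload = {
        "node_coverage": {
            "total_nodes": ns.total_nodes,
            "per_source": {s: list(cp) for s, cp in ns.per_source.items()},
            "covered_by_none": list(ns.covered_by_none),
            "exactly_one": list(ns.exactly_one),
            "at_least": {str(k): list(cp) for k, cp in ns.at_least.items()},
        },
        "edge_coverage": {
            "total_edges": es.total_edges,
            "within_any_one": list(es.within_any_one),
            "within_source": {s: list(cp) for s, cp in es.within_source.items()},
            "cross_source_only": list(es.cross_source_only),
            "one_endpoint_only": list(es.one_endpoint_only),
            "neither_endpoint": list(es.neither_endpoint),
            "partition_sum": es.partition_sum,
            "partition_discrepancy": es.partition_discrepancy,
        },
        "level_coverage": {
            level: {
                "nodes_in_map": ls.nodes_in_map[level],
                "nodes_covered": ls.nodes_covered[level],
                "percent_covered": ls.percent_covered[level],
            }
            for level in ls.levels
        },
        "gradient_decreasing": report.gradient_decreasing,
        "gaps": {
            "uncovered_nodes": list(report.uncovered_nodes),
            "uncovered_edges": [list(e) for e in report.uncovered_edges],
        },
        "validation": {
            "warnings": list(report.validation.warnings),
            "errors": list(report.validation.errors),
        },
        "diagnostics": list(report.diagnostics),
    }
    if report.provenance is not None:
        payload["provenance"] = report.provenance
    return payload


def _csv_text(df) -> str:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()


def render_report(report: GapReport, format: str = "markdown") -> dict:
    """Render deterministically to ``{filename: text}``.

    Formats: ``markdown`` (one document mirroring the three summary tables,
    with footnotes, gaps and diagnostics), ``csv`` (one file per summary plus
    the gap lists), ``json`` (a single lossless document).
    """
    if format == "json":
        return {"report.json": json.dumps(report_to_dict(report), indent=2) + "\n"}
    if format == "csv":
        import pandas as pd

        out = {
            "node_coverage.csv": _csv_text(report.node_summary.to_frame()),
            "edge_coverage.csv": _csv_text(report.edge_summary.to_frame()),
            "level_coverage.csv": _csv_text(report.level_summary.to_frame()),
            "gap_nodes.csv": _csv_text(pd.DataFrame({"node_id": report.uncovered_nodes})),
            "gap_edges.csv": _csv_text(
                pd.DataFrame(report.uncovered_edges, columns=["source", "target"])
            ),
        }
        return out
    if format == "markdown":
        parts = ["# Data-gap audit report", ""]
        if report.diagnostics:
            parts += ["## DIAGNOSTICS", ""] + [f"**{d}**" for d in report.diagnostics] + [""]
        parts += ["## Factor (node) coverage", "", report.node_summary.to_markdown()]
        parts += ["## Causal-mechanism (edge) coverage", "", report.edge_summary.to_markdown()]
        parts += ["## Coverage by social-ecological level", "", report.level_summary.to_markdown()]
        parts += [
            f"Coverage strictly decreases along the social-ecological order: "
            f"{'yes' if report.gradient_decreasing else 'no'}",
            "",
            "## Gaps",
            "",
            f"- {len(report.uncovered_nodes)} factor(s) covered by no data source",
            f"- {len(report.uncovered_edges)} mechanism(s) with no single source covering "
            f"both endpoints",
            "",
        ]
        if report.validation.warnings:
            parts += ["## Map validation warnings", ""]
            parts += [f"- {w}" for w in report.validation.warnings] + [""]
        if report.provenance is not None:
            parts += ["## Provenance", "", "```json",
                      json.dumps(report.provenance, indent=2), "```", ""]
        return {"report.md": "\n".join(parts)}
    raise ValueError(f"unknown report format {format!r}")


def write_report(report: GapReport, outdir, format: str = "markdown") -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in render_report(report, format).items():
        path = outdir / name
        path.write_text(text, encoding="utf-8")
        written.append(path)
    return written
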