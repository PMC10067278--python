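import csv

import pytest

from mapgap.coverage import CoverageMatrix
from mapgap.map_io import Edge, Node, SystemsMap


def make_map(node_specs, edge_pairs=()):
    """Build a map from ``[(id, label, levels), ...]`` and ``[(src, tgt), ...]``."""
    nodes = [
        Node(id=i, label=label, levels=frozenset(levels))
        for i, label, levels in node_specs
    ]
    return SystemsMap(nodes, [Edge(s, t) for s, t in edge_pairs])


def make_coverage(smap, sources, present):
    """Coverage matrix from ``{node_id: [sources covering it]}``."""
    entries = {
        (node, s): True for node, covering in present.items() for s in covering
    }
    return CoverageMatrix.from_dict(entries, smap.node_ids, sources)


def write_csv(path, header, rows):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)
    return path


@pytest.fixture
def tiny_map():
    """A→B, B→C; A and B individual, C community+societal."""
    return make_map(
        [
            ("A", "housing stability", ["individual"]),
            ("B", "hopelessness", ["individual"]),
            ("C", "community cohesion", ["community", "societal"]),
        ],
        [("A", "B"), ("B", "C")],
    )


@pytest.fixture
def four_node_map():
    return make_map(
        [
            ("A", "alpha factor", ["individual"]),
            ("B", "beta factor", ["individual"]),
            ("C", "gamma factor", ["relationship"]),
            ("D", "delta factor", ["societal"]),
        ],
        [("A", "B"), ("C", "D")],
    )
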