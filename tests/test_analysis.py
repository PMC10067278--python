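import itertools

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from mapgap.analysis import (
    edge_coverage,
    gradient_check,
    level_coverage,
    node_coverage,
    percent_of,
)
from mapgap.errors import IntegrityError

from conftest import make_coverage, make_map
from oracles import oracle_edge_summary, oracle_node_summary, pct as oracle_pct


@pytest.mark.parametrize("count,total,expected", [
    (252, 364, 69.23),
    (26, 55, 47.27),
    (0, 364, 0.00),
    (289, 364, 79.40),   # 79.3956... rounds up at the half rule's side
    (1, 3, 33.33),
    (1, 800, 0.13),      # 0.125 -> half away from zero
])
def test_percent_of(count, total, expected):
    assert percent_of(count, total) == expected


def test_percent_of_errors():
    with pytest.raises(ZeroDivisionError):
        percent_of(1, 0)
    with pytest.raises(ValueError):
        percent_of(5, 3)


@settings(max_examples=200, derandomize=True)
@given(total=st.integers(1, 2000), data=st.data())
def test_percent_of_matches_integer_arithmetic_oracle(total, data):
    count = data.draw(st.integers(0, total))
    assert percent_of(count, total) == oracle_pct(count, total)


def test_node_coverage_four_node_enumeration(four_node_map):
    cm = make_coverage(four_node_map, ["S1", "S2"],
                       {"A": ["S1", "S2"], "B": ["S1"], "D": ["S2"]})
    s = node_coverage(four_node_map, cm)
    assert s.total_nodes == 4
    assert s.per_source["S1"].count == 2 and s.per_source["S2"].count == 2
    assert s.covered_by_none.count == 1
    assert s.exactly_one.count == 2
    assert s.at_least[1].count == 3 and s.at_least[2].count == 1
    assert s.all_sources.count == 1
    assert s.covered_by_none.count + s.at_least[1].count == s.total_nodes


def test_node_coverage_all_absent(four_node_map):
    cm = make_coverage(four_node_map, ["S1", "S2"], {})
    s = node_coverage(four_node_map, cm)
    assert s.covered_by_none.count == 4
    assert all(cp.count == 0 for cp in s.per_source.values())
    assert all(cp.count == 0 for cp in s.at_least.values())


def test_edge_coverage_hand_enumeration(tiny_map):
    cm = make_coverage(tiny_map, ["S1", "S2"], {"A": ["S1"], "B": ["S1"], "C": ["S2"]})
    s = edge_coverage(tiny_map, cm)
    assert s.within_any_one.count == 1      # A->B via S1
    assert s.cross_source_only.count == 1   # B->C split across S1/S2
    assert s.one_endpoint_only.count == 0 and s.neither_endpoint.count == 0
    assert s.within_source["S1"].count == 1 and s.within_source["S2"].count == 0


def test_edge_coverage_single_full_source(tiny_map):
    cm = make_coverage(tiny_map, ["S1"], {n: ["S1"] for n in tiny_map.node_ids})
    s = edge_coverage(tiny_map, cm)
    assert s.within_any_one.count == s.total_edges == 2
    assert s.cross_source_only.count == s.one_endpoint_only.count == 0
    assert s.neither_endpoint.count == 0


def test_misaligned_matrix_rejected(tiny_map, four_node_map):
    cm = make_coverage(four_node_map, ["S1"], {})
    with pytest.raises(IntegrityError):
        node_coverage(tiny_map, cm)
    with pytest.raises(IntegrityError):
        edge_coverage(tiny_map, cm)


def test_level_coverage_basic():
    smap = make_map([("A", "a", ["individual"]), ("B", "b", ["individual"])])
    cm = make_coverage(smap, ["S1"], {"A": ["S1"]})
    s = level_coverage(smap, cm)
    assert s.nodes_in_map["individual"] == 2
    assert s.nodes_covered["individual"] == 1
    assert s.percent_covered["individual"] == 50.00


def test_multi_level_node_counts_in_each_level():
    smap = make_map([("A", "a", ["community", "societal"])])
    cm = make_coverage(smap, ["S1"], {"A": ["S1"]})
    s = level_coverage(smap, cm)
    for level in ("community", "societal"):
        assert s.nodes_in_map[level] == 1 and s.nodes_covered[level] == 1
    assert sum(s.nodes_in_map.values()) == 2  # exceeds the 1-node total


@pytest.mark.parametrize("percents,expected", [
    ((86.84, 83.45, 73.74, 47.27), True),
    ((50.0, 50.0, 40.0, 30.0), False),   # strictness: a tie fails
    ((50.0, 60.0, 10.0, 5.0), False),
])
def test_gradient_check(percents, expected):
    from mapgap.analysis import LevelCoverageSummary
    from mapgap.map_io import LEVELS

    s = LevelCoverageSummary(
        nodes_in_map=dict.fromkeys(LEVELS, 100),
        nodes_covered={l: int(p) for l, p in zip(LEVELS, percents)},
        percent_covered=dict(zip(LEVELS, percents)),
    )
    assert gradient_check(s) is expected


def test_gradient_check_rejects_non_permutation():
    smap = make_map([("A", "a", ["individual"])])
    s = level_coverage(smap, make_coverage(smap, ["S1"], {}))
    with pytest.raises(ValueError):
        gradient_check(s, order=("individual", "individual", "community", "societal"))


# ---------------------------------------------------------------------------
# oracle equivalence and partition invariants on small maps


def _random_case(rng):
    n = int(rng.integers(2, 9))
    n_sources = int(rng.integers(1, 4))
    levels = ["individual", "relationship", "community", "societal"]
    specs = [
        (f"n{i}", f"label {i}",
         [levels[int(rng.integers(4))]] + ([levels[int(rng.integers(4))]]
                                           if rng.random() < 0.3 else []))
        for i in range(n)
    ]
    all_pairs = [(f"n{a}", f"n{b}") for a in range(n) for b in range(n)]
    k = int(rng.integers(0, len(all_pairs) + 1))
    idx = rng.choice(len(all_pairs), size=k, replace=False)
    edges = [all_pairs[i] for i in idx]
    smap = make_map(specs, set(edges))
    sources = [f"S{j}" for j in range(n_sources)]
    present = {
        node: [s for s in sources if rng.random() < 0.5] for node in smap.node_ids
    }
    return smap, sources, present


def _assert_matches_oracle(smap, sources, present):
    cm = make_coverage(smap, sources, present)
    present_pairs = {(n, s) for n, ss in present.items() for s in ss}
    ns = node_coverage(smap, cm)
    on = oracle_node_summary(smap.node_ids, sources, present_pairs)
    assert ns.covered_by_none.count == on["none"]
    assert ns.exactly_one.count == on["exactly_one"]
    assert {s: cp.count for s, cp in ns.per_source.items()} == on["per_source"]
    assert {k: cp.count for k, cp in ns.at_least.items()} == on["at_least"]

    es = edge_coverage(smap, cm)
    edge_pairs = [(e.source, e.target) for e in smap.edges]
    oe = oracle_edge_summary(smap.node_ids, sources, present_pairs, edge_pairs)
    assert es.within_any_one.count == oe["within_any"]
    assert es.cross_source_only.count == oe["cross"]
    assert es.one_endpoint_only.count == oe["one_end"]
    assert es.neither_endpoint.count == oe["neither"]
    assert {s: cp.count for s, cp in es.within_source.items()} == oe["per_source"]
    assert es.partition_sum == es.total_edges


def test_oracle_equivalence_random_small_maps():
    import numpy as np

    rng = np.random.default_rng(20261002)
    for _ in range(150):
        _assert_matches_oracle(*_random_case(rng))


def test_oracle_equivalence_exhaustive_coverage_matrices():
    """Every coverage matrix on a 3-node, 2-source map, including self-loop edges."""
    smap = make_map(
        [("A", "a", ["individual"]), ("B", "b", ["relationship"]),
         ("C", "c", ["societal"])],
        [("A", "B"), ("B", "C"), ("C", "A"), ("A", "A")],
    )
    sources = ["S1", "S2"]
    cells = [(n, s) for n in smap.node_ids for s in sources]
    for bits in itertools.product([False, True], repeat=len(cells)):
        present = {}
        for (n, s), bit in zip(cells, bits):
            if bit:
                present.setdefault(n, []).append(s)
        _assert_matches_oracle(smap, sources, present)


@settings(max_examples=100, derandomize=True, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(data=st.data())
def test_adding_a_flag_is_monotone(four_node_map, data):
    sources = ["S1", "S2", "S3"]
    present = {
        n: [s for s in sources if data.draw(st.booleans(), label=f"{n}/{s}")]
        for n in four_node_map.node_ids
    }
    cm = make_coverage(four_node_map, sources, present)
    node = data.draw(st.sampled_from(list(four_node_map.node_ids)))
    source = data.draw(st.sampled_from(sources))
    bumped = cm.with_flag(node, source, True)

    before_n, after_n = node_coverage(four_node_map, cm), node_coverage(four_node_map, bumped)
    assert after_n.covered_by_none.count <= before_n.covered_by_none.count
    before_e, after_e = edge_coverage(four_node_map, cm), edge_coverage(four_node_map, bumped)
    assert after_e.within_any_one.count >= before_e.within_any_one.count


def test_node_level_consistency(four_node_map):
    """Sum over levels of covered nodes >= nodes covered anywhere; equality if single-level."""
    cm = make_coverage(four_node_map, ["S1"], {"A": ["S1"], "D": ["S1"]})
    ns = node_coverage(four_node_map, cm)
    ls = level_coverage(four_node_map, cm)
    assert sum(ls.nodes_covered.values()) == ns.at_least[1].count  # all single-level
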