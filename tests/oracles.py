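"""Independent brute-force reference for the coverage summaries.

Deliberately literal: every (node, source) and (edge, source) combination is
enumerated on plain dicts and sets, with no shared code with the package's
analysis module.
"""

def pct(count, total):
    # half-away-from-zero at 2 decimals via pure integer arithmetic
    n = 100 * count * 100  # value in hundredths of a percent, before division
    q, r = divmod(n, total)
    if 2 * r >= total:
        q += 1
    return q / 100


def oracle_node_summary(node_ids, sources, present):
    """``present``: set of (node_id, source) pairs coded yes."""
    total = len(node_ids)
    per_source = {}
    for s in sources:
        c = 0
        for n in node_ids:
            if (n, s) in present:
                c += 1
        per_source[s] = c
    counts = {}
    for n in node_ids:
        k = 0
        for s in sources:
            if (n, s) in present:
                k += 1
        counts[n] = k
    out = {
        "total": total,
        "per_source": per_source,
        "none": sum(1 for n in node_ids if counts[n] == 0),
        "exactly_one": sum(1 for n in node_ids if counts[n] == 1),
        "at_least": {
            k: sum(1 for n in node_ids if counts[n] >= k)
            for k in range(1, len(sources) + 1)
        },
    }
    return out


def oracle_edge_summary(node_ids, sources, present, edges):
    """``edges``: iterable of (u, v) pairs, already deduplicated."""
    covered_any = {n: any((n, s) in present for s in sources) for n in node_ids}
    within_any = cross = one_end = neither = 0
    per_source = {s: 0 for s in sources}
    for (u, v) in edges:
        single = False
        for s in sources:
            if (u, s) in present and (v, s) in present:
                per_source[s] += 1
                single = True
        if single:
            within_any += 1
        elif covered_any[u] and covered_any[v]:
            cross += 1
        elif covered_any[u] or covered_any[v]:
            one_end += 1
        else:
            neither += 1
    return {
        "total": len(list(edges)),
        "within_any": within_any,
        "per_source": per_source,
        "cross": cross,
        "one_end": one_end,
        "neither": neither,
    }
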