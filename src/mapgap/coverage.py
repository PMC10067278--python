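"""The node x source presence/absence coding linking data sources to map factors.

The coding is strictly binary: a cell is "yes" when the source contains at
least one question or indicator that could measure the factor, "no" otherwise.
There is no partial credit and no notion of how well a question measures the
construct.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .errors import FormatError, IntegrityError
from .map_io import SystemsMap

logger = logging.getLogger(__name__)

#: Accepted cell spellings (case-insensitive) for the binary coding.
TRUTHY = frozenset({"yes", "y", "1", "true"})
FALSY = frozenset({"no", "n", "0", "false", ""})


class CoverageMatrix:
    """Binary node x source coverage, total on a companion map's node set.

    Backed by a boolean :class:`pandas.DataFrame` (index: node ids in map
    order; columns: sources in file/header order).
    """

    def __init__(self, data: pd.DataFrame):
        self._df = data.astype(bool)

    @classmethod
    def from_dict(cls, entries: dict, node_ids, sources) -> "CoverageMatrix":
        """Build from a ``{(node_id, source): bool}`` mapping; missing cells are absent."""
        df = pd.DataFrame(False, index=list(node_ids), columns=list(sources))
        for (node, source), value in entries.items():
            df.loc[node, source] = bool(value)
        return cls(df)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(self._df.columns)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self._df.index)

    def is_present(self, node_id: str, source: str) -> bool:
        self._check_node(node_id)
        if source not in self._df.columns:
            raise KeyError(f"unknown source {source!r}")
        return bool(self._df.at[node_id, source])

    def covered_any(self, node_id: str) -> bool:
        """True iff at least one source codes the node present."""
        self._check_node(node_id)
        return bool(self._df.loc[node_id].any())

    def n_sources_covering(self, node_id: str) -> int:
        self._check_node(node_id)
        return int(self._df.loc[node_id].sum())

    def with_flag(self, node_id: str, source: str, value: bool = True) -> "CoverageMatrix":
        """Return a copy with one cell set; the original is unchanged."""
        self._check_node(node_id)
        df = self._df.copy()
        df.loc[node_id, source] = value
        return CoverageMatrix(df)

    def _check_node(self, node_id: str) -> None:
        if node_id not in self._df.index:
            raise KeyError(f"unknown node id {node_id!r}")

    def __repr__(self) -> str:
        return f"CoverageMatrix(n_nodes={len(self._df)}, sources={list(self.sources)})"


def _parse_cell(token: str, lineno: int, column: str, path) -> bool:
    low = token.strip().lower()
    if low in TRUTHY:
        return True
    if low in FALSY:
        return False
    raise FormatError(
        f"{path}: unrecognized cell {token!r} at line {lineno}, column {column!r} "
        f"(expected one of {sorted(TRUTHY | FALSY - {''})})"
    )


def read_coverage(path, smap: SystemsMap) -> CoverageMatrix:
    """Read a wide coverage CSV aligned to ``smap``.

    Layout: first column is the node id, every further column one data source;
    cells use a yes/no vocabulary (``yes/no``, ``y/n``, ``1/0``, ``true/false``,
    case-insensitive).  Node ids absent from the map are a hard error — silent
    drift between map versions and codings is exactly the failure mode a gap
    audit must not have.  Map nodes missing from the file are filled as
    all-absent with a logged warning.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if len(header) < 2:
            raise FormatError(f"{path}: need a node-id column plus at least one source column")
        sources = [c.strip() for c in header[1:]]
        if len(set(sources)) != len(sources):
            raise FormatError(f"{path}: duplicate source columns in header")
        rows: dict[str, list[bool]] = {}
        unknown: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            node_id = row[0].strip()
            if node_id in rows:
                raise IntegrityError(f"{path}: duplicate row for node {node_id!r} at line {lineno}")
            if node_id not in smap:
                unknown.append(f"line {lineno}: {node_id!r}")
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: line {lineno} has {len(row)} cells, expected {len(header)}"
                )
            rows[node_id] = [
                _parse_cell(tok, lineno, col, path) for tok, col in zip(row[1:], sources)
            ]
    if unknown:
        raise IntegrityError(
            f"{path}: {len(unknown)} row(s) name nodes absent from the map:\n  "
            + "\n  ".join(unknown)
        )
    missing = [n for n in smap.node_ids if n not in rows]
    if missing:
        logger.warning(
            "%s: %d map node(s) absent from coverage file, coded all-absent: %s",
            path, len(missing), missing[:10],
        )
    df = pd.DataFrame(
        [rows.get(n, [False] * len(sources)) for n in smap.node_ids],
        index=list(smap.node_ids),
        columns=sources,
    )
    return CoverageMatrix(df)


def write_coverage(cm: CoverageMatrix, path, vocabulary: tuple[str, str] = ("yes", "no")) -> None:
    """Write the matrix in the dialect :func:`read_coverage` reads."""
    yes, no = vocabulary
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", *cm.sources])
        for node_id in cm.node_ids:
            writer.writerow(
                [node_id, *(yes if cm.is_present(node_id, s) else no for s in cm.sources)]
            )
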