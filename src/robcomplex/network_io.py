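"""Readers and writers for PPI networks, complex sets and annotation tables.

Protein identifiers are opaque, case-sensitive strings; no identifier
mapping is attempted.  Networks are simple undirected graphs: self-loops are
dropped and duplicate edges (in either orientation) collapse to one.
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx

ComplexSet = list[frozenset[str]]
LocalizationTable = dict[str, set[str]]


def _data_lines(path: str | os.PathLike) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(path: str | os.PathLike, format: str = "edgelist") -> nx.Graph:
    """Read a PPI network from an edge list or SIF file.

    Parameters
    ----------
    path
        Two-column whitespace-delimited edge list, or SIF
        (``source interaction-type target``).  ``#`` comment lines are
        skipped.
    format
        ``"edgelist"`` or ``"sif"``.

    Returns
    -------
    networkx.Graph
        Simple undirected graph.  Self-loops are discarded and repeated
        pairs (in either order) are collapsed.  An empty file yields an
        empty graph.
    """
    if format not in ("edgelist", "sif"):
        raise ValueError(f"unknown network format: {format!r}")
    net = nx.Graph()
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if format == "edgelist":
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
        else:
            if len(tokens) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: SIF lines need at least 3 tokens, got {len(tokens)}"
                )
            u, v = tokens[0], tokens[2]
        if u == v:
            # self-interactions are not modelled
            continue
        net.add_edge(u, v)
    return net


def write_network(net: nx.Graph, path: str | os.PathLike) -> None:
    """Write a network as a canonical two-column edge list (sorted endpoints/lines).

    Isolated nodes cannot be expressed in an edge list and are omitted.
    """
    lines = sorted(tuple(sorted((u, v))) for u, v in net.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")


def read_complexes(path: str | os.PathLike) -> ComplexSet:
    """Read a complex set: one complex per line, whitespace-separated protein IDs.

    Duplicate IDs within a line collapse (set semantics); blank lines are
    skipped.  An empty file yields an empty set.
    """
    complexes: ComplexSet = []
    for _lineno, line in _data_lines(path):
        complexes.append(frozenset(line.split()))
    return complexes


def canonical_complexes(cs: Iterable[frozenset[str]]) -> ComplexSet:
    """Deterministic order: size descending, then lexicographic member tuple."""
    return sorted((frozenset(c) for c in cs), key=lambda c: (-len(c), tuple(sorted(c))))


def write_complexes(cs: Iterable[frozenset[str]], path: str | os.PathLike) -> None:
    """Write a complex set, one complex per line.

    Members of a line are sorted lexicographically; lines are ordered by
    size descending then lexicographic first member, so output is
    byte-reproducible for a given set.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for c in canonical_complexes(cs):
            fh.write(" ".join(sorted(c)) + "\n")


def read_localization(path: str | os.PathLike) -> LocalizationTable:
    """Read a protein -> sub-cellular-location table.

    TSV rows: ``protein<TAB>loc1,loc2,...``.  Repeated protein rows union
    their label sets; a row without a second column contributes an empty
    set.  Proteins never mentioned are simply absent.
    """
    table: LocalizationTable = {}
    with open(path, encoding="utf-8") as fh:
        lines = [(i, raw.rstrip("\n")) for i, raw in enumerate(fh, start=1)]
    for lineno, line in lines:
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        protein = fields[0].strip()
        if not protein:
            raise ValueError(f"{path}: line {lineno}: missing protein ID")
        labels = set()
        if len(fields) > 1:
            labels = {lab.strip() for lab in fields[1].split(",") if lab.strip()}
        table.setdefault(protein, set()).update(labels)
    return table
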