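"""Readers and writers for the plain-text formats the pipeline uses.

All formats are simple whitespace/tab-separated text:

* network: 2+ column edge list (extra columns ignored, ``#`` comments allowed)
* annotations: 2 column (protein, compartment)
* essentials: one protein ID per line
* ranking: 3 column TSV with header (rank, protein, score)

Networks are held as :class:`networkx.Graph` objects whose nodes are protein
ID strings.  Reading cleans raw edge lists into valid undirected simple
graphs: self-loops are dropped and duplicate edges (in either orientation)
collapse to one.  IDs are taken verbatim — no case folding — because species
ID schemes differ and silent folding corrupts joins.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, NamedTuple

import networkx as nx


class ParseError(ValueError):
    """A line of an input file could not be parsed; the message names the line."""


class CleaningReport(NamedTuple):
    """Bookkeeping from edge-list cleaning."""

    lines_read: int
    self_loops_dropped: int
    duplicates_collapsed: int


class NetworkStats(NamedTuple):
    """Summary counts for a network plus its annotation and benchmark overlap."""

    n_proteins: int
    n_interactions: int
    n_essential: int
    n_annotated: int


def _data_lines(path: str | os.PathLike) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(path: str | os.PathLike) -> nx.Graph:
    """Read an undirected edge list into a cleaned simple graph.

    The first two whitespace-separated tokens of each line are the edge
    endpoints; extra columns are ignored.  Self-loops are dropped and
    duplicate edges collapsed.  Cleaning counts are stored under
    ``graph.graph["cleaning"]`` as a :class:`CleaningReport`.
    """
    graph = nx.Graph()
    lines_read = 0
    self_loops = 0
    duplicates = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}: line {lineno}: expected >=2 columns, got {len(tokens)}")
        lines_read += 1
        u, v = tokens[0], tokens[1]
        graph.add_node(u)
        graph.add_node(v)
        if u == v:
            # the loop is dropped but its endpoint stays a (possibly
            # isolated) node: membership is independent of degree
            self_loops += 1
            continue
        if graph.has_edge(u, v):
            duplicates += 1
            continue
        graph.add_edge(u, v)
    graph.graph["cleaning"] = CleaningReport(lines_read, self_loops, duplicates)
    return graph


def read_annotations(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read (protein, compartment) pairs into a compartment -> protein-set mapping.

    A protein annotated to several compartments appears under each of them;
    duplicate (protein, compartment) lines collapse.
    """
    annotations: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(tokens)}")
        protein, compartment = tokens
        annotations.setdefault(compartment, set()).add(protein)
    return annotations


def read_essentials(path: str | os.PathLike) -> set[str]:
    """Read a one-ID-per-line essential-protein list; blank lines are skipped."""
    essentials: set[str] = set()
    for _lineno, line in _data_lines(path):
        essentials.add(line.split()[0])
    return essentials


def write_ranking(path: str | os.PathLike, ranking: list[str], scores: Mapping[str, float]) -> None:
    """Write a ranking as a 3-column TSV (rank, protein, score) with a header.

    Scores are printed with 12 significant digits so a read-back reproduces
    them exactly enough for downstream use.
    """
    if not ranking:
        raise ValueError("cannot write an empty ranking")
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as handle:
        handle.write("rank\tprotein\tscore\n")
        for rank, protein in enumerate(ranking, start=1):
            handle.write(f"{rank}\t{protein}\t{scores[protein]:.12g}\n")
    os.replace(tmp, path)


def read_ranking(path: str | os.PathLike) -> tuple[list[str], dict[str, float]]:
    """Read back a ranking TSV written by :func:`write_ranking`."""
    ranking: list[str] = []
    scores: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("rank"):
            raise ParseError(f"{path}: missing 'rank' header line")
        for lineno, raw in enumerate(handle, start=2):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split("\t")
            if len(tokens) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(tokens)}")
            _rank, protein, score = tokens
            ranking.append(protein)
            scores[protein] = float(score)
    return ranking, scores


def network_stats(
    net: nx.Graph,
    annotations: Mapping[str, set[str]] | None = None,
    essentials: set[str] | None = None,
) -> NetworkStats:
    """Count proteins, interactions, network-present essentials and annotated proteins."""
    nodes = set(net.nodes)
    n_essential = len(nodes & essentials) if essentials else 0
    annotated: set[str] = set()
    if annotations:
        for members in annotations.values():
            annotated |= members
    return NetworkStats(
        n_proteins=net.number_of_nodes(),
        n_interactions=net.number_of_edges(),
        n_essential=n_essential,
        n_annotated=len(nodes & annotated),
    )
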