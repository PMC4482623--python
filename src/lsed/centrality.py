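"""The seven topology centralities applied inside PSLINs, plus external scores.

DC  degree centrality (raw degree)
BC  shortest-path betweenness (unnormalized)
CC  closeness; strict mode by default (0 for any node that cannot reach the
    whole network), per-component mode as an option
SC  subgraph centrality — diagonal of exp(A)
EC  eigenvector centrality, computed per connected component
IC  information centrality (Stephenson–Zelen), per component
NC  sum of edge clustering coefficients over a node's incident edges

PSLINs are small and frequently disconnected, so the behavior on
disconnected graphs is explicit for every method rather than left to a
library default.  BC and CC are kept unnormalized: the only downstream use
is ranking, which is invariant to the usual normalizations, and raw forms
are the easiest to check against brute force.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)


class Method(str, enum.Enum):
    DC = "DC"
    BC = "BC"
    CC = "CC"
    SC = "SC"
    EC = "EC"
    IC = "IC"
    NC = "NC"
    EXTERNAL = "EXTERNAL"


@dataclass(frozen=True)
class MethodSpec:
    """Fully determines a centrality computation given a network.

    Parameters
    ----------
    method:
        Which centrality to compute.
    cc_mode:
        ``"strict"`` (default): closeness is 0 for any node that cannot reach
        every other node, so a disconnected graph scores all zeros.
        ``"component"``: closeness within the node's own component.
    external_tables:
        For ``Method.EXTERNAL``: mapping from compartment label to a score
        table path, consulted by the score-matrix builder.
    """

    method: Method = Method.DC
    cc_mode: str = "strict"
    external_tables: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cc_mode not in ("strict", "component"):
            raise ValueError(f"unknown cc_mode {self.cc_mode!r}")


def compute_centrality(net: nx.Graph, spec: MethodSpec) -> dict[str, float]:
    """Compute the centrality named by *spec* for every node of *net*."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot compute centrality on an empty network")
    method = spec.method
    if method == Method.DC:
        return {v: float(d) for v, d in net.degree()}
    if method == Method.BC:
        return {v: float(s) for v, s in nx.betweenness_centrality(net, normalized=False).items()}
    if method == Method.CC:
        return _closeness(net, spec.cc_mode)
    if method == Method.SC:
        return _subgraph_centrality(net)
    if method == Method.EC:
        return _eigenvector_centrality(net)
    if method == Method.IC:
        return _information_centrality(net)
    if method == Method.NC:
        return nc_centrality(net)
    raise ValueError(f"method {method} requires externally supplied scores")


def _closeness(net: nx.Graph, mode: str) -> dict[str, float]:
    n = net.number_of_nodes()
    scores: dict[str, float] = {}
    for v in net.nodes:
        lengths = nx.single_source_shortest_path_length(net, v)
        total = sum(lengths.values())
        if mode == "strict":
            # Any unreachable node zeroes the score: on a disconnected graph
            # every node scores 0, the pathology that motivates per-PSLIN care.
            scores[v] = (n - 1) / total if len(lengths) == n and total > 0 else 0.0
        else:
            m = len(lengths)  # size of v's component
            scores[v] = (m - 1) / total if total > 0 else 0.0
    return scores


def _subgraph_centrality(net: nx.Graph) -> dict[str, float]:
    # diag(e^A) from the symmetric eigendecomposition: exact for symmetric A.
    nodes = list(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes)
    w, U = scipy.linalg.eigh(A)
    diag = (U * U) @ np.exp(w)
    return {v: float(diag[i]) for i, v in enumerate(nodes)}


def _eigenvector_centrality(net: nx.Graph) -> dict[str, float]:
    """Principal eigenvector per connected component, jointly normalized.

    Each non-trivial component contributes its Perron vector scaled by the
    component's spectral radius; the concatenated vector is then scaled to
    unit Euclidean norm so components with heavier spectra dominate, which
    degrades gracefully on disconnected PSLINs.  Isolated nodes score 0.
    """
    scores = {v: 0.0 for v in net.nodes}
    vec: dict[str, float] = {}
    for component in nx.connected_components(net):
        if len(component) < 2:
            continue
        nodes = sorted(component)
        A = nx.to_numpy_array(net, nodelist=nodes)
        w, U = scipy.linalg.eigh(A)
        radius = w[-1]
        principal = U[:, -1]
        # Perron vector of a connected graph has one sign; make it nonnegative.
        if principal.sum() < 0:
            principal = -principal
        principal = np.abs(principal)
        for i, v in enumerate(nodes):
            vec[v] = radius * float(principal[i])
    norm = np.sqrt(sum(x * x for x in vec.values()))
    if norm > 0:
        for v, x in vec.items():
            scores[v] = float(x / norm)
    return scores


def _information_centrality(net: nx.Graph) -> dict[str, float]:
    """Stephenson–Zelen information centrality, per connected component.

    For a component of size m >= 2 with Laplacian L, invert B = L + J (J the
    all-ones matrix) to get C; then
    ``score(i) = m / (m*C_ii + trace(C) - 2*rowsum_i(C))``.
    Isolated nodes score 0.
    """
    scores = {v: 0.0 for v in net.nodes}
    for component in nx.connected_components(net):
        m = len(component)
        if m < 2:
            continue
        nodes = sorted(component)
        sub = net.subgraph(nodes)
        L = nx.laplacian_matrix(sub, nodelist=nodes).toarray().astype(float)
        C = np.linalg.inv(L + np.ones((m, m)))
        trace = np.trace(C)
        rowsums = C.sum(axis=1)
        diag = np.diag(C)
        values = m / (m * diag + trace - 2 * rowsums)
        for i, v in enumerate(nodes):
            scores[v] = float(values[i])
    return scores


def edge_clustering_coefficient(net: nx.Graph, u: str, v: str) -> float:
    """Common-neighbor density of one edge: z(u,v) / min(deg(u)-1, deg(v)-1).

    Returns 0 when the denominator is 0 (a pendant endpoint can close no
    triangle).  Raises if the edge is not in the network.
    """
    if not net.has_edge(u, v):
        raise ValueError(f"edge ({u!r}, {v!r}) not in network")
    z = len(set(net[u]) & set(net[v]))
    denom = min(net.degree(u) - 1, net.degree(v) - 1)
    return z / denom if denom > 0 else 0.0


def nc_centrality(net: nx.Graph) -> dict[str, float]:
    """NC: each node's sum of edge clustering coefficients over incident edges."""
    scores = {v: 0.0 for v in net.nodes}
    for u, v in net.edges:
        ecc = edge_clustering_coefficient(net, u, v)
        scores[u] += ecc
        scores[v] += ecc
    return scores


def external_scores(net: nx.Graph, table: str | os.PathLike) -> dict[str, float]:
    """Load per-protein scores from a 2-column TSV for a pluggable method.

    Network nodes missing from the table score 0; table rows for proteins
    absent from the network are ignored (count logged).  Negative scores are
    rejected.
    """
    from lsed.io import _data_lines, ParseError

    table_scores: dict[str, float] = {}
    for lineno, line in _data_lines(table):
        tokens = line.split()
        if len(tokens) != 2:
            raise ParseError(f"{table}: line {lineno}: expected 2 columns, got {len(tokens)}")
        protein, raw = tokens
        value = float(raw)
        if value < 0:
            raise ValueError(f"{table}: line {lineno}: negative score {value} for {protein}")
        table_scores[protein] = value
    nodes = set(net.nodes)
    ignored = len(set(table_scores) - nodes)
    if ignored:
        logger.info("external score table %s: %d rows for proteins absent from network", table, ignored)
    return {v: table_scores.get(v, 0.0) for v in net.nodes}
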