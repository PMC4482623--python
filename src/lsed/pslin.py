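"""Construction of per-compartment interaction subnetworks (PSLINs).

A PSLIN for compartment *i* is the subgraph of the global PIN induced by the
proteins annotated to *i*: nodes ``V_i = V ∩ Loc(i)`` and every global edge
with both endpoints in ``V_i``.  A protein annotated to several compartments
appears in each of their PSLINs.

Each PSLIN carries a confidence level ``C(S_i) = |S_i| / |S_Max|``: its
protein count divided by the largest PSLIN's protein count, in (0, 1].  The
confidence weights how much a centrality score measured in that compartment
is trusted when scores are combined into one LCS per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import networkx as nx

#: The eleven compartments of a eukaryotic animal cell conventionally used to
#: annotate protein localization.  Documented for convenience only —
#: compartment labels are free strings and this list is not enforced.
CANONICAL_COMPARTMENTS: tuple[str, ...] = (
    "Cytoskeleton",
    "Cytosol",
    "Endoplasmic",
    "Endosome",
    "Extracellular",
    "Golgi",
    "Lysosome",
    "Mitochondrion",
    "Nucleus",
    "Peroxisome",
    "Plasma",
)


@dataclass(frozen=True)
class Pslin:
    """One compartment's induced subnetwork plus its confidence level.

    ``confidence`` is ``None`` until :func:`compute_confidence` assigns it.
    """

    compartment: str
    graph: nx.Graph
    confidence: float | None = None

    @property
    def size(self) -> int:
        """Network size = number of proteins (not edges)."""
        return self.graph.number_of_nodes()


def build_pslins(global_net: nx.Graph, annotations: Mapping[str, set[str]]) -> list[Pslin]:
    """Induce one PSLIN per compartment from the global PIN.

    Compartments whose annotated proteins are all absent from the network are
    dropped: a size-0 network supports no centrality and would fall outside
    the (0, 1] confidence range.  Output is ordered by compartment label so
    the result is independent of mapping iteration order.
    """
    if not annotations:
        raise ValueError("annotations mapping is empty; no PSLINs can be built")
    pslins = []
    for compartment in sorted(annotations):
        members = set(global_net.nodes) & annotations[compartment]
        if not members:
            continue
        subgraph = nx.Graph(global_net.subgraph(members))
        pslins.append(Pslin(compartment=compartment, graph=subgraph))
    return pslins


def compute_confidence(pslins: list[Pslin]) -> list[Pslin]:
    """Assign each PSLIN its confidence: node count over the largest node count."""
    if not pslins:
        raise ValueError("no PSLINs to assign confidence to")
    largest = max(p.size for p in pslins)
    if largest == 0:
        raise ValueError("all PSLINs are empty")
    return [replace(p, confidence=p.size / largest) for p in pslins]


def sort_pslins(pslins: list[Pslin]) -> list[Pslin]:
    """Order PSLINs descending by confidence, ties broken by compartment label.

    The label tie-break is a convention: the LCS scan can depend on processing
    order when confidences tie, and a total order makes runs reproducible.
    """
    for p in pslins:
        if p.confidence is None:
            raise ValueError(f"PSLIN {p.compartment!r} has no confidence assigned")
    return sorted(pslins, key=lambda p: (-p.confidence, p.compartment))
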