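"""The LCS combination step: per-PSLIN scores folded into one score per protein.

The score matrix holds ``Ess(p, S_i)`` — protein p's centrality inside PSLIN
S_i, zero where p is absent from S_i — with columns in descending-confidence
order.  The LCS scan starts each protein at 0 and walks the columns in that
order: whenever the protein's score in a PSLIN strictly exceeds its running
LCS, the LCS moves toward that score by the PSLIN's confidence fraction:

    LCS(p) <- LCS(p) + (Ess(p, S_i) - LCS(p)) * C(S_i)

so a high score seen in a trusted (large) compartment pulls hard, and the
same score seen only in a small compartment pulls weakly.  The scan is
monotone nondecreasing and bounded above by max_i Ess(p, S_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from lsed.centrality import Method, MethodSpec, compute_centrality, external_scores
from lsed.pslin import Pslin


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-protein, per-PSLIN centrality values.

    ``proteins`` covers the whole global network (sorted); ``pslins`` are in
    descending-confidence order and ``values[i, j]`` is protein i's score in
    PSLIN j — zero where the protein is not a member.
    """

    proteins: tuple[str, ...]
    pslins: tuple[Pslin, ...]
    values: np.ndarray

    @property
    def confidences(self) -> np.ndarray:
        return np.array([p.confidence for p in self.pslins])

    def to_frame(self) -> pd.DataFrame:
        """Wide protein × compartment view for inspection or export."""
        return pd.DataFrame(
            self.values,
            index=list(self.proteins),
            columns=[p.compartment for p in self.pslins],
        )


@dataclass(frozen=True)
class LcsTable:
    """Final per-protein scores and the descending ranking derived from them."""

    scores: dict[str, float]
    ranking: tuple[str, ...]


def score_matrix(global_net: nx.Graph, pslins: list[Pslin], spec: MethodSpec) -> ScoreMatrix:
    """Fill the Ess(p, S_i) matrix by running the centrality on each PSLIN.

    *pslins* must already be confidence-sorted.  Proteins of the global
    network absent from every PSLIN get an all-zero row.  With
    ``Method.EXTERNAL`` each column is loaded from the per-compartment table
    named in ``spec.external_tables``.
    """
    proteins = tuple(sorted(global_net.nodes))
    index = {p: i for i, p in enumerate(proteins)}
    values = np.zeros((len(proteins), len(pslins)))
    for j, pslin in enumerate(pslins):
        if spec.method == Method.EXTERNAL:
            try:
                table = spec.external_tables[pslin.compartment]
            except KeyError:
                raise ValueError(
                    f"no external score table for compartment {pslin.compartment!r}"
                ) from None
            column = external_scores(pslin.graph, table)
        else:
            column = compute_centrality(pslin.graph, spec)
        for protein, score in column.items():
            values[index[protein], j] = score
    return ScoreMatrix(proteins=proteins, pslins=tuple(pslins), values=values)


def compute_lcs(matrix: ScoreMatrix) -> LcsTable:
    """Run the confidence-weighted scan over the sorted PSLIN columns."""
    if np.any(matrix.values < 0):
        raise ValueError("score matrix contains negative values")
    confidences = matrix.confidences
    lcs = np.zeros(len(matrix.proteins))
    for j in range(matrix.values.shape[1]):
        ess = matrix.values[:, j]
        gain = ess > lcs  # strict gate: equal scores leave the LCS unchanged
        lcs[gain] += (ess[gain] - lcs[gain]) * confidences[j]
    scores = {p: float(lcs[i]) for i, p in enumerate(matrix.proteins)}
    return LcsTable(scores=scores, ranking=tuple(rank_by_score(scores)))


def rank_by_score(scores: Mapping[str, float]) -> list[str]:
    """Descending score order; equal scores broken by ascending protein ID."""
    return sorted(scores, key=lambda p: (-scores[p], p))
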