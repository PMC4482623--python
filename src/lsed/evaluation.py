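"""Ranked-list evaluation against a benchmark essential-protein set.

A method's ranking is judged by how enriched its top c% is for known
essential proteins:

* ``Acc``    — percentage of true essentials in the top-c% selection
* ``IAcc``   — relative improvement of one method's Acc over a baseline's
* ``AIAcc``  — mean IAcc over a set of cutoffs
* ``AKAcc``  — mean Acc over species at one cutoff

The top-c% selection takes the first floor(c/100 * |ranking|) proteins.
Benchmark IDs absent from the ranking never count as true positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


def top_fraction(ranking: Sequence[str], c: float) -> list[str]:
    """The first floor(c/100 * |ranking|) proteins of the ranking."""
    if not ranking:
        raise ValueError("ranking is empty")
    if not 0 < c <= 100:
        raise ValueError(f"cutoff percentage must be in (0, 100], got {c}")
    n = int(len(ranking) * c / 100)
    if n == 0:
        raise ValueError(f"top {c}% of {len(ranking)} proteins selects nothing")
    return list(ranking[:n])


def accuracy(selected: Sequence[str] | set[str], essentials: set[str]) -> float:
    """Percentage of the selection that is in the benchmark essential set."""
    selected = set(selected)
    if not selected:
        raise ValueError("empty selection")
    return 100.0 * len(selected & essentials) / len(selected)


def improved_accuracy(acc_new: float, acc_baseline: float) -> float | None:
    """Relative improvement, in percent, of one accuracy over a baseline.

    Returns ``None`` (not-available) when the baseline is 0 — never a silent 0.
    Negative values mean the baseline did better.
    """
    if acc_baseline == 0:
        return None
    return 100.0 * (acc_new - acc_baseline) / acc_baseline


def average_improved_accuracy(iaccs: Sequence[float]) -> float:
    """Arithmetic mean of per-cutoff IAcc values."""
    if not iaccs:
        raise ValueError("no IAcc values to average")
    return sum(iaccs) / len(iaccs)


def average_accuracy_over_species(accs: Sequence[float]) -> float:
    """Arithmetic mean of one method's Acc at a cutoff across species."""
    if not accs:
        raise ValueError("no Acc values to average")
    return sum(accs) / len(accs)


@dataclass(frozen=True)
class DifferenceReport:
    """Top-k disagreement between two rankings and its essential content.

    The two one-sided difference sets always have equal cardinality because
    both rankings select exactly k proteins.  Percentages are ``None``
    (not-available) when the rankings agree on the whole top k.
    """

    n_different: int
    pct_essential_a: float | None
    pct_essential_b: float | None


def difference_analysis(
    ranking_a: Sequence[str],
    ranking_b: Sequence[str],
    essentials: set[str],
    k: int = 100,
) -> DifferenceReport:
    """Compare the top-k protein sets of two rankings.

    Reports how many proteins each method ranks in its top k that the other
    does not, and what percentage of each one-sided difference set is
    essential — the proteins one method finds that the other misses.
    """
    if k > len(ranking_a) or k > len(ranking_b):
        raise ValueError(f"k={k} exceeds a ranking length")
    top_a = set(ranking_a[:k])
    top_b = set(ranking_b[:k])
    only_a = top_a - top_b
    only_b = top_b - top_a
    if not only_a:
        return DifferenceReport(0, None, None)
    return DifferenceReport(
        n_different=len(only_a),
        pct_essential_a=accuracy(only_a, essentials),
        pct_essential_b=accuracy(only_b, essentials),
    )
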