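"""GO Biological Process term-frequency summarization of hit lists.

For a list of hit genes, each gene contributes at most one count per
distinct term it carries; frequencies are raw counts (not enrichment), and
the top-k terms are ranked descending by count with alphabetical
tie-breaking.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

__all__ = ["TermFrequencyResult", "term_frequencies", "top_k"]

AnnotationTable = dict[str, set[str]]


@dataclass(frozen=True)
class TermFrequencyResult:
    """Term counts over a hit list plus annotation coverage."""

    counts: dict[str, int]
    n_hits: int
    n_annotated: int  # hit genes carrying at least one term

    @property
    def total_mass(self) -> int:
        """Total (gene, term) annotation pairs among hit genes."""
        return sum(self.counts.values())


def term_frequencies(hits: list[str], ann: AnnotationTable) -> TermFrequencyResult:
    """Count, per term, how many hit genes carry it."""
    counter: Counter[str] = Counter()
    n_annotated = 0
    for gene in hits:
        terms = ann.get(gene, set())
        if terms:
            n_annotated += 1
            counter.update(set(terms))
    return TermFrequencyResult(
        counts=dict(counter), n_hits=len(hits), n_annotated=n_annotated
    )


def top_k(counts: dict[str, int], k: int = 30) -> list[tuple[str, int]]:
    """Highest-count terms, descending; ties alphabetical; at most k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
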