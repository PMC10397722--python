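"""Variable-gene selection and gene-set intersection/coverage analytics."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from orthoclass.datamodel import ExpressionMatrix


class GeneSetError(ValueError):
    pass


def top_variable_genes(matrix: ExpressionMatrix, n: int = 500) -> list[str]:
    """The ``n`` genes with the highest across-sample variance, descending.

    Variance is the sample variance (denominator n−1) computed on log10-TPM
    values; ties are broken by gene id so the ranking is total and
    ``top_variable_genes(m, n)`` is always a prefix of
    ``top_variable_genes(m, n + 1)``.
    """
    if matrix.unit != "log10_tpm":
        raise GeneSetError(f"expected unit 'log10_tpm', got {matrix.unit!r}")
    if n > matrix.n_genes:
        raise GeneSetError(f"requested {n} genes but the matrix has {matrix.n_genes}")
    variances = matrix.values.var(axis=1, ddof=1)
    ranked = sorted(
        range(matrix.n_genes), key=lambda i: (-variances[i], matrix.gene_ids[i])
    )
    return [matrix.gene_ids[i] for i in ranked[:n]]


@dataclass
class IntersectionTable:
    """Exclusive membership-pattern counts (upset semantics) plus pairwise sizes."""

    set_names: list[str]
    patterns: dict  # frozenset of set names -> count of elements exactly there
    pairwise: dict  # frozenset({a, b}) -> |a ∩ b|
    union_size: int

    def pattern_count(self, names) -> int:
        return self.patterns.get(frozenset(names), 0)

    def pairwise_size(self, a: str, b: str) -> int:
        return self.pairwise.get(frozenset((a, b)), 0)

    def to_rows(self) -> list[tuple[str, int]]:
        """(pattern string 'A&B', count) rows sorted by count descending."""
        rows = [
            ("&".join(sorted(p)), c) for p, c in self.patterns.items() if c > 0
        ]
        return sorted(rows, key=lambda r: (-r[1], r[0]))


def intersect_sets(named_sets: dict) -> IntersectionTable:
    """Exact exclusive-pattern counts over >= 2 named sets.

    Every element of the union is classified by the exact subset of inputs
    containing it, so pattern counts are disjoint and sum to the union size.
    Pairwise (Venn-style) intersection sizes are exposed alongside.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise GeneSetError("need at least 2 named sets")
    if len(set(names)) != len(names):
        raise GeneSetError("duplicate set names")
    sets = {k: set(v) for k, v in named_sets.items()}
    union = set().union(*sets.values())
    patterns: dict = {}
    for element in union:
        pattern = frozenset(k for k in names if element in sets[k])
        patterns[pattern] = patterns.get(pattern, 0) + 1
    pairwise = {
        frozenset((a, b)): len(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    return IntersectionTable(
        set_names=names,
        patterns=patterns,
        pairwise=pairwise,
        union_size=len(union),
    )


def coverage_fraction(target_set, reference_set) -> float:
    """|target ∩ reference| / |reference|."""
    reference = set(reference_set)
    if not reference:
        raise GeneSetError("empty reference set")
    return len(set(target_set) & reference) / len(reference)
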