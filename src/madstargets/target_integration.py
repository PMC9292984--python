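"""Combine CArG-filtered binding with differential-expression evidence.

A gene is a *high-confidence target* of a complex when (i) at least one
CArG-passing consensus peak of that complex is assigned to it and (ii) it is
differentially expressed in the inducible-expression assay matching that
complex.  Overlap significance uses a one-sided Fisher exact test (equal to
the hypergeometric upper tail); enrichment of targets within dormancy DEG
sets uses the hypergeometric test directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from scipy import stats

from .deg_analysis import DEGSet
from .peak_processing import PeakGeneAssignment

__all__ = [
    "EnrichmentResult",
    "fisher_overlap",
    "hypergeom_overlap",
    "bound_gene_sets",
    "set_partition_counts",
    "PartitionCounts",
    "high_confidence_targets",
    "enrichment_in_dormancy_degs",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 / hypergeometric overlap test.

    ``k`` genes shared by a set of size ``K`` and a set of size ``n`` drawn
    from a universe of size ``N``; upper-tail p-value for enrichment.
    """

    k: int
    K: int
    n: int
    N: int
    p_value: float
    test: str
    odds_ratio: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) <= self.N):
            raise ValueError(
                f"inconsistent counts k={self.k} K={self.K} n={self.n} N={self.N}"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def _counts(
    set1: set[str], set2: set[str], universe: set[str]
) -> tuple[int, int, int, int]:
    if not universe:
        raise ValueError("empty universe")
    if not set1 <= universe or not set2 <= universe:
        raise ValueError("sets must be contained in the universe")
    return len(set1 & set2), len(set1), len(set2), len(universe)


def fisher_overlap(
    set1: set[str], set2: set[str], universe: set[str]
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher exact test of the overlap of two sets."""
    k, K, n, N = _counts(set1, set2, universe)
    table = [[k, K - k], [n - k, N - K - n + k]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(
        k=k, K=K, n=n, N=N, p_value=float(p), test="fisher_one_sided",
        odds_ratio=float(odds),
    )


def hypergeom_overlap(
    set1: set[str], set2: set[str], universe: set[str]
) -> EnrichmentResult:
    """Hypergeometric upper-tail P(X >= k) for the overlap of two sets."""
    k, K, n, N = _counts(set1, set2, universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        k=k, K=K, n=n, N=N, p_value=min(1.0, max(p, 5e-324)), test="hypergeometric"
    )


def bound_gene_sets(
    assignments_by_complex: Mapping[str, Sequence[PeakGeneAssignment]],
    passing_peak_ids_by_complex: Mapping[str, set[str]],
    closest_only: bool = False,
) -> dict[str, set[str]]:
    """Per-complex sets of genes with >= 1 CArG-passing assigned peak.

    With ``closest_only`` a gene counts only when it is the closest gene of
    one of its passing peaks (both behaviors are valid target definitions;
    the default uses all window assignments).
    """
    bound: dict[str, set[str]] = {}
    for complex_label, assignments in assignments_by_complex.items():
        passing = passing_peak_ids_by_complex[complex_label]
        genes = {
            a.gene_id
            for a in assignments
            if a.peak_id in passing and (a.is_closest or not closest_only)
        }
        bound[complex_label] = genes
    return bound


@dataclass
class PartitionCounts:
    """Counts of genes per non-empty membership pattern over labelled sets."""

    labels: tuple[str, ...]
    counts: dict[frozenset[str], int]

    @property
    def n_union(self) -> int:
        return sum(self.counts.values())

    def n_in_at_least(self, m: int) -> int:
        return sum(c for pat, c in self.counts.items() if len(pat) >= m)

    @property
    def fraction_in_at_least_two(self) -> float:
        return self.n_in_at_least(2) / self.n_union if self.n_union else 0.0

    @property
    def n_in_all(self) -> int:
        return self.counts.get(frozenset(self.labels), 0)


def set_partition_counts(gene_sets: Mapping[str, set[str]]) -> PartitionCounts:
    """Exact per-membership-pattern counts (Venn cells) for >= 2 sets."""
    if len(gene_sets) < 2:
        raise ValueError("need at least two sets")
    labels = tuple(sorted(gene_sets))
    counts: dict[frozenset[str], int] = {}
    union: set[str] = set().union(*gene_sets.values())
    for gene in union:
        pattern = frozenset(l for l in labels if gene in gene_sets[l])
        counts[pattern] = counts.get(pattern, 0) + 1
    return PartitionCounts(labels=labels, counts=counts)


def high_confidence_targets(
    bound_sets: Mapping[str, set[str]],
    deg_sets: Mapping[str, DEGSet],
    pairing: Mapping[str, str],
) -> tuple[dict[str, set[str]], dict[str, EnrichmentResult], dict[str, dict[str, str]]]:
    """Intersect each complex's bound genes with its paired assay's DEGs.

    Returns per-complex high-confidence sets, the Fisher overlap result per
    complex (universe = genes tested in that assay), and the regulation
    direction of each high-confidence gene.
    """
    unpaired = set(bound_sets) - set(pairing)
    if unpaired:
        raise ValueError(f"complexes without a paired DEG assay: {sorted(unpaired)}")
    hc: dict[str, set[str]] = {}
    tests: dict[str, EnrichmentResult] = {}
    directions: dict[str, dict[str, str]] = {}
    for complex_label, bound in bound_sets.items():
        degset = deg_sets[pairing[complex_label]]
        universe = degset.universe
        bound_in_universe = bound & universe
        hc[complex_label] = bound_in_universe & degset.deg_ids
        tests[complex_label] = fisher_overlap(
            bound_in_universe, degset.deg_ids, universe
        )
        directions[complex_label] = {
            g: ("up" if g in degset.up_ids else "down") for g in hc[complex_label]
        }
    return hc, tests, directions


def enrichment_in_dormancy_degs(
    hc_sets: Mapping[str, set[str]],
    core_degs: set[str],
    universe: set[str],
) -> dict[str, EnrichmentResult]:
    """Hypergeometric enrichment of each complex's targets in the dormancy
    core DEG set (sets are restricted to the universe before testing)."""
    if not universe:
        raise ValueError("empty universe")
    return {
        label: hypergeom_overlap(hc & universe, core_degs & universe, universe)
        for label, hc in hc_sets.items()
    }
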