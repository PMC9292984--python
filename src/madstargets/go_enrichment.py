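"""Flat GO-term enrichment with directional signed reporting.

Annotation is a flat gene -> term mapping (no ontology-graph propagation).
Per gene set and term, enrichment is the hypergeometric upper tail on the
annotated universe.  For directional reporting, up- and downregulated gene
sets are tested separately, the best (smallest) p-value per term is kept and
transformed to ``-log10 p``, signed positive when it came from the up set and
negative from the down set; values with best p > alpha are zeroed.  Raw
p-values drive the signed matrix (a BH-adjusted column is offered alongside,
never used for the zeroing rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .target_integration import EnrichmentResult, hypergeom_overlap
from .trajectory_clustering import ClusterAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "GOAnnotation",
    "term_enrichment",
    "signed_log10_best",
    "directional_signed_matrix",
    "cluster_go_report",
]


def signed_log10_best(p_up: float, p_down: float, alpha: float = 0.05) -> float:
    """Signed ``-log10`` of the best of two directional p-values.

    Positive when the best (smallest) p comes from the upregulated set,
    negative from the downregulated set, zero when the best p exceeds
    ``alpha``.  Ties are resolved positive.
    """
    best = min(p_up, p_down)
    if best > alpha:
        return 0.0
    sign = 1.0 if p_up <= p_down else -1.0
    return sign * -math.log10(best)


@dataclass
class GOAnnotation:
    """Flat gene -> GO-term annotation over an annotated universe."""

    gene_to_terms: dict[str, set[str]]
    term_labels: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is None:
            self.universe = set(self.gene_to_terms)
        if not set(self.gene_to_terms) <= self.universe:
            raise ValueError("annotated genes must be contained in the universe")
        if any(not terms for terms in self.gene_to_terms.values()):
            raise ValueError("genes with empty term sets are not allowed")

    @property
    def terms(self) -> list[str]:
        out: set[str] = set()
        for t in self.gene_to_terms.values():
            out |= t
        return sorted(out)

    def term_to_genes(self) -> dict[str, set[str]]:
        mapping: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                mapping.setdefault(t, set()).add(gene)
        return mapping

    @classmethod
    def from_tsv(
        cls, path: str | Path, label_path: str | Path | None = None
    ) -> "GOAnnotation":
        pairs = pd.read_csv(path, sep="\t", header=0)
        if pairs.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (gene_id, term_id)")
        gene_to_terms: dict[str, set[str]] = {}
        for gene, term in zip(
            pairs.iloc[:, 0].astype(str), pairs.iloc[:, 1].astype(str)
        ):
            gene_to_terms.setdefault(gene, set()).add(term)
        labels: dict[str, str] = {}
        if label_path is not None:
            lab = pd.read_csv(label_path, sep="\t", header=0)
            labels = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))
        return cls(gene_to_terms=gene_to_terms, term_labels=labels)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tterm_id\n")
            for gene in sorted(self.gene_to_terms):
                for term in sorted(self.gene_to_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")


def term_enrichment(
    gene_set: set[str],
    annotation: GOAnnotation,
    universe: set[str] | None = None,
) -> dict[str, EnrichmentResult]:
    """Hypergeometric enrichment of every annotated term in ``gene_set``."""
    universe = universe if universe is not None else annotation.universe
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene set must be contained in the universe")
    results: dict[str, EnrichmentResult] = {}
    for term, genes in annotation.term_to_genes().items():
        results[term] = hypergeom_overlap(genes & universe, gene_set, universe)
    return results


def directional_signed_matrix(
    row_sets_up: Mapping[str, set[str]],
    row_sets_down: Mapping[str, set[str]],
    annotation: GOAnnotation,
    alpha: float = 0.05,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Rows x terms matrix of signed -log10(best p) values.

    Positive values mark enrichment in the upregulated set, negative in the
    downregulated set; cells with best p > alpha are zero.  Up/down ties are
    resolved positive (logged).
    """
    if set(row_sets_up) != set(row_sets_down):
        raise ValueError("up and down mappings must share the same rows")
    terms = annotation.terms
    rows = sorted(row_sets_up)
    data = {}
    for row in rows:
        up, down = row_sets_up[row], row_sets_down[row]
        if up & down:
            raise ValueError(f"row {row!r}: up and down sets overlap")
        p_up = term_enrichment(up, annotation, universe)
        p_down = term_enrichment(down, annotation, universe)
        values = []
        for term in terms:
            pu, pd_ = p_up[term].p_value, p_down[term].p_value
            if pu == pd_ and pu <= alpha:
                logger.info(
                    "row %s term %s: up/down p tie (%.3g); reported positive",
                    row, term, pu,
                )
            values.append(signed_log10_best(pu, pd_, alpha))
        data[row] = values
    return pd.DataFrame.from_dict(data, orient="index", columns=terms).loc[rows]


def cluster_go_report(
    assignment: ClusterAssignment,
    annotation: GOAnnotation,
    alpha: float = 0.05,
    universe: set[str] | None = None,
) -> dict[int, pd.DataFrame]:
    """Per-cluster table of terms with p < alpha (strict); clusters with no
    significant term are omitted from the report and logged."""
    universe = universe if universe is not None else annotation.universe
    report: dict[int, pd.DataFrame] = {}
    for cluster in sorted(assignment.labels.unique()):
        genes = set(assignment.labels.index[assignment.labels == cluster].astype(str))
        genes &= universe
        if not genes:
            logger.info("cluster %s: no genes in the annotated universe", cluster)
            continue
        results = term_enrichment(genes, annotation, universe)
        records = [
            {
                "term": term,
                "label": annotation.term_labels.get(term, ""),
                "k": r.k,
                "K": r.K,
                "p_value": r.p_value,
                "neg_log10_p": -math.log10(r.p_value),
            }
            for term, r in results.items()
            if r.p_value < alpha
        ]
        if not records:
            logger.info("cluster %s: no significant GO term; omitted", cluster)
            continue
        frame = pd.DataFrame.from_records(records).sort_values(
            ["p_value", "term"], ignore_index=True
        )
        frame["p_adj_bh"] = multipletests(frame["p_value"], method="fdr_bh")[1]
        report[int(cluster)] = frame
    return report
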