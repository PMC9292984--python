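"""Threshold differential-expression tables and build the dormancy core set.

Tables carry one row per tested gene with columns ``gene_id``, ``log2fc`` and
``padj``.  A gene is called differentially expressed when ``padj <= alpha``
(non-strict) and, where a fold-change threshold applies, ``|log2fc|`` is
strictly greater than it.  The dormancy core is the intersection of the DEG
calls from two independent dormancy transcriptome datasets, with the overlap
significance measured on their shared tested universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DEGSet", "read_deg_table", "filter_degs", "dormancy_core_degs"]

REQUIRED_COLUMNS = ("gene_id", "log2fc", "padj")


@dataclass
class DEGSet:
    """A labelled DEG call: significant genes plus the tested universe."""

    label: str
    deg_ids: set[str]
    up_ids: set[str]
    down_ids: set[str]
    universe: set[str]
    alpha: float
    lfc_threshold: float | None
    n_dropped_na: int = 0

    def __post_init__(self) -> None:
        if not self.deg_ids <= self.universe:
            raise ValueError(f"{self.label}: DEG ids not contained in universe")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return table


def filter_degs(
    table: pd.DataFrame,
    label: str,
    alpha: float = 0.05,
    lfc_threshold: float | None = None,
) -> DEGSet:
    """Call DEGs at ``padj <= alpha`` and (optionally) ``|log2fc| > threshold``.

    Rows with missing ``padj`` are dropped from the DEG call (their genes stay
    in the universe) and the drop count is logged.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing required columns {missing}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if lfc_threshold is not None and lfc_threshold < 0:
        raise ValueError("lfc_threshold must be >= 0")

    universe = set(table["gene_id"].astype(str))
    usable = table.dropna(subset=["padj"])
    n_dropped = len(table) - len(usable)
    if n_dropped:
        logger.info("%s: dropped %d records with missing padj", label, n_dropped)
    if ((usable["padj"] < 0) | (usable["padj"] > 1)).any():
        raise ValueError(f"{label}: padj values outside [0, 1]")

    keep = usable["padj"] <= alpha
    if lfc_threshold is not None:
        keep &= usable["log2fc"].abs() > lfc_threshold
    degs = usable[keep]
    up = set(degs.loc[degs["log2fc"] > 0, "gene_id"].astype(str))
    down = set(degs.loc[degs["log2fc"] < 0, "gene_id"].astype(str))
    return DEGSet(
        label=label,
        deg_ids=up | down | set(degs.loc[degs["log2fc"] == 0, "gene_id"].astype(str)),
        up_ids=up,
        down_ids=down,
        universe=universe,
        alpha=alpha,
        lfc_threshold=lfc_threshold,
        n_dropped_na=n_dropped,
    )


def dormancy_core_degs(degset_a: DEGSet, degset_b: DEGSet):
    """Intersect two dormancy DEG sets and test the overlap significance.

    Returns ``(core_gene_set, EnrichmentResult)``; the hypergeometric test is
    conditioned on the shared tested universe.
    """
    from .target_integration import hypergeom_overlap  # local to avoid cycle

    shared = degset_a.universe & degset_b.universe
    if not shared:
        raise ValueError("the two DEG sets share no tested genes")
    core = degset_a.deg_ids & degset_b.deg_ids
    result = hypergeom_overlap(
        degset_a.deg_ids & shared, degset_b.deg_ids & shared, shared
    )
    return core, result
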