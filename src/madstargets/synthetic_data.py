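"""Synthetic benchmark generator with planted, recoverable structure.

Emulates the data shapes consumed by the pipeline: a random genome with
non-overlapping gene models, four TF-complex peak sets whose true target
genes carry a CArG-box planted inside the promoter/gene window, replicate
peak files with summit jitter and dropout, inducible-expression DEG tables
in which bound genes are enriched, two dormancy DEG datasets enriched only
for the heteromeric complexes' targets, an 8-timepoint annual expression
course with planted cluster shapes, and block-structured GO annotations
aligned with the clusters.  Everything is deterministic given the seed, and
the planted truth is returned (and written) so recovery can be measured.

The background sequence is i.i.d. uniform over A/C/G/T, so chance CArG
occurrences follow an analytically known rate; motifs are written over the
existing bases (never inserted) so gene coordinates stay valid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .carg_scanner import CARG_VARIANTS
from .go_enrichment import GOAnnotation
from .intervals_io import (
    GeneModel,
    Genome,
    GenomicInterval,
    Peak,
    write_fasta,
    write_gff3,
    write_peaks,
)

__all__ = [
    "SyntheticConfig",
    "PlantedSite",
    "PlantedTruth",
    "SyntheticBundle",
    "make_genome_and_genes",
    "plant_carg_and_peaks",
    "simulate_deg_tables",
    "simulate_timecourse_and_go",
    "generate_bundle",
    "write_bundle",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: default trajectory shapes over 8 annual timepoints (already near z-scale):
#: endodormancy-peaking, ecodormancy-peaking, monotone-declining,
#: budbreak-induced.
DEFAULT_PROTOTYPES: tuple[tuple[float, ...], ...] = (
    (-1.2, -0.8, 0.3, 1.2, 1.4, 0.6, -0.4, -1.1),
    (-1.3, -1.0, -0.6, 0.0, 0.8, 1.4, 1.0, -0.3),
    (1.5, 1.1, 0.7, 0.3, -0.1, -0.5, -0.9, -1.3),
    (-0.9, -1.0, -1.0, -0.8, -0.4, 0.2, 1.2, 1.7),
)

DEFAULT_COMPLEXES: tuple[str, ...] = (
    "DAM1-SVPa",
    "DAM4-SVPa",
    "FLC-SVPa",
    "SVPa-SVPa",
)


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the benchmark conditions."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length_bp: int = 1_500_000
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (1500, 3000)
    intergenic_min: int = 4500
    complexes: tuple[str, ...] = DEFAULT_COMPLEXES
    n_true_targets: int = 50
    n_background_peaks: int = 200
    n_replicates: int = 3
    peak_length_mean: float = 300.0
    peak_length_sd: float = 50.0
    summit_jitter_sd: float = 20.0
    replicate_miss_rate: float = 0.05
    upstream_bp: int = 3000
    downstream_bp: int = 1000
    carg_variant_probs: tuple[float, float] = (0.5, 0.5)  # (AT6, AT5)
    #: fraction of planted sites drawn from the proximal promoter
    #: [TSS - 1000, TSS + 200] (in gene orientation) rather than uniformly
    #: from the whole assignment window; real TF binding concentrates there.
    promoter_bias: float = 0.7
    deg_effect: float = 0.9
    deg_background_rate: float = 0.05
    dormancy_effect: float = 0.5
    dormancy_detect_rate: float = 0.85
    #: complexes whose targets are enriched in the dormancy datasets; the
    #: homomer analogue (last label) is deliberately left out.
    dormancy_complexes: tuple[str, ...] = DEFAULT_COMPLEXES[:3]
    include_null_assay: bool = True
    timepoints: int = 8
    prototypes: tuple[tuple[float, ...], ...] = DEFAULT_PROTOTYPES
    trajectory_noise_sd: float = 0.4
    n_go_terms: int = 40
    go_block_size: int = 5
    go_within_block_rate: float = 0.6
    go_background_rate: float = 0.05

    def __post_init__(self) -> None:
        positive = {
            "n_chrom": self.n_chrom,
            "chrom_length_bp": self.chrom_length_bp,
            "n_genes": self.n_genes,
            "n_true_targets": self.n_true_targets,
            "n_replicates": self.n_replicates,
            "timepoints": self.timepoints,
            "n_go_terms": self.n_go_terms,
            "go_block_size": self.go_block_size,
        }
        for name, value in positive.items():
            if value < 1:
                raise ValueError(f"{name} must be positive (got {value})")
        if self.n_true_targets > self.n_genes:
            raise ValueError("n_true_targets cannot exceed n_genes")
        if any(len(p) != self.timepoints for p in self.prototypes):
            raise ValueError("every prototype must have length = timepoints")
        if self.n_go_terms < len(self.prototypes) * self.go_block_size:
            raise ValueError("n_go_terms too small for the cluster-aligned blocks")
        if not set(self.dormancy_complexes) <= set(self.complexes):
            raise ValueError("dormancy_complexes must be a subset of complexes")

    @property
    def assay_label(self) -> dict[str, str]:
        """Pairing complex -> inducible-assay DEG table label."""
        return {c: f"GR:{c}" for c in self.complexes}

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass(frozen=True)
class PlantedSite:
    complex_label: str
    gene_id: str
    chrom: str
    start: int
    variant: str


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests."""

    targets: dict[str, set[str]] = field(default_factory=dict)
    sites: list[PlantedSite] = field(default_factory=list)
    clusters: dict[str, int] = field(default_factory=dict)
    #: assay label -> {gene_id: "up"|"down"} for planted target DEGs
    deg_status: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "targets": {c: sorted(g) for c, g in self.targets.items()},
            "sites": [asdict(s) for s in self.sites],
            "clusters": self.clusters,
            "deg_status": self.deg_status,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            targets={c: set(g) for c, g in payload["targets"].items()},
            sites=[PlantedSite(**s) for s in payload["sites"]],
            clusters={g: int(c) for g, c in payload["clusters"].items()},
            deg_status=payload["deg_status"],
        )


# ---------------------------------------------------------------------------
# Stage 0: genome and gene models


def make_genome_and_genes(
    config: SyntheticConfig,
) -> tuple[Genome, list[GeneModel]]:
    """Random uniform-base genome with non-overlapping, spaced gene models."""
    rng = config._rng(0)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    per_chrom = [
        config.n_genes // config.n_chrom
        + (1 if i < config.n_genes % config.n_chrom else 0)
        for i in range(config.n_chrom)
    ]
    gene_counter = 0
    lo_len, hi_len = config.gene_length_range
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        clen = config.chrom_length_bp
        seq = _BASES[rng.integers(0, 4, size=clen)].tobytes().decode()
        sequences[chrom] = seq
        n = per_chrom[ci]
        if n == 0:
            continue
        lengths = rng.integers(lo_len, hi_len + 1, size=n)
        slack = clen - int(lengths.sum()) - (n + 1) * config.intergenic_min
        if slack < 0:
            raise ValueError(
                f"{n} genes do not fit on {chrom}: need "
                f"{int(lengths.sum()) + (n + 1) * config.intergenic_min} bp, "
                f"have {clen}"
            )
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        strands = rng.integers(0, 2, size=n)
        cursor = 0
        for gi in range(n):
            cursor += config.intergenic_min + int(extra[gi])
            start = cursor
            end = start + int(lengths[gi])
            cursor = end
            gene_counter += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gene_counter:04d}",
                    interval=GenomicInterval(
                        chrom, start, end, "+" if strands[gi] == 0 else "-"
                    ),
                )
            )
    return Genome(sequences), genes


# ---------------------------------------------------------------------------
# Stage 1: planted CArG sites and replicate peak sets


def _truncated_peak_length(rng: np.random.Generator, config: SyntheticConfig) -> int:
    return max(50, int(round(rng.normal(config.peak_length_mean, config.peak_length_sd))))


def plant_carg_and_peaks(
    genome: Genome,
    genes: Sequence[GeneModel],
    config: SyntheticConfig,
) -> tuple[Genome, dict[str, list[list[Peak]]], PlantedTruth]:
    """Plant one CArG-box per true target and build replicate peak sets.

    Each complex draws its targets independently; each target receives one
    box (variant per ``carg_variant_probs``) written into the genome inside
    the gene's assignment window, and one true peak with its summit at the
    box center.  Background peaks are placed uniformly (no planted box).
    Each replicate drops peaks independently and jitters summits.
    """
    rng = config._rng(1)
    mutable = {c: bytearray(genome[c].encode()) for c in genome.chroms()}
    lengths = genome.lengths
    chrom_names = genome.chroms()
    chrom_probs = np.array([lengths[c] for c in chrom_names], dtype=float)
    chrom_probs /= chrom_probs.sum()
    gene_ids = [g.gene_id for g in genes]
    gene_map = {g.gene_id: g for g in genes}
    planted_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    truth = PlantedTruth()
    replicate_peaks: dict[str, list[list[Peak]]] = {}
    variant_names = ("AT6", "AT5")

    for complex_label in config.complexes:
        targets = rng.choice(gene_ids, size=config.n_true_targets, replace=False)
        truth.targets[complex_label] = set(map(str, targets))
        base_peaks: list[Peak] = []

        for gene_id in map(str, targets):
            gene = gene_map[gene_id]
            chrom = gene.interval.chrom
            clen = lengths[chrom]
            variant = variant_names[
                rng.choice(2, p=np.asarray(config.carg_variant_probs))
            ]
            vlen = CARG_VARIANTS[variant][1]
            if gene.interval.strand == "+":
                lo = gene.tss - config.upstream_bp
                hi = gene.tes + config.downstream_bp
                prox_lo, prox_hi = gene.tss - 1000, gene.tss + 200
            else:
                lo = gene.tes - config.downstream_bp
                hi = gene.tss + config.upstream_bp
                prox_lo, prox_hi = gene.tss - 200, gene.tss + 1000
            lo = max(0, lo)
            hi = min(clen - vlen, hi - vlen + 1)
            prox_lo = max(lo, prox_lo)
            prox_hi = min(hi, prox_hi)
            if hi < lo:
                raise ValueError(f"no room to plant a box for {gene_id}")
            for _attempt in range(200):
                if rng.random() < config.promoter_bias and prox_lo <= prox_hi:
                    pos = int(rng.integers(prox_lo, prox_hi + 1))
                else:
                    pos = int(rng.integers(lo, hi + 1))
                if all(
                    pos + vlen <= s or pos >= e for s, e in planted_by_chrom[chrom]
                ):
                    break
            else:  # pragma: no cover - would need an absurdly dense config
                raise RuntimeError(f"could not place a box for {gene_id}")
            n_wobble = vlen - 4
            core = _BASES[rng.integers(0, 2, size=n_wobble) * 3]  # A or T
            motif = b"CC" + core.tobytes() + b"GG"
            mutable[chrom][pos : pos + vlen] = motif
            planted_by_chrom[chrom].append((pos, pos + vlen))
            truth.sites.append(
                PlantedSite(
                    complex_label=complex_label,
                    gene_id=gene_id,
                    chrom=chrom,
                    start=pos,
                    variant=variant,
                )
            )
            plen = _truncated_peak_length(rng, config)
            center = pos + vlen // 2
            start = int(np.clip(center - plen // 2, 0, clen - plen))
            base_peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, start + plen),
                    peak_id=f"{complex_label}:true:{gene_id}",
                    score=float(rng.uniform(10, 30)),
                    summit_offset=center - start,
                )
            )

        for bi in range(config.n_background_peaks):
            plen = _truncated_peak_length(rng, config)
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
            start = int(rng.integers(0, lengths[chrom] - plen + 1))
            base_peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, start + plen),
                    peak_id=f"{complex_label}:bg:{bi:04d}",
                    score=float(rng.uniform(1, 8)),
                    summit_offset=plen // 2,
                )
            )

        replicates: list[list[Peak]] = []
        for r in range(config.n_replicates):
            rep: list[Peak] = []
            for p in base_peaks:
                if rng.random() < config.replicate_miss_rate:
                    continue
                plen = len(p.interval)
                jitter = int(round(rng.normal(0.0, config.summit_jitter_sd)))
                offset = int(np.clip(p.summit_offset + jitter, 0, plen - 1))
                rep.append(
                    Peak(
                        interval=p.interval,
                        peak_id=f"{p.peak_id}:r{r}",
                        score=float(p.score * np.exp(rng.normal(0.0, 0.2))),
                        summit_offset=offset,
                        replicate_id=f"rep{r}",
                    )
                )
            replicates.append(rep)
        replicate_peaks[complex_label] = replicates

    planted_genome = Genome(
        {c: mutable[c].decode() for c in chrom_names}
    )
    return planted_genome, replicate_peaks, truth


# ---------------------------------------------------------------------------
# Stage 2: DEG tables


def _deg_table(
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    planted: dict[str, str],
    background_rate: float,
) -> pd.DataFrame:
    """Null table with planted significant genes and random background DEGs."""
    n = len(gene_ids)
    padj = rng.uniform(0.0, 1.0, size=n)
    lfc = rng.normal(0.0, 0.3, size=n)
    index = {g: i for i, g in enumerate(gene_ids)}
    for gene, direction in planted.items():
        i = index[gene]
        padj[i] = rng.uniform(0.0, 0.01)
        lfc[i] = rng.uniform(2.0, 4.0) * (1.0 if direction == "up" else -1.0)
    background = (rng.uniform(size=n) < background_rate) & ~np.isin(
        gene_ids, list(planted)
    )
    for i in np.flatnonzero(background):
        padj[i] = rng.uniform(0.0, 0.01)
        lfc[i] = rng.uniform(2.0, 4.0) * (1.0 if rng.random() < 0.5 else -1.0)
    return pd.DataFrame({"gene_id": list(gene_ids), "log2fc": lfc, "padj": padj})


def simulate_deg_tables(
    genes: Sequence[GeneModel],
    truth: PlantedTruth,
    config: SyntheticConfig,
) -> dict[str, pd.DataFrame]:
    """DEG tables for the inducible assays, the optional non-enriched null
    assay, and the two dormancy datasets (``datasetA``/``datasetB``)."""
    rng = config._rng(2)
    gene_ids = sorted(g.gene_id for g in genes)
    tables: dict[str, pd.DataFrame] = {}

    for complex_label in config.complexes:
        label = config.assay_label[complex_label]
        planted: dict[str, str] = {}
        for gene in sorted(truth.targets[complex_label]):
            if rng.random() < config.deg_effect:
                planted[gene] = "up" if rng.random() < 0.5 else "down"
        truth.deg_status[label] = planted
        tables[label] = _deg_table(rng, gene_ids, planted, config.deg_background_rate)

    if config.include_null_assay:
        truth.deg_status["GR_null"] = {}
        tables["GR_null"] = _deg_table(
            rng, gene_ids, {}, config.deg_background_rate
        )

    # datasets A and B measure the same dormancy biology: the dormancy-DEG
    # status is drawn once per gene, and each dataset detects it with
    # probability dormancy_detect_rate.
    dormancy_targets = sorted(
        set().union(*(truth.targets[c] for c in config.dormancy_complexes))
    )
    dormancy_truth: dict[str, str] = {}
    for gene in dormancy_targets:
        if rng.random() < config.dormancy_effect:
            dormancy_truth[gene] = "up" if rng.random() < 0.5 else "down"
    for dataset in ("datasetA", "datasetB"):
        planted = {
            g: d
            for g, d in dormancy_truth.items()
            if rng.random() < config.dormancy_detect_rate
        }
        truth.deg_status[dataset] = planted
        tables[dataset] = _deg_table(
            rng, gene_ids, planted, config.deg_background_rate
        )
    return tables


# ---------------------------------------------------------------------------
# Stage 3: time course and GO annotation


def simulate_timecourse_and_go(
    genes: Sequence[GeneModel],
    truth: PlantedTruth,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GOAnnotation]:
    """Annual expression course with planted cluster shapes and GO blocks.

    Each gene follows one prototype plus i.i.d. Gaussian noise; GO terms come
    in blocks aligned with the clusters (genes of cluster k are preferentially
    annotated to the terms of block k) on top of a uniform background.
    """
    rng = config._rng(3)
    gene_ids = sorted(g.gene_id for g in genes)
    n = len(gene_ids)
    n_proto = len(config.prototypes)
    labels = rng.integers(0, n_proto, size=n)
    truth.clusters = {g: int(l) + 1 for g, l in zip(gene_ids, labels)}
    prototypes = np.asarray(config.prototypes, dtype=float)
    values = prototypes[labels] + rng.normal(
        0.0, config.trajectory_noise_sd, size=(n, config.timepoints)
    )
    expression = pd.DataFrame(
        values,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"T{t + 1}" for t in range(config.timepoints)],
    )

    terms = [f"TERM{i:04d}" for i in range(config.n_go_terms)]
    term_labels = {t: f"synthetic process {i}" for i, t in enumerate(terms)}
    gene_to_terms: dict[str, set[str]] = {}
    for gi, gene in enumerate(gene_ids):
        block = labels[gi]
        assigned: set[str] = set()
        start = block * config.go_block_size
        for t in terms[start : start + config.go_block_size]:
            if rng.random() < config.go_within_block_rate:
                assigned.add(t)
        for t in terms:
            if rng.random() < config.go_background_rate:
                assigned.add(t)
        if assigned:
            gene_to_terms[gene] = assigned
    annotation = GOAnnotation(
        gene_to_terms=gene_to_terms,
        term_labels=term_labels,
        universe=set(gene_ids),
    )
    return expression, annotation


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: Genome
    genes: list[GeneModel]
    replicate_peaks: dict[str, list[list[Peak]]]
    deg_tables: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    go_annotation: GOAnnotation
    truth: PlantedTruth


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Run all generator stages in order under the config's seed."""
    config = config if config is not None else SyntheticConfig()
    genome, genes = make_genome_and_genes(config)
    genome, replicate_peaks, truth = plant_carg_and_peaks(genome, genes, config)
    deg_tables = simulate_deg_tables(genes, truth, config)
    expression, annotation = simulate_timecourse_and_go(genes, truth, config)
    return SyntheticBundle(
        config=config,
        genome=genome,
        genes=genes,
        replicate_peaks=replicate_peaks,
        deg_tables=deg_tables,
        expression=expression,
        go_annotation=annotation,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, object]:
    """Write the full bundle to disk; returns a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / "genome.fa")
    write_gff3(bundle.genes, outdir / "genes.gff3")
    peak_dir = outdir / "peaks"
    peak_files: dict[str, list[str]] = {}
    for label, replicates in bundle.replicate_peaks.items():
        d = peak_dir / label
        d.mkdir(parents=True, exist_ok=True)
        files = []
        for r, peaks in enumerate(replicates):
            path = d / f"rep{r}.narrowPeak"
            write_peaks(peaks, path, dialect="narrowpeak")
            files.append(str(path))
        peak_files[label] = files
    deg_dir = outdir / "degs"
    deg_dir.mkdir(exist_ok=True)
    deg_files: dict[str, str] = {}
    for label, table in bundle.deg_tables.items():
        path = deg_dir / f"{label.replace(':', '_')}.tsv"
        table.to_csv(path, sep="\t", index=False)
        deg_files[label] = str(path)
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t")
    bundle.go_annotation.to_tsv(outdir / "go_annotation.tsv")
    bundle.truth.to_json(outdir / "truth.json")
    manifest = {
        "genome": str(outdir / "genome.fa"),
        "annotation": str(outdir / "genes.gff3"),
        "peaks": peak_files,
        "deg_tables": deg_files,
        "expression": str(outdir / "expression.tsv"),
        "go_annotation": str(outdir / "go_annotation.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
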