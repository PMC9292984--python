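"""Genomic coordinate types and readers/writers for FASTA, GFF3, BED6 and narrowPeak.

Every coordinate held in memory is 0-based half-open; conversions to and from
the 1-based inclusive GFF3 convention happen only at the I/O boundary.  The
parsers are deliberately strict: malformed records raise :class:`FormatError`
naming the offending line, and duplicate identifiers are rejected, because
silent coordinate or identity errors are the classic failure mode of
peak-to-gene pipelines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FormatError",
    "Genome",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_peaks",
    "write_peaks",
]

_VALID_BASES = frozenset("ACGTN")
_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


class FormatError(ValueError):
    """A file violates its format contract (message names the line)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A peak interval with optional summit offset and replicate label."""

    interval: GenomicInterval
    peak_id: str
    score: float = 0.0
    summit_offset: int | None = None
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative score for peak {self.peak_id}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak {self.peak_id}"
            )

    @property
    def anchor(self) -> int:
        """Point position used for gene assignment: summit, else midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES derived from its interval.

    For a ``+`` gene the TSS is ``start`` and the TES ``end - 1``; for a
    ``-`` gene the TSS is ``end - 1`` and the TES ``start``.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must be stranded")

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.interval.strand == "+" else self.interval.start


class Genome:
    """Mapping of chromosome name to an uppercase A/C/G/T/N sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name}")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name} contains invalid characters {sorted(bad)}"
                )
            if name in seqs:
                raise ValueError(f"duplicate chromosome name {name}")
            seqs[name] = seq
        self._seqs = seqs

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end)``; bounds are checked."""
        seq = self._seqs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) exceeds chromosome {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences uppercased)."""
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                if name in seqs:
                    raise FormatError(
                        f"{path}: duplicate FASTA header {name!r} at line {lineno}"
                    )
                seqs[name] = []
                current = name
            else:
                if current is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                chunk = line.strip().upper()
                if set(chunk) - _VALID_BASES:
                    raise FormatError(
                        f"{path}: invalid sequence characters at line {lineno}"
                    )
                seqs[current].append(chunk)
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    try:
        return Genome({name: "".join(parts) for name, parts in seqs.items()})
    except ValueError as exc:  # empty record
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: str | Path, feature_types: Sequence[str] = ("gene",)
) -> list[GeneModel]:
    """Read gene features from a GFF3 file (1-based inclusive on disk).

    Only rows whose feature type is in ``feature_types`` are retained; their
    coordinates are converted to 0-based half-open.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    wanted = set(feature_types)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: expected 9 tab-separated fields at line {lineno}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in wanted:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer coordinates at line {lineno}"
                ) from None
            if start1 > end1:
                raise FormatError(f"{path}: start > end at line {lineno}")
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: unknown strand {strand!r} at line {lineno}"
                )
            m = _GFF_ID_RE.search(attrs)
            if not m:
                raise FormatError(f"{path}: missing ID attribute at line {lineno}")
            gene_id = m.group(1).strip()
            if gene_id in seen:
                raise FormatError(
                    f"{path}: duplicate gene ID {gene_id!r} at line {lineno}"
                )
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    interval=GenomicInterval(chrom, start1 - 1, end1, strand),
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tmadstargets\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED6 / narrowPeak

_DIALECTS = ("bed6", "narrowpeak")


def read_peaks(
    path: str | Path, dialect: str = "narrowpeak", replicate_id: str | None = None
) -> list[Peak]:
    """Read peaks from a BED6 or ENCODE narrowPeak file (0-based half-open).

    narrowPeak column 10 is the summit offset from the interval start; the
    sentinel ``-1`` means no summit.  Missing/``.`` names are replaced with
    auto-generated ``peak_<n>`` identifiers.
    """
    dialect = dialect.lower()
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown peak dialect {dialect!r}; expected {_DIALECTS}")
    min_fields = 6 if dialect == "bed6" else 10
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise FormatError(
                    f"{path}: expected >= {min_fields} fields at line {lineno}"
                )
            chrom, start_s, end_s, name, score_s, _strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                score = 0.0 if score_s == "." else float(score_s)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric coordinates/score at line {lineno}"
                ) from None
            if start >= end:
                raise FormatError(f"{path}: start >= end at line {lineno}")
            summit: int | None = None
            if dialect == "narrowpeak":
                try:
                    summit_raw = int(fields[9])
                except ValueError:
                    raise FormatError(
                        f"{path}: non-integer summit at line {lineno}"
                    ) from None
                if summit_raw != -1:
                    if not (0 <= summit_raw < end - start):
                        raise FormatError(
                            f"{path}: summit offset {summit_raw} outside interval "
                            f"at line {lineno}"
                        )
                    summit = summit_raw
            peak_id = name if name not in (".", "") else f"peak_{len(peaks) + 1}"
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    peak_id=peak_id,
                    score=score,
                    summit_offset=summit,
                    replicate_id=replicate_id,
                )
            )
    return peaks


def write_peaks(
    peaks: Iterable[Peak], path: str | Path, dialect: str = "narrowpeak"
) -> None:
    dialect = dialect.lower()
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown peak dialect {dialect!r}; expected {_DIALECTS}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            base = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t{p.score:g}\t."
            if dialect == "bed6":
                fh.write(base + "\n")
            else:
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(base + f"\t{p.score:g}\t-1\t-1\t{summit}\n")
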