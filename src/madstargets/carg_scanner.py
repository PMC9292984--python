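"""CArG-box scanning and background-rate estimation.

MADS transcription-factor complexes bind CArG-box elements.  Two variants are
recognized here: the canonical box ``CC(A/T)6GG`` (AT6, 10 bp) and the
shortened box ``CC(A/T)5GG`` (AT5, 9 bp) recurrently found for SVP/DAM-type
complexes.  The variant set is closed under reverse complement, so a single
forward-strand scan counts every double-stranded occurrence exactly once per
strand orientation; ``N`` bases never match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals_io import Genome, Peak

__all__ = [
    "CARG_VARIANTS",
    "CArGMatch",
    "scan_carg",
    "filter_peaks_by_carg",
    "carg_background_rate",
    "per_start_probability",
]

#: variant name -> (regex pattern, match length)
CARG_VARIANTS: dict[str, tuple[str, int]] = {
    "AT6": (r"CC[AT]{6}GG", 10),
    "AT5": (r"CC[AT]{5}GG", 9),
}

# lookahead form reports overlapping matches
_COMPILED = {
    name: re.compile(rf"(?=({pat}))") for name, (pat, _len) in CARG_VARIANTS.items()
}


@dataclass(frozen=True)
class CArGMatch:
    """One occurrence of a CArG-box variant within a scanned sequence."""

    position: int
    variant: str
    text: str


def _check_variants(variants: Sequence[str]) -> tuple[str, ...]:
    unknown = set(variants) - set(CARG_VARIANTS)
    if unknown:
        raise ValueError(f"unknown CArG variants {sorted(unknown)}")
    return tuple(variants)


def scan_carg(
    sequence: str, variants: Sequence[str] = ("AT6", "AT5")
) -> list[CArGMatch]:
    """Return all (possibly overlapping) CArG-box matches, sorted by
    ``(position, variant)``."""
    variants = _check_variants(variants)
    seq = sequence.upper()
    matches: list[CArGMatch] = []
    for name in variants:
        for m in _COMPILED[name].finditer(seq):
            matches.append(CArGMatch(position=m.start(), variant=name, text=m.group(1)))
    matches.sort(key=lambda x: (x.position, x.variant))
    return matches


def filter_peaks_by_carg(
    peaks: Sequence[Peak],
    genome: Genome,
    variants: Sequence[str] = ("AT6", "AT5"),
) -> tuple[list[Peak], float]:
    """Keep peaks whose full interval sequence contains >= 1 CArG-box.

    Returns the passing peaks and the passing fraction (0.0 for no peaks).
    """
    variants = _check_variants(variants)
    passing = [
        p
        for p in peaks
        if scan_carg(
            genome.fetch(p.interval.chrom, p.interval.start, p.interval.end), variants
        )
    ]
    fraction = len(passing) / len(peaks) if peaks else 0.0
    return passing, fraction


def per_start_probability(variant: str) -> float:
    """P(a given admissible start matches ``variant``) under i.i.d. uniform bases."""
    _pat, length = CARG_VARIANTS[variant]
    n_fixed = 4  # CC...GG
    n_wobble = length - n_fixed  # A/T positions
    return (0.25**n_fixed) * (0.5**n_wobble)


def carg_background_rate(
    peak_lengths: Sequence[int],
    model: str = "analytic",
    variants: Sequence[str] = ("AT6", "AT5"),
    sequences: Sequence[str] | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """Expected fraction of peaks containing >= 1 CArG-box by chance.

    ``model="analytic"`` assumes i.i.d. uniform bases and treats the admissible
    start positions as independent, giving
    ``P(>=1) = 1 - prod_v (1 - p_v)^(L - len_v + 1)`` for a peak of length
    ``L`` — a documented approximation that is excellent for these rare,
    nearly non-overlapping motifs.  ``model="shuffle"`` mononucleotide-shuffles
    each provided peak sequence ``n_shuffles`` times and reports the empirical
    fraction with a match.
    """
    variants = _check_variants(variants)
    if model == "analytic":
        probs = []
        for length in peak_lengths:
            p_none = 1.0
            for name in variants:
                vlen = CARG_VARIANTS[name][1]
                n_starts = max(0, length - vlen + 1)
                p_none *= (1.0 - per_start_probability(name)) ** n_starts
            probs.append(1.0 - p_none)
        return float(np.mean(probs)) if probs else 0.0
    if model == "shuffle":
        if sequences is None:
            raise ValueError("shuffle model requires the peak sequences")
        rng = np.random.default_rng(seed)
        hits = 0
        total = 0
        for seq in sequences:
            letters = np.frombuffer(seq.upper().encode(), dtype="S1")
            for _ in range(n_shuffles):
                shuffled = letters[rng.permutation(len(letters))].tobytes().decode()
                total += 1
                if scan_carg(shuffled, variants):
                    hits += 1
        return hits / total if total else 0.0
    raise ValueError(f"unknown background model {model!r}")


def write_matches_bed(
    matches_by_peak: Iterable[tuple[Peak, Sequence[CArGMatch]]], path
) -> None:
    """Write CArG matches in genome coordinates as BED6 (name = variant)."""
    with open(path, "w") as fh:
        for peak, matches in matches_by_peak:
            for m in matches:
                start = peak.interval.start + m.position
                end = start + CARG_VARIANTS[m.variant][1]
                fh.write(f"{peak.interval.chrom}\t{start}\t{end}\t{m.variant}\t0\t+\n")
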