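# Methods

This note documents the statistical procedures implemented in
`madstargets`, the assumptions behind them, the defaults and why they were
chosen, what the synthetic benchmark does and does not emulate, and the
numerical conventions that make every run reproducible.

## Coordinate conventions

All in-memory coordinates are 0-based half-open. GFF3 (1-based inclusive)
is converted at the I/O boundary; BED6/narrowPeak are native. A gene's TSS
is `start` on `+` and `end − 1` on `−`; the TES is the opposite end. Peaks
without a summit use the interval midpoint `⌊(start+end)/2⌋` wherever a
point position is needed.

## Consensus peak merging

Replicate peaks on the same chromosome overlapping by ≥ 1 bp form connected
components (for intervals this is the maximal run of mutually overlapping
intervals under a sorted sweep). A component supported by at least
`min_support` distinct replicates (default 2) yields one consensus peak:
the union interval, the mean member score, and the summit of the
highest-scoring member that has one (ties to the smaller peak id).
Touching-but-not-overlapping intervals do not merge. The procedure is
invariant to replicate-file order; this is a deliberately simple,
reproducible merging rule, exposed as configuration.

## Peak-to-gene assignment

A peak is assigned to **every** gene whose strand-oriented window
\[TSS − `upstream_bp`, TES + `downstream_bp`\] (defaults 3000/1000,
inclusive at both ends) contains the peak anchor. Distances are signed in
gene orientation (negative = upstream of the TSS). Among a peak's
assignments, `is_closest` marks the gene with minimum |distance to TSS|,
ties broken by the lexicographically smaller gene id — a deterministic rule
that makes profiles order-independent. Gene-level target sets use all
assignments by default (`closest_only` restricts to the closest gene);
both definitions are defensible and the choice is recorded in the outputs.

## Metagene profile and the random-interval null

Anchors of closest-gene assignments are mapped to a normalized coordinate:
the upstream flank in `n_upstream` fixed-width bins (bin 0 farthest from
the TSS), the gene body linearly rescaled to `n_body` bins, the downstream
flank in `n_downstream` fixed-width bins (defaults 30/50/10, proportional
to the region sizes). The null model draws `n_sets` (default 1000) random
peak sets preserving the observed number and lengths of peaks; each peak is
placed uniformly on a chromosome chosen with probability proportional to
its length, and each null set is assigned and binned identically to the
observed set. Per-bin bounds are the empirical 2.5th/97.5th percentiles
across null sets. The null ignores overlap between random peaks and does
not mask assembly gaps; with ~200 integer counts per set the empirical
percentile band slightly over-covers (exact simulation of the procedure
puts expected coverage near 0.96 rather than 0.95) — an inherent property
of percentile bands on discrete counts, not an implementation artifact.
The null is vectorized and exactly reproduces the scalar assignment path
(asserted by test).

## CArG-box scanning

Two exact patterns are scanned: AT6 = `CC[AT]{6}GG` (10 bp) and AT5 =
`CC[AT]{5}GG` (9 bp). Overlapping matches are all reported; `N` never
matches. The pattern set is closed under reverse complement, so a
single-strand scan counts double-strand occurrences (positions map by
x → L − x − len); this avoids double counting and is asserted by a property
test. A peak passes the filter iff its **full interval sequence** contains
at least one match. The expected chance rate under i.i.d. uniform bases
treats admissible start positions as independent:

P(≥ 1 match in L) = 1 − Π<sub>v</sub> (1 − p<sub>v</sub>)^(L − len<sub>v</sub> + 1),
 p<sub>AT6</sub> = (1/4)⁴(1/2)⁶, p<sub>AT5</sub> = (1/4)⁴(1/2)⁵.

For L = 1000 this gives ≈ 0.166 and agrees with Monte-Carlo simulation to
well within binomial noise; the clumping correction neglected by the
independence approximation is negligible for motifs this rare. A
mononucleotide-shuffle estimator is provided for non-uniform base
composition. Mismatch-tolerant or extended CArG dialects are not scanned by
default; the variant set is a configuration hook.

## DEG thresholding and the dormancy core

A gene is differentially expressed when adj. P ≤ α (non-strict, default
0.05) and, where a fold-change threshold applies, |log₂FC| strictly exceeds
it (default 1.75 for the two dormancy datasets; the inducible assays use
the α rule alone). Records with missing adj. P are dropped from the call
but stay in the tested universe; the drop count is logged. The dormancy
core is the intersection of the two datasets' DEG sets; overlap
significance is the hypergeometric upper tail conditioned on the shared
tested universe — conditioning on tested genes (rather than all annotated
genes) is the conservative choice when the analysis universe is not
otherwise specified.

## Overlap statistics

All set-overlap tests reduce to P(X ≥ k) for X hypergeometric with
universe N, margins K and n. `fisher_overlap` computes it as a one-sided
Fisher exact test on the 2×2 table and `hypergeom_overlap` as the
hypergeometric survival function — two independent code paths that agree to
< 10⁻¹² with an exact enumeration oracle for every (N ≤ 25, K, n, k). The
universe for binding/expression overlaps is the paired assay's tested gene
set; for dormancy enrichment it is the genes tested in both dormancy
datasets. Per-complex tests are reported without multiple-testing
correction (four planned, individually reported comparisons); GO reports
carry a Benjamini–Hochberg column alongside raw p-values but the
significance rules below always use raw p.

## High-confidence targets

HC(c) = bound(c) ∩ DEG(assay(c)), where bound(c) is the set of genes with
≥ 1 CArG-passing consensus peak of complex c assigned, and assay(c) is the
complex's paired inducible-expression table. Regulation direction
(up/down) is carried from the DEG records. Membership-pattern counts over
the four bound sets (Venn cells), the fraction of targets in ≥ 2 sets and
the all-complex count are derived exactly by per-gene tabulation.

## Trajectory clustering

Rows are standardized to mean 0 / population SD 1; constant rows are
mapped to zeros, flagged, and excluded from clustering (they carry no shape
information). Clustering is hierarchical agglomerative with distance
1 − Pearson correlation and average linkage — fully deterministic given the
input, with no initialization randomness. k is selected by maximizing the
mean silhouette (precomputed-distance form) over a configured range
(default 2–10), ties to the smaller k; k can instead be pinned to mirror a
known cluster count. Cluster labels are renumbered 1..k by first
appearance so output is stable under row permutation (up to relabeling,
which the tests check via the adjusted Rand index). Cluster mean profiles
are arithmetic means of member z-scores.

## Directional GO enrichment

Annotation is a flat gene → term mapping; ontology-graph propagation is
deliberately not performed (flat testing of the provided table is the
reproducible baseline; propagate beforehand if ancestor closure is
wanted). Per row (complex or cluster) and term, the up- and downregulated
subsets are tested separately by hypergeometric upper tail; the best
(smallest) p is kept and transformed to −log₁₀ p, signed positive for the
up set and negative for the down set, with up/down ties resolved positive
(logged). Cells with best p > 0.05 are set to zero — so no cell magnitude
can lie strictly between 0 and −log₁₀ 0.05, and a value at exactly
p = 0.05 is kept. Cluster GO reports retain a cluster only if it has at
least one term with p strictly < 0.05; omitted clusters are logged.

## Synthetic benchmark

The generator's defaults define the benchmark conditions:

| parameter | default | meaning |
| --- | --- | --- |
| genome | 2 chromosomes × 1.5 Mb, i.i.d. uniform A/C/G/T | closed-form background motif rate |
| genes | 400, lengths 1500–3000 bp, spacing ≥ 4500 bp | non-overlapping annotation |
| complexes | 4 (three heteromers + one homomer analogue) | per-complex peak sets |
| true targets | 50 per complex, drawn independently | planted CArG + true peak each |
| background peaks | 200 per complex | placed uniformly, no planted box |
| replicates | 3; miss rate 0.05; summit jitter SD 20 bp | replicate variability |
| peak length | Normal(300, 50) truncated ≥ 50 bp | realistic peak sizes |
| promoter bias | 0.7 toward \[TSS − 1000, TSS + 200\] | TSS-proximal binding signal |
| DEG effect | 0.9 (inducible), background rate 0.05 | planted adj. P ∈ (0, 0.01), \|log₂FC\| ∈ (2, 4) |
| dormancy DEGs | effect 0.5, detected per dataset at 0.85 | datasets A/B share one truth |
| time course | 8 timepoints, 4 prototype shapes, noise SD 0.4 | endodormancy-peaking, ecodormancy-peaking, declining, budbreak-induced |
| GO | 40 terms, blocks of 5 aligned with clusters | within-block rate 0.6, background 0.05 |

Planting **overwrites** bases (never inserts), so coordinates stay valid;
planted sites never overlap each other, and scanning each planted site
recovers exactly the planted variant. The homomer analogue's targets are
excluded from the dormancy datasets, and an extra null inducible assay with
no planted effect is generated, so the pipeline's negative control
(no enrichment, Fisher p > 0.05) is testable. All randomness comes from
one seeded generator per stage (`default_rng([seed, stage])`); outputs are
byte-identical across runs with the same seed.

What the benchmark does **not** emulate: linked peak co-occurrence between
complexes (target sets are drawn independently, so between-complex sharing
is near-chance, unlike real paralogous complexes), read-level noise and
peak-calling artifacts, non-uniform genomic base composition,
isoform-resolved annotation, and correlated (non-i.i.d.) expression noise.
Passing the recovery tests therefore shows the inference machinery is
correct under the stated noise model, not that real data of any particular
depth would yield the same rates.

## Numerical choices and degenerate inputs

- z-scores use the population SD; constant rows → zeros + flag.
- Silhouette selection requires ≥ 2 non-constant rows and skips k values
  that collapse to one cluster; pinned k > n rows is an error.
- Empty peak input to merging warns and returns empty; a peak longer than
  every chromosome is an error for the null; peaks on chromosomes absent
  from the namespace abort with the offending ids.
- Hypergeometric p-values are clamped into (0, 1]; enrichment results
  validate 0 ≤ k ≤ min(K, n) ≤ N.
- All TSV outputs are written with fixed column orders, and the pipeline's
  per-stage JSON summaries contain no timing or hardware-dependent values,
  so reruns are byte-identical.

## Problem sizes

The shipped tests run the full pipeline at the default benchmark scale
(3 Mb genome, 4 × 250 peaks × 3 replicates), the null calibration at
200 peaks × 1000 null sets × 50 repetitions on a 2 × 1 Mb two-chromosome
fixture tiled by 280 identical genes (seven equal 1-kb bins per window, so
per-bin expected counts ~28 keep the discrete percentile band close to its
nominal level), and exact-test validation over the complete (N ≤ 25)
grid of 23,750 margin combinations. These sizes keep the whole suite under
a minute while leaving every statistical check well-powered.
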