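# madstargets

Target-gene analysis for MADS-box transcription-factor complexes.

MIKC-type MADS transcription factors (the DAM/SVP/FLC family that controls
bud dormancy in temperate fruit trees, among many other programs) act as
multimeric complexes that bind CArG-box elements — canonically
CC(A/T)<sub>6</sub>GG, with a shortened CC(A/T)<sub>5</sub>GG variant — in
the promoters of their target genes.  Genome-wide in-vitro binding assays
(DAP-seq-style peak sets per complex) say *where* a complex can bind;
inducible-expression experiments (e.g. a glucocorticoid-receptor fusion
activated by dexamethasone) say *which* genes respond transcriptionally.
`madstargets` implements the full evidence-integration pipeline that joins
the two, for analysts working with replicate peak files, DEG tables and
expression time courses:

1. **Consensus peaks** — replicate peak sets are merged (≥ 1 bp overlap,
   configurable replicate support) into consensus intervals.
2. **Peak-to-gene assignment** — a peak is assigned to every gene whose
   window \[TSS − 3 kb, TES + 1 kb\] (strand-oriented) contains the peak
   anchor (summit, else midpoint).
3. **Metagene profile with a positional null** — anchor positions are
   binned over a normalized gene coordinate and compared with the empirical
   95% band from 1000 random peak sets that preserve peak number and
   lengths.
4. **CArG-box filter** — peaks whose sequence lacks any CArG-box are
   discarded; the expected chance rate is available analytically
   (P(match per start) = (1/4)⁴(1/2)ᵏ for a k-base A/T core) or by
   mononucleotide shuffling.
5. **High-confidence targets** — per complex, bound genes are intersected
   with the DEGs (adj. *P* ≤ 0.05) of the paired inducible assay; overlap
   significance is a one-sided Fisher exact test, equal to the
   hypergeometric upper tail P(X ≥ k).
6. **Dormancy-core integration** — DEGs called in two independent dormancy
   datasets (adj. *P* ≤ 0.05 and |log₂FC| > 1.75) are intersected, and each
   complex's targets are tested for enrichment in that core
   (hypergeometric).
7. **Trajectory clustering** — target expression time courses are row
   z-scored and clustered (average-linkage hierarchical clustering on
   1 − Pearson correlation, silhouette-selected k).
8. **Directional GO enrichment** — per gene set and term, up- and
   downregulated subsets are tested separately; the best p is reported as
   signed −log₁₀ p (positive = up, negative = down, zero when p > 0.05).

A first-class synthetic-data module generates genomes, gene models, planted
CArG sites, replicate peak sets, DEG tables, expression courses and
block-structured GO annotations with known ground truth, so every stage is
testable without any download.

## Worked example

Generate a synthetic benchmark (four complexes, 50 planted targets each,
200 background peaks, 3 replicates) and run the whole pipeline:

```sh
madstargets simulate --seed 7 --out demo --null-sets 200
madstargets all --config demo/pipeline_config.yaml
```

Selected numbers from `demo/results/summary.json` for seed 7:

```
scan  DAM1-SVPa : 62 of 239 consensus peaks carry a CArG-box (26%)
high-confidence : DAM1-SVPa 48, DAM4-SVPa 47, FLC-SVPa 48, SVPa-SVPa 49
Fisher overlap  : DAM1-SVPa p = 4.9e-30
dormancy core   : 53 genes in the intersection of datasets A and B
clustering      : k = 4 over 159 high-confidence genes (silhouette 0.80)
```

Reading these: each complex's planted 50 targets are recovered almost
completely as high-confidence targets (bound + differentially expressed);
the binding/expression overlap is overwhelmingly non-random (p ≈ 10⁻³⁰,
versus p > 0.05 for the deliberately non-enriched control assay); ~26% of
consensus peaks carry a CArG-box because the benchmark deliberately mixes
50 true peaks with 200 random background peaks per complex (background
peaks of ~300 bp contain a box ~5% of the time by chance); and silhouette
selection recovers exactly the 4 planted trajectory shapes.

Every stage is also available as a library function
(`madstargets.merge_replicates`, `assign_peaks`, `filter_peaks_by_carg`,
`random_peak_null`, `filter_degs`, `high_confidence_targets`,
`cluster_trajectories`, `directional_signed_matrix`, ...) and as an
individual subcommand (`merge`, `assign`, `scan-stage`, `profile`,
`integrate`, `cluster`, `go`) driven by the same YAML config.

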