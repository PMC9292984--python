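import numpy as np
import pytest

from madstargets import (
    AssignmentWindow,
    BinScheme,
    GeneModel,
    Genome,
    GenomicInterval,
    Peak,
    assign_peaks,
    merge_replicates,
    metagene_profile,
    random_peak_null,
)
from madstargets.peak_processing import _closest_bins_vectorized, _metagene_bin


def mk_peak(chrom, start, end, peak_id="p", summit=None, score=1.0, rep=None):
    return Peak(
        GenomicInterval(chrom, start, end),
        peak_id=peak_id,
        score=score,
        summit_offset=summit,
        replicate_id=rep,
    )


class TestMerge:
    def test_identical_peak_in_all_replicates(self):
        reps = [[mk_peak("c1", 100, 200, f"p{r}")] for r in range(3)]
        (consensus,) = merge_replicates(reps, min_support=2)
        assert (consensus.interval.start, consensus.interval.end) == (100, 200)

    def test_single_replicate_support_excluded(self):
        reps = [[mk_peak("c1", 100, 200, "p0")], [], []]
        assert merge_replicates(reps, min_support=2) == []

    def test_union_interval(self):
        reps = [[mk_peak("c1", 100, 200, "a")], [mk_peak("c1", 150, 250, "b")]]
        (consensus,) = merge_replicates(reps, min_support=2)
        assert (consensus.interval.start, consensus.interval.end) == (100, 250)

    def test_touching_intervals_do_not_merge(self):
        # [100,200) and [200,300) share no base
        reps = [[mk_peak("c1", 100, 200, "a")], [mk_peak("c1", 200, 300, "b")]]
        assert merge_replicates(reps, min_support=2) == []

    def test_order_independence_and_union_contains_members(self):
        rng = np.random.default_rng(0)
        reps = []
        for r in range(3):
            peaks = []
            for i in range(40):
                start = int(rng.integers(0, 5000))
                peaks.append(
                    mk_peak(
                        "c1", start, start + int(rng.integers(50, 300)),
                        f"r{r}p{i}", summit=10, score=float(rng.uniform(1, 9)),
                    )
                )
            reps.append(peaks)
        forward = merge_replicates(reps, min_support=2)
        backward = merge_replicates(list(reversed(reps)), min_support=2)
        assert forward == backward
        # every consensus interval contains every member overlapping it
        for c in forward:
            members = [
                p
                for rep in reps
                for p in rep
                if p.interval.start < c.interval.end
                and c.interval.start < p.interval.end
            ]
            assert members
            assert c.interval.start == min(p.interval.start for p in members)
            assert c.interval.end == max(p.interval.end for p in members)

    def test_consensus_score_and_summit(self):
        reps = [
            [mk_peak("c1", 100, 200, "a", summit=10, score=2.0)],
            [mk_peak("c1", 150, 250, "b", summit=80, score=6.0)],
        ]
        (c,) = merge_replicates(reps, min_support=2)
        assert c.score == pytest.approx(4.0)
        # summit from the higher-scoring member "b": 150 + 80 - 100
        assert c.summit_offset == 130

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            assert merge_replicates([[]], min_support=1) == []


WINDOW = AssignmentWindow(3000, 1000)


class TestAssign:
    gene = GeneModel("g1", GenomicInterval("c1", 5000, 8001, "+"))  # TSS 5000 TES 8000

    def _assign(self, anchor):
        peak = mk_peak("c1", anchor - 5, anchor + 5, "p1", summit=5)
        return assign_peaks([peak], [self.gene], WINDOW)

    def test_upstream_anchor_assigned_with_negative_distance(self):
        (a,) = self._assign(2500)
        assert a.gene_id == "g1" and a.distance_to_tss == -2500 and a.is_closest

    def test_anchor_beyond_downstream_bound_excluded(self):
        assert self._assign(9500) == []

    def test_downstream_boundary_inclusive(self):
        (a,) = self._assign(9000)
        assert a.distance_to_tss == 4000

    def test_minus_strand_orientation(self):
        gene = GeneModel("g2", GenomicInterval("c1", 5000, 8001, "-"))  # TSS 8000
        peak = mk_peak("c1", 9495, 9505, "p", summit=5)  # 1500 bp upstream
        (a,) = assign_peaks([peak], [gene], WINDOW)
        assert a.distance_to_tss == -1500

    def test_near_tie_resolved_by_distance(self):
        g_a = GeneModel("ga", GenomicInterval("c1", 1000, 2000, "+"))  # TSS 1000
        g_b = GeneModel("gb", GenomicInterval("c1", 3000, 4000, "-"))  # TSS 3999
        peak = mk_peak("c1", 2494, 2504, "p", summit=5)  # anchor 2499
        hits = assign_peaks([peak], [g_a, g_b], WINDOW)
        info = {a.gene_id: (a.distance_to_tss, a.is_closest) for a in hits}
        # downstream of both genes in their orientation: both distances positive
        assert info == {"ga": (1499, True), "gb": (1500, False)}

    def test_exact_tie_prefers_lexicographically_smaller(self):
        g_a = GeneModel("gb", GenomicInterval("c1", 1000, 2000, "+"))  # TSS 1000
        g_b = GeneModel("ga", GenomicInterval("c1", 3000, 4001, "-"))  # TSS 4000
        peak = mk_peak("c1", 2495, 2505, "p", summit=5)  # anchor 2500: |1500| both
        hits = assign_peaks([peak], [g_a, g_b], WINDOW)
        closest = {a.gene_id: a.is_closest for a in hits}
        assert closest == {"ga": True, "gb": False}

    def test_unknown_chromosome_error_lists_peaks(self):
        peak = mk_peak("cX", 10, 20, "lost")
        with pytest.raises(ValueError, match="lost"):
            assign_peaks([peak], [self.gene], WINDOW)

    def test_multi_gene_assignment(self):
        g_a = GeneModel("ga", GenomicInterval("c1", 1000, 2000, "+"))
        g_b = GeneModel("gb", GenomicInterval("c1", 2500, 3500, "+"))
        peak = mk_peak("c1", 2195, 2205, "p", summit=5)  # in both windows
        hits = assign_peaks([peak], [g_a, g_b], WINDOW)
        assert {a.gene_id for a in hits} == {"ga", "gb"}
        assert sum(a.is_closest for a in hits) == 1


SCHEME = BinScheme(30, 50, 10)


class TestMetageneBins:
    gene = GeneModel("g1", GenomicInterval("c1", 5000, 8000, "+"))

    def test_upstream_binning(self):
        # 1500 bp upstream with 30 bins of 100 bp -> bin 15 (0 = farthest)
        assert _metagene_bin(self.gene, 3500, WINDOW, SCHEME) == 15

    def test_anchor_at_tss_first_body_bin(self):
        assert _metagene_bin(self.gene, 5000, WINDOW, SCHEME) == 30

    def test_body_midpoint(self):
        # body fraction 0.5 of a 3000 bp gene with 50 body bins -> bin 25
        assert _metagene_bin(self.gene, 6500, WINDOW, SCHEME) == 30 + 25

    def test_downstream_binning(self):
        assert _metagene_bin(self.gene, 8000, WINDOW, SCHEME) == 80  # u=1 -> first
        assert _metagene_bin(self.gene, 8999, WINDOW, SCHEME) == 89  # u=1000 -> last

    def test_out_of_window_raises(self):
        with pytest.raises(ValueError):
            _metagene_bin(self.gene, 500, WINDOW, SCHEME)

    def test_profile_counts_sum_to_closest_assignments(self):
        genes = [self.gene]
        peaks = [mk_peak("c1", 4000 + 100 * i, 4060 + 100 * i, f"p{i}", summit=30)
                 for i in range(20)]
        assignments = assign_peaks(peaks, genes, WINDOW)
        profile = metagene_profile(assignments, genes, WINDOW, SCHEME)
        n_closest = sum(a.is_closest for a in assignments)
        assert profile.observed.sum() == n_closest


def random_instance(seed, n_genes=30, n_peaks=120, clen=200_000):
    rng = np.random.default_rng(seed)
    genes = []
    cursor = 500
    for i in range(n_genes):
        length = int(rng.integers(800, 2500))
        strand = "+" if rng.integers(2) == 0 else "-"
        genes.append(
            GeneModel(f"g{i:03d}", GenomicInterval("c1", cursor, cursor + length, strand))
        )
        cursor += length + int(rng.integers(300, 2000))
    peaks = []
    for i in range(n_peaks):
        start = int(rng.integers(0, clen - 400))
        length = int(rng.integers(100, 400))
        peaks.append(mk_peak("c1", start, start + length, f"p{i:03d}",
                             summit=int(rng.integers(0, length))))
    return genes, peaks, clen


class TestVectorizedEquivalence:
    def test_vectorized_bins_match_scalar_path(self):
        genes, peaks, _ = random_instance(2)
        assignments = assign_peaks(peaks, genes, WINDOW)
        profile = metagene_profile(assignments, genes, WINDOW, SCHEME)
        anchors = np.array([p.anchor for p in peaks], dtype=np.int64)
        codes = np.zeros(len(peaks), dtype=np.int64)
        bins = _closest_bins_vectorized(
            codes, anchors, genes, {"c1": 0}, WINDOW, SCHEME
        )
        counts = np.bincount(bins[bins >= 0], minlength=SCHEME.n_bins)
        assert (counts == profile.observed).all()


class TestRandomNull:
    def _tiny_genome(self, clen=20_000):
        return Genome({"c1": "A" * clen})

    def test_whole_chromosome_peak_forces_null_equal_observed(self):
        # the only possible placement of a chromosome-length peak is start 0,
        # so every null set equals the observed set and the CI collapses
        clen = 12_000
        genome = self._tiny_genome(clen)
        genes = [GeneModel("g1", GenomicInterval("c1", 4000, 9000, "+"))]
        peaks = [mk_peak("c1", 0, clen, "p0")]  # midpoint anchor 6000 in body
        profile = random_peak_null(
            peaks, genes, genome, n_sets=5, seed=0,
            window=WINDOW, scheme=SCHEME,
        )
        assert (profile.lower == profile.observed).all()
        assert (profile.upper == profile.observed).all()
        assert (profile.null_mean == profile.observed).all()

    def test_peak_longer_than_every_chromosome_raises(self):
        genome = self._tiny_genome(1000)
        genes = [GeneModel("g1", GenomicInterval("c1", 100, 400, "+"))]
        with pytest.raises(ValueError, match="longer than every chromosome"):
            random_peak_null([mk_peak("c1", 0, 1000, "p")], genes,
                             Genome({"c1": "A" * 500}), n_sets=2, seed=0)

    def test_null_is_deterministic_given_seed(self):
        genes, peaks, clen = random_instance(4)
        genome = Genome({"c1": "A" * clen})
        a = random_peak_null(peaks, genes, genome, n_sets=20, seed=9)
        b = random_peak_null(peaks, genes, genome, n_sets=20, seed=9)
        assert (a.lower == b.lower).all() and (a.upper == b.upper).all()
        assert (a.null_mean == b.null_mean).all()


def mirror_instance(genes, peaks, clen):
    """Reverse-complement mirror: x -> clen - x, strands flipped."""
    m_genes = [
        GeneModel(
            g.gene_id,
            GenomicInterval(
                "c1",
                clen - g.interval.end,
                clen - g.interval.start,
                "-" if g.interval.strand == "+" else "+",
            ),
        )
        for g in genes
    ]
    m_peaks = [
        Peak(
            GenomicInterval("c1", clen - p.interval.end, clen - p.interval.start),
            peak_id=p.peak_id,
            score=p.score,
            summit_offset=(len(p.interval) - 1 - p.summit_offset),
        )
        for p in peaks
    ]
    return m_genes, m_peaks


class TestStrandSymmetry:
    def test_assignment_and_profile_invariant_under_mirroring(self):
        genes, peaks, clen = random_instance(6)
        m_genes, m_peaks = mirror_instance(genes, peaks, clen)
        fwd = assign_peaks(peaks, genes, WINDOW)
        rev = assign_peaks(m_peaks, m_genes, WINDOW)
        key = lambda a: (a.peak_id, a.gene_id, a.distance_to_tss, a.is_closest)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))
        p_fwd = metagene_profile(fwd, genes, WINDOW, SCHEME)
        p_rev = metagene_profile(rev, m_genes, WINDOW, SCHEME)
        assert (p_fwd.observed == p_rev.observed).all()
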