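import numpy as np
import pytest

from madstargets import (
    DEGSet,
    EnrichmentResult,
    bound_gene_sets,
    enrichment_in_dormancy_degs,
    fisher_overlap,
    high_confidence_targets,
    hypergeom_overlap,
    set_partition_counts,
)
from madstargets.peak_processing import PeakGeneAssignment

from oracles import hypergeom_upper_tail_exact


def universe(n):
    return {f"g{i:02d}" for i in range(n)}


class TestOverlapTests:
    def test_zero_overlap_gives_p_one(self):
        u = universe(20)
        r = fisher_overlap({"g00"}, {"g01"}, u)
        assert r.k == 0 and r.p_value == 1.0

    def test_full_margin_gives_p_one(self):
        u = universe(10)
        r = fisher_overlap(u, {"g00", "g01"}, u)  # K = N
        assert r.p_value == pytest.approx(1.0)

    def test_exact_value_against_enumeration(self):
        u = sorted(universe(20))
        s1, s2 = set(u[:5]), set(u[1:5])
        expected = float(hypergeom_upper_tail_exact(4, 5, 4, 20))
        assert expected == pytest.approx(5 / 4845)
        assert fisher_overlap(s1, s2, set(u)).p_value == pytest.approx(
            expected, abs=1e-12
        )
        assert hypergeom_overlap(s1, s2, set(u)).p_value == pytest.approx(
            expected, abs=1e-12
        )

    def test_fisher_equals_hypergeometric_tail(self):
        rng = np.random.default_rng(1)
        u = sorted(universe(40))
        for _ in range(25):
            s1 = set(rng.choice(u, size=rng.integers(1, 20), replace=False))
            s2 = set(rng.choice(u, size=rng.integers(1, 20), replace=False))
            f = fisher_overlap(s1, s2, set(u))
            h = hypergeom_overlap(s1, s2, set(u))
            assert f.p_value == pytest.approx(h.p_value, rel=1e-9)

    def test_p_monotone_decreasing_in_k(self):
        N, K, n = 30, 10, 8
        ps = [float(hypergeom_upper_tail_exact(k, K, n, N)) for k in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        # and the implementation follows the oracle at every k
        u = sorted(universe(N))
        for k in range(0, n + 1):
            s1 = set(u[:K])
            s2 = set(u[:k]) | set(u[K : K + n - k])
            got = hypergeom_overlap(s1, s2, set(u)).p_value
            assert got == pytest.approx(ps[k] if k < len(ps) else None, abs=1e-12)

    def test_containment_violation_is_error(self):
        with pytest.raises(ValueError, match="contained"):
            fisher_overlap({"zz"}, {"g01"}, universe(5))

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            EnrichmentResult(k=5, K=3, n=4, N=10, p_value=0.5, test="x")


class TestSetPartition:
    def test_two_set_enumeration(self):
        counts = set_partition_counts({"s1": {"a", "b"}, "s2": {"b", "c"}})
        assert counts.counts == {
            frozenset({"s1"}): 1,
            frozenset({"s2"}): 1,
            frozenset({"s1", "s2"}): 1,
        }
        assert counts.fraction_in_at_least_two == pytest.approx(1 / 3)

    def test_identical_sets_all_in_full_cell(self):
        s = {"a", "b", "c"}
        counts = set_partition_counts({"x": s, "y": s, "z": s})
        assert counts.counts == {frozenset({"x", "y", "z"}): 3}
        assert counts.n_in_all == 3

    def test_matches_brute_force_membership_tabulation(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        sets = {
            f"c{j}": set(rng.choice(genes, size=60, replace=False))
            for j in range(4)
        }
        counts = set_partition_counts(sets)
        # brute force: per-gene membership pattern
        brute: dict[frozenset, int] = {}
        for g in genes:
            pat = frozenset(l for l, s in sets.items() if g in s)
            if pat:
                brute[pat] = brute.get(pat, 0) + 1
        assert counts.counts == brute
        assert counts.n_union == len(set().union(*sets.values()))

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            set_partition_counts({"only": {"a"}})


def assignment(peak_id, gene_id, closest=True):
    return PeakGeneAssignment(peak_id, gene_id, 0, 0, closest)


class TestBoundSets:
    def test_carg_filter_gates_membership(self):
        assignments = {
            "c1": [assignment("p1", "g1"), assignment("p2", "g2"),
                   assignment("p3", "g1")]
        }
        bound = bound_gene_sets(assignments, {"c1": {"p1", "p3"}})
        assert bound == {"c1": {"g1"}}  # g2's peak failed the filter; g1 once

    def test_closest_only_mode(self):
        assignments = {
            "c1": [assignment("p1", "g1", closest=False), assignment("p1", "g2")]
        }
        assert bound_gene_sets(assignments, {"c1": {"p1"}}) == {"c1": {"g1", "g2"}}
        assert bound_gene_sets(
            assignments, {"c1": {"p1"}}, closest_only=True
        ) == {"c1": {"g2"}}


def degset(label, ids, up, universe_ids):
    ids = set(ids)
    return DEGSet(
        label=label,
        deg_ids=ids,
        up_ids=set(up),
        down_ids=ids - set(up),
        universe=set(universe_ids),
        alpha=0.05,
        lfc_threshold=None,
    )


class TestHighConfidence:
    def test_intersection_and_directions(self):
        bound = {"c1": {"g1", "g2"}}
        degs = {"a1": degset("a1", {"g2", "g3"}, {"g2"},
                             {f"g{i}" for i in range(10)})}
        hc, tests, directions = high_confidence_targets(bound, degs, {"c1": "a1"})
        assert hc == {"c1": {"g2"}}
        assert directions == {"c1": {"g2": "up"}}
        assert tests["c1"].k == 1

    def test_disjoint_gives_empty(self):
        bound = {"c1": {"g1"}}
        degs = {"a1": degset("a1", {"g2"}, {"g2"},
                             {f"g{i}" for i in range(10)})}
        hc, _, _ = high_confidence_targets(bound, degs, {"c1": "a1"})
        assert hc == {"c1": set()}

    def test_unpaired_complex_is_error(self):
        with pytest.raises(ValueError, match="without a paired"):
            high_confidence_targets({"c1": set()}, {}, {})


class TestDormancyEnrichment:
    def test_complete_containment_gives_minimal_p(self):
        u = universe(20)
        hc = {"c1": {"g00", "g01", "g02"}}
        core = {"g00", "g01", "g02", "g03"}
        (r,) = enrichment_in_dormancy_degs(hc, core, u).values()
        minimal = float(hypergeom_upper_tail_exact(3, 3, 4, 20))
        assert r.p_value == pytest.approx(minimal, abs=1e-12)

    def test_overlap_at_expectation_is_unremarkable(self):
        # N=20, K=10, n=10, k=5 = nK/N -> p near 0.5, matching enumeration
        u = sorted(universe(20))
        hc = {"c1": set(u[:10])}
        core = set(u[5:15])
        (r,) = enrichment_in_dormancy_degs(hc, core, set(u)).values()
        oracle = float(hypergeom_upper_tail_exact(5, 10, 10, 20))
        assert r.p_value == pytest.approx(oracle, abs=1e-12)
        assert 0.3 < r.p_value < 0.8

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="empty universe"):
            enrichment_in_dormancy_degs({"c1": set()}, set(), set())
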