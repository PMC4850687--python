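import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nipiscreen.enrichment import (
    bicluster,
    complex_coverage,
    correlation_distance_matrix,
    enrich_all,
    foundlings,
    hypergeom_upper,
    membership_matrix,
)
from nipiscreen.screen_io import AnnotationClass, ComplexRecord


def enumeration_upper_tail(k, K, n, N):
    """Oracle: enumerate every draw of n genes from N and count overlaps >= k."""
    hits = total = 0
    class_genes = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(class_genes.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomUpper:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper(0, 5, 4, 10) == 1.0

    def test_full_overlap_of_the_whole_universe(self):
        assert hypergeom_upper(4, 10, 4, 10) == pytest.approx(1.0)

    def test_worked_example_against_enumeration(self):
        # all C(10, 4) = 210 draws; 5 of them contain >= 4 of the 5 class genes
        assert enumeration_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210)
        assert hypergeom_upper(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)

    def test_agrees_with_exhaustive_enumeration_for_all_small_universes(self):
        for N in range(1, 13):
            for n in range(N + 1):
                draws = list(itertools.combinations(range(N), n))
                for K in range(N + 1):
                    class_genes = set(range(K))
                    counts = [len(class_genes.intersection(d)) for d in draws]
                    for k in range(min(K, n) + 1):
                        expected = sum(c >= k for c in counts) / len(draws)
                        assert math.isclose(
                            hypergeom_upper(k, K, n, N), expected, abs_tol=1e-10
                        ), (k, K, n, N)

    def test_monotone_nonincreasing_in_overlap(self):
        for K, n, N in [(5, 4, 10), (8, 6, 20), (3, 3, 7)]:
            ps = [hypergeom_upper(k, K, n, N) for k in range(min(K, n) + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_point_masses_sum_to_one(self):
        for K, n, N in [(5, 4, 10), (7, 7, 12), (2, 9, 11), (0, 4, 9)]:
            total = sum(
                hypergeom_upper(k, K, n, N)
                - (hypergeom_upper(k + 1, K, n, N) if k < min(K, n) else 0.0)
                for k in range(min(K, n) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_ease_mode_penalizes_by_one_overlap_gene(self):
        assert hypergeom_upper(3, 5, 4, 10, mode="ease") == pytest.approx(
            hypergeom_upper(2, 5, 4, 10, mode="fisher")
        )
        assert hypergeom_upper(0, 5, 4, 10, mode="ease") == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(5, 4, 10, 10)
        with pytest.raises(ValueError):
            hypergeom_upper(1, 11, 4, 10)


def _classes(spec):
    return [AnnotationClass(cid, cid, frozenset(genes))
            for cid, genes in spec.items()]


class TestEnrichAll:
    UNIVERSE = {f"g{i}" for i in range(40)}
    QUERY = {f"g{i}" for i in range(10)}

    def test_query_identical_class_is_most_significant(self):
        classes = _classes({
            "match": self.QUERY,
            "half": {f"g{i}" for i in range(5, 25)},
            "other": {f"g{i}" for i in range(20, 40)},
        })
        results = enrich_all(self.QUERY, classes, self.UNIVERSE)
        assert results[0].class_id == "match"

    def test_disjoint_class_has_p_one(self):
        classes = _classes({"off": {f"g{i}" for i in range(20, 30)}})
        (res,) = enrich_all(self.QUERY, classes, self.UNIVERSE)
        assert res.p_raw == pytest.approx(1.0)
        assert not res.significant

    def test_bonferroni_never_exceeds_one_and_counts_tested_classes(self):
        classes = _classes(
            {f"c{i}": {f"g{i}", f"g{i + 1}"} for i in range(30)}
        )
        results = enrich_all(self.QUERY, classes, self.UNIVERSE)
        assert all(r.p_corrected <= 1.0 for r in results)
        m = len(results)
        for r in results:
            assert r.p_corrected == pytest.approx(min(1.0, r.p_raw * m))

    def test_class_order_does_not_change_the_significant_set(self):
        classes = _classes({
            "a": self.QUERY, "b": {"g0", "g20"}, "c": {f"g{i}" for i in range(15, 40)},
        })
        fwd = enrich_all(self.QUERY, classes, self.UNIVERSE)
        rev = enrich_all(self.QUERY, classes[::-1], self.UNIVERSE)
        sig = {r.class_id for r in fwd if r.significant}
        assert sig == {r.class_id for r in rev if r.significant}

    def test_query_genes_outside_universe_dropped_with_warning(self):
        classes = _classes({"a": {"g1", "g2"}})
        with pytest.warns(UserWarning, match="outside the universe"):
            (res,) = enrich_all({"g1", "alien"}, classes, {"g1", "g2", "g3"})
        assert res.n == 1

    def test_planted_class_ranks_first_in_95_percent_of_replicates(self):
        rng = np.random.default_rng(2016)
        universe = [f"g{i}" for i in range(300)]
        wins = 0
        for _ in range(100):
            genes = list(universe)
            rng.shuffle(genes)
            planted = set(genes[:25])
            decoys = {
                f"decoy{j}": set(rng.choice(universe, size=25, replace=False))
                for j in range(15)
            }
            classes = _classes({"planted": planted, **decoys})
            query = set(rng.choice(sorted(planted), size=12, replace=False))
            query |= set(rng.choice(universe, size=8, replace=False))
            results = enrich_all(query, classes, set(universe))
            wins += results[0].class_id == "planted"
        assert wins >= 95


class TestFoundlings:
    def test_definition_instances(self):
        universe = {f"u{i}" for i in range(16)} | {"a", "b", "c", "d"}
        classes = _classes({"sig": {"a", "b"}, "weak": {"c"}})
        results = enrich_all({"a", "b", "c", "d"}, classes, universe, alpha=0.1)
        sig_ids = {r.class_id for r in results if r.significant}
        assert sig_ids == {"sig"}  # sanity: only the overlap-2 class is called
        found = foundlings({"a", "b", "c", "d"}, results, classes)
        # gene in no class at all, and gene only in non-significant classes,
        # are foundlings; members of a significant class are not
        assert found == {"c", "d"}


class TestBicluster:
    def test_identical_rows_merge_first_and_sit_adjacent(self):
        matrix = pd.DataFrame(
            [[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]],
            index=["r1", "r2", "r3"], columns=list("abcd"),
        )
        row_order, _, row_linkage, _ = bicluster(matrix)
        assert row_linkage[0, 2] == pytest.approx(0.0)  # first merge at d = 0
        assert abs(row_order.index("r1") - row_order.index("r2")) == 1

    def test_anticorrelated_rows_at_distance_two(self):
        data = np.array([[1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]])
        dist = correlation_distance_matrix(data)
        assert dist[0, 1] == pytest.approx(2.0)

    def test_constant_rows_sit_at_distance_one(self):
        data = np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 4.0]])
        assert correlation_distance_matrix(data)[0, 1] == pytest.approx(1.0)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(4)
        matrix = pd.DataFrame(rng.integers(0, 2, size=(12, 6)).astype(float))
        matrix.iloc[0, 0] += 0.5  # break ties deterministically
        first = bicluster(matrix)
        second = bicluster(matrix.copy())
        assert first[0] == second[0] and first[1] == second[1]

    def test_too_few_nonconstant_rows_rejected(self):
        matrix = pd.DataFrame([[1, 1, 1], [2, 2, 2], [0, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="non-constant"):
            bicluster(matrix)

    def test_membership_matrix_is_binary(self):
        classes = _classes({"a": {"g1"}, "b": {"g1", "g2"}})
        matrix = membership_matrix(["g1", "g2", "g3"], classes)
        assert set(np.unique(matrix.to_numpy())) <= {0, 1}
        assert matrix.loc["g1", "a"] == 1 and matrix.loc["g3", "b"] == 0


class TestComplexCoverage:
    CATALOG = [
        ComplexRecord("three_quarters", frozenset("abcd")),
        ComplexRecord("exactly_half", frozenset("abxy")),
        ComplexRecord("tiny", frozenset("ab")),
        ComplexRecord("full", frozenset("abc")),
        ComplexRecord("untouched", frozenset("xyz")),
    ]
    HITS = set("abc")

    def test_strictly_more_than_half_of_at_least_three_members(self):
        retained = complex_coverage(self.CATALOG, self.HITS)
        assert [r[0] for r in retained] == ["full", "three_quarters"]
        by_id = {r[0]: r for r in retained}
        assert by_id["three_quarters"][1:] == (3, 4, pytest.approx(0.75))

    def test_exactly_half_excluded_by_strict_inequality(self):
        ids = {r[0] for r in complex_coverage(self.CATALOG, self.HITS)}
        assert "exactly_half" not in ids

    def test_small_complexes_excluded_regardless_of_coverage(self):
        ids = {r[0] for r in complex_coverage(self.CATALOG, self.HITS)}
        assert "tiny" not in ids
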