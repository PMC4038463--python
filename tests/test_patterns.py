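import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from foldmech import patterns as pt
from foldmech.mapping import StructureStepMatrix, build_pa_matrix, cull_dataset

PATTERN_4 = frozenset({"Bimolecular nucleophilic substitution",
                       "Proton transfer"})
PATTERN_15 = frozenset({"Bimolecular nucleophilic addition",
                        "Proton transfer",
                        "Unimolecular elimination by the conjugate base"})


class TestExtractPatterns:
    def test_identical_repertoires_share_one_pattern(self, make_matrix):
        matrix = make_matrix({"A": PATTERN_4, "B": PATTERN_4})
        table = pt.extract_patterns(matrix)
        assert len(table) == 1
        assert table.patterns[0].members == frozenset({"A", "B"})

    def test_aldolase_repertoire_is_a_20_type_singleton(self, curated_matrix):
        table = pt.extract_patterns(curated_matrix)
        pattern = next(p for p in table if "3.20.20.70" in p.members)
        assert pattern.size == 20
        assert pattern.n_members == 1

    def test_all_distinct_rows_give_one_pattern_each(self, random_bool_matrix):
        matrix = random_bool_matrix(30, seed=0)
        distinct = {tuple(sorted(matrix.row_types(r))) for r in matrix.row_ids}
        assert len(pt.extract_patterns(matrix)) == len(distinct)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_patterns_partition_rows(self, random_bool_matrix, seed):
        matrix = random_bool_matrix(40, seed=seed)
        table = pt.extract_patterns(matrix)
        all_members = list(itertools.chain.from_iterable(
            p.members for p in table))
        assert sorted(all_members) == sorted(matrix.row_ids)
        assert len({p.key for p in table}) == len(table)


class TestPatternStats:
    def test_counts_and_histogram_conservation(self, curated_matrix):
        table = pt.extract_patterns(curated_matrix)
        stats = pt.pattern_stats(table)
        assert stats["n_rows"] == len(curated_matrix)
        assert stats["histogram"].sum() == len(curated_matrix)
        assert stats["n_singleton_patterns"] <= stats["n_patterns"]

    def test_two_member_pattern_is_not_singleton(self, make_matrix):
        matrix = make_matrix({"A": PATTERN_4, "B": PATTERN_4})
        stats = pt.pattern_stats(pt.extract_patterns(matrix))
        assert stats["n_patterns"] == 1
        assert stats["n_singleton_patterns"] == 0

    def test_named_query_counts_exact_repertoires(self, purine, vocabulary):
        entries, ages = purine
        culled, _ = cull_dataset(entries, ages)
        matrix = build_pa_matrix(culled, ages, vocabulary,
                                 granularity="enzyme-domain")
        table = pt.extract_patterns(matrix)
        # three pathway rows use exactly the two-type combination
        assert pt.member_count(table, PATTERN_4, vocabulary) == 3

    def test_query_with_unknown_name_rejected(self, make_matrix, vocabulary):
        table = pt.extract_patterns(make_matrix({"A": PATTERN_4}))
        with pytest.raises(ValueError, match="unknown"):
            pt.member_count(table, {"Dark matter catalysis"}, vocabulary)


class TestJaccard:
    def test_pathway_pattern_extension_halves_similarity(self, purine,
                                                         vocabulary):
        """Adding two step types to the two-type core yields J = 2/4."""
        entries, ages = purine
        culled, _ = cull_dataset(entries, ages)
        matrix = build_pa_matrix(culled, ages, vocabulary,
                                 granularity="enzyme-domain")
        sim = pt.jaccard_matrix(matrix)
        assert sim.table.loc["M0326|3.20.20.60", "M0234|3.40.50.880"] == \
            pytest.approx(0.5)

    def test_self_similarity_is_one(self, random_bool_matrix):
        matrix = random_bool_matrix(10, seed=3)
        sim = pt.jaccard_matrix(matrix)
        assert (np.diag(sim.table.to_numpy()) == 1.0).all()

    def test_disjoint_rows_score_zero(self, make_matrix):
        matrix = make_matrix({"A": {"Proton transfer"}, "B": {"Redox"}})
        assert pt.jaccard_matrix(matrix).table.loc["A", "B"] == 0.0

    def test_matches_brute_force_set_arithmetic(self, random_bool_matrix):
        matrix = random_bool_matrix(50, seed=7)
        sim = pt.jaccard_matrix(matrix)
        for a, b in itertools.combinations(matrix.row_ids[:20], 2):
            sa, sb = matrix.row_types(a), matrix.row_types(b)
            assert sim.table.loc[a, b] == pytest.approx(
                len(sa & sb) / len(sa | sb))

    def test_unit_similarity_iff_same_pattern(self, random_bool_matrix):
        matrix = random_bool_matrix(30, seed=8)
        sim = pt.jaccard_matrix(matrix)
        table = pt.extract_patterns(matrix)
        pattern_of = {m: p.key for p in table for m in p.members}
        for a, b in itertools.combinations(matrix.row_ids, 2):
            same = pattern_of[a] == pattern_of[b]
            assert (sim.table.loc[a, b] == 1.0) == same


class TestClusterOrder:
    def test_identical_structures_merge_first(self, make_matrix):
        matrix = make_matrix({"A": PATTERN_4, "B": PATTERN_4,
                              "C": {"Redox"}})
        _, merges = pt.cluster_order(pt.jaccard_matrix(matrix))
        assert set(merges[0].left + merges[0].right) == {"A", "B"}
        assert merges[0].distance == pytest.approx(0.0)

    def test_most_similar_pair_merges_first(self, make_matrix):
        matrix = make_matrix({
            "A": PATTERN_15,
            "B": PATTERN_15 | {"Redox"},
            "C": {"Claisen rearrangement", "Coordination"}})
        _, merges = pt.cluster_order(pt.jaccard_matrix(matrix))
        assert set(merges[0].left + merges[0].right) == {"A", "B"}

    def test_fewer_than_two_rows_identity(self, make_matrix):
        matrix = make_matrix({"A": PATTERN_4})
        order, merges = pt.cluster_order(pt.jaccard_matrix(matrix))
        assert order == ["A"] and merges == []

    def test_row_permutation_invariance(self, random_bool_matrix, vocabulary):
        matrix = random_bool_matrix(12, seed=4)
        perm = matrix.table.sample(frac=1.0, random_state=1)
        permuted = StructureStepMatrix(perm, matrix.nd.reindex(perm.index),
                                       vocabulary)
        o1, m1 = pt.cluster_order(pt.jaccard_matrix(matrix))
        o2, m2 = pt.cluster_order(pt.jaccard_matrix(permuted))
        assert o1 == o2
        assert m1 == m2

    def test_merge_heights_match_scipy_average_linkage(self):
        """With all pairwise distances distinct there are no ties, so the
        merge heights must agree with an independent implementation."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(0)
        n = 12
        d = rng.uniform(0.05, 0.95, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        assert len(np.unique(squareform(d, checks=False))) == n * (n - 1) // 2
        ids = [f"R{i:02d}" for i in range(n)]
        sim = pt.SimilarityMatrix(pd.DataFrame(1.0 - d, index=ids,
                                               columns=ids))
        _, merges = pt.cluster_order(sim)
        ours = sorted(m.distance for m in merges)
        scipy_heights = sorted(linkage(squareform(d, checks=False),
                                       method="average")[:, 2])
        assert np.allclose(ours, scipy_heights, atol=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=40), st.integers(0, 10_000))
def test_pattern_partition_property(n_rows, seed):
    """Any boolean matrix's patterns partition its rows (hypothesis)."""
    from foldmech.io import StepTypeVocabulary

    vocab = StepTypeVocabulary.default()
    rng = np.random.default_rng(seed)
    data = rng.random((n_rows, len(vocab))) < 0.1
    for i in range(n_rows):
        if not data[i].any():
            data[i, rng.integers(len(vocab))] = True
    ids = [f"R{i}" for i in range(n_rows)]
    matrix = StructureStepMatrix(
        pd.DataFrame(data, index=ids, columns=list(vocab.names)),
        pd.Series(rng.random(n_rows), index=ids), vocab)
    table = pt.extract_patterns(matrix)
    members = sorted(m for p in table for m in p.members)
    assert members == sorted(ids)
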