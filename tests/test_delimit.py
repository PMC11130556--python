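import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap import (
    DistanceMatrix,
    DistancePolicy,
    compare_partition,
    merge_heights,
    ranked_partitions,
    single_linkage_clusters,
)
from barcodegap.delimit import (
    CongruenceStatus,
    Partition,
    read_partition_tsv,
    write_partition_tsv,
)


def matrix_from(ids, dist):
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in dist.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    comp = np.full((n, n), 100, dtype=int)
    return DistanceMatrix(ids=list(ids), d=d, comparable=comp,
                          policy=DistancePolicy.STRICT)


def brute_force_components(m, t):
    """Oracle: exhaustive transitive closure of the d < t relation."""
    groups = [{i} for i in range(len(m.ids))]
    changed = True
    while changed:
        changed = False
        for g1, g2 in itertools.combinations(groups, 2):
            if any(m.d[i, j] < t for i in g1 for j in g2):
                groups.remove(g1)
                groups.remove(g2)
                groups.append(g1 | g2)
                changed = True
                break
    return {frozenset(m.ids[i] for i in g) for g in groups}


def as_sets(p: Partition):
    return {frozenset(members) for members in p.clusters().values()}


def test_all_singletons_when_every_distance_above_t():
    m = matrix_from("abc", {("a", "b"): 0.5, ("a", "c"): 0.6, ("b", "c"): 0.7})
    assert single_linkage_clusters(m, 0.03).k == 3


def test_chain_merges_transitively():
    m = matrix_from("abc", {("a", "b"): 0.02, ("b", "c"): 0.02, ("a", "c"): 0.04})
    p = single_linkage_clusters(m, 0.03)
    assert p.k == 1


def test_threshold_comparison_is_strict():
    m = matrix_from("ab", {("a", "b"): 0.03})
    assert single_linkage_clusters(m, 0.03).k == 2


def test_cluster_ids_contiguous_first_seen():
    m = matrix_from("abcd", {("a", "b"): 0.9, ("a", "c"): 0.01, ("a", "d"): 0.9,
                             ("b", "c"): 0.9, ("b", "d"): 0.9, ("c", "d"): 0.9})
    p = single_linkage_clusters(m, 0.03)
    assert p.assignment == {"a": 1, "b": 2, "c": 1, "d": 3}


def test_undefined_distances_rejected():
    m = matrix_from("ab", {})
    m.d[0, 1] = m.d[1, 0] = np.nan
    m.comparable[0, 1] = m.comparable[1, 0] = 0
    with pytest.raises(ValueError, match="undefined"):
        single_linkage_clusters(m, 0.03)


@settings(max_examples=60, derandomize=True)
@given(st.data())
def test_oracle_equivalence_random_matrices(data):
    n = data.draw(st.integers(min_value=2, max_value=12))
    ids = [f"r{i}" for i in range(n)]
    vals = data.draw(
        st.lists(
            st.floats(min_value=0.001, max_value=0.5, allow_nan=False),
            min_size=n * (n - 1) // 2,
            max_size=n * (n - 1) // 2,
        )
    )
    dist = dict(zip(itertools.combinations(ids, 2), vals))
    m = matrix_from(ids, dist)
    for h in merge_heights(m):
        t = np.nextafter(h, 1.0)
        assert as_sets(single_linkage_clusters(m, t)) == brute_force_components(m, t)


def test_merge_heights_examples():
    m2 = matrix_from("ab", {("a", "b"): 0.05})
    assert merge_heights(m2) == [0.05]
    m3 = matrix_from("abc", {("a", "b"): 0.01, ("b", "c"): 0.04, ("a", "c"): 0.05})
    assert merge_heights(m3) == pytest.approx([0.01, 0.04])


@settings(max_examples=40, derandomize=True)
@given(st.data())
def test_partitions_refine_monotonically(data):
    n = data.draw(st.integers(min_value=3, max_value=10))
    ids = [f"r{i}" for i in range(n)]
    vals = data.draw(
        st.lists(
            st.floats(min_value=0.001, max_value=0.5, allow_nan=False),
            min_size=n * (n - 1) // 2,
            max_size=n * (n - 1) // 2,
        )
    )
    m = matrix_from(ids, dict(zip(itertools.combinations(ids, 2), vals)))
    ts = sorted(data.draw(st.lists(st.floats(0.0, 0.6), min_size=2, max_size=6)))
    prev_k = None
    prev_sets = None
    for t in ts:
        p = single_linkage_clusters(m, t)
        if prev_k is not None:
            assert p.k <= prev_k
            # every earlier cluster fits inside one later cluster
            for cluster in prev_sets:
                assert any(cluster <= c for c in as_sets(p))
        prev_k, prev_sets = p.k, as_sets(p)
    # extremes
    assert single_linkage_clusters(m, 0.0).k == n
    assert single_linkage_clusters(m, np.nextafter(float(m.d.max()), 1.0)).k == 1


class TestRankedPartitions:
    def test_two_tight_clusters_rank_one(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        dist = {}
        for x, y in itertools.combinations(ids, 2):
            same = x[0] == y[0]
            dist[(x, y)] = 0.01 if same else 0.10
        m = matrix_from(ids, dist)
        ranked = ranked_partitions(m)
        assert ranked[0].partition.k == 2
        assert ranked[0].gap_score == pytest.approx((0.10 - 0.01) / 0.10)
        assert [r.rank for r in ranked] == list(range(1, len(ranked) + 1))
        scores = [r.gap_score for r in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_single_outlier(self):
        ids = ["a", "b", "c", "d"]
        dist = {p: 0.0 for p in itertools.combinations(ids[:3], 2)}
        for x in ids[:3]:
            dist[(x, "d")] = 0.5
        m = matrix_from(ids, dist)
        ranked = ranked_partitions(m)
        assert ranked[0].partition.k == 2

    def test_degenerate_all_equal(self):
        m = matrix_from("abc", {p: 0.2 for p in itertools.combinations("abc", 2)})
        ranked = ranked_partitions(m)
        assert len(ranked) == 1
        assert ranked[0].gap_score == 0.0
        assert ranked[0].partition.k == 1

    def test_needs_three_records(self):
        m = matrix_from("ab", {("a", "b"): 0.1})
        with pytest.raises(ValueError):
            ranked_partitions(m)


class TestComparePartition:
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}

    def test_identical_partition_all_congruent(self):
        p = Partition({"a1": 1, "a2": 1, "b1": 2, "b2": 2, "c1": 3})
        cmp_res = compare_partition(p, self.labels)
        assert all(s is CongruenceStatus.CONGRUENT for s in cmp_res.status.values())
        assert cmp_res.n_congruent == 3

    def test_lumped_pair(self):
        p = Partition({"a1": 1, "a2": 1, "b1": 1, "b2": 1, "c1": 2})
        cmp_res = compare_partition(p, self.labels)
        assert cmp_res.status["A"] is CongruenceStatus.LUMPED
        assert cmp_res.status["B"] is CongruenceStatus.LUMPED
        assert cmp_res.status["C"] is CongruenceStatus.CONGRUENT

    def test_split_species(self):
        p = Partition({"a1": 1, "a2": 2, "b1": 3, "b2": 3, "c1": 4})
        cmp_res = compare_partition(p, self.labels)
        assert cmp_res.status["A"] is CongruenceStatus.SPLIT

    def test_mixed_species(self):
        # A occupies two clusters, one of them shared with B
        p = Partition({"a1": 1, "a2": 2, "b1": 2, "b2": 2, "c1": 3})
        cmp_res = compare_partition(p, self.labels)
        assert cmp_res.status["A"] is CongruenceStatus.MIXED

    def test_unlabelled_record_rejected(self):
        p = Partition({"a1": 1, "mystery": 2})
        with pytest.raises(ValueError, match="mystery"):
            compare_partition(p, self.labels)

    def test_counts_sum_to_species(self):
        p = Partition({"a1": 1, "a2": 1, "b1": 1, "b2": 2, "c1": 3})
        cmp_res = compare_partition(p, self.labels)
        assert sum(cmp_res.counts.values()) == 3


def test_partition_tsv_roundtrip(tmp_path):
    p = Partition({"r1": 1, "r2": 1, "r3": 2})
    path = tmp_path / "p.tsv"
    write_partition_tsv(p, path)
    again = read_partition_tsv(path)
    assert again.assignment == p.assignment
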