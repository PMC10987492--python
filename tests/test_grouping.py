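"""Dereplication, similarity matrices, clustering and C-terminal profiles."""

import numpy as np
import pytest

from arrestscreen.grouping import (
    SimilarityMatrix,
    cluster,
    cterm_profile,
    dereplicate,
    similarity_matrix,
)

from conftest import random_protein


def test_dereplicate_merges_identical_sequences():
    proteins = {
        ("g2", "a"): "MAPLE",
        ("g1", "b"): "MAPLE",
        ("g3", "c"): "MOOSE",
    }
    reps, members = dereplicate(proteins)
    assert reps == {("g1", "b"): "MAPLE", ("g3", "c"): "MOOSE"}
    assert members[("g1", "b")] == ["g1", "g2"]


def test_dereplicate_identity_on_distinct_input():
    proteins = {("g1", "a"): "MA", ("g2", "b"): "MC", ("g3", "c"): "MD"}
    reps, members = dereplicate(proteins)
    assert reps == proteins
    assert all(members[k] == [k[0]] for k in proteins)


def test_dereplicate_counting(rng):
    uniques = [random_protein(rng, 30) for _ in range(20)]
    proteins = {}
    n_dupes = 0
    for i, seq in enumerate(uniques):
        proteins[(f"g{i:02d}", "a")] = seq
        if i % 3 == 0:
            proteins[(f"g{i:02d}x", "a")] = seq  # planted duplicate
            n_dupes += 1
    reps, _ = dereplicate(proteins)
    assert len(reps) + n_dupes == len(proteins)


def test_similarity_matrix_trivial_values():
    mat = similarity_matrix({"a": "MAPLEMAPLE", "b": "MAPLEMAPLE", "c": "WWWWWWWWWW"})
    idx = {i: n for n, i in enumerate(mat.ids)}
    assert mat.values[idx["a"], idx["b"]] == 1.0
    assert mat.values[idx["a"], idx["c"]] == 0.0


def test_kmer_jaccard_matches_brute_force(rng):
    reps = {f"s{i}": random_protein(rng, 25) for i in range(10)}
    mat = similarity_matrix(reps, method="kmer_jaccard", k=3)
    for i, a in enumerate(mat.ids):
        for j, b in enumerate(mat.ids):
            sa = {reps[a][p : p + 3] for p in range(len(reps[a]) - 2)}
            sb = {reps[b][p : p + 3] for p in range(len(reps[b]) - 2)}
            expected = len(sa & sb) / len(sa | sb)
            assert mat.values[i, j] == pytest.approx(expected)


def test_sw_identity_values(rng):
    a = random_protein(rng, 40)
    mat = similarity_matrix({"a": a, "b": a, "c": "AAAA", "d": "AATA"}, method="sw_identity")
    idx = {i: n for n, i in enumerate(mat.ids)}
    assert mat.values[idx["a"], idx["b"]] == 1.0
    # full-length local alignment of AAAA/AATA: 3 identities over 4 columns
    assert mat.values[idx["c"], idx["d"]] == pytest.approx(0.75)


def _chain_matrix():
    ids = ["A", "B", "C", "D"]
    values = np.full((4, 4), 0.1)
    np.fill_diagonal(values, 1.0)
    for i, j in [(0, 1), (1, 2), (2, 3)]:
        values[i, j] = values[j, i] = 0.6
    return SimilarityMatrix(ids=ids, values=values, method="kmer_jaccard")


def test_cluster_chain_set_cover_vs_connected():
    mat = _chain_matrix()
    con = cluster(mat, 0.5, "connected")
    assert con.as_partition() == [frozenset("ABCD")]
    cov = cluster(mat, 0.5, "set_cover")
    parts = {tuple(sorted(c["members"])): c["representative"] for c in cov.clusters}
    assert parts == {("A", "B", "C"): "B", ("D",): "D"}


def test_cluster_identical_set_one_cluster():
    mat = similarity_matrix({f"s{i}": "MAPLEMAPLE" for i in range(5)})
    for mode in ("set_cover", "connected"):
        assert len(cluster(mat, 0.9, mode).clusters) == 1


def test_cluster_no_edges_all_singletons():
    ids = ["a", "b", "c"]
    mat = SimilarityMatrix(ids=ids, values=np.eye(3), method="kmer_jaccard")
    for mode in ("set_cover", "connected"):
        assert cluster(mat, 0.5, mode).as_partition() == [
            frozenset({"a"}), frozenset({"b"}), frozenset({"c"})
        ]


def test_cluster_empty_matrix():
    mat = SimilarityMatrix(ids=[], values=np.zeros((0, 0)), method="kmer_jaccard")
    assert cluster(mat, 0.5).clusters == []


def _naive_greedy_set_cover(ids, adj):
    """Independent pure-python restatement of the greedy covering rule."""
    unassigned = set(ids)
    clusters = []
    while unassigned:
        candidates = []
        for node in sorted(unassigned):
            neighbors = sorted(
                other for other in unassigned
                if other != node and adj[(node, other)] > 0
            )
            total = sum(adj[(node, other)] for other in neighbors)
            candidates.append((-len(neighbors), -total, node, neighbors))
        candidates.sort()
        _, _, rep, neighbors = candidates[0]
        clusters.append((rep, frozenset([rep, *neighbors])))
        unassigned -= {rep, *neighbors}
    return clusters


def test_set_cover_matches_naive_oracle_on_small_graphs(rng):
    for trial in range(25):
        n = int(rng.integers(2, 13))
        ids = [f"n{i:02d}" for i in range(n)]
        values = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                sim = round(float(rng.random()), 3)
                values[i, j] = values[j, i] = sim
        threshold = 0.5
        mat = SimilarityMatrix(ids=ids, values=values, method="kmer_jaccard")
        result = cluster(mat, threshold, "set_cover")
        adj = {
            (a, b): (values[i, j] if values[i, j] >= threshold else 0.0)
            for i, a in enumerate(ids)
            for j, b in enumerate(ids)
        }
        expected = _naive_greedy_set_cover(ids, adj)
        got = [(c["representative"], frozenset(c["members"])) for c in result.clusters]
        assert sorted(got) == sorted(expected)
        # greedy covers all nodes in at most |V| rounds
        assert len(got) <= n


def test_connected_coarsens_set_cover(rng):
    for trial in range(10):
        n = int(rng.integers(3, 12))
        ids = [f"n{i}" for i in range(n)]
        values = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                sim = float(rng.random())
                values[i, j] = values[j, i] = sim
        mat = SimilarityMatrix(ids=ids, values=values, method="kmer_jaccard")
        cov = cluster(mat, 0.6, "set_cover").as_partition()
        con = cluster(mat, 0.6, "connected").as_partition()
        for cov_cluster in cov:
            assert any(cov_cluster <= comp for comp in con)


def test_cluster_is_input_order_invariant(rng):
    reps = {f"s{i}": random_protein(rng, 20, alphabet="ACDE") for i in range(8)}
    mat1 = similarity_matrix(reps)
    mat2 = similarity_matrix(dict(reversed(list(reps.items()))))
    for mode in ("set_cover", "connected"):
        assert cluster(mat1, 0.3, mode).as_partition() == cluster(mat2, 0.3, mode).as_partition()


def test_cterm_profile_unanimous_motif():
    prof = cterm_profile(["MAAARAPP", "MWWRAPP", "MRAPP"], window_len=4)
    assert prof.frequencies[-4] == {"R": 1.0}
    assert prof.frequencies[-3] == {"A": 1.0}
    assert prof.frequencies[-2] == {"P": 1.0}
    assert prof.frequencies[-1] == {"P": 1.0}


def test_cterm_profile_split_and_padding():
    prof = cterm_profile(["MRAPP", "MRGPP"], window_len=5)
    assert prof.frequencies[-3] == {"A": 0.5, "G": 0.5}
    short = cterm_profile(["AP", "MRAP"], window_len=4)
    assert short.frequencies[-4] == {"-": 0.5, "M": 0.5}


def test_cterm_profile_matches_hand_count(rng):
    members = [random_protein(rng, int(rng.integers(5, 15))) for _ in range(5)]
    window = 6
    prof = cterm_profile(members, window)
    for offset in range(-window, 0):
        column = [
            seq[len(seq) + offset] if len(seq) + offset >= 0 else "-"
            for seq in members
        ]
        for res in set(column):
            assert prof.frequencies[offset][res] == pytest.approx(
                column.count(res) / len(members)
            )
        assert sum(prof.frequencies[offset].values()) == pytest.approx(1.0)
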