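"""Dereplication, similarity-graph clustering and C-terminal profiles.

Clustering follows the two modes used for homology-group construction in
large sequence-set clustering tools: a greedy set-cover pass (compact
clusters around a representative) and connected components (merging more
remote homologs).  A single similarity pass — k-mer Jaccard by default,
optional Smith–Waterman identity — stands in for iterative profile searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices


@dataclass
class SimilarityMatrix:
    ids: list
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        if n and not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        if n and not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if n and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("similarity values must lie in [0, 1]")


@dataclass
class ClusterSet:
    mode: str
    clusters: list[dict] = field(default_factory=list)  # {"representative", "members"}

    def membership(self) -> dict:
        out = {}
        for cl in self.clusters:
            for member in cl["members"]:
                out[member] = cl["representative"]
        return out

    def as_partition(self) -> list[frozenset]:
        return [frozenset(cl["members"]) for cl in self.clusters]


@dataclass
class ConservationProfile:
    """Per-position residue frequencies over a right-anchored C-terminal window.

    Positions are indexed -window_len ... -1 (the protein's final residue is
    -1); shorter sequences are left-padded with the gap symbol '-'.
    """

    window_len: int
    frequencies: dict[int, dict[str, float]]
    n_sequences: int


def dereplicate(proteins: dict) -> tuple[dict, dict]:
    """Exact-identity dereplication of a (genome_id, locus_tag) -> seq map.

    Returns ``(representatives, members)`` where representatives maps the
    lexicographically smallest id of each identical-sequence group to the
    sequence, and members maps that id to the sorted genome_ids carrying it.
    """
    by_seq: dict[str, list] = {}
    for key in sorted(proteins):
        by_seq.setdefault(proteins[key], []).append(key)
    representatives = {}
    members = {}
    for seq, keys in by_seq.items():
        rep = min(keys)
        representatives[rep] = seq
        members[rep] = sorted({k[0] if isinstance(k, tuple) else k for k in keys})
    return representatives, members


def _kmer_set(seq: str, k: int) -> frozenset:
    if len(seq) < k:
        # short sequence: a single right-padded k-mer of itself
        return frozenset({seq.ljust(k, "-")})
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _sw_identity(a: str, b: str, aligner: PairwiseAligner) -> float:
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return 0.0
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def similarity_matrix(
    representatives: dict, method: str = "kmer_jaccard", k: int = 3
) -> SimilarityMatrix:
    """All-vs-all similarity of representative sequences.

    ``kmer_jaccard``: Jaccard index of k-mer sets (default k=3).
    ``sw_identity``: identities / aligned columns of the optimal local
    alignment (BLOSUM62, gap open 11 / extend 1).
    """
    if method not in ("kmer_jaccard", "sw_identity"):
        raise ValueError(f"unknown similarity method {method!r}")
    ids = sorted(representatives)
    seqs = [representatives[i] for i in ids]
    n = len(ids)
    values = np.eye(n)
    if method == "kmer_jaccard":
        sets = [_kmer_set(s, k) for s in seqs]
        for i in range(n):
            for j in range(i + 1, n):
                union = len(sets[i] | sets[j])
                sim = len(sets[i] & sets[j]) / union if union else 0.0
                values[i, j] = values[j, i] = sim
    else:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        for i in range(n):
            for j in range(i + 1, n):
                sim = _sw_identity(seqs[i], seqs[j], aligner)
                values[i, j] = values[j, i] = sim
    return SimilarityMatrix(ids=ids, values=values, method=method)


def cluster(matrix: SimilarityMatrix, threshold: float, mode: str = "set_cover") -> ClusterSet:
    """Partition sequences by thresholding the similarity graph.

    ``connected``: connected components of {edge iff similarity >= threshold};
    the lexicographically smallest member represents each component.
    ``set_cover``: greedily pick the unassigned node with the most unassigned
    neighbors (ties: larger total similarity to unassigned neighbors, then
    smaller id); it and its unassigned neighbors form one cluster.
    Deterministic and input-order invariant.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if mode not in ("set_cover", "connected"):
        raise ValueError(f"unknown cluster mode {mode!r}")
    ids = list(matrix.ids)
    n = len(ids)
    if n == 0:
        return ClusterSet(mode=mode, clusters=[])
    adj = matrix.values >= threshold

    if mode == "connected":
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        graph.add_edges_from(
            (i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]
        )
        clusters = []
        for comp in nx.connected_components(graph):
            members = sorted(ids[i] for i in comp)
            clusters.append({"representative": members[0], "members": members})
        clusters.sort(key=lambda c: c["representative"])
        return ClusterSet(mode=mode, clusters=clusters)

    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best = None
        for i in sorted(unassigned, key=lambda i: ids[i]):
            neighbors = [j for j in unassigned if j != i and adj[i, j]]
            key = (len(neighbors), sum(matrix.values[i, j] for j in neighbors))
            if best is None or key > best[0]:
                best = (key, i, neighbors)
        _, rep, neighbors = best
        members = sorted(ids[j] for j in [rep] + neighbors)
        clusters.append({"representative": ids[rep], "members": members})
        unassigned -= {rep, *neighbors}
    clusters.sort(key=lambda c: c["representative"])
    return ClusterSet(mode="set_cover", clusters=clusters)


def cterm_profile(cluster_members: list[str], window_len: int) -> ConservationProfile:
    """Right-anchored C-terminal residue-frequency profile of a cluster.

    No alignment is performed: the motifs of interest are anchored at or
    near the C-terminus, so sequences are aligned at their last residue and
    gap-padded on the left.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if not cluster_members:
        raise ValueError("cluster must have at least one member")
    frequencies: dict[int, dict[str, float]] = {}
    n = len(cluster_members)
    for offset in range(-window_len, 0):
        counts: dict[str, int] = {}
        for seq in cluster_members:
            idx = len(seq) + offset
            res = seq[idx] if idx >= 0 else "-"
            counts[res] = counts.get(res, 0) + 1
        frequencies[offset] = {res: c / n for res, c in sorted(counts.items())}
    return ConservationProfile(window_len=window_len, frequencies=frequencies, n_sequences=n)
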