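"""Gene presence/absence profiles, bootstrap clustering, and alignment-free
composition-vector distances.

Presence/absence of marker-gene homologs across genomes (E-value <= 1e-5 and
an identity floor of 35% by default) is clustered hierarchically; clade
confidence comes from bootstrap resampling of the marker rows, with support
defined by leaf-bipartition identity. Whole-genome relatedness without
alignment uses the composition-vector distance: k-mer frequencies with a
(k-2)-order Markov background subtracted, compared by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .genome_io import HomologyHit

__all__ = [
    "ProfileThresholds",
    "PresenceAbsenceMatrix",
    "DendroNode",
    "Dendrogram",
    "presence_matrix",
    "profile_distance",
    "hcluster",
    "bootstrap_support",
    "composition_vector",
    "composition_vector_distance",
    "distance_tree",
]


@dataclass(frozen=True)
class ProfileThresholds:
    """Homolog-presence cutoffs: E-value inclusive, identity as a floor.

    ``identity_is_floor=False`` flips the identity comparison to <=, for
    sensitivity analysis against sources that print the threshold as a
    ceiling.
    """

    max_evalue: float = 1e-5
    min_identity: float = 35.0
    identity_is_floor: bool = True

    def passes(self, hit: HomologyHit) -> bool:
        if hit.evalue > self.max_evalue:
            return False
        if self.identity_is_floor:
            return hit.percent_identity >= self.min_identity
        return hit.percent_identity <= self.min_identity


@dataclass
class PresenceAbsenceMatrix:
    """Binary marker x genome table plus the thresholds that produced it."""

    data: pd.DataFrame  # bool, rows = marker gene ids, columns = genome ids
    thresholds: ProfileThresholds = field(default_factory=ProfileThresholds)
    reference_genome: str | None = None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("presence/absence matrix has missing cells")
        self.data = self.data.astype(bool)

    @property
    def markers(self) -> list[str]:
        return list(self.data.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.data.columns)


def presence_matrix(
    marker_genes: Sequence[str],
    hits_by_genome: Mapping[str, Iterable[HomologyHit]],
    thresholds: ProfileThresholds = ProfileThresholds(),
    reference_genome: str | None = None,
) -> PresenceAbsenceMatrix:
    """Build the marker presence/absence matrix from per-genome hit tables.

    A marker is present in a genome iff at least one hit with that marker as
    query passes the thresholds. The reference genome (the markers' own
    genome), when named, is set all-present. Markers hitting nothing
    anywhere are kept as all-absent rows.
    """
    genomes = sorted(hits_by_genome)
    mat = pd.DataFrame(False, index=list(marker_genes), columns=genomes)
    marker_set = set(marker_genes)
    for genome, hits in hits_by_genome.items():
        for h in hits:
            if h.query_id in marker_set and thresholds.passes(h):
                mat.loc[h.query_id, genome] = True
    if reference_genome is not None:
        if reference_genome not in mat.columns:
            mat[reference_genome] = True
            mat = mat[sorted(mat.columns)]
        else:
            mat[reference_genome] = True
    return PresenceAbsenceMatrix(mat, thresholds, reference_genome)


def profile_distance(matrix: PresenceAbsenceMatrix, metric: str = "hamming") -> pd.DataFrame:
    """Genome x genome distances from presence profiles.

    hamming: mismatched rows / total rows. jaccard: 1 - |intersection| /
    |union| of present markers (0 when both profiles are empty).
    """
    df = matrix.data
    cols = list(df.columns)
    x = df.to_numpy(dtype=bool)
    n = len(cols)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[:, i], x[:, j]
            if metric == "hamming":
                d = float(np.mean(a != b)) if len(a) else 0.0
            elif metric == "jaccard":
                union = int(np.sum(a | b))
                d = 1.0 - int(np.sum(a & b)) / union if union else 0.0
            else:
                raise ValueError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# Hierarchical clustering with bootstrap support
# ---------------------------------------------------------------------------

@dataclass
class DendroNode:
    leaves: tuple[str, ...]  # sorted leaf labels under this node
    height: float
    children: tuple["DendroNode", "DendroNode"] | None = None
    support: float | None = None  # bootstrap %, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class Dendrogram:
    """Rooted binary merge tree over genome ids."""

    root: DendroNode

    def internal_nodes(self) -> list[DendroNode]:
        out = []

        def walk(node: DendroNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Leaf bipartitions induced by internal nodes (root excluded)."""
        all_leaves = frozenset(self.root.leaves)
        parts = set()
        for node in self.internal_nodes():
            side = frozenset(node.leaves)
            if side != all_leaves:
                parts.add(frozenset({side, all_leaves - side}))
        return parts

    def clade_support(self, leaves: Iterable[str]) -> float | None:
        target = frozenset(leaves)
        for node in self.internal_nodes():
            if frozenset(node.leaves) == target:
                return node.support
        return None

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: DendroNode, parent_h: float) -> str:
            bl = max(0.0, parent_h - node.height)
            if node.is_leaf:
                return f"{node.leaves[0]}:{bl:.6g}"
            inner = ",".join(fmt(ch, node.height) for ch in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{bl:.6g}"

        r = self.root
        if r.is_leaf:
            return f"{r.leaves[0]};"
        inner = ",".join(fmt(ch, r.height) for ch in r.children)
        label = f"{r.support:g}" if with_support and r.support is not None else ""
        return f"({inner}){label};"


def _cluster_distance(
    d: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int], linkage: str
) -> float:
    sub = d[np.ix_(idx_a, idx_b)]
    if linkage == "average":
        return float(sub.mean())
    if linkage == "complete":
        return float(sub.max())
    if linkage == "single":
        return float(sub.min())
    raise ValueError(f"unknown linkage {linkage!r}")


def hcluster(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Deterministic agglomerative clustering of a labelled distance matrix.

    At each step the pair of clusters at minimal linkage distance merges;
    exact ties are broken by the lexicographically smallest (leaf-tuple,
    leaf-tuple) pair, so the result is independent of input order.
    """
    labels = list(dist.index)
    if len(labels) < 2:
        raise ValueError("clustering needs >= 2 items")
    if list(dist.columns) != labels:
        raise ValueError("distance matrix index and columns must match")
    d = dist.to_numpy(dtype=float)
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    clusters: list[tuple[DendroNode, list[int]]] = [
        (DendroNode(leaves=(labels[i],), height=0.0), [i]) for i in order
    ]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = _cluster_distance(d, clusters[i][1], clusters[j][1], linkage)
                key = (dij, *sorted((clusters[i][0].leaves, clusters[j][0].leaves)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dij, *_), i, j = best
        node_i, idx_i = clusters[i]
        node_j, idx_j = clusters[j]
        a, b = sorted((node_i, node_j), key=lambda nd: nd.leaves)
        merged = DendroNode(
            leaves=tuple(sorted(node_i.leaves + node_j.leaves)),
            height=dij,
            children=(a, b),
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, idx_i + idx_j))
        clusters.sort(key=lambda c: c[0].leaves)
    return Dendrogram(root=clusters[0][0])


def bootstrap_support(
    matrix: PresenceAbsenceMatrix,
    metric: str = "hamming",
    linkage: str = "average",
    n_reps: int = 1000,
    seed: int = 0,
) -> Dendrogram:
    """Cluster the full matrix and attach bootstrap supports.

    Marker rows are resampled with replacement ``n_reps`` times; an internal
    node's support is the percentage of replicate dendrograms containing the
    same leaf bipartition. Deterministic per seed and invariant to the row
    order of the input matrix (rows are sorted before resampling).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    df = matrix.data.sort_index()
    base = hcluster(profile_distance(PresenceAbsenceMatrix(df, matrix.thresholds), metric), linkage)
    all_leaves = frozenset(df.columns)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    nrows = len(df)
    for _ in range(n_reps):
        rows = rng.integers(0, nrows, size=nrows)
        rep_df = df.iloc[rows]
        rep = hcluster(
            profile_distance(PresenceAbsenceMatrix(rep_df, matrix.thresholds), metric), linkage
        )
        for part in rep.bipartitions():
            counts[part] = counts.get(part, 0) + 1
    for node in base.internal_nodes():
        side = frozenset(node.leaves)
        if side == all_leaves:
            node.support = 100.0
        else:
            part = frozenset({side, all_leaves - side})
            node.support = 100.0 * counts.get(part, 0) / n_reps
    return base


# ---------------------------------------------------------------------------
# Composition-vector distance
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_RC_TRANS = str.maketrans("ACGT", "TGCA")


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Counts of all 4^k k-mers; windows containing N are skipped."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes)
    if n < k:
        return np.zeros(4**k, dtype=np.int64)
    valid = codes >= 0
    vals = np.where(valid, codes, 0)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    # rolling polynomial evaluation via strided windows
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    kmers = (win * weights).sum(axis=1)[ok]
    return np.bincount(kmers, minlength=4**k)


def composition_vector(seq: str, k: int = 6, merge_strands: bool = True) -> np.ndarray:
    """Markov-subtracted k-string composition vector of one sequence.

    For each k-string s = s1..sk with observed frequency f(s), the
    background expectation under a (k-2)-order Markov model is
    f0(s) = f(s1..sk-1) * f(s2..sk) / f(s2..sk-1); the component is
    a(s) = (f(s) - f0(s)) / f0(s) where f0 > 0, else 0. Counts from the
    reverse complement are added first when ``merge_strands``.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    seqs = [seq.upper()]
    if merge_strands:
        seqs.append(seqs[0].translate(_RC_TRANS)[::-1])
    ck = sum(_kmer_counts(s, k) for s in seqs)
    ck1 = sum(_kmer_counts(s, k - 1) for s in seqs)
    ck2 = sum(_kmer_counts(s, k - 2) for s in seqs)
    fk = ck / max(1, ck.sum())
    fk1 = ck1 / max(1, ck1.sum())
    fk2 = ck2 / max(1, ck2.sum())
    idx = np.arange(4**k)
    pre = idx // 4           # s1..sk-1
    suf = idx % (4 ** (k - 1))  # s2..sk
    mid = suf // 4           # s2..sk-1
    with np.errstate(divide="ignore", invalid="ignore"):
        f0 = np.where(fk2[mid] > 0, fk1[pre] * fk1[suf] / np.where(fk2[mid] > 0, fk2[mid], 1), 0.0)
        a = np.where(f0 > 0, (fk - f0) / np.where(f0 > 0, f0, 1), 0.0)
    return a


def composition_vector_distance(
    seq_a: str, seq_b: str, k: int = 6, merge_strands: bool = True
) -> float:
    """CV distance (1 - cosine similarity) / 2, in [0, 1]."""
    a = composition_vector(seq_a, k, merge_strands)
    b = composition_vector(seq_b, k, merge_strands)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.5  # no compositional signal: cosine treated as 0
    c = float(a @ b / (na * nb))
    c = min(1.0, max(-1.0, c))
    return (1.0 - c) / 2.0


def distance_tree(dist: pd.DataFrame, method: str = "nj") -> str:
    """Newick tree from a symmetric distance matrix (NJ unrooted, UPGMA rooted)."""
    arr = dist.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    ids = [str(x) for x in dist.index]
    if method == "nj":
        tree = nj(DistanceMatrix(arr, ids))
        return str(tree).strip()
    if method == "upgma":
        from scipy.spatial.distance import squareform

        z = _scipy_linkage(squareform(arr, checks=False), method="average")
        tree = TreeNode.from_linkage_matrix(z, ids)
        return str(tree).strip()
    raise ValueError(f"unknown method {method!r}")
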