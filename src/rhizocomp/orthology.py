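"""Reciprocal-best-hit orthology and pan-genome partitioning.

Similarity hits are filtered by the four classical cutoffs (E-value < 1e-5,
identity > 30%, query coverage > 70%, bit score > 60; all strict), mutual
best hits between genome pairs become ortholog pairs, pairs across the
cohort are merged into ortholog groups (connected components of the pair
graph), and groups are classified as core (all genomes), shared-by-k, or
strain-specific. A strict single-copy core (exactly one member per genome)
supports marker-gene sampling for presence/absence profiling.

Group construction deliberately uses connected components rather than Markov
clustering: the downstream statistics need only a deterministic grouping,
and component structure is fully reproducible and auditable. Counts obtained
this way are therefore not expected to match Markov-clustering group counts
on real data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .genome_io import GenomeAnnotation, HomologyHit

__all__ = [
    "HomologyThresholds",
    "OrthoGroup",
    "PanGenomePartition",
    "filter_hits",
    "reciprocal_best_hits",
    "build_groups",
    "partition_pan_genome",
    "single_copy_core",
    "sample_marker_genes",
]


@dataclass(frozen=True)
class HomologyThresholds:
    """Hit filter cutoffs; all four comparisons are strict inequalities."""

    max_evalue: float = 1e-5
    min_identity: float = 30.0
    min_coverage: float = 70.0
    min_bitscore: float = 60.0

    def passes(self, hit: HomologyHit) -> bool:
        return (
            hit.evalue < self.max_evalue
            and hit.percent_identity > self.min_identity
            and hit.query_coverage > self.min_coverage
            and hit.bit_score > self.min_bitscore
        )


@dataclass(frozen=True)
class OrthoGroup:
    """A multi-genome gene family: >= 2 (genome, gene) members."""

    group_id: str
    members: tuple[tuple[str, str], ...]  # (genome_id, gene_id)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ortholog group needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate (genome, gene) member in group")

    @property
    def genome_multiset(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for genome_id, _ in self.members:
            out[genome_id] = out.get(genome_id, 0) + 1
        return out

    @property
    def n_genomes(self) -> int:
        return len({g for g, _ in self.members})


@dataclass
class PanGenomePartition:
    """Core / shared-by-k / strain-specific classification of a cohort."""

    n_genomes: int
    core: list[OrthoGroup]
    shared_k: dict[int, list[OrthoGroup]]  # k in 2..n-1
    specific: dict[str, list[str]]  # genome_id -> genes in no group

    @property
    def n_groups(self) -> int:
        return len(self.core) + sum(len(v) for v in self.shared_k.values())

    @property
    def core_fraction(self) -> float:
        return len(self.core) / self.n_groups if self.n_groups else float("nan")

    def summary(self) -> dict:
        """Group counts and percentages plus per-genome core gene counts."""
        total = self.n_groups
        out = {
            "n_genomes": self.n_genomes,
            "n_groups": total,
            "core_groups": len(self.core),
            "core_pct": 100.0 * len(self.core) / total if total else float("nan"),
            "shared_k_groups": {k: len(v) for k, v in sorted(self.shared_k.items())},
            "specific_genes": {g: len(v) for g, v in sorted(self.specific.items())},
        }
        per_genome: dict[str, int] = {}
        for grp in self.core:
            for genome_id, _ in grp.members:
                per_genome[genome_id] = per_genome.get(genome_id, 0) + 1
        out["core_genes_per_genome"] = dict(sorted(per_genome.items()))
        return out


def filter_hits(
    hits: Iterable[HomologyHit], thresholds: HomologyThresholds = HomologyThresholds()
) -> list[HomologyHit]:
    """Keep hits passing all four strict cutoffs; drop self-hits."""
    return [h for h in hits if h.query_id != h.subject_id and thresholds.passes(h)]


def _best_hits(hits: Sequence[HomologyHit]) -> dict[str, HomologyHit]:
    """Best surviving hit per query.

    Best = max bit score, ties broken by min E-value, then max identity,
    then lexicographically smallest subject id.
    """
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (-h.bit_score, h.evalue, -h.percent_identity, h.subject_id)
        key_cur = (-cur.bit_score, cur.evalue, -cur.percent_identity, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[HomologyHit],
    hits_ba: Iterable[HomologyHit],
    thresholds: HomologyThresholds = HomologyThresholds(),
) -> list[tuple[str, str]]:
    """Mutual-best ortholog pairs between two genomes.

    (a, b) is emitted iff b is a's best surviving A->B hit and a is b's best
    surviving B->A hit; each gene ends up in at most one pair. Output is
    sorted by the A-side gene id.
    """
    best_ab = _best_hits(filter_hits(hits_ab, thresholds))
    best_ba = _best_hits(filter_hits(hits_ba, thresholds))
    pairs = []
    for a, hit in best_ab.items():
        b = hit.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append((a, b))
    return sorted(pairs)


def build_groups(
    pair_sets: Mapping[tuple[str, str], Sequence[tuple[str, str]]],
) -> list[OrthoGroup]:
    """Ortholog groups as connected components of the cross-genome pair graph.

    ``pair_sets`` maps (genome_a, genome_b) to ortholog pairs from
    :func:`reciprocal_best_hits`. Singleton genes never form groups; group
    ids are content-addressed (short hash of the sorted member list) so the
    same grouping always gets the same ids.
    """
    g = nx.Graph()
    for (ga, gb), pairs in pair_sets.items():
        for a, b in pairs:
            g.add_edge((ga, a), (gb, b))
    groups = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        digest = hashlib.sha1("|".join(f"{x}:{y}" for x, y in members).encode()).hexdigest()[:12]
        groups.append(OrthoGroup(group_id=f"OG_{digest}", members=members))
    groups.sort(key=lambda grp: grp.members)
    return groups


def partition_pan_genome(
    groups: Sequence[OrthoGroup], genomes: Sequence[GenomeAnnotation]
) -> PanGenomePartition:
    """Classify groups by distinct-genome span; list group-less genes as specific.

    Core groups cover all n genomes (>= 1 member in each); shared_k groups
    span exactly k of the n genomes, 2 <= k <= n-1. Genes belonging to no
    group are strain-specific.
    """
    n = len(genomes)
    if n < 2:
        raise ValueError("pan-genome partition needs >= 2 genomes")
    genome_ids = [a.genome_id for a in genomes]
    core: list[OrthoGroup] = []
    shared: dict[int, list[OrthoGroup]] = {k: [] for k in range(2, n)}
    grouped: set[tuple[str, str]] = set()
    for grp in groups:
        grouped.update(grp.members)
        k = grp.n_genomes
        if k == n:
            core.append(grp)
        else:
            shared.setdefault(k, []).append(grp)
    specific = {}
    for annot in genomes:
        specific[annot.genome_id] = sorted(
            g.gene_id
            for g in annot.iter_genes()
            if not g.is_trna and (annot.genome_id, g.gene_id) not in grouped
        )
    return PanGenomePartition(n_genomes=n, core=core, shared_k=shared, specific=specific)


def single_copy_core(
    groups: Sequence[OrthoGroup], genomes: Sequence[GenomeAnnotation]
) -> list[OrthoGroup]:
    """Core groups with exactly one member per genome (the strict single-copy core)."""
    n = len(genomes)
    ids = {a.genome_id for a in genomes}
    out = []
    for grp in groups:
        ms = grp.genome_multiset
        if set(ms) == ids and all(v == 1 for v in ms.values()):
            out.append(grp)
    return out


def sample_marker_genes(
    scc_groups: Sequence[OrthoGroup],
    n: int = 210,
    seed: int = 0,
    reference_genome: str | None = None,
) -> list[str]:
    """Uniformly sample n single-copy core genes without replacement.

    Gene ids are taken from ``reference_genome`` (default: the
    lexicographically first genome in the groups). Deterministic per seed.
    """
    if not scc_groups:
        raise ValueError("no single-copy core groups to sample from")
    if reference_genome is None:
        reference_genome = min(g for grp in scc_groups for g, _ in grp.members)
    pool = sorted(
        gene for grp in scc_groups for genome, gene in grp.members if genome == reference_genome
    )
    if n > len(pool):
        raise ValueError(f"requested {n} markers but only {len(pool)} single-copy core genes")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return sorted(pool[i] for i in idx)
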