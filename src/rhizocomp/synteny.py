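"""Perfectly conserved synteny blocks and gene synteny scores.

A perfect block between genomes A and B is a maximal run of consecutive
genes in A whose orthologs in B are consecutive and either co-linear with
equal strands (forward) or exactly reversed with flipped strands (inverted).
Genes lacking orthologs break runs, as do replicon boundaries; the
segmentation is greedy left-to-right in A, so blocks never overlap and every
gene in synteny belongs to exactly one block.

Each gene in a block receives a synteny score equal to the block's length in
genes (a gene in a seven-gene block scores 7); the per-pair mean of these
scores over genes in synteny summarizes how much gene order the pair
shares, and pairs of score distributions are compared with a Welch t-test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeAnnotation

__all__ = [
    "SyntenyBlock",
    "SyntenyScoreSet",
    "perfect_blocks",
    "gene_scores",
    "compare_score_sets",
    "pairwise_synteny_report",
    "ttest_matrix",
]


@dataclass(frozen=True)
class SyntenyBlock:
    genome_a: str
    genome_b: str
    a_replicon: str
    a_start_rank: int
    a_end_rank: int
    b_replicon: str
    b_start_rank: int
    b_end_rank: int
    orientation: str  # "forward" | "inverted"
    a_genes: tuple[str, ...]
    b_genes: tuple[str, ...]

    @property
    def length_genes(self) -> int:
        return len(self.a_genes)


@dataclass
class SyntenyScoreSet:
    """Per-gene block-length scores for one genome of a pair."""

    genome_a: str
    genome_b: str
    reference_genome: str
    scores: dict[str, int]  # gene_id -> length of its block

    @property
    def covered_genes(self) -> int:
        return len(self.scores)

    @property
    def mean_score(self) -> float:
        if not self.scores:
            return math.nan
        return float(np.mean(list(self.scores.values())))

    def mean_score_all_genes(self, total_genes: int) -> float:
        """Sensitivity variant: mean over all genes, scoring 0 outside blocks."""
        if total_genes <= 0:
            return math.nan
        return sum(self.scores.values()) / total_genes

    def values(self) -> np.ndarray:
        return np.asarray(list(self.scores.values()), dtype=float)


def _gene_positions(annot: GenomeAnnotation) -> dict[str, tuple[str, int, str]]:
    return {g.gene_id: (g.replicon_id, g.rank, g.strand) for g in annot.iter_genes()}


def perfect_blocks(
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    ortholog_pairs: Iterable[tuple[str, str]],
    min_block: int = 2,
    circular_wrap: bool = False,
) -> list[SyntenyBlock]:
    """Detect maximal perfectly conserved blocks between two genomes.

    ``ortholog_pairs`` must be a one-to-one relation (A gene, B gene);
    many-to-many inputs raise a contract error. With ``circular_wrap`` the
    first and last runs of a circular replicon may join across the origin
    (rank n-1 to rank 0 in A, with the B ranks continuing modulo the B
    replicon's gene count).
    """
    pairs = list(ortholog_pairs)
    a_seen: set[str] = set()
    b_seen: set[str] = set()
    for a, b in pairs:
        if a in a_seen or b in b_seen:
            raise ValueError(f"ortholog map is not one-to-one at pair ({a}, {b})")
        a_seen.add(a)
        b_seen.add(b)
    a_to_b = dict(pairs)
    pos_b = _gene_positions(annot_b)
    b_rep_sizes = {r.replicon_id: len(r.genes) for r in annot_b.replicons}
    b_rep_circular = {r.replicon_id: r.circular for r in annot_b.replicons}

    blocks: list[SyntenyBlock] = []
    for rep in annot_a.replicons:
        rep_blocks: list[SyntenyBlock] = []
        run: list[tuple] = []  # (a_gene, a_rank, b_gene, b_rep, b_rank)
        run_dir = 0

        def close() -> None:
            nonlocal run, run_dir
            if len(run) >= min_block:
                b_ranks = [x[4] for x in run]
                rep_blocks.append(
                    SyntenyBlock(
                        genome_a=annot_a.genome_id,
                        genome_b=annot_b.genome_id,
                        a_replicon=rep.replicon_id,
                        a_start_rank=run[0][1],
                        a_end_rank=run[-1][1],
                        b_replicon=run[0][3],
                        b_start_rank=min(b_ranks),
                        b_end_rank=max(b_ranks),
                        orientation="forward" if run_dir == 1 else "inverted",
                        a_genes=tuple(x[0] for x in run),
                        b_genes=tuple(x[2] for x in run),
                    )
                )
            run, run_dir = [], 0

        for g in rep.genes:
            b_gene = a_to_b.get(g.gene_id)
            if b_gene is None or b_gene not in pos_b:
                close()
                continue
            b_rep, b_rank, b_strand = pos_b[b_gene]
            concord = 1 if g.strand == b_strand else -1
            entry = (g.gene_id, g.rank, b_gene, b_rep, b_rank)
            if run:
                _, pa, _, p_rep, pb, p_concord = run[-1]
                step = b_rank - pb
                contiguous = g.rank == pa + 1 and b_rep == p_rep
                ok = False
                if contiguous and concord == p_concord:
                    if concord == 1 and step == 1 and run_dir in (0, 1):
                        run_dir = 1
                        ok = True
                    elif concord == -1 and step == -1 and run_dir in (0, -1):
                        run_dir = -1
                        ok = True
                if ok:
                    run.append(entry + (concord,))
                    continue
                close()
            run.append(entry + (concord,))
        close()

        if circular_wrap and rep.circular and len(rep_blocks) >= 2:
            first, last = rep_blocks[0], rep_blocks[-1]
            merged = _try_wrap_merge(
                first, last, len(rep.genes), b_rep_sizes, b_rep_circular
            )
            if merged is not None:
                rep_blocks = [merged] + rep_blocks[1:-1]
        blocks.extend(rep_blocks)
    return blocks


def _try_wrap_merge(
    first: SyntenyBlock,
    last: SyntenyBlock,
    n_a: int,
    b_sizes: Mapping[str, int],
    b_circ: Mapping[str, bool],
) -> SyntenyBlock | None:
    """Join the first and last block of a circular replicon when the origin
    junction satisfies the same extension predicate (B ranks wrap modulo the
    B replicon size)."""
    if first is last:
        return None
    if last.a_end_rank != n_a - 1 or first.a_start_rank != 0:
        return None
    if first.orientation != last.orientation or first.b_replicon != last.b_replicon:
        return None
    if not b_circ.get(first.b_replicon, False):
        return None
    nb = b_sizes[first.b_replicon]
    if first.orientation == "forward":
        ok = (last.b_end_rank + 1) % nb == first.b_start_rank
    else:
        ok = (last.b_start_rank - 1) % nb == first.b_end_rank
    if not ok:
        return None
    return SyntenyBlock(
        genome_a=first.genome_a,
        genome_b=first.genome_b,
        a_replicon=first.a_replicon,
        a_start_rank=last.a_start_rank,
        a_end_rank=first.a_end_rank,  # spans the origin
        b_replicon=first.b_replicon,
        b_start_rank=min(first.b_start_rank, last.b_start_rank),
        b_end_rank=max(first.b_end_rank, last.b_end_rank),
        orientation=first.orientation,
        a_genes=last.a_genes + first.a_genes,
        b_genes=last.b_genes + first.b_genes,
    )


def gene_scores(blocks: Sequence[SyntenyBlock], reference_genome: str) -> SyntenyScoreSet:
    """Score every gene in synteny by the length of its block.

    Only genes inside blocks are scored; the mean is over those genes (the
    all-genes variant is available on the result object).
    """
    if blocks:
        genome_a, genome_b = blocks[0].genome_a, blocks[0].genome_b
    else:
        genome_a = genome_b = reference_genome
    scores: dict[str, int] = {}
    for blk in blocks:
        genes = (
            blk.a_genes
            if reference_genome == blk.genome_a
            else blk.b_genes
            if reference_genome == blk.genome_b
            else None
        )
        if genes is None:
            raise ValueError(
                f"reference genome {reference_genome!r} is not part of the pair "
                f"({blk.genome_a}, {blk.genome_b})"
            )
        for g in genes:
            if g in scores:
                raise ValueError(f"gene {g} scored by two blocks")
            scores[g] = blk.length_genes
    return SyntenyScoreSet(
        genome_a=genome_a, genome_b=genome_b, reference_genome=reference_genome, scores=scores
    )


def compare_score_sets(
    set_1: SyntenyScoreSet | Sequence[float],
    set_2: SyntenyScoreSet | Sequence[float],
) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances, two-sided) on score vectors.

    When both samples are constant the test is degenerate: p = 1 if the two
    means are equal, else t = +/-inf with p = 0.
    """
    x = set_1.values() if isinstance(set_1, SyntenyScoreSet) else np.asarray(set_1, float)
    y = set_2.values() if isinstance(set_2, SyntenyScoreSet) else np.asarray(set_2, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both score sets need >= 2 values")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return (math.copysign(math.inf, float(np.mean(x) - np.mean(y))), 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def pairwise_synteny_report(
    annotations: Sequence[GenomeAnnotation],
    ortholog_maps: Mapping[tuple[str, str], Sequence[tuple[str, str]]],
    min_block: int = 2,
    reference_genome: str | None = None,
    circular_wrap: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], SyntenyScoreSet]]:
    """Per-pair block statistics plus the score sets behind them.

    One row per unordered genome pair (deterministic id order): number of
    blocks, mean block length, mean gene score, and the fraction of the
    first genome's genes covered by blocks. Score sets are keyed by the
    (genome_a, genome_b) pair and scored on genome_a (or on
    ``reference_genome`` for pairs containing it).
    """
    by_id = {a.genome_id: a for a in annotations}
    rows = []
    score_sets: dict[tuple[str, str], SyntenyScoreSet] = {}
    for ga, gb in sorted(ortholog_maps):
        pairs = ortholog_maps[(ga, gb)]
        blocks = perfect_blocks(by_id[ga], by_id[gb], pairs, min_block, circular_wrap)
        ref = ga
        if reference_genome is not None and reference_genome in (ga, gb):
            ref = reference_genome
        ss = gene_scores(blocks, ref)
        score_sets[(ga, gb)] = ss
        total = sum(1 for _ in by_id[ref].iter_genes())
        rows.append(
            {
                "genome_a": ga,
                "genome_b": gb,
                "n_blocks": len(blocks),
                "mean_block_length": (
                    float(np.mean([b.length_genes for b in blocks])) if blocks else math.nan
                ),
                "mean_score": ss.mean_score,
                "covered_genes": ss.covered_genes,
                "covered_fraction": ss.covered_genes / total if total else math.nan,
            }
        )
    return pd.DataFrame(rows), score_sets


def ttest_matrix(score_sets: Mapping[tuple[str, str], SyntenyScoreSet]) -> pd.DataFrame:
    """Welch p-values for every pair of score distributions (Table-S3 style)."""
    keys = sorted(score_sets)
    labels = [f"{a}|{b}" for a, b in keys]
    mat = pd.DataFrame(np.ones((len(keys), len(keys))), index=labels, columns=labels)
    for (i, k1), (j, k2) in itertools.combinations(enumerate(keys), 2):
        _, p = compare_score_sets(score_sets[k1], score_sets[k2])
        mat.iloc[i, j] = mat.iloc[j, i] = p
    return mat
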