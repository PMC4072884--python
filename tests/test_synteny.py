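"""Synteny blocks against a brute-force interval oracle, gene scores, and
the Welch comparison of score distributions."""

import math

import numpy as np
import pytest
from scipy import stats

from rhizocomp.synteny import (
    compare_score_sets,
    gene_scores,
    pairwise_synteny_report,
    perfect_blocks,
    ttest_matrix,
)
from tests.conftest import annot_from_order


def identity_pairs(order, ga="A", gb="B"):
    return [(f"{ga}:{k}", f"{gb}:{k}") for k, _ in order]


def brute_force_blocks(order_a, order_b, min_block=2):
    """Greedy segmentation where each candidate interval is re-checked from
    scratch against the perfect-conservation predicate."""
    pos_b = {k: (r, s) for r, (k, s) in enumerate(order_b)}

    def valid(i, j):
        keys = [order_a[t][0] for t in range(i, j + 1)]
        if any(k not in pos_b for k in keys):
            return False
        b_ranks = [pos_b[k][0] for k in keys]
        concord = [order_a[t][1] == pos_b[order_a[t][0]][1] for t in range(i, j + 1)]
        if all(concord):
            return all(b - a == 1 for a, b in zip(b_ranks, b_ranks[1:]))
        if not any(concord):
            return all(b - a == -1 for a, b in zip(b_ranks, b_ranks[1:]))
        return False

    n = len(order_a)
    blocks = []
    i = 0
    while i < n:
        j_best = None
        for j in range(n - 1, i - 1, -1):  # longest valid interval starting at i
            if valid(i, j):
                j_best = j
                break
        if j_best is None or j_best == i:
            if j_best == i and min_block <= 1 and order_a[i][0] in pos_b:
                blocks.append((i, i, 1))
            i += 1
            continue
        length = j_best - i + 1
        if length >= min_block:
            k0, k1 = order_a[i][0], order_a[i + 1][0]
            orient = "forward" if pos_b[k1][0] > pos_b[k0][0] else "inverted"
            blocks.append((i, j_best, orient, length))
        i = j_best + 1
    return blocks


def detected(annot_a, annot_b, pairs, min_block=2):
    return [
        (b.a_start_rank, b.a_end_rank, b.orientation, b.length_genes)
        for b in perfect_blocks(annot_a, annot_b, pairs, min_block)
    ]


class TestPerfectBlocks:
    def test_identical_genomes_one_forward_block(self):
        order = [(k, "+") for k in range(10)]
        a, b = annot_from_order("A", order), annot_from_order("B", order)
        assert detected(a, b, identity_pairs(order)) == [(0, 9, "forward", 10)]

    def test_internal_inversion_gives_three_blocks(self):
        order = [(k, "+") for k in range(10)]
        inv = order[:3] + [(k, "-") for k, _ in reversed(order[3:7])] + order[7:]
        a = annot_from_order("A", order)
        b = annot_from_order("B", inv)
        assert detected(a, b, identity_pairs(order)) == [
            (0, 2, "forward", 3),
            (3, 6, "inverted", 4),
            (7, 9, "forward", 3),
        ]

    def test_empty_ortholog_map_no_blocks(self):
        order = [(k, "+") for k in range(5)]
        a, b = annot_from_order("A", order), annot_from_order("B", order)
        assert perfect_blocks(a, b, []) == []

    def test_missing_ortholog_breaks_runs(self):
        order = [(k, "+") for k in range(6)]
        a, b = annot_from_order("A", order), annot_from_order("B", order)
        pairs = [p for p in identity_pairs(order) if p[0] != "A:3"]
        assert detected(a, b, pairs) == [(0, 2, "forward", 3), (4, 5, "forward", 2)]

    def test_non_injective_map_rejected(self):
        order = [(k, "+") for k in range(3)]
        a, b = annot_from_order("A", order), annot_from_order("B", order)
        with pytest.raises(ValueError, match="one-to-one"):
            perfect_blocks(a, b, [("A:0", "B:0"), ("A:1", "B:0")])

    def test_matches_brute_force_on_random_signed_permutations(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(2, 9))
            order_a = [(k, "+") for k in range(n)]
            perm = rng.permutation(n)
            order_b = [(int(k), "+-"[rng.integers(2)]) for k in perm]
            a = annot_from_order("A", order_a)
            b = annot_from_order("B", order_b)
            assert detected(a, b, identity_pairs(order_a)) == brute_force_blocks(
                order_a, order_b
            )

    def test_symmetry_of_gene_content_and_orientation(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n = int(rng.integers(4, 12))
            order_a = [(k, "+-"[rng.integers(2)]) for k in range(n)]
            order_b = [(int(k), "+-"[rng.integers(2)]) for k in rng.permutation(n)]
            a = annot_from_order("A", order_a)
            b = annot_from_order("B", order_b)
            fwd = perfect_blocks(a, b, identity_pairs(order_a))
            rev = perfect_blocks(b, a, [(y, x) for x, y in identity_pairs(order_a)])
            fwd_sets = sorted(
                (frozenset(blk.a_genes), frozenset(blk.b_genes), blk.orientation)
                for blk in fwd
            )
            rev_sets = sorted(
                (frozenset(blk.b_genes), frozenset(blk.a_genes), blk.orientation)
                for blk in rev
            )
            assert fwd_sets == rev_sets

    def test_min_block_monotonicity(self):
        rng = np.random.default_rng(31)
        order_a = [(k, "+") for k in range(30)]
        order_b = [(int(k), "+-"[rng.integers(2)]) for k in rng.permutation(30)]
        a = annot_from_order("A", order_a)
        b = annot_from_order("B", order_b)
        covered = []
        for mb in (2, 3, 4, 6):
            blocks = perfect_blocks(a, b, identity_pairs(order_a), min_block=mb)
            covered.append(sum(blk.length_genes for blk in blocks))
        assert covered == sorted(covered, reverse=True)

    def test_replicon_boundary_breaks_runs(self):
        from rhizocomp.genome_io import GeneRecord, GenomeAnnotation, Replicon

        def two_rep(gid):
            g = lambda key, rid, rank: GeneRecord(
                f"{gid}:{key}", rid, 10 * rank + 1, 10 * rank + 6, "+", rank
            )
            return GenomeAnnotation(
                gid,
                [
                    Replicon(f"{gid}_r1", False, "", [g(0, f"{gid}_r1", 0), g(1, f"{gid}_r1", 1)]),
                    Replicon(f"{gid}_r2", False, "", [g(2, f"{gid}_r2", 0), g(3, f"{gid}_r2", 1)]),
                ],
            )

        a, b = two_rep("A"), two_rep("B")
        pairs = [(f"A:{k}", f"B:{k}") for k in range(4)]
        got = perfect_blocks(a, b, pairs)
        assert [(blk.a_replicon, blk.length_genes) for blk in got] == [
            ("A_r1", 2),
            ("A_r2", 2),
        ]

    def test_circular_wrap_joins_origin_blocks(self):
        order_a = [(k, "+") for k in range(6)]
        rolled = order_a[2:] + order_a[:2]  # same circle, different origin
        a = annot_from_order("A", order_a, circular=True)
        b = annot_from_order("B", rolled, circular=True)
        flat = detected(a, b, identity_pairs(order_a))
        assert len(flat) == 2
        wrapped = perfect_blocks(a, b, identity_pairs(order_a), circular_wrap=True)
        assert len(wrapped) == 1 and wrapped[0].length_genes == 6


class TestGeneScores:
    def test_seven_gene_block_scores_seven(self):
        order = [(k, "+") for k in range(7)]
        a, b = annot_from_order("A", order), annot_from_order("B", order)
        blocks = perfect_blocks(a, b, identity_pairs(order))
        ss = gene_scores(blocks, "A")
        assert set(ss.scores.values()) == {7}
        assert ss.covered_genes == 7
        assert ss.mean_score == 7.0

    def test_mean_over_mixed_block_lengths(self):
        order = [(k, "+") for k in range(7)]
        b_order = order[:2] + [(10, "+")] + order[3:]  # break gene 2's run
        a = annot_from_order("A", order)
        b = annot_from_order("B", b_order)
        pairs = [p for p in identity_pairs(order) if p[0] != "A:2"]
        blocks = perfect_blocks(a, b, pairs)
        ss = gene_scores(blocks, "A")
        assert sorted(set(ss.scores.values())) == [2, 4]
        assert ss.mean_score == pytest.approx((2 * 2 + 4 * 4) / 6)
        assert ss.mean_score_all_genes(7) == pytest.approx(20 / 7)

    def test_no_blocks_mean_is_missing(self):
        ss = gene_scores([], "A")
        assert ss.covered_genes == 0 and math.isnan(ss.mean_score)


class TestCompareScoreSets:
    def test_identical_vectors_null_case(self):
        t, p = compare_score_sets([3, 3, 3], [3, 3, 3])
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_unequal_means(self):
        t, p = compare_score_sets([5, 5, 5, 5, 5], [2, 2, 2, 2, 2])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_welch_closed_form(self):
        x = np.array([10.0, 12.0, 9.0, 11.0, 13.0])
        y = np.array([8.0, 7.0, 9.0, 6.0])
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_exp = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df)
        t, p = compare_score_sets(x, y)
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-10)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_score_sets([1.0], [2.0, 3.0])


class TestReport:
    def test_two_genome_cohort_single_row(self, small_cohort):
        _, (annots, _, truth) = small_cohort
        sub = {("G0", "G1"): truth.ortholog_map[("G0", "G1")]}
        df, ss = pairwise_synteny_report(annots[:2], sub)
        assert len(df) == 1 and list(ss) == [("G0", "G1")]

    def test_unrearranged_pair_fully_covered(self):
        from rhizocomp.simulate import SimConfig, simulate_cohort

        cfg = SimConfig(n_genomes=2, genes_per_genome=100, island_spec=None,
                        seed=19, with_sequences=False)
        annots, _, truth = simulate_cohort(cfg)
        df, _ = pairwise_synteny_report(annots, truth.ortholog_map)
        row = df.iloc[0]
        assert row.covered_fraction == 1.0
        assert row.mean_score == 100.0

    def test_rearrangement_gradient_orders_mean_scores(self):
        from rhizocomp.simulate import SimConfig, simulate_cohort

        means = {"G1": [], "G2": []}
        for seed in range(4):
            cfg = SimConfig(
                n_genomes=3, genes_per_genome=300, island_spec=None,
                inversion_rate=(0, 2, 15), seed=100 + seed, with_sequences=False,
            )
            annots, _, truth = simulate_cohort(cfg)
            df, ss = pairwise_synteny_report(annots, truth.ortholog_map)
            m = df.set_index(["genome_a", "genome_b"]).mean_score
            means["G1"].append(m[("G0", "G1")])
            means["G2"].append(m[("G0", "G2")])
        # G1 carries far fewer inversions than G2 relative to G0
        assert np.mean(means["G1"]) > np.mean(means["G2"])
        tt = ttest_matrix(ss)
        assert tt.shape == (3, 3)
        assert np.allclose(np.diag(tt), 1.0)
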