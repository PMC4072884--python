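"""Shared fixtures: small simulated cohorts and helpers."""

from __future__ import annotations

import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("fixed", derandomize=True)
_hyp_settings.load_profile("fixed")

from rhizocomp.genome_io import GeneRecord, GenomeAnnotation, Replicon, hits_from_rows
from rhizocomp.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """3 genomes, 200 genes, mild rearrangements, no island, with sequences."""
    cfg = SimConfig(
        n_genomes=3,
        genes_per_genome=200,
        mean_gene_len=300,
        island_spec=None,
        inversion_rate=(0, 2, 5),
        translocation_rate=(0, 1, 2),
        ortholog_loss_rate=0.05,
        seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def island_genome():
    """One genome with the default planted island (100 genes, GC -5 pp)."""
    cfg = SimConfig(n_genomes=1, genes_per_genome=600, seed=7)
    annots, hits, truth = simulate_cohort(cfg)
    return cfg, annots[0], truth


def annot_from_order(genome_id, order, replicon_id=None, circular=False):
    """Build a sequence-less annotation from a [(key, strand), ...] gene order.

    Gene ids are f"{genome_id}:{key}" so identity ortholog maps are easy to
    construct for permutation tests.
    """
    rid = replicon_id or f"{genome_id}_r"
    genes = [
        GeneRecord(
            gene_id=f"{genome_id}:{key}",
            replicon_id=rid,
            start=10 * rank + 1,
            end=10 * rank + 6,
            strand=strand,
            rank=rank,
        )
        for rank, (key, strand) in enumerate(order)
    ]
    return GenomeAnnotation(genome_id, [Replicon(rid, circular, "", genes)])


def cohort_rbh_pairs(hit_tables, truth, thresholds=None):
    """Reciprocal-best-hit pairs for every unordered genome pair of a cohort."""
    from rhizocomp.orthology import HomologyThresholds, reciprocal_best_hits

    thr = thresholds or HomologyThresholds()
    genomes = sorted({g for pair in hit_tables for g in pair})
    out = {}
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            out[(ga, gb)] = reciprocal_best_hits(
                hits_from_rows(hit_tables[(ga, gb)], truth.gene_lengths),
                hits_from_rows(hit_tables[(gb, ga)], truth.gene_lengths),
                thr,
            )
    return out
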