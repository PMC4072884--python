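"""Synthetic genome-cohort simulator.

Generates cohorts of annotated circular replicons with planted orthology,
rearrangements (inversions / translocations), lineage-specific gene loss,
optional clade-structured gene content, and one compositionally shifted
genomic island (lower GC, biased codon usage, transposase enrichment,
flanking tRNA), together with matching BLAST-style similarity tables and a
machine-readable truth record.

Genomes are simulated at the gene-tile level: each gene is an in-frame codon
string sampled from a base-composition model, concatenated with short
intergenic spacers. Downstream stages consume gene order, strand and
composition — not alignments — so no substitution model is applied; ortholog
gene copies share the ancestral sequence verbatim.

The first genome of the cohort is the reference lineage: it keeps every
ancestral gene and (under scalar rearrangement rates) an unrearranged gene
order, so that per-lineage loss expectations and rearrangement gradients are
interpretable against it. The island, when configured, is planted in the
reference genome — inline in its chromosome or as a separate plasmid
replicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genome_io import (
    CODONS,
    GeneRecord,
    GenomeAnnotation,
    Replicon,
    write_blast_tab,
    write_fasta,
    write_gff3,
)

__all__ = [
    "IslandSpec",
    "HitNoise",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "apply_inversion",
    "apply_translocation",
    "emit_files",
    "codon_distribution",
    "BIASED_CODONS",
]

# Default codon subset upweighted inside planted islands. Chosen GC-balanced
# around ~0.56 so that biasing barely perturbs the island GC target (which is
# then corrected exactly by the bisection in codon_distribution), and
# Lys-free so the lysine-excluded codon-usage comparison retains power.
BIASED_CODONS: tuple[str, ...] = ("CTG", "GAC", "TTC", "GCA", "CGT", "ATC")

_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
_CODON_ARR = np.array(CODONS)
_CODON_GC = np.array([sum(b in "GC" for b in c) / 3 for c in CODONS])


@dataclass(frozen=True)
class IslandSpec:
    length_genes: int = 100
    gc_shift: float = -0.05
    codon_bias_weight: float = 3.0
    n_transposase: int = 8
    flank_trna: bool = True
    as_plasmid: bool = False


@dataclass(frozen=True)
class HitNoise:
    identity_sd: float = 0.0
    spurious_hit_rate: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``inversion_rate`` / ``translocation_rate`` are expected event counts per
    non-reference genome (a scalar) or an explicit per-genome sequence whose
    entry 0 applies to the reference. ``ortholog_loss_rate`` is the per-gene,
    per-non-reference-lineage loss probability, so a gene lineage survives in
    all n genomes with probability (1 - loss)^(n-1).
    """

    n_genomes: int = 5
    genes_per_genome: int = 1000
    mean_gene_len: int = 900
    background_gc: float = 0.63
    island_spec: IslandSpec | None = field(default_factory=IslandSpec)
    n_background_transposase: int = 2
    inversion_rate: float | tuple[float, ...] = 0.0
    translocation_rate: float | tuple[float, ...] = 0.0
    ortholog_loss_rate: float = 0.0
    clades: tuple[tuple[int, ...], ...] | None = None
    clade_genes: int = 0
    hit_noise: HitNoise = field(default_factory=HitNoise)
    spacer_len: int = 100
    seed: int = 0
    with_sequences: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.ortholog_loss_rate < 1:
            raise ValueError("ortholog_loss_rate must be in [0, 1)")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")
        if self.island_spec is not None:
            isl = self.island_spec
            if isl.length_genes >= self.genes_per_genome:
                raise ValueError("island length_genes must be < genes_per_genome")
            gc = self.background_gc + isl.gc_shift
            if not 0 < gc < 1:
                raise ValueError("island GC (background + shift) outside (0, 1)")
            if isl.n_transposase > isl.length_genes:
                raise ValueError("n_transposase exceeds island length_genes")
        if self.clades is not None:
            flat = [g for cl in self.clades for g in cl]
            if any(g >= self.n_genomes or g < 0 for g in flat):
                raise ValueError("clade genome index out of range")
            if self.clade_genes * len(self.clades) > self.genes_per_genome:
                raise ValueError("clade_genes exceed the ancestral gene pool")

    def rate_for(self, which: str, genome_index: int) -> float:
        rate = getattr(self, f"{which}_rate")
        if isinstance(rate, (int, float)):
            return 0.0 if genome_index == 0 else float(rate)
        return float(rate[genome_index])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("island_spec") is not None:
            raw["island_spec"] = IslandSpec(**raw["island_spec"])
        if raw.get("hit_noise") is not None:
            raw["hit_noise"] = HitNoise(**raw["hit_noise"])
        if raw.get("clades") is not None:
            raw["clades"] = tuple(tuple(c) for c in raw["clades"])
        for key in ("inversion_rate", "translocation_rate"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground-truth bookkeeping for a simulated cohort."""

    # (genome_a, genome_b) with a < b -> list of (gene_a, gene_b)
    ortholog_map: dict[tuple[str, str], list[tuple[str, str]]]
    # (genome_a, genome_b) -> list of (a_start_rank, a_end_rank, orientation, length)
    planted_blocks: dict[tuple[str, str], list[tuple[int, int, str, int]]]
    island_regions: list[tuple[str, str, int, int]]  # genome, replicon, start, end (1-based)
    transposase_ids: dict[str, list[str]]
    trna_anchor_ids: dict[str, list[str]]
    codon_tallies: dict[str, dict[str, int]]  # per-genome codon sampling tallies
    gene_lengths: dict[str, int]  # protein lengths (aa) by gene id, all genomes


# ---------------------------------------------------------------------------
# Composition model
# ---------------------------------------------------------------------------

def _codon_probs_from_base_gc(gc: float) -> np.ndarray:
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    return np.array([p[a] * p[b] * p[c] for a, b, c in CODONS])


def codon_distribution(
    target_gc: float,
    bias_codons: Sequence[str] = (),
    bias_weight: float = 1.0,
) -> np.ndarray:
    """A 64-codon sampling distribution with exact expected GC.

    Starts from an independent-base model at the target GC, multiplies the
    weights of ``bias_codons`` by ``bias_weight``, then corrects the base GC
    by bisection so the biased distribution's expected GC equals
    ``target_gc`` again.
    """
    bias = np.ones(len(CODONS))
    for c in bias_codons:
        bias[_CODON_INDEX[c]] = bias_weight

    def dist(base_gc: float) -> np.ndarray:
        q = _codon_probs_from_base_gc(base_gc) * bias
        return q / q.sum()

    if bias_weight == 1.0 or not bias_codons:
        return dist(target_gc)
    lo, hi = 0.02, 0.98
    for _ in range(60):
        mid = (lo + hi) / 2
        if float(dist(mid) @ _CODON_GC) < target_gc:
            lo = mid
        else:
            hi = mid
    return dist((lo + hi) / 2)


def _codons_to_seq(idx: np.ndarray) -> str:
    return "".join(_CODON_ARR[idx])


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("AGCT"))[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# Rearrangement operators
# ---------------------------------------------------------------------------

def apply_inversion(gene_order: Sequence[tuple], i: int, j: int) -> list[tuple]:
    """Reverse segment [i..j] of a (gene, strand) order, flipping strands."""
    n = len(gene_order)
    if not (0 <= i <= j < n):
        raise IndexError(f"inversion indices ({i}, {j}) out of range for n={n}")
    flip = {"+": "-", "-": "+"}
    seg = [(*g[:-1], flip[g[-1]]) for g in reversed(gene_order[i : j + 1])]
    return list(gene_order[:i]) + seg + list(gene_order[j + 1 :])


def apply_translocation(
    gene_order: Sequence[tuple], i: int, j: int, dest: int
) -> list[tuple]:
    """Move segment [i..j] so it starts at position ``dest`` of the remainder."""
    n = len(gene_order)
    if not (0 <= i <= j < n):
        raise IndexError(f"translocation indices ({i}, {j}) out of range for n={n}")
    seg = list(gene_order[i : j + 1])
    rest = list(gene_order[:i]) + list(gene_order[j + 1 :])
    if not 0 <= dest <= len(rest):
        raise IndexError(f"translocation destination {dest} out of range")
    return rest[:dest] + seg + rest[dest:]


# ---------------------------------------------------------------------------
# Truth synteny blocks (independent rank-difference scan)
# ---------------------------------------------------------------------------

def _truth_blocks_for_pair(
    order_a: Sequence[tuple[object, str]],
    order_b: Sequence[tuple[object, str]],
    min_block: int = 2,
) -> list[tuple[int, int, str, int]]:
    """Greedy left-to-right maximal perfectly conserved runs.

    Orders are (gene_key, strand) lists; keys present in only one order
    (lost genes, island genes, tRNAs) break runs. Returned ranks index the
    full ``order_a`` list, matching annotation gene ranks.
    """
    keys_b = {g for g, _ in order_b}
    pos_b = {g: (r, s) for r, (g, s) in enumerate(order_b)}
    blocks: list[tuple[int, int, str, int]] = []
    run_start = None
    run_dir = 0
    prev: tuple[int, int, int] | None = None  # a_rank, b_rank, concordance

    def close(a_end: int, length: int) -> None:
        if length >= min_block:
            blocks.append(
                (run_start, a_end, "forward" if run_dir == 1 else "inverted", length)
            )

    run_len = 0
    for a_rank, (g, s) in enumerate(order_a):
        if g not in keys_b:
            if prev is not None:
                close(prev[0], run_len)
            prev, run_start, run_dir, run_len = None, None, 0, 0
            continue
        b_rank, b_s = pos_b[g]
        concord = 1 if s == b_s else -1
        if prev is not None:
            pa, pb, pc = prev
            step = b_rank - pb
            ok = (
                a_rank == pa + 1
                and pc == concord
                and (
                    (concord == 1 and step == 1 and run_dir in (0, 1))
                    or (concord == -1 and step == -1 and run_dir in (0, -1))
                )
            )
            if ok:
                run_dir = 1 if concord == 1 else -1
                run_len += 1
                prev = (a_rank, b_rank, concord)
                continue
            close(pa, run_len)
        run_start, run_dir, run_len = a_rank, 0, 1
        prev = (a_rank, b_rank, concord)
    if prev is not None:
        close(prev[0], run_len)
    return blocks


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimConfig,
) -> tuple[list[GenomeAnnotation], dict[tuple[str, str], list[dict]], SimTruth]:
    """Generate a cohort: annotations, directed hit tables, and truth.

    Returns ``(annotations, hit_tables, truth)`` where ``hit_tables`` maps
    each ordered genome pair (query genome, subject genome) to a list of
    outfmt-6 row dicts. Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes
    ng = config.genes_per_genome
    genome_ids = [f"G{i}" for i in range(n)]
    isl = config.island_spec

    # --- ancestral gene complement ---------------------------------------
    mean_codons = max(30, config.mean_gene_len // 3)
    anc_codons = np.maximum(
        30, np.round(rng.normal(mean_codons, mean_codons / 6, size=ng)).astype(int)
    )
    anc_strands = np.where(rng.random(ng) < 0.5, "+", "-")
    bg_dist = codon_distribution(config.background_gc)
    anc_seqs: list[str] = [""] * ng
    anc_gene_tally = np.zeros((ng, len(CODONS)), dtype=np.int64)
    if config.with_sequences:
        for k in range(ng):
            idx = rng.choice(len(CODONS), size=int(anc_codons[k]), p=bg_dist)
            anc_gene_tally[k] = np.bincount(idx, minlength=len(CODONS))
            anc_seqs[k] = _codons_to_seq(idx)

    # --- clade-specific gene content --------------------------------------
    clade_of_gene: dict[int, set[int]] = {}
    if config.clades and config.clade_genes:
        pool = rng.permutation(ng)
        off = 0
        for clade in config.clades:
            for x in pool[off : off + config.clade_genes]:
                clade_of_gene[int(x)] = set(clade)
            off += config.clade_genes

    # --- presence per genome (reference keeps all non-clade genes) --------
    presence = np.ones((n, ng), dtype=bool)
    for gi in range(1, n):
        presence[gi] &= rng.random(ng) >= config.ortholog_loss_rate
    for gidx, members in clade_of_gene.items():
        for gi in range(n):
            presence[gi, gidx] = gi in members

    # --- background transposases ------------------------------------------
    bg_tnp = {
        int(x)
        for x in rng.choice(ng, size=min(config.n_background_transposase, ng), replace=False)
    }

    # --- ancestral gene orders per genome, then rearrangements ------------
    orders: list[list[tuple[int, str]]] = []
    for gi in range(n):
        order: list[tuple[int, str]] = [
            (k, str(anc_strands[k])) for k in range(ng) if presence[gi, k]
        ]
        for _ in range(rng.poisson(config.rate_for("inversion", gi))):
            m = len(order)
            i, j = sorted(int(x) for x in rng.integers(0, m, size=2))
            order = apply_inversion(order, i, j)
        for _ in range(rng.poisson(config.rate_for("translocation", gi))):
            m = len(order)
            i = int(rng.integers(0, m))
            j = min(m - 1, i + int(rng.integers(1, max(2, m // 20))))
            order = apply_translocation(order, i, j, int(rng.integers(0, m - (j - i))))
        orders.append(order)

    # --- island content ----------------------------------------------------
    # Island/tRNA entries carry string keys ("isl:t", "trna") so they can sit
    # in the same order lists as ancestral int keys without ever matching one.
    island_entries: list[tuple[str, str]] = []
    island_gene_data: dict[str, tuple[str, int, bool]] = {}  # key -> seq, n_codons, tnp
    isl_tally = np.zeros(len(CODONS), dtype=np.int64)
    island_insert_at = 0
    if isl is not None:
        island_dist = codon_distribution(
            config.background_gc + isl.gc_shift, BIASED_CODONS, isl.codon_bias_weight
        )
        tnp_slots = {
            int(x) for x in rng.choice(isl.length_genes, size=isl.n_transposase, replace=False)
        }
        if isl.flank_trna:
            island_entries.append(("trna", "+"))
        for t in range(isl.length_genes):
            k = max(30, int(round(rng.normal(mean_codons, mean_codons / 6))))
            seq = ""
            if config.with_sequences:
                idx = rng.choice(len(CODONS), size=k, p=island_dist)
                isl_tally += np.bincount(idx, minlength=len(CODONS))
                seq = _codons_to_seq(idx)
            key = f"isl:{t}"
            island_gene_data[key] = (seq, k, t in tnp_slots)
            island_entries.append((key, "+" if t % 3 else "-"))
        if not isl.as_plasmid:
            island_insert_at = int(rng.integers(len(orders[0]) // 4, 3 * len(orders[0]) // 4))

    # --- final per-genome orders (with the island spliced in) -------------
    full_orders: list[list[tuple[object, str]]] = []
    plasmid_order: list[tuple[object, str]] = []
    for gi in range(n):
        fo: list[tuple[object, str]] = list(orders[gi])
        if isl is not None and gi == 0:
            if isl.as_plasmid:
                plasmid_order = list(island_entries)
            else:
                fo = fo[:island_insert_at] + list(island_entries) + fo[island_insert_at:]
        full_orders.append(fo)

    # --- assemble annotations ----------------------------------------------
    annotations: list[GenomeAnnotation] = []
    truth_islands: list[tuple[str, str, int, int]] = []
    tnp_ids: dict[str, list[str]] = {}
    trna_ids: dict[str, list[str]] = {}
    tallies: dict[str, dict[str, int]] = {}
    gene_lengths: dict[str, int] = {}
    sp = config.spacer_len
    trna_len = 75

    def _build_replicon(
        gid: str, rep_id: str, order: Sequence[tuple[object, str]], island_here: bool
    ) -> tuple[Replicon, tuple[int, int] | None]:
        pos = 1
        parts: list[str] = []
        genes: list[GeneRecord] = []
        island_start = None
        island_end = None
        for key, strand in order:
            if config.with_sequences:
                parts.append(_random_bases(rng, sp, config.background_gc))
            pos += sp
            if key == "trna":
                gene_id, length, seq = f"{gid}_trnaGly", trna_len, ""
                is_trna, is_tnp, plen = True, False, None
            elif isinstance(key, str):  # island gene
                seq, n_cod, is_tnp = island_gene_data[key]
                t = int(key.split(":")[1])
                gene_id, length, plen = f"{gid}_isl{t:04d}", n_cod * 3, n_cod
                is_trna = False
                if island_start is None:
                    island_start = pos
                island_end = pos + length - 1
            else:
                k = key
                seq, n_cod = anc_seqs[k], int(anc_codons[k])
                gene_id, length, plen = f"{gid}_{k:05d}", n_cod * 3, n_cod
                is_trna, is_tnp = False, k in bg_tnp
            start, end = pos, pos + length - 1
            if config.with_sequences:
                body = seq if not is_trna else _random_bases(rng, trna_len, config.background_gc)
                parts.append(body if strand == "+" else _revcomp(body))
            pos = end + 1
            genes.append(
                GeneRecord(
                    gene_id=gene_id, replicon_id=rep_id, start=start, end=end,
                    strand=strand, rank=len(genes), is_transposase=is_tnp,
                    is_trna=is_trna, trna_isotype="Gly" if is_trna else None,
                    protein_length=plen,
                )
            )
            if plen is not None:
                gene_lengths[gene_id] = plen
        if config.with_sequences:
            parts.append(_random_bases(rng, sp, config.background_gc))
        rep = Replicon(rep_id, circular=True, sequence="".join(parts), genes=genes)
        span = (island_start, island_end) if island_start is not None else None
        return rep, span

    for gi, gid in enumerate(genome_ids):
        chr_rep, chr_span = _build_replicon(gid, f"{gid}_chr", full_orders[gi], gi == 0)
        replicons = [chr_rep]
        if chr_span is not None:
            truth_islands.append((gid, chr_rep.replicon_id, chr_span[0], chr_span[1]))
        if gi == 0 and plasmid_order:
            p_rep, p_span = _build_replicon(gid, f"{gid}_p1", plasmid_order, True)
            replicons.append(p_rep)
            if p_span is not None:
                truth_islands.append((gid, p_rep.replicon_id, p_span[0], p_span[1]))
        annot = GenomeAnnotation(genome_id=gid, replicons=replicons)
        annotations.append(annot)
        tnp_ids[gid] = [g.gene_id for g in annot.iter_genes() if g.is_transposase]
        trna_ids[gid] = [g.gene_id for g in annot.iter_genes() if g.is_trna]
        if config.with_sequences:
            t = anc_gene_tally[presence[gi]].sum(axis=0)
            if gi == 0 and isl is not None:
                t = t + isl_tally
            tallies[gid] = {CODONS[i]: int(t[i]) for i in np.flatnonzero(t)}
        else:
            tallies[gid] = {}

    # --- truth: ortholog map and planted blocks ----------------------------
    ortholog_map: dict[tuple[str, str], list[tuple[str, str]]] = {}
    planted_blocks: dict[tuple[str, str], list[tuple[int, int, str, int]]] = {}
    for a in range(n):
        for b in range(a + 1, n):
            ga, gb = genome_ids[a], genome_ids[b]
            both = presence[a] & presence[b]
            ortholog_map[(ga, gb)] = [
                (f"{ga}_{k:05d}", f"{gb}_{k:05d}") for k in np.flatnonzero(both)
            ]
            planted_blocks[(ga, gb)] = _truth_blocks_for_pair(full_orders[a], full_orders[b])

    # --- hit tables ---------------------------------------------------------
    hit_tables: dict[tuple[str, str], list[dict]] = {}
    noise = config.hit_noise
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            ga, gb = genome_ids[a], genome_ids[b]
            rows: list[dict] = []
            both = presence[a] & presence[b]
            for k in np.flatnonzero(both):
                qid, sid = f"{ga}_{k:05d}", f"{gb}_{k:05d}"
                qlen = int(anc_codons[k])
                ident = 88.0
                if noise.identity_sd:
                    ident = float(np.clip(rng.normal(88.0, noise.identity_sd), 40.0, 100.0))
                bits = round(2.0 * (ident / 100.0) * qlen, 1)
                ev = 10.0 ** (-min(180.0, bits / 10.0))
                rows.append(
                    dict(
                        qseqid=qid, sseqid=sid, pident=round(ident, 1), length=qlen,
                        mismatch=int(round(qlen * (1 - ident / 100))), gapopen=0,
                        qstart=1, qend=qlen, sstart=1, send=qlen,
                        evalue=f"{ev:.2e}", bitscore=bits,
                    )
                )
            n_spur = rng.poisson(noise.spurious_hit_rate * ng)
            a_ids = [f"{ga}_{k:05d}" for k in np.flatnonzero(presence[a])]
            b_ids = [f"{gb}_{k:05d}" for k in np.flatnonzero(presence[b])]
            for _ in range(n_spur):
                qid = a_ids[int(rng.integers(len(a_ids)))]
                sid = b_ids[int(rng.integers(len(b_ids)))]
                alen = int(rng.integers(30, 80))
                rows.append(
                    dict(  # identity and bit score both below the RBH cutoffs
                        qseqid=qid, sseqid=sid,
                        pident=round(float(rng.uniform(20.0, 28.0)), 1), length=alen,
                        mismatch=alen // 2, gapopen=1, qstart=1, qend=alen,
                        sstart=1, send=alen, evalue=f"{rng.uniform(1e-4, 1.0):.2e}",
                        bitscore=round(float(rng.uniform(30.0, 55.0)), 1),
                    )
                )
            hit_tables[(ga, gb)] = rows

    truth = SimTruth(
        ortholog_map=ortholog_map,
        planted_blocks=planted_blocks,
        island_regions=truth_islands,
        transposase_ids=tnp_ids,
        trna_anchor_ids=trna_ids,
        codon_tallies=tallies,
        gene_lengths=gene_lengths,
    )
    return annotations, hit_tables, truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def emit_files(
    cohort: tuple[list[GenomeAnnotation], dict[tuple[str, str], list[dict]], SimTruth],
    out_dir: str | Path,
) -> dict[str, list[Path]]:
    """Write the cohort as FASTA + GFF3 per genome, one directed hit table per
    ordered genome pair, and truth TSVs. Returns the written paths by kind."""
    annotations, hit_tables, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[Path]] = {"fasta": [], "gff3": [], "hits": [], "truth": []}
    for annot in annotations:
        fa = out / f"{annot.genome_id}.fasta"
        write_fasta([(r.replicon_id, r.sequence) for r in annot.replicons if r.sequence], fa)
        written["fasta"].append(fa)
        gff = out / f"{annot.genome_id}.gff3"
        write_gff3(annot, gff)
        written["gff3"].append(gff)
    for (ga, gb), rows in sorted(hit_tables.items()):
        p = out / f"hits_{ga}_vs_{gb}.tsv"
        write_blast_tab(rows, p)
        written["hits"].append(p)

    p = out / "truth_orthologs.tsv"
    with open(p, "w") as fh:
        fh.write("genome_a\tgene_a\tgenome_b\tgene_b\n")
        for (ga, gb), pairs in sorted(truth.ortholog_map.items()):
            for a_id, b_id in pairs:
                fh.write(f"{ga}\t{a_id}\t{gb}\t{b_id}\n")
    written["truth"].append(p)

    p = out / "truth_islands.tsv"
    with open(p, "w") as fh:
        fh.write("genome_id\treplicon_id\tstart\tend\n")
        for row in truth.island_regions:
            fh.write("\t".join(map(str, row)) + "\n")
    written["truth"].append(p)

    p = out / "truth_blocks.tsv"
    with open(p, "w") as fh:
        fh.write("genome_a\tgenome_b\ta_start_rank\ta_end_rank\torientation\tlength\n")
        for (ga, gb), blocks in sorted(truth.planted_blocks.items()):
            for srt, end, orient, length in blocks:
                fh.write(f"{ga}\t{gb}\t{srt}\t{end}\t{orient}\t{length}\n")
    written["truth"].append(p)

    p = out / "truth_gene_flags.tsv"
    with open(p, "w") as fh:
        fh.write("genome_id\tgene_id\tflag\n")
        for gid in sorted(truth.transposase_ids):
            for x in truth.transposase_ids[gid]:
                fh.write(f"{gid}\t{x}\ttransposase\n")
        for gid in sorted(truth.trna_anchor_ids):
            for x in truth.trna_anchor_ids[gid]:
                fh.write(f"{gid}\t{x}\ttrna\n")
    written["truth"].append(p)

    p = out / "truth_gene_lengths.tsv"
    with open(p, "w") as fh:
        fh.write("gene_id\tprotein_length\n")
        for gid in sorted(truth.gene_lengths):
            fh.write(f"{gid}\t{truth.gene_lengths[gid]}\n")
    written["truth"].append(p)
    return written
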