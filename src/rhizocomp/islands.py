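"""Genomic-island characterization from four evidence classes.

Candidate regions come from a sliding-window GC z-score scan (plus every
plasmid replicon evaluated whole, encoding the hypothesis that small
replicons may be excised islands). Each candidate is then annotated with:

1. GC deviation (percentage points) against the replicon backbone;
2. codon-usage divergence of its genes against the backbone genes, as a
   Euclidean distance between RSCU vectors with the lysine family excluded
   by default (its usage is too variable to be informative), tested by
   gene-label permutation;
3. transposase enrichment — the fraction of the genome's transposase genes
   concentrated in the region;
4. presence of a tRNA gene adjacent to a region boundary (a classical
   island integration signature).

The evidence score (0-4) counts how many of the four signals clear their
configurable thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    CODONS,
    SYNONYMOUS_FAMILIES,
    GeneRecord,
    GenomeAnnotation,
    Replicon,
    gc_content,
)

__all__ = [
    "IslandParams",
    "IslandCall",
    "gc_deviation_scan",
    "rscu_divergence",
    "transposase_enrichment",
    "trna_adjacency",
    "call_islands",
    "replicon_report",
    "island_calls_to_bed",
]

_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class IslandParams:
    window: int = 5000
    step: int = 1000
    gc_z_threshold: float = 2.0
    min_island_len: int = 10_000
    merge_gap: int = 5_000
    rscu_n_perm: int = 1000
    trna_max_dist: int = 5_000
    excluded_amino_acids: frozenset[str] = frozenset({"Lys"})
    # evidence-score thresholds
    gc_dev_pp_min: float = 1.5
    rscu_p_max: float = 0.05
    transposase_fraction_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("window", "step", "min_island_len", "merge_gap", "rscu_n_perm", "trna_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class IslandCall:
    genome_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int
    gc_percent: float
    gc_deviation_pp: float
    rscu_distance: float
    rscu_pvalue: float
    transposase_count: int
    transposase_fraction_of_genome: float  # nan when the genome has none
    trna_adjacent: bool
    trna_isotype: str | None
    trna_distance_bp: int | None
    evidence_score: int
    low_power: bool = False  # region had < 10 genes for the codon-usage test
    source: str = "gc_scan"  # "gc_scan" | "plasmid"

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# GC deviation scan
# ---------------------------------------------------------------------------

def _window_gc(seq: str, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """(window_starts (1-based), gc fraction per window); N bases excluded."""
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
    is_acgt = (codes >= 0).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_gc)])
    ct = np.concatenate([[0], np.cumsum(is_acgt)])
    n = len(seq)
    starts0 = np.arange(0, n - window + 1, step)
    gc_cnt = cg[starts0 + window] - cg[starts0]
    tot = ct[starts0 + window] - ct[starts0]
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(tot > 0, gc_cnt / np.maximum(tot, 1), np.nan)
    return starts0 + 1, gc


def gc_deviation_scan(
    replicon: Replicon, params: IslandParams = IslandParams()
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Window GC z-scores and merged candidate spans for one replicon.

    Windows are z-scored against the replicon's own window-GC mean/sd; runs
    of windows with |z| >= ``gc_z_threshold`` merge when separated by at
    most ``merge_gap`` bp, and merged spans shorter than
    ``min_island_len`` are dropped. Returns (window table, spans) with
    1-based inclusive span coordinates.
    """
    if replicon.length < params.window:
        raise ValueError(
            f"replicon {replicon.replicon_id} ({replicon.length} bp) shorter "
            f"than window {params.window}"
        )
    starts, gc = _window_gc(replicon.sequence, params.window, params.step)
    mu = float(np.nanmean(gc))
    sd = float(np.nanstd(gc))
    z = (gc - mu) / sd if sd > 0 else np.zeros_like(gc)
    df = pd.DataFrame({"window_start": starts, "gc": gc, "z": z})
    hot = np.abs(z) >= params.gc_z_threshold  # nan windows never trigger
    spans: list[tuple[int, int]] = []
    cur: list[int] | None = None
    for s, h in zip(starts, hot):
        if not h:
            continue
        w_start, w_end = int(s), int(s) + params.window - 1
        if cur is not None and w_start - cur[1] - 1 <= params.merge_gap:
            cur[1] = max(cur[1], w_end)
        else:
            if cur is not None:
                spans.append((cur[0], cur[1]))
            cur = [w_start, w_end]
    if cur is not None:
        spans.append((cur[0], cur[1]))
    spans = [(a, b) for a, b in spans if b - a + 1 >= params.min_island_len]
    return df, spans


# ---------------------------------------------------------------------------
# Codon-usage divergence
# ---------------------------------------------------------------------------

def _codon_vector(seq: str) -> np.ndarray:
    """64-long codon count vector; codons with N are skipped."""
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    codes = _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)].astype(np.int64)
    tri = codes.reshape(-1, 3)
    ok = (tri >= 0).all(axis=1)
    vals = tri[ok] @ np.array([16, 4, 1])
    return np.bincount(vals, minlength=64)


def _included_families(excluded: Iterable[str]) -> list[np.ndarray]:
    fams = []
    for aa, codons in sorted(SYNONYMOUS_FAMILIES.items()):
        if aa in set(excluded) or len(codons) == 1:
            continue
        fams.append(np.array([_CODON_INDEX[c] for c in codons]))
    return fams


def _rscu_vec(counts: np.ndarray, fams: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenated RSCU over the included families; zero-usage families
    contribute the uniform value 1 so they never inflate the distance."""
    parts = []
    for fam in fams:
        tot = counts[fam].sum()
        if tot > 0:
            parts.append(counts[fam] * len(fam) / tot)
        else:
            parts.append(np.ones(len(fam)))
    return np.concatenate(parts)


def rscu_divergence(
    genes_region: Sequence[str] | Sequence[np.ndarray],
    genes_backbone: Sequence[str] | Sequence[np.ndarray],
    params: IslandParams = IslandParams(),
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Codon-usage distance between two gene sets with a permutation p-value.

    Gene inputs are CDS strings or precomputed 64-long codon-count vectors.
    Distance is the Euclidean norm of the difference between the two sets'
    RSCU vectors over the included amino-acid families (lysine excluded by
    default). The p-value shuffles gene labels between the sets
    ``rscu_n_perm`` times: p = (1 + #{perm >= observed}) / (1 + n_perm).
    Returns (distance, p, low_power) where low_power marks a region of
    fewer than 10 genes.
    """
    if len(genes_region) == 0 or len(genes_backbone) == 0:
        raise ValueError("both gene sets must be non-empty")

    def as_counts(genes) -> np.ndarray:
        rows = [g if isinstance(g, np.ndarray) else _codon_vector(g) for g in genes]
        return np.vstack(rows)

    reg = as_counts(genes_region)
    back = as_counts(genes_backbone)
    fams = _included_families(params.excluded_amino_acids)
    obs = float(
        np.linalg.norm(_rscu_vec(reg.sum(0), fams) - _rscu_vec(back.sum(0), fams))
    )
    pool = np.vstack([reg, back])
    n1 = len(reg)
    rng = np.random.default_rng(seed)
    total = pool.sum(0)
    hits = 0
    for _ in range(params.rscu_n_perm):
        idx = rng.permutation(len(pool))
        s1 = pool[idx[:n1]].sum(0)
        d = float(np.linalg.norm(_rscu_vec(s1, fams) - _rscu_vec(total - s1, fams)))
        if d >= obs:
            hits += 1
    p = (1 + hits) / (1 + params.rscu_n_perm)
    return obs, p, len(reg) < 10


# ---------------------------------------------------------------------------
# Content evidence
# ---------------------------------------------------------------------------

def _genes_in_span(rep: Replicon, start: int, end: int) -> list[GeneRecord]:
    """Genes whose midpoint falls inside [start, end]."""
    return [g for g in rep.genes if start <= (g.start + g.end) // 2 <= end]


def transposase_enrichment(
    annot: GenomeAnnotation, region: tuple[str, int, int] | str
) -> tuple[int, float]:
    """(transposases inside the region, fraction of the genome's total).

    ``region`` is (replicon_id, start, end) or a bare replicon id meaning
    the whole replicon. Fraction is nan when the genome has no transposases.
    """
    total = sum(1 for g in annot.iter_genes() if g.is_transposase)
    if isinstance(region, str):
        rep = annot.replicons_by_id[region]
        inside = sum(1 for g in rep.genes if g.is_transposase)
    else:
        rep_id, start, end = region
        rep = annot.replicons_by_id[rep_id]
        inside = sum(1 for g in _genes_in_span(rep, start, end) if g.is_transposase)
    frac = inside / total if total else math.nan
    return inside, frac


def trna_adjacency(
    annot: GenomeAnnotation,
    region: tuple[str, int, int],
    params: IslandParams = IslandParams(),
) -> tuple[bool, str | None, int | None]:
    """Is a tRNA gene near a region boundary?

    True when a tRNA lies within ``trna_max_dist`` bp of either boundary
    (outside the span) or inside the span within one window of a boundary.
    Distances on circular replicons wrap around the origin. Returns
    (flag, nearest isotype, distance bp).
    """
    rep_id, start, end = region
    rep = annot.replicons_by_id[rep_id]
    L = rep.length or max((g.end for g in rep.genes), default=0)
    best: tuple[int, str | None] | None = None
    for g in rep.genes:
        if not g.is_trna:
            continue
        if start <= g.start and g.end <= end:  # inside: distance to nearest boundary
            d = min(g.start - start, end - g.end)
            reach = params.window
        else:
            # gap = bases strictly between the tRNA edge and the span boundary
            cands = []
            if g.end < start:
                cands.append(start - g.end - 1)
            if g.start > end:
                cands.append(g.start - end - 1)
            if rep.circular and L:
                if g.start > end:
                    cands.append(L - g.end + start - 1)
                if g.end < start:
                    cands.append(L - end + g.start - 1)
            if not cands:  # straddles a boundary
                cands.append(0)
            d = min(cands)
            reach = params.trna_max_dist
        if d <= reach and (best is None or d < best[0]):
            best = (d, g.trna_isotype)
    if best is None:
        return False, None, None
    return True, best[1], best[0]


# ---------------------------------------------------------------------------
# Island calling
# ---------------------------------------------------------------------------

def _region_backbone_split(
    annot: GenomeAnnotation, rep: Replicon, start: int, end: int
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    inside = _genes_in_span(rep, start, end)
    inside_ids = {g.gene_id for g in inside}
    backbone = [
        g
        for g in annot.iter_genes()
        if g.gene_id not in inside_ids and not g.is_trna
    ]
    inside = [g for g in inside if not g.is_trna]
    return inside, backbone


def call_islands(
    annot: GenomeAnnotation,
    params: IslandParams = IslandParams(),
    seed: int = 0,
) -> list[IslandCall]:
    """Call candidate genomic islands on one genome.

    Candidates are GC-deviant spans from :func:`gc_deviation_scan` on every
    replicon, plus each plasmid (any replicon but the longest) evaluated
    whole regardless of GC. Each candidate is annotated with all four
    evidence classes; the evidence score counts |GC deviation| >=
    ``gc_dev_pp_min`` pp, permutation p <= ``rscu_p_max``, transposase
    fraction >= ``transposase_fraction_min``, and tRNA adjacency. Calls are
    sorted by evidence score then length, both descending.
    """
    if not annot.replicons:
        return []
    chromosome = max(annot.replicons, key=lambda r: r.length)
    calls: list[IslandCall] = []
    for rep in annot.replicons:
        is_plasmid = rep is not chromosome and len(annot.replicons) > 1
        candidates: list[tuple[int, int, str]] = []
        if is_plasmid:
            # a plasmid is always one whole-replicon candidate (excised-island
            # hypothesis); its internal GC structure is not re-segmented
            candidates.append((1, max(1, rep.length or max(g.end for g in rep.genes)), "plasmid"))
        elif rep.length >= params.window:
            _, spans = gc_deviation_scan(rep, params)
            candidates.extend((a, b, "gc_scan") for a, b in spans)
        for start, end, source in candidates:
            region_seq = rep.sequence[start - 1 : end] if rep.sequence else ""
            backbone_seq = (
                (rep.sequence[: start - 1] + rep.sequence[end:]) if rep.sequence else ""
            )
            if source == "plasmid" and rep.sequence:
                backbone_seq = chromosome.sequence
            try:
                gc_pct = gc_content(region_seq, ndigits=None) if region_seq else math.nan
                back_gc = gc_content(backbone_seq, ndigits=None) if backbone_seq else math.nan
            except ValueError:
                gc_pct = back_gc = math.nan
            gc_dev = gc_pct - back_gc if not (math.isnan(gc_pct) or math.isnan(back_gc)) else math.nan

            inside, backbone = _region_backbone_split(annot, rep, start, end)
            if source == "plasmid":
                backbone = [g for g in chromosome.genes if not g.is_trna]
            if inside and backbone and rep.sequence:
                reps_by_id = annot.replicons_by_id
                reg_seqs = [rep.gene_sequence(g) for g in inside]
                back_seqs = [reps_by_id[g.replicon_id].gene_sequence(g) for g in backbone]
                dist, pval, low_power = rscu_divergence(reg_seqs, back_seqs, params, seed)
            else:
                dist, pval, low_power = math.nan, math.nan, True

            region = (rep.replicon_id, start, end)
            tnp_n, tnp_frac = transposase_enrichment(annot, region)
            flag, isotype, tdist = trna_adjacency(annot, region, params)

            score = 0
            if not math.isnan(gc_dev) and abs(gc_dev) >= params.gc_dev_pp_min:
                score += 1
            if not math.isnan(pval) and pval <= params.rscu_p_max:
                score += 1
            if not math.isnan(tnp_frac) and tnp_frac >= params.transposase_fraction_min:
                score += 1
            if flag:
                score += 1
            calls.append(
                IslandCall(
                    genome_id=annot.genome_id,
                    replicon_id=rep.replicon_id,
                    start=start,
                    end=end,
                    gc_percent=gc_pct,
                    gc_deviation_pp=gc_dev,
                    rscu_distance=dist,
                    rscu_pvalue=pval,
                    transposase_count=tnp_n,
                    transposase_fraction_of_genome=tnp_frac,
                    trna_adjacent=flag,
                    trna_isotype=isotype,
                    trna_distance_bp=tdist,
                    evidence_score=score,
                    low_power=low_power,
                    source=source,
                )
            )
    calls.sort(key=lambda c: (-c.evidence_score, -c.length_bp, c.replicon_id, c.start))
    return calls


def island_calls_to_bed(calls: Sequence[IslandCall]) -> str:
    """BED (0-based half-open) lines for a set of calls."""
    lines = []
    for c in calls:
        lines.append(
            f"{c.replicon_id}\t{c.start - 1}\t{c.end}\t"
            f"{c.genome_id}_island\t{c.evidence_score}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Replicon report
# ---------------------------------------------------------------------------

def replicon_report(annotations: Sequence[GenomeAnnotation], ndigits: int = 2) -> pd.DataFrame:
    """Per-replicon (and genome-total) size, GC, CDS/transposase/tRNA counts."""
    rows = []
    for annot in annotations:
        tot_len = 0
        tot_cds = tot_tnp = tot_trna = 0
        gc_num = 0.0
        gc_den = 0
        for rep in annot.replicons:
            cds = sum(1 for g in rep.genes if not g.is_trna)
            tnp = sum(1 for g in rep.genes if g.is_transposase)
            trna = sum(1 for g in rep.genes if g.is_trna)
            size = rep.length
            gc = gc_content(rep.sequence, ndigits) if rep.sequence else math.nan
            rows.append(
                {
                    "genome_id": annot.genome_id,
                    "replicon_id": rep.replicon_id,
                    "size_bp": size,
                    "gc_percent": gc,
                    "n_cds": cds,
                    "n_transposase": tnp,
                    "n_trna": trna,
                }
            )
            tot_len += size
            tot_cds += cds
            tot_tnp += tnp
            tot_trna += trna
            if rep.sequence:
                s = rep.sequence
                acgt = sum(s.count(b) for b in "ACGT")
                gc_num += s.count("G") + s.count("C")
                gc_den += acgt
        rows.append(
            {
                "genome_id": annot.genome_id,
                "replicon_id": "TOTAL",
                "size_bp": tot_len,
                "gc_percent": round(100.0 * gc_num / gc_den, ndigits) if gc_den else math.nan,
                "n_cds": tot_cds,
                "n_transposase": tot_tnp,
                "n_trna": tot_trna,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        tnp_tot = df[df.replicon_id == "TOTAL"].set_index("genome_id")["n_transposase"]
        df["transposase_fraction"] = [
            (r.n_transposase / tnp_tot[r.genome_id]) if tnp_tot.get(r.genome_id) else math.nan
            for r in df.itertuples()
        ]
    return df
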