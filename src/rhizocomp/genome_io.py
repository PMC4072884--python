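"""Genome, annotation and similarity-hit I/O plus nucleotide/codon composition.

This module defines the in-memory model shared by the whole package — ordered,
stranded gene records on (possibly circular) replicons — together with readers
for the three interchange formats the pipeline consumes (FASTA, GFF3, BLAST
tabular outfmt 6) and the composition primitives used downstream: GC content,
sliding-window G-C skew, codon counts, relative synonymous codon usage (RSCU)
and the codon adaptation index (CAI).

Coordinates are 1-based inclusive throughout (GFF3 convention); BED-style
half-open coordinates appear only at export time in :mod:`rhizocomp.islands`.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "Replicon",
    "GenomeAnnotation",
    "HomologyHit",
    "CompositionParams",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gff3",
    "read_blast_tab",
    "write_blast_tab",
    "hits_from_rows",
    "gc_content",
    "gc_skew",
    "codon_counts",
    "rscu",
    "cai",
    "reference_weights",
    "CODONS",
    "SYNONYMOUS_FAMILIES",
    "STOP_CODONS",
    "TRANSPOSASE_KEYWORDS",
]

BASES = "ACGT"
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

# Standard genetic code (table 11 and table 1 agree for these assignments at
# the amino-acid level used here; bacterial reinitiation codons are irrelevant
# because only synonymous-family membership matters).
_GENETIC_CODE = {
    "TTT": "Phe", "TTC": "Phe", "TTA": "Leu", "TTG": "Leu",
    "CTT": "Leu", "CTC": "Leu", "CTA": "Leu", "CTG": "Leu",
    "ATT": "Ile", "ATC": "Ile", "ATA": "Ile", "ATG": "Met",
    "GTT": "Val", "GTC": "Val", "GTA": "Val", "GTG": "Val",
    "TCT": "Ser", "TCC": "Ser", "TCA": "Ser", "TCG": "Ser",
    "CCT": "Pro", "CCC": "Pro", "CCA": "Pro", "CCG": "Pro",
    "ACT": "Thr", "ACC": "Thr", "ACA": "Thr", "ACG": "Thr",
    "GCT": "Ala", "GCC": "Ala", "GCA": "Ala", "GCG": "Ala",
    "TAT": "Tyr", "TAC": "Tyr", "TAA": "*", "TAG": "*",
    "CAT": "His", "CAC": "His", "CAA": "Gln", "CAG": "Gln",
    "AAT": "Asn", "AAC": "Asn", "AAA": "Lys", "AAG": "Lys",
    "GAT": "Asp", "GAC": "Asp", "GAA": "Glu", "GAG": "Glu",
    "TGT": "Cys", "TGC": "Cys", "TGA": "*", "TGG": "Trp",
    "CGT": "Arg", "CGC": "Arg", "CGA": "Arg", "CGG": "Arg",
    "AGT": "Ser", "AGC": "Ser", "AGA": "Arg", "AGG": "Arg",
    "GGT": "Gly", "GGC": "Gly", "GGA": "Gly", "GGG": "Gly",
}

STOP_CODONS = frozenset(c for c, aa in _GENETIC_CODE.items() if aa == "*")

SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _aa in _GENETIC_CODE.items():
    if _aa != "*":
        SYNONYMOUS_FAMILIES.setdefault(_aa, ())
        SYNONYMOUS_FAMILIES[_aa] += (_c,)

TRANSPOSASE_KEYWORDS = ("transposase", "insertion sequence")


class ParseError(ValueError):
    """A malformed record in an input file."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coordinates, strand, order rank, and content flags."""

    gene_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive, >= start
    strand: str  # "+" or "-"
    rank: int    # 0-based position in replicon gene order (by start)
    is_transposase: bool = False
    is_trna: bool = False
    trna_isotype: str | None = None
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class Replicon:
    replicon_id: str
    circular: bool
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        for g in self.genes:
            if self.sequence and g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds replicon "
                    f"{self.replicon_id} length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_sequence(self, gene: GeneRecord) -> str:
        s = self.sequence[gene.start - 1 : gene.end]
        if gene.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


@dataclass
class GenomeAnnotation:
    """A genome as an ordered collection of replicons with ordered genes."""

    genome_id: str
    replicons: list[Replicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rep in self.replicons:
            for g in rep.genes:
                if g.gene_id in seen:
                    raise ValueError(f"duplicate gene_id {g.gene_id!r} in genome {self.genome_id}")
                seen.add(g.gene_id)

    def iter_genes(self) -> Iterable[GeneRecord]:
        for rep in self.replicons:
            yield from rep.genes

    @property
    def genes_by_id(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.iter_genes()}

    @property
    def replicons_by_id(self) -> dict[str, Replicon]:
        return {r.replicon_id: r for r in self.replicons}

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.replicons)


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise protein similarity record (BLAST outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float
    query_coverage: float  # 100 * alignment_length / query protein length, capped at 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity {self.percent_identity} outside [0, 100]")
        if not 0.0 <= self.query_coverage <= 100.0:
            raise ValueError(f"query_coverage {self.query_coverage} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} < 0")


@dataclass(frozen=True)
class CompositionParams:
    """Sliding-window parameters for composition scans (1-kb windows by default)."""

    window: int = 1000
    step: int = 1000
    ndigits: int = 2

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")


def normalize_sequence(seq: str) -> str:
    """Uppercase, RNA->DNA; restrict the alphabet to {A, C, G, T, N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC-core characters in sequence: {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record) FASTA file.

    Sequences are uppercased and U is normalized to T; record order is
    preserved. Raises :class:`ParseError` naming the offending line for an
    empty header or a record with no sequence.
    """
    path = Path(path)
    # Pre-scan for structural problems so errors can name line numbers;
    # Bio.SeqIO then does the actual parsing.
    header_line = None
    saw_seq = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header_line is not None and not saw_seq:
                    raise ParseError(f"{path}:{header_line}: record has no sequence")
                if not line[1:].strip():
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                saw_seq = False
            elif line.strip():
                if header_line is None:
                    raise ParseError(f"{path}:{lineno}: sequence before any header")
                saw_seq = True
    if header_line is not None and not saw_seq:
        raise ParseError(f"{path}:{header_line}: record has no sequence")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, normalize_sequence(str(rec.seq))))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write records wrapped at 70 columns."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(recs)


def read_gene_table(
    path_gff3: str | Path,
    genome_id: str,
    sequences: Mapping[str, str] | None = None,
    transposase_keywords: Sequence[str] = TRANSPOSASE_KEYWORDS,
) -> GenomeAnnotation:
    """Parse a GFF3 gene table into a :class:`GenomeAnnotation`.

    Ranks are assigned by start position within each replicon. A gene is
    flagged as a transposase when its ``product`` attribute contains any of
    ``transposase_keywords`` (case-insensitive); tRNA features get
    ``is_trna`` and, where the product looks like ``tRNA-Xyz``, the isotype.

    ``sequences`` optionally supplies replicon sequences (by id) so that
    coordinates can be validated against replicon length and downstream
    composition statistics can run; replicons present only in ``sequences``
    are carried through with empty gene lists.
    """
    db = gffutils.create_db(
        str(path_gff3), dbfn=":memory:", merge_strategy="error", keep_order=True
    )
    circular_ids: set[str] = set()
    for d in db.directives:
        # "sequence-region id start end" carries no topology; we accept an
        # optional "circular id" directive emitted by our own writer.
        if d.startswith("circular "):
            circular_ids.add(d.split(None, 1)[1].strip())
    per_replicon: dict[str, list[GeneRecord]] = {}
    seen_ids: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS", "tRNA"):
            continue
        fid = feat.id
        if fid in seen_ids:
            raise ValueError(f"duplicate feature ID {fid!r} in {path_gff3}")
        seen_ids.add(fid)
        product = (feat.attributes.get("product") or [""])[0]
        is_trna = feat.featuretype == "tRNA" or product.startswith("tRNA-")
        isotype = None
        if is_trna and "tRNA-" in product:
            isotype = product.split("tRNA-", 1)[1].split()[0] or None
        lowered = product.lower()
        is_tnp = any(k in lowered for k in transposase_keywords)
        plen = None
        if feat.featuretype == "CDS" and not is_trna:
            span = feat.end - feat.start + 1
            if span % 3 == 0:
                plen = span // 3
        per_replicon.setdefault(feat.seqid, []).append(
            GeneRecord(
                gene_id=fid,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                rank=-1,
                is_transposase=is_tnp,
                is_trna=is_trna,
                trna_isotype=isotype,
                protein_length=plen,
            )
        )
    sequences = dict(sequences or {})
    replicons = []
    rep_ids = list(per_replicon)
    for rid in sequences:
        if rid not in rep_ids:
            rep_ids.append(rid)
    for rid in rep_ids:
        genes = sorted(per_replicon.get(rid, []), key=lambda g: (g.start, g.gene_id))
        genes = [replace(g, rank=i) for i, g in enumerate(genes)]
        seq = sequences.get(rid, "")
        if seq:
            too_far = [g for g in genes if g.end > len(seq)]
            if too_far:
                g = too_far[0]
                raise ValueError(
                    f"feature {g.gene_id} extends to {g.end} beyond replicon "
                    f"{rid} length {len(seq)}"
                )
        replicons.append(Replicon(rid, circular=rid in circular_ids, sequence=seq, genes=genes))
    return GenomeAnnotation(genome_id=genome_id, replicons=replicons)


def write_gff3(annot: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3 (version pragma first, one line per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in annot.replicons:
            if rep.length:
                fh.write(f"##sequence-region {rep.replicon_id} 1 {rep.length}\n")
            if rep.circular:
                fh.write(f"##circular {rep.replicon_id}\n")
        for rep in annot.replicons:
            for g in rep.genes:
                ftype = "tRNA" if g.is_trna else "CDS"
                attrs = [f"ID={g.gene_id}"]
                if g.is_trna:
                    attrs.append(f"product=tRNA-{g.trna_isotype or 'Xxx'}")
                elif g.is_transposase:
                    attrs.append("product=transposase")
                else:
                    attrs.append("product=hypothetical protein")
                fh.write(
                    f"{rep.replicon_id}\trhizocomp\t{ftype}\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t{'0' if ftype == 'CDS' else '.'}\t{';'.join(attrs)}\n"
                )


_BLAST_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path: str | Path, query_lengths: Mapping[str, int]) -> list[HomologyHit]:
    """Read 12-column BLAST tabular (outfmt 6) hits.

    Query coverage is derived as ``100 * alignment_length / protein_length``
    (capped at 100); every qseqid must appear in ``query_lengths``.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", names=_BLAST_COLS, header=None, comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed BLAST tabular file: {exc}") from exc
    if len(df) == 0:
        return []
    for col in ("pident", "length", "evalue", "bitscore"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ParseError(f"{path}: non-numeric value in column {col!r} at data row {bad}")
    missing = set(df["qseqid"]) - set(query_lengths)
    if missing:
        raise KeyError(
            f"{path}: {len(missing)} query ids missing from query_lengths, "
            f"e.g. {sorted(missing)[:3]}"
        )
    hits = []
    for row in df.itertuples(index=False):
        qlen = query_lengths[row.qseqid]
        cov = min(100.0, 100.0 * row.length / qlen) if qlen else 0.0
        hits.append(
            HomologyHit(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                percent_identity=float(row.pident),
                alignment_length=int(row.length),
                evalue=float(row.evalue),
                bit_score=float(row.bitscore),
                query_coverage=cov,
            )
        )
    return hits


def hits_from_rows(
    rows: Iterable[Mapping[str, object]], query_lengths: Mapping[str, int]
) -> list[HomologyHit]:
    """Build HomologyHit objects from outfmt-6 row dicts (no file round trip)."""
    hits = []
    for r in rows:
        qlen = query_lengths[str(r["qseqid"])]
        alen = int(r["length"])
        cov = min(100.0, 100.0 * alen / qlen) if qlen else 0.0
        hits.append(
            HomologyHit(
                query_id=str(r["qseqid"]),
                subject_id=str(r["sseqid"]),
                percent_identity=float(r["pident"]),
                alignment_length=alen,
                evalue=float(r["evalue"]),
                bit_score=float(r["bitscore"]),
                query_coverage=cov,
            )
        )
    return hits


def write_blast_tab(rows: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write outfmt-6 lines from dicts keyed by the 12 standard column names."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in _BLAST_COLS) + "\n")


# ---------------------------------------------------------------------------
# Composition primitives
# ---------------------------------------------------------------------------

def gc_content(sequence: str, ndigits: int | None = 2) -> float:
    """GC percentage of a sequence, excluding N from both counts.

    Raises ValueError on a sequence with no unambiguous bases.
    """
    s = sequence.upper()
    g = s.count("G")
    c = s.count("C")
    a = s.count("A")
    t = s.count("T")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("GC content undefined: sequence has no unambiguous bases")
    pct = 100.0 * (g + c) / denom
    return round(pct, ndigits) if ndigits is not None else pct


def gc_skew(
    sequence: str, params: CompositionParams = CompositionParams(), circular: bool = False
) -> list[tuple[int, float]]:
    """(G - C)/(G + C) in sliding windows.

    Returns (window_start, skew) pairs with 1-based window starts; a window
    with no G or C yields ``nan``. Circular sequences wrap the final windows
    around the origin.
    """
    s = normalize_sequence(sequence)
    n = len(s)
    if params.window > n:
        raise ValueError(f"window {params.window} exceeds sequence length {n}")
    ext = s + s[: params.window - 1] if circular else s
    last_start = n - 1 if circular else n - params.window
    out = []
    for start0 in range(0, last_start + 1, params.step):
        w = ext[start0 : start0 + params.window]
        g = w.count("G")
        c = w.count("C")
        skew = (g - c) / (g + c) if (g + c) else math.nan
        out.append((start0 + 1, skew))
    return out


def codon_counts(cds_sequences: Iterable[str], gene_ids: Sequence[str] | None = None) -> dict[str, int]:
    """Tally the 64 codons over a collection of in-frame CDS sequences.

    Codons containing N are skipped; a CDS whose length is not divisible by
    3 raises a frame error naming the gene (by id if given, else by index).
    """
    counts = dict.fromkeys(CODONS, 0)
    for i, seq in enumerate(cds_sequences):
        s = normalize_sequence(seq)
        if len(s) % 3 != 0:
            name = gene_ids[i] if gene_ids is not None else f"#{i}"
            raise ValueError(f"CDS {name}: length {len(s)} not divisible by 3")
        for j in range(0, len(s), 3):
            codon = s[j : j + 3]
            if "N" not in codon:
                counts[codon] += 1
    return counts


def rscu(counts: Mapping[str, int]) -> dict[str, float]:
    """Relative synonymous codon usage per sense codon.

    RSCU(c) = count(c) * family_size / family_total. Codons of a family with
    zero total usage are reported as ``nan``; stop codons are excluded.
    """
    out: dict[str, float] = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        total = sum(counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = counts.get(c, 0) * k / total if total else math.nan
    return out


def reference_weights(reference_counts: Mapping[str, int]) -> dict[str, float]:
    """Relative adaptiveness w(c) = RSCU(c) / max RSCU in c's family.

    Computed from a designated reference gene set's codon counts; Met/Trp
    (single-codon families) and stops are excluded from the result.
    """
    r = rscu(reference_counts)
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if len(codons) == 1:
            continue
        vals = [r[c] for c in codons]
        if any(math.isnan(v) for v in vals):
            continue
        mx = max(vals)
        if mx == 0:
            continue
        for c in codons:
            w[c] = r[c] / mx
    return w


def cai(
    gene_codon_counts: Mapping[str, int],
    weights: Mapping[str, float],
    zero_weight_floor: float = 0.01,
) -> float:
    """Codon adaptation index: geometric mean of w(c) over the gene's codons.

    Codons absent from ``weights`` (single-codon families, stops, families
    unseen in the reference) are ignored. A zero weight is replaced by
    ``zero_weight_floor`` with a logged warning so the geometric mean stays
    finite. Raises ValueError when no codon of the gene is scorable.
    """
    log_sum = 0.0
    n = 0
    warned = False
    for codon, count in gene_codon_counts.items():
        if count == 0 or codon not in weights:
            continue
        w = weights[codon]
        if w == 0.0:
            if not warned:
                logger.warning("CAI: zero-weight codon %s floored at %g", codon, zero_weight_floor)
                warned = True
            w = zero_weight_floor
        log_sum += count * math.log(w)
        n += count
    if n == 0:
        raise ValueError("CAI undefined: gene has no codons with defined weights")
    return math.exp(log_sum / n)
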