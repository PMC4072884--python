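# Methods

This note documents the models and procedures implemented in `rhizocomp`,
the parameter defaults and why they were chosen, what the synthetic cohorts
do and do not emulate, and the numerical conventions adopted where the
underlying methods literature leaves choices open.

## Orthology

Hits are BLAST-style directed protein similarity records. The filter keeps
hits satisfying **all four strict inequalities**: E-value < 1e-5, percent
identity > 30, query coverage > 70, bit score > 60. Coverage is defined
against the *query* protein length (100 · alignment_length / protein_length,
capped at 100); the convention matters at the 70% boundary and is stated
here because tabular BLAST output does not fix a denominator.

A pair (a, b) is orthologous when b is a's best surviving hit and a is b's.
"Best" needs a total order, so ties are broken deterministically: higher bit
score, then lower E-value, then higher identity, then lexicographically
smaller subject id. Each gene lands in at most one pair per genome pair.

Ortholog **groups** are connected components of the undirected graph over
all pairwise ortholog pairs. This is deliberately *not* Markov clustering:
component structure is exactly reproducible, auditable, and sufficient for
the downstream statistics (core/accessory counting, marker sampling).
Group counts from this construction are not comparable 1:1 with
Markov-clustering counts on real data; components can chain families that
inflation would split. In-paralogs (same-genome mutual best hits) are not
merged into groups in this version.

The pan-genome partition classifies each group by the number of distinct
genomes it spans: core (all n), shared_k (2 ≤ k ≤ n−1); genes in no group
are strain-specific. The single-copy core restricts core groups to exactly
one member per genome — the natural unit for marker-gene work, and the
strict reading of a "one ortholog per genome" core when the cohort has more
than four genomes. Marker sampling is uniform without replacement,
deterministic per seed (default n = 210, a typical marker-panel size).

## Synteny

A perfect block between genomes A and B is a maximal run of consecutive
A-ranks whose ortholog B-ranks are consecutive and strictly increasing with
equal strands (forward) or strictly decreasing with flipped strands
(inverted). Genes without orthologs break runs — no gap tolerance — as do
replicon boundaries. Segmentation is greedy left-to-right in A: from each
position the run is extended as far as the predicate allows, so blocks never
overlap and every gene in synteny belongs to exactly one block. At a pivot
gene where a forward run meets an inverted run, the gene joins the left
(earlier) run; this is the one place where "maximality" needs a tie rule.
`min_block` defaults to 2 (a single shared gene is not synteny).

Circular wrap-around (joining the run ending at rank n−1 to the run
starting at rank 0) is implemented but **off by default**: annotated
bacterial genomes are conventionally linearized at a fixed origin (dnaA for
chromosomes, repABC for rhizobial plasmids), which makes linear scanning the
comparable convention.

Gene scores equal the containing block's length in genes. The per-pair mean
is taken over genes in blocks only ("genes in synteny"); a variant scoring 0
for unsyntenic genes is available on the result object for sensitivity
analysis. Distributions are compared with Welch's unequal-variance
two-sample t-test, two-sided — the pooled-variance assumption has no
justification when two genome pairs differ precisely in their score spread.
Degenerate inputs are handled by convention: two constant samples with equal
means give p = 1; with unequal means, t = ±inf and p = 0.

## Presence/absence profiles and trees

Homolog presence uses E-value ≤ 1e-5 (inclusive) and an identity **floor**
of 35%. An identity ceiling is selectable (`identity_is_floor=False`) for
comparison against sources that print the threshold as "≤ 35%" — a ceiling
contradicts the purpose of a homolog screen, so the floor is the default
and the ceiling exists only as a sensitivity switch.

Clustering is agglomerative with average linkage (UPGMA-style mean pairwise
distance) on Hamming-fraction distances by default; complete/single linkage
and Jaccard distance are selectable. Exact merge ties are broken by the
lexicographically smallest leaf-tuple pair, so dendrograms are independent
of input order. Bootstrap support resamples marker rows with replacement;
a node's support is the percentage of replicates whose dendrogram contains
the same leaf *bipartition* (clade vs rest), which is invariant to
rotations and to where the root falls inside the clade.

The composition vector of a genome is indexed by all 4^k k-strings
(k = 6 default — informative but still dense for multi-megabase bacterial
genomes; k = 3 is the minimum the Markov construction supports). Counts are
strand-merged (forward plus reverse complement). The expected frequency of
s1..sk under a (k−2)-order Markov model, f0 = f(s1..sk−1)·f(s2..sk) /
f(s2..sk−1), is subtracted and normalized: a(s) = (f − f0)/f0 (0 where
f0 = 0). The distance between genomes is (1 − cosine)/2 ∈ [0, 1]. The
triangle inequality is not guaranteed and not asserted. Trees come from
neighbor joining (unrooted; scikit-bio) or UPGMA (rooted; scipy linkage).

## Genomic islands

Four independent evidence classes, each with a configurable threshold,
scored 0–4 per candidate region:

| evidence | statistic | default threshold |
|---|---|---|
| GC deviation | region GC − backbone GC (pp) | ≥ 1.5 pp absolute |
| codon usage | RSCU distance, permutation p | p ≤ 0.05 |
| transposases | fraction of genome total inside | ≥ 0.5 |
| tRNA adjacency | gap to nearest tRNA | ≤ 5 kb of a boundary |

Candidates are found by a sliding-window GC scan (window 5 kb, step 1 kb):
windows are z-scored against the replicon's own window-GC mean/sd, runs
with |z| ≥ 2 merge across gaps ≤ 5 kb, and merged spans shorter than 10 kb
are dropped. Real island-backbone contrasts in rhizobia (≈ 58–59% vs
≈ 62.5–62.9% GC; 80–86% of transposases concentrated in the island) clear
these defaults by wide margins, which is why they are set where they are;
they are deliberately conservative rather than tuned. Every plasmid (any
replicon other than the longest) is additionally evaluated whole regardless
of GC, encoding the hypothesis that small replicons may be excised islands;
its GC and codon usage are compared against the chromosome. Plasmids are
not re-segmented internally, so calls never overlap.

Codon-usage divergence is the Euclidean distance between the two gene
sets' RSCU vectors over multi-codon amino-acid families, with **lysine
excluded by default**: its two-codon family is empirically too volatile
between regions to be informative and would dominate the norm. Families
with zero usage in a set contribute the uniform RSCU value 1 rather than a
missing value, so sparse regions are not artificially divergent.
Significance comes from gene-label permutation — genes are exchangeable
between region and backbone under the null, and permutation avoids the
sparse-cell assumptions of a chi-square on 59 codons. p = (1 + #{perm ≥
obs}) / (1 + n_perm), deterministic per seed; regions with fewer than 10
genes are flagged low-power rather than suppressed. A chromosomal region's
backbone is the rest of the genome excluding the region itself.

tRNA adjacency distance is the number of bases strictly between the tRNA
edge and the span boundary, wrapping the origin on circular replicons;
tRNAs inside the span count when within one window of a boundary.

## The synthetic cohorts

Genomes are simulated at the **gene-tile** level: an ancestral complement
of genes (default 1,000 per genome, lengths ~ N(300, 50) codons, in-frame
codon strings sampled from an independent-base model at the background GC
of 0.63) joined by 100-bp random spacers on one circular chromosome.
Ortholog copies share the ancestral sequence verbatim — downstream stages
consume order, strand and composition, not alignments, so no substitution
model is applied. Per non-reference genome: Poisson-distributed inversions
(segment reversed, strands flipped) and translocations, and independent
per-gene loss. The reference genome (G0) keeps every gene and, under
scalar rates, an unrearranged order, so the probability a gene lineage is
core is exactly (1 − loss)^(n−1). Rates may also be given per genome to
build rearrangement gradients. Optional clade-structured gene content
(genes present only in a designated genome subset) plants recoverable
clades for presence/absence clustering.

The island (default 100 genes in G0, inline or as a plasmid) is sampled
from a codon distribution with GC shifted by −5 pp and a 6-codon
GC-balanced, lysine-free subset upweighted ×3; a bisection on the base
composition makes the biased distribution's expected GC land exactly on
the target. n_transposase island genes (default 8) plus 2 background
transposases give the 0.8 island fraction by construction; a tRNA-Gly is
placed one spacer upstream of the island.

Hit tables contain one reciprocal hit per true ortholog pair (identity 88%
± configurable noise, bit score a monotone function of identity × length so
threshold filtering is meaningful) plus optional spurious hits generated
*below* the filter cutoffs. With noise zeroed, reciprocal best hits on the
emitted tables equal the truth ortholog map exactly.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: sequence-level divergence between orthologs
(hence no alignment realism and an optimistic RBH setting), in-paralogs and
gene families, rearrangements spanning replicons, multiple islands per
genome, amelioration of island composition over time, and real intergenic
structure. The oracle-equivalence tests (brute-force RBH, brute-force
interval search for blocks, exhaustive k-mer tallies) are independent of
these simplifications; the recovery tests are not.

## Problem sizes and determinism

All randomness flows through integer-seeded numpy generators; no iteration
over unordered containers feeds results. The test suite and the acceptance
script use desk-scale sizes chosen to keep statistical properties
measurable: 1,000-gene genomes for partition/synteny/island recovery, 50
island seeds and 500 (tests) / 200 (script) permutation-null replicates,
1,000 bootstrap replicates on 8-genome matrices, exhaustive signed
permutations to n = 7 plus 500 random n = 12 instances for the synteny
oracle. Larger cohorts scale linearly in genes × genomes for everything
except bootstrap clustering (quadratic-to-cubic in genomes, which are few).

## Known limitations

- Connected-component grouping chains families that Markov clustering would
  split; real-data group counts will differ from inflation-based tools.
- The GC scan z-scores windows against a contaminated background (the
  island itself raises the sd); with islands ≫ 30% of a replicon the z
  threshold loses sensitivity.
- CV distance is not metric; NJ on it is a heuristic, as in standard
  practice.
- The island caller reports evidence, not integration mechanics: no
  integrase/attachment-site detection.
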