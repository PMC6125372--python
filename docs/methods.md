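# Methods

## Scope and model of the data

The pipeline compares one fully annotated reference genome against a set
of related genomes organized into phylogenetic groups (several strains
per group). Genomes are bags of genes on replicons; all coordinates are
1-based inclusive (GFF3/GenBank convention) and gene order is expressed
as a 0-based rank per replicon, assigned by start coordinate. Circular
replicons carry a topology flag but are linearized at the origin: no
window or synteny computation wraps around the origin. Non-CDS features
(rRNA, tRNA) are retained for feature counting but excluded from
orthology and windows, which operate on proteins.

## Orthology

**Alignment.** Protein pairs are aligned with exact Smith–Waterman local
alignment under BLOSUM62 with affine gap penalties, via Biopython's
`PairwiseAligner` (C implementation). A gap of length L costs
`gap_open + L*gap_extend` (defaults 11/1, the BLAST convention;
implemented as `open_gap_score = -(open+extend)`,
`extend_gap_score = -extend`). Identity is the fraction of alignment
columns (gap columns included) with identical residues; coverage is the
number of a sequence's residues inside the local alignment over its
length. Exactness at this scale is preferable to re-implementing a seed
heuristic: the filtering thresholds, not search internals, define the
procedure.

**E-values.** Karlin–Altschul statistics with the published gapped
BLOSUM62 constants (λ = 0.267, K = 0.041):
`bits = (λ·S − ln K)/ln 2`, `E = m·n·2^(−bits)` with the two sequence
lengths as search space and no edge-effect correction. The worked
consequence `bits = log2(m·n) ⇒ E = 1` anchors the unit tests.

**Filtering.** Hits are kept when identity ≥ 0.35 AND coverage ≥ 0.60
AND E ≤ 1e-5, all boundaries inclusive. The coverage rule applies to
`min(coverage_query, coverage_subject)` by default — the strictest
symmetric reading — with `query`/`subject` available as configuration
because the convention is genuinely ambiguous in the field.

**Candidate enumeration.** All-vs-all alignment per genome pair is
preceded by a k-mer seeding step: only pairs sharing ≥ 2 distinct 5-mers
are aligned (both parameters configurable; the prefilter can be disabled,
and disabling it provably does not change filtered output on test
fixtures). A pair at the 35 % identity floor over a 300-residue
alignment shares ~1.6 exact 5-mers in expectation, so the filter is
meaningful only for pairs far below threshold; real homologs at the
divergences this pipeline targets share hundreds. A second exact gate
skips the traceback when the alignment score is below the minimum raw
score that could reach E ≤ 1e-5 for the pair's lengths — this cannot
change filtered output.

**RBH.** (a,b) is an ortholog pair iff each is the other's best
bitscore hit in the partner genome. Ties are broken deterministically:
conserved-region preference (below), then higher identity, then lower
gene rank. The relation is one-to-one per genome pair by construction.

**Families.** Connected components of the cross-pair RBH graph (via
networkx; a union-find oracle checks it in the tests). A gene left
without any RBH edge — typically an in-paralog that lost every
reciprocal tie to its duplicate — is recruited into the family of its
best-bitscore filtered hit. This recruitment is what makes per-genome
copy numbers (reported alongside presence) reflect duplications as
counts ≥ 2 rather than orphan singletons, matching how a copy-number
column is read off an RBH table in practice.

## Synteny

Conserved regions are maximal runs of RBH anchors sorted by reference
rank, monotone (increasing = `same`, decreasing = `inverted`) in the
other genome's rank, with at most `max_gap` (default 2) unmatched genes
between consecutive anchors on either genome and at least
`min_block_len` (default 3) anchors. Runs are built greedily left to
right, so blocks never overlap on the reference. The defaults tolerate
single-gene insertions without inventing long-range claims.

Conserved regions enter the pipeline only as a binary "lies in a
conserved region" attribute used to weight ortholog assignment; a
nucleotide-level whole-genome aligner could supply it, and gene-order
collinearity preserves exactly that role while staying self-contained. The one operational consequence
implemented is ambiguous-assignment resolution: where candidate partners
tie in bitscore (within `tie_margin`, default 0 = exact ties), the
candidate that fits collinearly into a block wins. Fitting is checked
against the block's neighboring anchors (replacing any anchor at the same
reference rank), not against the block's rank span — a dispersed
duplicate landing inside a long block's span would otherwise count as
syntenic. Score bonuses or other readings of "weighting" are deliberately
not implemented.

## Core genomes, sharing calls, locus completeness

Presence of a reference gene in a genome means its ortholog family has
at least one member there; reference genes without a family are present
only in the reference. Copy counts are kept in a parallel matrix.
Plasmid genes are ordinary rows labeled by replicon.

A group's core genome is the set of reference genes present in every
member. Sharing categories are mutually exclusive and exhaustive:

- `strain_unique` — present only in the reference strain;
- `species_unique` — present in every reference-group genome and in no
  genome outside the group;
- `group_core_shared` — in the reference group's core and in ≥ 1 outside
  genome;
- `mosaic` — anything else (patchy within the reference group).

No additional identity ceiling is applied to species-unique calls:
remote homologs below 35 %/60 %/1e-5 are already absent from the
presence matrix by construction.

Locus completeness is the fraction of a named, ordered reference gene
cluster present in a genome, binned as `full` (= 1.0), `absent`
(< 0.10) or a partial decile (`partial_0.1` … `partial_0.9`); only the
two extreme bins are externally fixed, deciles are this package's
choice of gray steps. Ring-track export emits long-format per-genome
presence/conservation tracks along reference gene order plus locus
annotation rows for external circular plotting; re-import restores the
matrix column exactly.

## Expression scan

Intensities (genes × samples, two conditions with replicates) are
quantile normalized — every sample mapped onto the mean order-statistic
distribution, ties receiving the mean reference value of their tied
ranks — then log2-transformed with pseudocount 1.0 (configurable).

Outlier samples are screened with distance = 1 − Pearson correlation
under Ward linkage: a sample is removed when it sits alone on one side
of the dendrogram's top split and its mean distance to the others
exceeds mean + k·sd (k = 2) of the pairwise distances **among the
remaining samples**. Restricting the margin to the remaining samples is
this package's operationalization: with ≤ 8 samples an outlier's own
distances inflate the overall spread so much that a margin over all
pairs can never fire (verified numerically on a 3-tight-plus-1-outlier
fixture).

Differential expression is a per-gene Welch two-sample t-test on the
log2 values (the standard choice for 4-vs-4 arrays without variance
moderation; configurable), called `up`/`down` at p ≤ 0.05 and linear
fold change ≥ 1.5 (|log2FC| ≥ log2 1.5 — the threshold is interpreted on
the linear scale because fold values are reported linearly). No
multiple-testing correction is applied by default, matching the stated
p-threshold; Benjamini–Hochberg is available off by default. Genes
detected (array present/absent flag) in fewer than half the samples of
both conditions are `undetected`. Zero within-group variance in both
groups yields p = 1 at equal means (p = 0 otherwise) rather than an
error.

The window profile counts `up` and `down` calls in every window of 15
consecutive genes (step 1, labeled by first rank) along reference gene
order; replicon boundaries are hard breaks and replicons shorter than
the window contribute no windows.

## Synthetic data generator

The generator emulates the study conditions every stage is scored
against: 4 groups × 3 strains; 300 universal-core families; 50
group-core families per group; two planted group-unique clusters on
group 1 (55 and 20 genes — a species-restricted flagellar system and
secretion system analog); a 60-gene plasmid on the reference strain; 10
strain-unique genes per strain; 2 % of universal families duplicated in
some strain; 2 block inversions (5–30 genes) per genome; amino-acid
divergence 0.10 between groups and 0.01 within.

Proteins are i.i.d. draws from background amino-acid frequencies
(lengths ~ N(300, 75²), min 50). Evolution is site-independent point
substitution: each site substitutes with probability 1 − exp(−d), the
replacement drawn from background frequencies excluding the current
residue; no indels by default, so identity and coverage stay
analytically predictable (expected ortholog identity
≈ exp(−d_total) + (1 − exp(−d_total))·Σf² with the collision term
≈ 0.0059·…, about half a percentage point at these divergences). Group
ancestors sit at d_between/2 from the root, strains at d_within/2 from
their group ancestor, so cross-group pairs are separated by
d_between + d_within in total.

Duplicates are dispersed exact copies (inserted at a random distant
position after strain-level mutation): identical copies produce exact
bitscore ties, which is precisely the ambiguity that conserved-region
weighting exists to resolve, and a distant position is what makes the
resolution positionally testable. Each genome's random stream is derived
from the master seed by stable hashing of the genome/group name, so
adding genomes never perturbs existing ones, and equal seeds give
byte-identical output files.

The expression generator draws log-normal baselines (CV-parameterized
replicate noise) and multiplies treatment means by the effect size
inside one contiguous planted block (defaults: 15 genes, fold change 4,
CV 10 %, 4 replicates per condition).

What the generator does **not** emulate: indels and domain shuffling
(so coverage filtering is never stressed below 100 %), codon-level
evolution, horizontal transfer between groups, compositional bias along
the genome, probe-level array artifacts, and intensity-dependent
detection failure. Passing tests therefore demonstrate correctness of
the pipeline's logic under clean divergence, not robustness to every
real-data pathology.

## Problem sizes and numerical choices

The default verification design (12 genomes × ~400–500 genes, proteins
~300 aa) keeps the exact all-vs-all comparison at roughly two minutes on
one CPU; the brute-force alignment oracle is exercised on all sequence
pairs up to length 3 over a 3-letter alphabet plus seeded longer draws,
the RBH and synteny oracles on 100 random instances each, and scan
calibration on 2,000-gene null matrices. Tie-breaking is deterministic
everywhere (documented per stage above); TSV outputs are byte-stable
across reruns with equal configuration and seed.

## Known limitations

- The k-mer prefilter is a heuristic: a true hit hovering exactly at the
  35 % identity floor can in principle be missed (expected shared 5-mers
  ~1.6 < 2); disable the prefilter for exhaustive behavior.
- Synteny blocks are gene-order based; nucleotide-level rearrangements
  inside genes, or conservation among genes missing RBH partners, are
  invisible to them.
- Family construction is single-linkage over RBH edges; promiscuous
  domains could in principle chain unrelated families together (not
  exercised by the generator, which draws independent families).
- The expression model tests calibration and power of the scan, not
  array preprocessing upstream of the intensity matrix.
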