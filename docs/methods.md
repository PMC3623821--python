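# Methods

This note records the models, conventions and numerical choices behind
`estssr`, in the order the pipeline runs them, together with what the
synthetic fixtures do and do not emulate.

## Sequence cleanup

**Poly-A/T trimming.** cDNA orientation is unknown, so maximal terminal
runs of either A or T are removed at either end, iteratively until no
terminal run of at least `trim_run_min` bases remains (default 10,
exact-base runs only — no mismatches). This rule is idempotent and never
touches interior runs. A sequence consumed entirely by terminal
homopolymer keeps one sentinel base and is then removed by the length
filter.

**Length filter.** Strictly-below-`min_length` sequences (default 100 bp)
are dropped; a sequence of exactly 100 bp is kept.

**Contaminant screen.** A sequence is removed when any reference from a
labelled contaminant set (vector, chloroplast, mitochondrial) has a local
alignment to it with identity ≥ 0.90 covering ≥ 0.50 of the sequence.
Alignment scoring is match +1, mismatch −1, gap −2 throughout the
package; N and the other IUPAC ambiguity codes never count as matches.
A shared-12-mer prefilter skips pairs that cannot reach the thresholds.
When a sequence matches references of several classes, the first class in
the fixed order vector → chloroplast → mitochondrial is the one charged
in the report, so the accounting is single-charge and reproducible.

**Redundancy clustering.** Greedy longest-first clustering in the style
of CD-HIT: sequences are visited by decreasing length (ties by id); each
joins the first existing representative with identity ≥ 0.90, where
identity is local-alignment matches divided by the shorter sequence's
length; otherwise it founds a new cluster. An 8-mer shared-word prefilter
precedes each alignment. Given the fixed visiting order the result is
deterministic.

**Accounting.** Every run asserts
`n_input = n_valid + n_removed_short + Σ contaminant removals` and
`n_clusters ≤ n_valid`; violations raise instead of writing a report.

## SSR detection

A locus is a maximal perfect tandem run of a *primitive* motif (not a
power of a shorter word) of period 2–6; mononucleotide runs are excluded.
For each period `p` the scanner marks positions where `s[i] == s[i+p]`
(ambiguity codes break runs), run-length-encodes the mask, and emits one
locus per maximal region: motif = the leftmost full copy, repeat count =
⌊region length / p⌋, end coordinate excluding any trailing partial copy.
Runs whose leading motif is non-primitive are skipped — the same region
is described at its true shorter period. If two periods ever describe the
identical interval the shorter period wins (with primitivity this is a
belt-and-braces rule; Fine–Wilf periodicity makes genuine double
descriptions non-primitive). Coordinates are 1-based inclusive in all
outputs, 0-based half-open internally.

Canonical motif classes are written `M/M′`, with `M` the lexicographic
minimum over all cyclic rotations of the motif and of its reverse
complement and `M′ = revcomp(M)`; a self-complementary class prints both
sides identical (e.g. `AT/AT`). Exhaustive enumeration gives 4 / 10 / 33
/ 102 / 350 classes for periods 2–6, which the tests freeze.

Presets: `misa_default` uses the classical EST-survey thresholds
(di ≥ 10, tri ≥ 6, tetra ≥ 5, penta ≥ 4, hexa ≥ 3 repeats, 100 bp
compound interruption). `cardle` uses the density-comparison thresholds
7/5/4/3 for di–penta; no hexamer threshold is defined for that criteria
set, so hexamers are simply not searched under it. `len20` approximates
length-based searches: any period 2–6, at least two copies, total length
strictly greater than 20 bp.

**Compound merging.** Consecutive loci on a sequence with gap ≤ 100 bp
chain into one compound (chains may exceed two members). Merging requires
non-overlapping input; because maximal runs of different periods can
overlap by a few bases, the pipeline first resolves overlaps by keeping
the longer locus (ties: shorter period, then smaller start).

**Summaries.** Density is reported as total bases ÷ locus count in kb
per SSR (undefined, not an error, at zero loci); frequency as the share
of sequences containing at least one SSR.

## Primer design

All forward windows in the 5′ flank and reverse-complement windows in the
3′ flank satisfying length 18–27 (optimum 20), Tm 57–63 °C (optimum 60),
GC 30–70% and a ≤ 7 bp self-complementarity screen are paired; pairs with
product size 100–300 bp spanning the repeat are ranked by

    penalty = |len_f − 20| + |len_r − 20| + |Tm_f − 60| + |Tm_r − 60|
              + |Tm_f − Tm_r|

(unit weights, configurable) with deterministic tie-breaks (smaller
product, then leftmost forward start); the best three are kept. Because
enumeration is exhaustive within the constraint windows the returned
optimum is global by construction, which is what the tests verify with an
independent re-enumeration. Nearest-neighbor Tm sums the unified
dinucleotide ΔH/ΔS parameters (SantaLucia 1998) with terminal initiation
terms, the salt correction ΔS + 0.368(N−1)ln[Na⁺] at 50 mM Na⁺, and
C_T/4 at 250 nM total oligo; the Wallace rule 2(A+T)+4(G+C) is available
for quick checks. The M13(−21) tail `TGTAAAACGACGGCCAGT` (18 nt) can be
prefixed to the forward primer once; product size grows accordingly.

## Genome placement

Standard 12-column BLAST tabular rows are parsed strictly (malformed rows
raise with their line number); `subject_start > subject_end` encodes the
minus strand. Per query, hits with identity ≤ 0.8 are discarded (the
cutoff is strict) and the survivor with the highest bitscore wins, ties
broken by longer alignment, lexicographic subject, smaller subject start.
A locus fully inside the hit's query interval maps by affine offset
(`g = subject_start ± (q − query_start)`); partial coverage is
`unplaced`. Optional refinement replaces the affine map with a global
pairwise alignment (match +1, mismatch −1, gap −2) of the matched
segments — a built-in stand-in for re-aligning around each locus with an
external aligner. Classification against GFF3 gene models picks the gene
with the largest total overlap, then the feature class (CDS / 5′UTR /
3′UTR) with the largest base overlap, ties CDS > UTR5 > UTR3; no feature
overlap means intergenic, and a chromosome absent from the annotation
leaves the locus unplaced.

## Diversity statistics

Frequencies are allele counts over `2 × n_typed` with per-locus deletion
of missing calls. `H_E = 1 − Σ P_i²`; `uH_E = 2n/(2n−1) H_E`. Two PIC
conventions are offered because the field's literature mixes them: the
widely printed `PIC = 1 − Σ P_i²` (algebraically identical to `H_E` —
the package asserts this identity) and the Botstein et al. form
`1 − Σ P_i² − Σ_{i<j} 2 P_i² P_j²`, which dedicated PIC calculators
implement and which is strictly smaller for ≥ 2 alleles. Surveys that
report different PIC and He ranges over the same loci have necessarily
used the Botstein form; both are emitted side by side. A locus is
polymorphic iff ≥ 2 alleles are observed among typed individuals.

The repeat-count effect on polymorphism is fit as a logistic regression
by IRLS/Newton scoring (≤ 25 iterations, tolerance 1e−8) with Wald
tests; because "correlation coefficient" is ambiguous for a logistic
model, the point-biserial Pearson r between repeat count and the 0/1
outcome is reported alongside, clearly labelled. Complete separation is
flagged and no finite slope is reported. Alleles are opaque integer
labels; no stepwise-mutation binning is applied.

## Transferability and trees

The binary distance is the mismatch proportion over loci scored in both
species (pairwise deletion; a pair with no shared scored locus is an
error). Neighbor joining follows Saitou–Nei with the standard Q
criterion; ties are broken by the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf), so the
agglomeration is deterministic. Negative branch lengths are clamped to
zero with the deficit transferred to the sibling branch. Bootstrap
support resamples loci (columns) with replacement — 1000 replicates by
default, seed mandatory — rebuilds distance + NJ, and scores each
internal edge of the full-data tree by the percentage of replicates
containing the same bipartition. Trees serialize to Newick with supports
as internal labels (scikit-bio containers underneath).

## GO enrichment

One 2×2 table per term present in the background: (term ∩ subset,
term ∩ background-only, subset-only, neither). The default test is
one-sided (overrepresentation); the two-sided variant is selectable.
P-values come from the exact hypergeometric tail; q-values from the
Benjamini–Hochberg step-up `q_(i) = min_{j≥i} m p_(j)/j`. The FDR is
applied globally, not per GO namespace, and no ancestor propagation over
the GO graph is performed — the input map is taken as given, which
matters when comparing against annotation tools that propagate.

## Synthetic fixtures

All generators are pure functions of their spec (seed included):
byte-identical outputs across runs. Backgrounds are rejection-sampled
against the package's own detector using the union of the three presets'
minima (di 7, tri 5, tetra 4, penta 3, hexa 3 — strictly below every
threshold, including the 20 bp length bound), so planted repeats are the
only detectable loci and recall/precision are exact, not approximate.
Assembled sequences are re-verified after insertion and redrawn if
planting fused with flanking bases. Duplicates are exact copies whose ids
sort after the original, matching the clustering tie-break; contaminant
spikes are verbatim reference substrings; poly-A/T tails are appended
only where the terminal base differs from the tail base so trimming
removes exactly the added run.

Transfer matrices are binary characters on a random unrooted topology.
In `exact` mode every character flips on exactly one edge and every edge
receives the same number of characters, making pairwise mismatch
proportions exactly additive on the tree — this is the identifiable
"zero-noise" condition used for topology-recovery checks (a naive
per-edge flip *probability* of zero would instead make all rows identical
and all distances zero). `stochastic` mode flips characters along edges
with probability proportional to edge share; independent per-cell noise
can be added to either. Annotation fixtures solve for the in-subset term
probability such that the *expected measured* fold — subset rate over
whole-background rate, subset included — equals the planted fold.

What the fixtures do **not** emulate: expression levels, isoforms,
sequencing error, realistic motif composition biases, linkage between
loci, or homoplasy structure beyond independent flips. Passing tests
certify the algorithms and their contracts, not field performance on any
real transcriptome.

## Problem sizes and tolerances

The test suite runs the detector against a brute-force per-position
enumeration oracle on ~1000 seeded sequences of 100–1500 bp plus a
handful at 5 kb, for all three presets; NJ is checked for exact topology
and branch-length recovery on 100 random additive trees of 4–8 taxa;
Fisher p-values match hypergeometric enumeration to 1e−10 for margins up
to ~30; IRLS matches direct likelihood maximization to 1e−4 at n = 200;
bootstrap recovery uses 8 species × 325 characters × 200 replicates.
Fixture sizes are chosen so the full suite completes in a few minutes on
one CPU. Statistical recovery checks on sampled quantities use 3-sigma
bounds, Šidák-adjusted when a family of comparisons is tested jointly.
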