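# Methods

This note records the models, rules and numerical choices behind each
stage, the conditions the synthetic-data generator emulates, and the known
limits of what the tests demonstrate.

## Gene catalogue construction

Predicted ORFs are compared all-against-all. Two genes are joined when
their pairwise identity exceeds 95 % **and** the alignment covers more
than 90 % of the shorter gene (both strictly — boundary values are
excluded, mirroring the "greater than" wording of the protocol this
reimplements). Clusters are the connected components of that graph, i.e.
groups sharing genes merge transitively (single linkage). The longest
member represents each cluster, ties breaking to the lexicographically
smallest id; representatives shorter than 100 bp are removed **after**
selection, so a 100 bp gene survives. A contig-set variant of the same
operation uses 90 % identity with an absolute ≥ 30 bp overlap and
inclusive comparisons ("at least").

Pairwise identity is seed-and-extend: a pair is considered only if it
shares an exact 11-mer in either orientation (reverse-complement matches
are searched, since genes may be called on either strand). Extension is a
local alignment (match +1, mismatch −1, gap open −2, extend −1) of the
shorter sequence against the longer; identity = matches / alignment
columns with gap columns counting as mismatch and `N` never matching, and
coverage is the aligned span on the shorter sequence. A banded
edit-distance screen discards pairs that cannot reach 80 % identity before
the full alignment is computed; 80 % is far below every threshold in use,
so the screen only removes pairs that could never form an edge. The
denominator convention (all alignment columns, including gaps) is a
deliberate, documented choice; alignment engines differ subtly here, and
the identity definition is configurable at the call site through the
scoring of the underlying aligner.

Representative translation uses NCBI genetic code 11; when a sequence is
flagged as a gene start, alternative initiator codons (GTG, TTG, …)
translate to M. Codons containing N give X; internal stops are retained as
`*` with a warning (fragmental or frameshifted ORFs); a trailing stop is
removed; 1–2 leftover bases are ignored with a warning.

Read-to-catalogue mapping assigns each read to the best-identity gene
among hits with identity ≥ 95 % (inclusive — "cutoff of 95 %") and
aligned length > 100 bp (strict — "> 100 bp"), ties breaking to the longer
overlap, then the smallest gene id. The deliberate asymmetry — strict
inequality for clustering, inclusive for read assignment — mirrors the
differing wording of the two protocol steps; both are configurable.

## Taxonomic assignment

Two routes, reflecting the sensitivity/precision trade-off of shotgun
profiling. The strict route takes alignment hit tables and applies the
≥ 95 % / > 100 bp best-hit rule above; it yields high-confidence,
species-level assignments for a small fraction of reads. The classifier
route attaches a full taxon path with per-rank confidences to every read
and filters at a cutoff of 0.7, **inclusive** (the boundary had to be
fixed; 0.70 keeps the assignment), truncating the path at the first
failing rank so that absent ranks always form a contiguous suffix. The
cutoff is interpreted per rank; an external classifier that reports a
single genus-level confidence can be represented by broadcasting it.

The bundled `KmerClassifier` is a deliberately simple shared-k-mer voting
classifier (k = 12 by default): the reference with the most k-mer hits
wins and confidence = best / (best + runner-up). It is desk-scale plumbing
that lets the whole pipeline run on synthetic data with exact ground
truth; it is not a model of a production classifier's error profile.

Per-rank abundance tables conserve reads exactly: taxon counts plus the
unassigned count equal the read count in every sample. Three export
conventions: raw counts; shares renormalized over assigned reads only
(composition-figure convention); and counts with the unassigned reads as
an explicit "Unclassified" pseudo-taxon, which lets differential tests
treat database coverage itself as a feature. Percentages are computed on
read counts, not base pairs.

## Normalization, diversity, ordination

Two-step normalization: divide each feature by its sample total, then
multiply the fractions by the mean total over samples — removing depth
differences while retaining a read-count-like scale. Column sums become
equal by construction (checked to 1e-9). The log transform is
log₁₀(x + 1), so absent features map to 0 rather than −∞.

Rarefaction subsamples reads without replacement (multivariate
hypergeometric), one draw per sample per run by default, with the seed
logged; averaging over draws is available. The expected richness at depth
n has the closed form Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], evaluated through
log-gamma for stability. The reference analysis rarefied to 3.5 × 10⁶
reads per sample; desk-scale runs pass a depth scaled to the simulated
library size (the package default is the minimum sample total).

Richness is the count of observed features; Chao1 = S + F₁²/(2F₂), with
the bias-corrected fallback S + F₁(F₁−1)/2 when no doubletons exist.
Simpson diversity is reported in the Gini-Simpson form 1 − Σpᵢ², so that
larger values mean a more even community ("higher = more diverse"); the
inverse form can be derived trivially from the same pᵢ.

Bray-Curtis is Σ|u−v| / Σ(u+v); a pair of all-zero samples is undefined
and raises. PCoA eigendecomposes the double-centred squared-distance
matrix (negative eigenvalues are reported, not hidden); NMDS minimizes
Kruskal stress-1 starting from the PCoA configuration, which makes it
deterministic without multiple random restarts. PCoA is the default
ordination; both are provided because metric and non-metric views of
Bray-Curtis distances are both in routine use for this kind of figure.

## Differential abundance

Per feature, a two-sided Wilcoxon rank-sum test: exact by enumeration when
n₁ + n₂ ≤ 20 with no ties, otherwise the normal approximation with the
standard Σ(t³−t) tie correction and continuity correction. Two identical
samples return p = 1 with a warning (degenerate statistic). Group means
and SDs (n−1 denominator) are reported on the normalized scale while the
test runs on the log-transformed matrix; a rank test is invariant to a
monotone transform, so this changes nothing about p, but it mirrors the
workflow and keeps reported means on the published percent-like scale.

BH q-values follow the step-up rule q₍ᵢ₎ = min_{j≥i}(p₍ⱼ₎ · m/j) with an
explicit family size m ≥ n. The explicit m matters when reproducing a
published table that prints only the top rows of a larger testing family:
the shipped 27-row phylum table's q column is reproduced exactly (at the
precision of its printed p-values) with m = 32, implying five untabulated
taxa in the original family. Features all-zero in both groups are excluded
with a warning before testing.

Significance uses the dual rule p ≤ 0.05 **and** q ≤ 0.1, both inclusive;
star annotations follow q < 0.1 / 0.05 / 0.01.

## Functional annotation

Genes take the ortholog group of their best hit among hits with e-value
≤ 10⁻⁵ (inclusive), ties broken by larger bit-score then smaller group id.
E-values are inputs — the package contains no alignment-statistics engine;
the synthetic generator fabricates them from planted homology. Category
aggregation splits each group's abundance evenly across its categories
("evenly", not weighted) and keeps unmapped mass in an explicit bucket
rather than renormalizing it away, because unassigned fractions across
database tiers are themselves a comparative result. Mass is conserved to
1e-9 by construction.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:

- **Design**: two groups — 60 individuals pooled into 8 libraries of
  (8,8,8,8,7,7,7,7) versus single-individual samples (desk-scale default
  20; the reference comparison used 124).
- **Composition**: per-taxon group base abundances; the shipped preset is
  proportional to the published per-host phylum means (26 named taxa; the
  "Unclassified" table row is not a community member — the unassigned
  fraction re-emerges downstream from classification). Inter-individual
  variation is log-normal, abundanceᵢ = base · exp(N(0, σ)), renormalized
  per individual; log-normality keeps abundances positive and matches the
  right-skewed variation such tables show. Preset σ is calibrated from
  the single-individual host's SD/mean via σ = √log(1+CV²), capped at 1
  (the pooled group's printed SDs are library-level and already shrunk by
  pooling, so they would underestimate individual dispersion).
- **Sequencing**: single-end 75 bp reads (paired ends exercise no
  additional computation here), uniform start positions, i.i.d.
  substitution errors at rate 0.01, genomes of 50 kb — long enough that
  11/12-mers are effectively unique, small enough for seconds-scale runs.
  Reads per library default to 5000; the end-to-end power runs use 1000.
- **Planted truth**: per-read source taxon/gene/ortholog, exact-duplicate
  or ~98 %-identity gene copies for catalogue tests, and unannotatable
  genes for assignment-fraction tests.

Not emulated: quality scores, indels, GC and coverage bias, chimeras,
strain-level variation, real database incompleteness, and real inter-taxon
sequence similarity (synthetic genomes are mutually random, so
classification is easier than on real data). Passing tests therefore
demonstrate that the **statistical machinery** recovers planted structure
under the stated noise model — not that any particular classifier would
achieve these accuracies on real reads.

## Desk-scale problem sizes

The package's own test and acceptance runs use: 1000-gene catalogues with
20 % planted duplicates; 200 random clustering instances of ≤ 50 genes
against a brute-force oracle; 1000 null replicates for the 8-vs-124
type-I-error simulation; 20 random count vectors × 300 draws for the
rarefaction Monte-Carlo; 5000 reads for cross-catalogue assignment and
5000 genes for annotation fractions; and 100 simulated studies for the
end-to-end power check (the planted ~5× contrast at 2.0 % vs 0.37 %-like
base abundance, σ = 0.3, must be recovered as significant with correct
direction in ≥ 95 of 100 runs). These sizes were chosen so each property
is resolved with comfortable statistical margin.

## Known limitations

- The seed-and-extend aligner reports a single best local alignment; for
  genes with internally repeated structure, coverage of the shorter gene
  is computed from that one alignment's span.
- The exact Wilcoxon path requires untied data; heavily tied small samples
  fall back to the corrected normal approximation, which is conservative
  at very small n.
- Chao1 assumes the singleton/doubleton counts are meaningful — i.e. raw
  (rarefied) counts, never normalized values; the matrix `raw` flag guards
  this but cannot detect counts that were normalized upstream of the
  package.
- The classifier's confidence is a vote ratio, not a calibrated posterior;
  the 0.7 cutoff reproduces the *rule*, not a validated error rate.
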