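# Methods

`barcodeaudit` implements a heuristic framework for auditing a large
DNA-barcode reference collection — the kind assembled by sequencing the ITS
(ITS1+5.8S+ITS2) region from thousands of vouchered herbarium macrofungi.
The goal of every component is *triage*, not diagnosis: the outputs point a
taxonomist at the specimens and taxa most in need of scrutiny.

## Pairwise distances and the retention rule

The unit of comparison is the **bp difference** between two barcodes under an
end-gap-free global alignment (match +1, mismatch −1, gap open −5, gap
extend −2): substitution columns plus internal gap columns, with terminal
overhangs excluded so that different primer trims do not inflate distances.
IUPAC ambiguity codes count as a match whenever their base sets intersect,
which is deliberately conservative toward intraspecific identity. A
`indel_as_single` switch counts a k-base indel as one difference instead of
k; the default is per-column because the bp-difference axis of the
divergence profile is a column count. Alignments are computed with
Biopython's `PairwiseAligner`; an exhaustive enumeration of end-gap-free
alignments on short strings serves as the independent oracle in the tests.
When both sequences have equal length the gap-free candidate is used
whenever the aligner's optimal score confirms it is optimal — a pure
speed-up that also fixes the tie-break in favour of the gap-free alignment.

Pairwise distances across a heterogeneous collection are only trustworthy in
the low-divergence regime, so a pair is **retained** only when

* its bp difference is at most `min(threshold_bp, floor(threshold_frac ×
  mean pair length))` — defaults 70 bp and 10%, the standard low-divergence
  regime for ~700 bp amplicons; and
* its aligned span covers at least `min_overlap_frac = 0.5` of the mean pair
  length.

The second condition is a necessary companion of end-gap-free scoring: for
two *unrelated* sequences the optimal end-gap-free alignment degenerates to
a sliver overlap (in the extreme, a single matching base with both flanks as
free end gaps), which would report a near-zero distance for a pair that
actually shares nothing. Such pairs carry no usable distance and are
censored exactly like pairs beyond the bp cap. Censored pairs keep their
identity and taxonomic flags but no distance value.

## Barcode-gap analysis and error detection

Every retained pair is classified intra- or inter-specific by the
morphological determination, with "species" meaning the binomial after
collapsing infraspecific epithets (var., f., subsp.); the collapse is
configurable. The divergence profile is a pair count per integer bp
difference for each class; percent divergence, when needed, is bp difference
divided by the mean pair length.

* **False negative**: two distinct morphospecies joined by a retained pair
  at 0 bp (ambiguity-tolerant; an exact-string mode exists). Deduplicated to
  unique species pairs.
* **False positive**: a morphospecies whose maximum within-species
  difference exceeds a cutoff (default 14 bp ≈ 2% of 700 bp). A censored
  within-species pair exceeds any cutoff by construction and is reported as
  such.
* **Near misses**: cross-species pairs at 1 bp (configurable), counted as
  specimen pairs by default with a species-pair collapse available.

Severity of a confusion is the deepest shared rank: congeneric >
confamilial > moderate (same order) > major (different order), with
"unknown" for genera missing from the taxonomy index. The taxonomy index is
a plain 3-column file; unresolved genera are reported, never fatal, because
out-of-date nomenclature is an expected finding of an audit, not an input
error.

The threshold sweep reports, for each candidate similarity cutoff, the
lumping errors (cross-species pairs at ≤ cutoff) and splitting errors
(within-species pairs above it, censored intra pairs always included).
Lumping is non-decreasing and splitting non-increasing in the cutoff; both
are asserted as invariants.

## Mini-barcodes

Regions are split by annotation coordinates when curated ones exist, else by
locating the conserved 5.8S with a local alignment against a packaged
~160 bp fungal 5.8S consensus (replaceable FASTA). An anchor hit is accepted
at ≥75% identity over ≥80% of the anchor length, and the unaligned anchor
flanks are projected so the cut spans the full 5.8S. Splits are lossless
(`its1 + s58 + its2 == sequence`) or recorded as failures with a reason.

Discriminating power of each spacer is the Pearson correlation between its
distance matrix and the full-length matrix over the **intersection** of
retained pairs, using bp differences (a percent mode exists). Undefined
correlations (zero variance, <3 shared pairs) are reported as such.
Note an interaction that matters when simulating this analysis: the
10%-of-length retention cap is only ~25 bp within a 250 bp spacer, so
simulated congeneric divergence must be kept modest (the packaged
experiments use `p_inter = 0.025`) or the very pairs the correlation needs
are censored — the same effect would occur on real data with unusually
divergent congeners.

## Concordance checks

UPGMA is implemented directly (naive O(n³) agglomeration) so the contract is
explicit: merge height is half the average inter-cluster distance, ties are
broken by the lexicographically smallest member, and censored pairs enter at
`threshold_bp + 1` — "far", just above the cap, without fabricating
precision (a `drop` policy removes the worst specimens instead). SciPy's
average-linkage is the independent oracle in the tests.

NMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on dissimilarity ranks with weighted Guttman
updates; 8 seeded random starts, 300 iterations, tolerance 1e-6, best stress
wins. Censored pairs default to the same threshold+1 censoring (only their
rank matters in a nonmetric embedding); the `exclude` policy removes them
from the stress sum entirely, but with heavily censored data that leaves
between-group placement unconstrained, so it is not the default. With
strongly clustered data the embedding may legitimately collapse clusters to
points (stress → 0); downstream code treats that as a valid degenerate
solution.

Flags: for each taxon (genus or family) with ≥2 sequenced accessions, the
smallest dendrogram clade containing all of them is found. Foreign specimens
inside that clade get `foreign_inclusion` flags; a taxon whose minimal clade
holds more than 3× its own accessions gets a `split_group` flag. The 3×
dilation factor is an invented, documented heuristic that operationalizes
the "taxon scattered over multiple clusters" symptom. The ordination
coherence score (mean within-taxon distance / mean distance to all other
points) quantifies per-taxon tightness; ~1 means no structure.

## PCR-success contingency analysis

Factors are decade of collection (floor(year/10)×10) or genus; outcomes are
PCR or sequencing success. The omnibus test is the Pearson chi-square
without continuity correction (Yates available as a flag). Post hoc, each
cell gets the Haberman standardized adjusted residual
`(O−E)/sqrt(E(1−row/n)(1−col/n))`, compared to a standard normal at a
Bonferroni-corrected alpha whose denominator is the **cell count** (3×2 →
0.05/6 ≈ 0.0083), plus the cell's relative contribution to the omnibus
statistic. The stratified report runs the genus analysis separately per age
stratum (default 1980s–1990s vs 2000s) and marks cells at both the raw and
corrected alpha. Invariants: contributions sum to 1; in a 2×2 table every
adjusted residual has magnitude sqrt(chi²).

## Synthetic collections

The generator emulates what the audit consumes: a multi-genus, multi-species
collection with a conserved 5.8S (the packaged consensus, mutation rate 0 by
default so the splitter has a perfect anchor), spacers evolved on a
star-shaped genealogy (genus ancestor spacers i.i.d. uniform per site →
species ancestors at `p_inter` per site → accessions at `p_intra`, uniform
substitution to the 3 alternatives), controlled error injections, and
age/taxon-dependent PCR success from a logistic model.

Defaults, chosen once as desk-scale study conditions: 8 genera × 4 species ×
3 accessions (96 specimens); region lengths 250/160/250 (≈700 bp total);
`p_intra = 0.005`, `p_inter = 0.05` (a 10× intra/inter contrast that
produces the characteristic divergence profile with intra mass near zero),
`spacer_bias = 0.5` (fraction of spacer mutations routed to ITS1; region
rate is `2·bias·p`, so equal-length spacers average to `p`); collection
years uniform on 1980–2005; success logit `1.0 − 0.5 × (decades of age
before 2010) + genus offset`, giving ~55% mean PCR success that declines
with age, and sequencing success at 0.58 given a positive PCR. Replicated
recovery analyses use a smaller 4×3×2 (24-specimen) configuration purely
for turnaround; the methods are size-independent.

Injections: a **false negative** duplicates one accession's sequence under a
different congeneric species name; a **false positive** regenerates one
accession of a species as an independent species-level lineage; a **major
misidentification** relabels an accession with a species of a genus from a
different family, sequence untouched. Every injection is recorded in the
ground truth together with per-specimen true success probabilities.

`expected_pair_divergence` gives the exact expectations behind the
Monte-Carlo tests. Per site, a lineage that substitutes with probability p
(uniform over 3 alternatives) differs from a sibling with probability
`2p(1−p) + (2/3)p²`; two rounds (species then accession) compose as
`p⊕r = 1 − [(1−p)(1−r) + pr/3]`; independent uniform ancestors differ at
3/4. Expected bp differences are these per-site probabilities summed over
region lengths.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: indel evolution (all sequences are
equal-length, so alignment gaps are never exercised at scale), chimeras and
mixed templates, heterozygous rDNA repeat variants, non-uniform specimen-age
distributions, and correlated misidentification patterns (real errors
cluster in hard genera; injections are uniform).

## Numerical and degenerate-input choices

* Pair ordering is canonicalized lexicographically everywhere, making
  outputs byte-stable and order-invariant; reruns with the same inputs and
  config are byte-identical.
* All randomness in a pipeline run flows from the single config seed.
* Zero expected counts in a contingency cell warn; a zero marginal is an
  error. Fewer than 2 non-empty factor rows is an error.
* `matrix_correlation` refuses <3 shared pairs and zero-variance vectors
  rather than returning NaN.
* An empty optimal alignment (nothing aligned at all) is treated as zero
  overlap and censored.

## Known limitations

* The bp-difference definition is one of several defensible readings of
  "pairwise nucleotide differences"; counts near the retention boundary are
  sensitive to the scoring and to the indel-counting mode.
* The split_group dilation factor (3×) and the overlap floor (0.5) are
  heuristics; both are exposed as parameters.
* NMDS on heavily censored matrices reflects the censoring value's rank,
  not measured distances, for far pairs.
* The anchor-based splitter assumes one 5.8S-like region; tandem repeats or
  chimeric sequences will split at the best-scoring copy only.
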