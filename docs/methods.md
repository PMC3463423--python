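# Methods

## The highly-expressed-gene reference set

Codon bias is quantified over a fixed 40-gene reference set in which
translational selection is strongest: the elongation factors *tufA*, *tsf*
and *fusA* plus 37 ribosomal-protein genes (*rplA*–*rplF*, *rplI*–*rplT*,
*rpsB*–*rpsT*).  Annotation tables are inconsistent about naming, so
matching is two-stage: a record matches if its gene symbol equals a
canonical name or a synonym (case-insensitive; e.g. *tuf*, *tufB* → *tufA*),
otherwise if its product text contains a catalog pattern such as
"50S ribosomal protein L1".  Patterns are matched as case-insensitive
substrings with a longest-match tie-break, which resolves the systematic
prefix collisions ("…protein S2" inside "…protein S20").  The synonym
table is extensible from a two-column text file, so what is traditionally a
by-hand curation step is explicit and repeatable.  Known limitation:
product matching can in principle hit modification enzymes whose product
text embeds a full pattern (e.g. "…30S ribosomal protein S12
methylthiotransferase…" would match if the annotation also carries the
"30S" prefix); the extensible synonym file is the escape hatch.

Paralogs: all matching copies are kept and counted (a `first_copy_only`
option keeps the first).  Keeping all copies is a documented default, not a
claim about how published tables were built; dropping copies would require
an arbitrary choice among them.  Missing genes never abort a build — a
completeness report is logged — but a table matching none of the 40 genes
is a hard error.

Coordinates follow the NCBI PTT convention (1-based, both ends inclusive);
minus-strand genes are reverse-complemented IUPAC-aware.  A gene whose
length is not a multiple of 3 loses its trailing 1–2 nt with a warning, so
codon counting is always frame 0 from the annotated start; no ORF
re-detection is attempted.  Translation uses bacterial table 11 with the
terminal stop dropped, internal stops rendered `*`, and ambiguous codons
rendered `X` (all logged).

## Metrics

With `x_ij` the count of codon *j* of amino acid *i* over the gene set and
`n_i` the synonymous family size (table 11: Leu/Ser/Arg have 6, Met/Trp 1,
61 sense codons in total):

* `RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij)`, range 0…n_i, mean 1 within a family;
* `NRSCU_ij = x_ij / Σ_j x_ij = RSCU_ij / n_i`, range 0…1, family sums to 1;
* `FB_ij = x_ij / Σ_{i=1..20} Σ_j x_ij`, the codon's share of all sense
  codons; sums to 1 over the 61.

Numerical conventions: stop codons are counted (and reported in the
64-row table) but excluded from every metric, because the FB denominator
runs over the 20 amino acids and RSCU/NRSCU families are amino-acid
families.  A family with zero total count yields 0/0; these entries are NaN
internally and the sentinel `NA` in written tables — reporting 0 would
falsely signal codon avoidance.  Triplets containing non-ACGT characters
are skipped and tallied separately, so input triplets always reconcile as
sense + stop + ambiguous.  Tables are written at 4 decimal places (full
precision retained in memory) to keep outputs diffable.

## Strain comparison

Profiles are vectors of one metric over the 59 informative sense codons —
the 61 sense codons minus the single-codon families ATG and TGG, which are
constant under RSCU/NRSCU and would inflate correlations (a flag re-includes
them, which is only meaningful for FB).  NRSCU is the default profile
metric; the correlation is Pearson's r by default with Spearman behind a
flag.  Entries undefined in either strain are dropped pairwise; fewer than
3 shared entries or a zero-variance profile is an error naming the pair.
Distances are `(1 − r)/2`, mapping r = +1 to 0 and r = −1 to 1.

Trees are fitted to the distance matrix by: neighbor joining for the
starting topology; ordinary (unweighted, power-0 Fitch–Margoliash)
least-squares re-estimation of branch lengths on that fixed topology via
the leaf-pair/edge incidence system; then greedy nearest-neighbor
interchange accepted while the residual decreases by more than 1e-12.
Negative branch-length estimates are clamped to zero after fitting and the
reported residual uses the clamped lengths.  The procedure is deterministic
given input order; on additive (tree-realizable) matrices it reproduces the
generating distances exactly, and the test suite checks the fitted topology
against an exhaustive search over all 105 six-taxon topologies.  Newick
output uses 6 decimals, quotes labels containing spaces, and orders
children by smallest descendant leaf so reruns are byte-identical.
PHYLIP square-matrix export pads names to the classic 10 characters,
replacing spaces and uniquifying truncation collisions.

Per-codon one-way fixed-effects ANOVA compares a metric across ≥2 groups
of ≥2 strains each.  Strains where a codon is undefined are dropped for
that codon; codons retaining fewer than two groups with ≥2 values are
skipped; a codon with no variation at all is reported F = 0, p = 1.
Because 59 codons are tested at once, Benjamini–Hochberg adjusted p-values
are reported alongside raw ones.  A pooled (all-codon) test variant is
possible future work; the per-codon form answers "which codons differ".

## Synthetic genomes

The fixture generator plants all 40 catalog genes (configurable) in a
random genome: per gene, amino acids are drawn i.i.d. (uniform over the 20
by default), then a codon within each family from planted probabilities
`p_ij`; a start ATG is forced, one random stop appended, strands alternate,
and intergenic filler (50 nt default) separates genes.  One
`numpy.random.default_rng(seed)` stream drives everything, so outputs are
byte-reproducible.  Default body length is 100 codons per gene; the default
codon distribution puts half the probability mass on one codon per family,
emulating the strong bias of highly expressed genes in fast-growing
bacteria, and `biased_codon_probs("first"/"last")` provides two
well-separated regimes for group-separation experiments.

What the fixtures do not model: real amino-acid composition, GC/mutational
strand asymmetry, annotation errors, overlapping genes, paralog divergence
and multi-replicon structure.  Passing tests therefore demonstrate the
correctness of the computations and the recoverability of planted signal,
not robustness to every artifact of real RefSeq annotation.

Problem sizes used in the test suite were chosen so the statistical checks
are decisive at desk scale: metric identities over 1,000 random count
tables; counting against a brute-force tally on 100 random genes;
parameter recovery at ~50,000 codons per family (absolute NRSCU error
< 0.02, i.e. many binomial standard errors wide); tree recovery on 20
random additive 6-taxon matrices against the exhaustive 105-topology
optimum; group separation for 10 seeds; and ANOVA type-I calibration over
~1,060 null codons (rejection rate 0.05 ± 0.02).

## Design choices that were genuinely open

* Correlation type (Pearson default, Spearman optional) and the profile
  codon subset (59 informative codons) are package choices; the comparison
  procedure itself only fixes the `(1 − r)/2` transform.
* NJ + least squares + NNI replaces a stochastic heuristic search over
  topologies: it optimizes the same unweighted least-squares objective,
  deterministically, at the scale this package targets; the exhaustive
  search remains a test-side oracle.
* The 0/0 sentinel (`NA`), the keep-paralogs default and the
  truncate-partial-codon policy are documented conventions where the
  problem statement is silent.
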