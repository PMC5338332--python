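# Methods

`gonadmir` implements the computational path of a developmental small-RNA
sequencing study of fish gonads: from raw adapter-ligated reads to class
composition, mature-miRNA counts, isomiR composition, differential
abundance, and the standard descriptive analytics.  This note documents
the models, the declared parameter choices, and what the synthetic
benchmark does and does not establish.

## The measurement model

A small-RNA library is a mixture of short RNA classes.  In gonads the
dominant fraction is piRNA (26–31 nt); miRNAs (~22 nt) contribute a
minority fraction that varies strongly between tissues and stages, with
tRNA-, rRNA- and lincRNA-derived fragments making up most of the rest.
Because the insert is shorter than the instrument read, every read runs
through its 3′ ligation adapter; preprocessing must remove the adapter
and low-quality 3′ ends before any assignment is meaningful.

### Preprocessing

`trim_adapter` removes the best-scoring 3′ adapter occurrence: a full
internal match, or a read-suffix/adapter-prefix overlap of at least
`min_overlap` (default 3) bases, accepting a candidate when its mismatch
fraction is ≤ `max_error_rate` (default 0.1; `N` counts as a mismatch).
Best means maximal (matches − mismatches), ties to the leftmost start so
the longest trim wins.  `quality_filter` then trims 3′ bases whose Phred
score is below 20 and discards reads whose mean quality stays below 20
or whose length falls under 16 nt.  The Phred < 20 rule is the study
convention; whether "removing low-quality sequences" means trimming or
discarding is ambiguous in common usage, so the filter does both —
3′ quality trimming first, then a mean-quality discard — and reports
each tally separately.

### Class annotation

Kept reads are assigned hierarchically to ncRNA classes with the fixed
priority miRNA > tRNA > rRNA > piRNA > lincRNA > other.  A read matches
a class reference by exact substring or full-length single-mismatch
comparison.  Inside the pipeline the miRNA decision is delegated to the
mature-miRNA index (next section) so that isomiR-bearing reads — end
shifts, short tails, one substitution — stay in the miRNA class with
exactly the tolerance quantification uses.  Hierarchical (not multiple)
counting is a declared convention: each read contributes to one class.

### Mature-miRNA mapping and the isomiR decomposition

Each mature miRNA is anchored inside its precursor, which carries ≥10 nt
of genomic flank on both sides.  For a read and a candidate 5′ offset
`o5` (|o5| ≤ 3), the decomposition is fully determined by positional
comparison with the precursor:

* read bases opposite precursor positions *before* the canonical 3′ end
  form the aligned core; at most one mismatch (a substitution call) is
  tolerated there, matching single-mismatch known-miRNA quantification;
* read bases at or past the canonical 3′ end are 3′ additions, each
  *templated* iff it equals the precursor base at that position;
* the signed 3′ offset `o3` (−3 … +4) falls out of the read length.

The only search dimension is `o5`; the best offset minimizes the edit
count (mismatches + |o5| + |o3|), then the number of untemplated
additions, then |o5|.  This canonicalizes the classic ambiguity between
"substitution at the last base" and "trim one, add one untemplated":
the substitution reading has one edit, the trim-and-tail reading two.
A consequence of keeping the single-mismatch budget authoritative is
that a trimmed read with ≥2 untemplated tail bases is out of the search
space (it would need two edits beyond the offset); the variant classes
reported in this kind of study (truncations, templated/untemplated
additions of 1–4 nt, terminal substitutions) all lie inside the bounds.
Test oracles re-derive calls by sliding the read along the entire
precursor and enumerating every placement, which also guards the anchor
arithmetic.

Variant calls are serialized to a canonical key grammar in the RNA
alphabet (`5p+2`, `3p-1`, `3p+AU*` with `*` marking untemplated bases,
`s22:U>G!` with `!` marking the 3′-terminal position).  The grammar is
invertible: `generate_variant_read` builds the unique read a key
describes, and generate → call is the identity over the search space —
the round-trip property the suite asserts key by key.

Multi-mapping reads split equally among hits tied at the best
(mismatches, end-shift) rank, so count-matrix column sums equal mapped
read counts exactly.  The isomiR call of a tied read uses the first hit
in the deterministic sort order; at realistic reference sizes exact ties
across matures are vanishingly rare.

### isomiR summaries

Variant fractions are computed per (group, mature) with replicates
pooled within a group, because stage-level composition is the reporting
unit; per-sample tables remain available from the call table for
variance estimation.  The reporting view suppresses variants below 5%
of a miRNA's reads in a group (`min_fraction=0.05`), while the full
table retains everything.  `substitution_dynamics` tracks the
group-wise fraction of reads carrying a given terminal substitution
(e.g. U→G), the quantity behind stage-resolved substitution profiles.

## Normalization and differential abundance

Size factors are median-of-ratios: `s_j = median_f count[f,j] /
geomean_k count[f,k]`, with the median over features that have no zero
in any sample.  When no such feature exists the estimator is undefined
and the caller must opt into a positive-count fallback (geometric means
over positive entries only).  Normalized counts are `count[f,j]/s_j`.

The test is a simplified negative-binomial Wald test, implemented here
rather than delegated, so that the computation matches the stated
normalization formula and thresholds exactly and every approximation is
visible and simulation-validated:

* dispersion: method-of-moments `α = max((var − mean)/mean², 1e-8)` from
  the within-group pooled variance of normalized counts, shrunk 50/50
  toward a non-negative least-squares `a0 + a1/mean` trend.  The floor
  keeps Poisson-like features well-defined;
* fold change: `log2((mean_B + 0.5)/(mean_A + 0.5))` with pseudo-count
  0.5 bounding the statistic when zeros occur, without shrinkage
  machinery;
* standard error: delta method with `Var(mean_g) = (μ_g + α μ_g²)/n_g`;
* reference distribution: Student t with `df = n_A + n_B − 2` when both
  groups are replicated, chosen over the normal because the moments
  dispersion estimate is noisy at n = 5 and the heavier tail keeps the
  null calibrated (the suite verifies false discoveries stay inside the
  binomial envelope at adj-p ≤ 0.01 with 500 null features); the normal
  is used only in the unreplicated fallback;
* multiplicity: Benjamini–Hochberg across tested features.

A feature is *called* when it passes all three study filters: larger
group mean of normalized reads ≥ 100 (raised to ≥ 1000 for
gonad-vs-gamete contrasts), |log2FC| ≥ 2, adjusted p ≤ 0.01.  "Abundance
in a stage" is read as the group mean, a declared choice.

Designs with single pooled libraries (an undifferentiated baseline, a
pooled spermatozoa sample) cannot support a per-group variance estimate.
The default behaviour is to borrow the pooled dispersion trend with an
explicit warning; silently fabricating replicate variance would be
worse, and refusing outright would exclude the baseline contrasts the
design exists for.

`contrast_matrix` enumerates the study's comparison families from the
sample sheet: each stage × sex against the undifferentiated baseline
(when present), consecutive stages within sex, ovary vs testis per
stage, and gonad vs gamete at the final stage with the raised abundance
filter.

## Descriptive analytics

* **Top-k rankings** use replicate-mean normalized abundance per group,
  ties broken lexicographically; the frequency table counts the groups
  in whose top-k a miRNA appears.
* **Ordination** is an exact PCA (SVD) of samples on log2(normalized+1),
  feature-centered; pseudo-count 1 is a declared choice.  Component
  signs are fixed by making the largest-magnitude loading positive.
* **Titration correlation** scales both libraries to reads per million,
  retains features above 100 RPM in the reference library, and reports
  Pearson r on log2 RPM (the raw-scale r is attached alongside, since
  the scale convention is a declared choice); retained features absent
  from the comparison library are listed as dropouts, the signature of
  low-input library preparation.
* **GO enrichment** is the empirical sampling approach: N = 10,000
  random gene sets of the target size drawn without replacement from
  the universe, `p = (b + 1)/(N + 1)` with b the draws reaching the
  observed overlap, BH across terms.  The +1 smoothing keeps p > 0 and
  unbiased conservativeness; the estimator converges to the exact
  hypergeometric tail, which the suite checks at N = 10⁵.  Target
  prediction itself is out of scope — the enrichment consumes a
  precomputed miRNA→gene table (if producing one with miRanda, the
  conventional cutoffs are a minimum total alignment score of 155 and
  maximum free energy −20 kcal/mol).

## The synthetic benchmark

The generator emulates the library structure such a study assumes:

* class mix defaulting to piRNA 0.55, miRNA 0.25, tRNA 0.08, rRNA 0.04,
  lincRNA 0.06, other 0.02, with class-typical fragment lengths (piRNA
  26–31 nt, tRNA fragments 30–36 nt, miRNA 20–24 nt), so length
  profiles show the piRNA bulge and the ~22 nt miRNA peak;
* per-feature negative-binomial counts (default dispersion 0.05 within
  groups) on a geometric abundance ladder (decay 0.85), the skew real
  libraries show where a handful of miRNAs dominate; planted log2 fold
  changes act multiplicatively on group means;
* five biological replicates per stage × tissue, single libraries for
  pooled designs, ~10,000 reads per library in the benchmark scenario —
  sized so every recovery check runs comfortably on one CPU while
  keeping multinomial sampling error well inside the asserted bands;
* reads are biological sequence + full 3′ adapter + random carrier
  bases, truncated to a 50 nt instrument read, so every read exercises
  the trimmer; per-position Phred scores are Gaussian (mean 35, sd 3,
  clamped to [2, 40]) around a configurable profile — enough to
  exercise the Q20 rule;
* one root seed; per-sample child streams are derived by stable hashing
  of the sample id, so output is byte-identical across runs and
  independent of sample order.

Background classes are random sequences of class-typical length rather
than real annotations: the pipeline consumes only their length and
identity structure.  The generator does **not** model ligation bias,
PCR duplication, or base-call errors beyond the quality scores (bases
are error-free), and references are toy-scale.  Passing recovery tests
therefore demonstrates correctness of the computational path — exact
read accounting, unbiased class and variant recovery, calibrated
testing — not robustness to the chemistry artifacts of real libraries.

Ground truth (expected counts, planted fold changes and variant
proportions, per-class and per-read provenance) is emitted alongside
the data, and every recovery test scores against this truth object,
never against a re-simulation.

## Numerical and degenerate-input conventions

Sequences are handled internally in the DNA alphabet (`U`→`T` at
ingest) and re-emitted as RNA in variant keys and reports.  Empty
libraries, all-zero count rows, constant matrices, too-few retained
features, unknown groups and malformed variant keys raise
`ValidationError` with actionable messages.  isomiR fractions per
(group, mature) sum to 1 within 1e-9 and are asserted to.  All
stochastic components take explicit seeds.

## Known limitations

* The Wald test is not a reimplementation of a full GLM framework: no
  outlier handling, no fold-change shrinkage, two-group contrasts only.
  Numerical parity with such frameworks is a non-goal; the agreement
  claimed — and tested — is with the stated formula and filters.
* isomiR calls carry no sequencing-error model; at real error rates a
  fraction of terminal "substitutions" would be miscalls, which is why
  per-position error modelling is listed as future work rather than
  implied by passing tests.
* Novel-miRNA discovery (hairpin folding and scoring) is out of scope;
  quantification is against a known mature catalogue.
* The class annotator is substring/1-mismatch, not a genome aligner; it
  reports class fractions, not per-locus assignments.
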