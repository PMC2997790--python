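# Methods

## Tag model

A tag library reads, for each transcript copy, a single 21-base tag:
`CATG` (the NlaIII site) plus the 17 downstream bases released by MmeI.
The analysis therefore treats a reference unigene not as a sequence to
align against but as a bag of *virtual tags* — every `CATG` window with
at least 17 downstream bases. Both strands are indexed by default
because de novo unigenes have unknown orientation; a flag restricts the
scan to the + strand. Windows containing `N` are skipped: an `N` can
never match a sequenced tag exactly, and all N-bearing reads are
removed by QC anyway. Coordinates are 0-based on the + strand; a
reverse-strand tag records the offset of its window's leftmost + strand
base.

Mismatch-tolerant lookup allows one substitution, restricted by default
to the 17-base variable region: a true tag necessarily begins at an
NlaIII cut, so a mismatch inside `CATG` would imply the tag was never
produced there. The restriction is a flag (`anchor_strict`), since an
instrument error can in principle hit the anchor too. Exact matches
pre-empt one-mismatch matches, so a perfectly matching tag is never
diluted by the 1-mismatch neighbourhood of other genes. Lookup is by
neighbourhood enumeration — 3×17 = 51 variants per query against a hash
map — which is O(1) per query and is verified in the tests against a
brute-force Hamming scan of the whole index.

## QC filters

Three filters, applied with a declared precedence so that the report is
an exact partition of the raw reads (first matching rule wins):

1. `N` anywhere in the first 21 bases → low quality;
2. no `CATG` at position 0 (adaptor-only/no insert; also any read
   shorter than 21 bases) → empty;
3. after tallying, tags with library-wide copy number exactly 1 →
   singletons, removed as probable sequencing errors.

The identity `n_raw = n_with_N + n_empty + n_singletons + n_clean` is
asserted inside the classifier on every run and property-tested on
random inputs. Bases 22–35 of a read are adaptor-2 sequence and are
ignored. Copy-number distributions use half-open bins `[lo, hi)` with
default edges 2, 5, 10, 20, 50, 100, ∞; the headline "copy number
greater than 100" shares are computed directly with a strict threshold
rather than from the default bins.

## Quantification

Only unambiguous tags (exactly one gene after exact-then-one-mismatch
resolution) contribute to gene counts; a tag whose neighbourhood spans
several genes is counted as mapped but not assigned — no fractional or
nearest-gene rescue. TPM is tag count per million *clean* tags (not
mapped tags), so TPMs sum to 10^6 only when every clean tag maps
unambiguously; this is a library-size normalization only, with no
transcript-length term, because each transcript contributes one tag
regardless of its length. Summary tables report distinct-tag
percentages relative to distinct clean tags and gene counts relative to
the reference size.

## Differential expression

For counts x, y in libraries of clean-tag depths N1, N2, the
Audic–Claverie conditional distribution of y given x (flat prior on the
shared abundance) is

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) ),

a negative binomial in y with x+1 successes and success probability
N1/(N1+N2). The pmf is evaluated in log space (gammaln), finite up to
counts of 10^6; cumulative tails use the regularized incomplete beta
function and its complement, so extreme tails keep full relative
precision.

Two-sided p-values double the smaller inclusive tail. The conditional
construction is not literally symmetric in the two libraries — the two
orientations differ by exactly the probability mass of the observed
point — so the implementation evaluates both orientations and reports
the larger doubled-min-tail, capped at 1. This symmetrized form is
exactly invariant under swapping (x, N1) ↔ (y, N2), conservative by
construction, and agrees with direct tail summation of the exact
rational pmf in the tests.

Multiplicity is controlled with Benjamini–Hochberg; a gene is called at
FDR < 0.001 and |log2 ratio| > 1 (both configurable). The ratio shown
and thresholded is the TPM ratio after substituting one pseudo-tag for
zero counts only — genes private to one library ("library-specific",
flagged separately) thus get a finite, large ratio — while the test
itself always uses the raw counts, which the statistic handles natively
at zero. Under the defaults this test is conservative (measured type-I
error ≈ 1.5% at nominal 5% on null simulations), which is the expected
behaviour of a discrete doubled-tail test.

## Enrichment

For N annotated background genes, M carrying a term, n annotated DE
genes and m of them carrying the term, the enrichment p-value is the
hypergeometric upper tail P(X ≥ m); m = 0 gives exactly 1. Unannotated
genes are excluded from both N and n, the tested universe is the set of
terms with at least one background member, and the correction
multiplicity is the number of tested terms — untested terms cannot
reject and should not inflate the correction. Bonferroni (GO-style) and
BH (KO-style) corrections are both offered at α = 0.05. No
ontology-graph propagation is performed: a gene's term set is taken as
given, and any DAG ancestor closure is the caller's responsibility.

## Synthetic data

The generator emulates the features the analysis depends on:

* **Reference**: log-normal gene lengths (median 841 bases, sigma
  0.45), uniform random sequence with one canonical tag planted as the
  last 21 bases — by construction the 3′-most site with a full
  downstream window, mirroring the chemistry's one-tag-per-transcript
  readout even though the index may hold several windows per gene. A
  configurable fraction of genes reuses another gene's canonical tag to
  exercise ambiguity.
* **Expression**: log-normal relative abundances (sigma 2.5 by
  default; a Zipf alternative is available). With 30,000 genes and one
  million reads the defaults reproduce the structure of a real tag
  library: tags with copy number above 100 carry ~67% of the clean
  mass but only ~3.5% of the distinct clean tags, and the clean
  fraction lands near 83%. Sigma and the reference size were chosen
  together against those structural targets and then frozen.
* **Reads**: 35 bases — the canonical tag plus adaptor-2 filler.
  Substitution errors hit the 21-base informative window at 1% per
  base (the filler is ignored downstream and emitted error-free);
  errors in the `CATG` anchor turn the read into an "empty" classifiee,
  and error variants of low-copy genes become singletons, so the QC
  losses arise mechanistically rather than by injection. N-containing
  (3%) and adaptor-only (4%) reads are injected on top. Read counts
  equal the configured depth exactly.
* **Paired experiments**: clean per-gene counts are drawn multinomially
  at the configured depth, with a `de_fraction` of genes scaled by
  `de_fold_change` in library 2 (half up, half down) and abundances
  renormalized; the truth table records the applied factor (1 for
  non-DE genes). Sampling counts directly is distributionally the same
  as simulating reads and running QC/mapping on them, and keeps
  many-seed recovery studies cheap; the read-level path exists
  separately for exercising QC and mapping.
* **Annotation**: background term sizes are log-normal (mean 25).
  Planted enriched terms take the configured mean size exactly — a
  heavy-tailed size draw can produce a planted term too small ever to
  reach significance, which would make it useless as a recovery
  benchmark — and sample members with 10:1 odds on the designated DE
  genes.

Every generating call requires a seed; the CLI draws one from entropy
only if none is given, and logs it.

What the generator does **not** emulate: quality scores, PCR
duplicates, positional error profiles, indels (the mapper is
Hamming-only by design), incomplete NlaIII digestion (which in real
data expresses non-3′-most tags), SNP-induced tag variants, and
unassembled transcripts (real libraries contain many legitimate tags
absent from the reference). Passing tests therefore demonstrate the
correctness and calibration of the statistics and bookkeeping under
the stated model, not robustness to every artefact of real libraries.

## Problem sizes and numerical choices

Validation studies use sizes chosen to make the checks statistically
meaningful yet quick: null calibration over 50 seeds at 2,000 genes and
depth 10^5 per library; fold-change recovery over 20 seeds at 10% DE
genes, 4-fold, depth 10^6 (pooled across seeds, empirical FDR ≈ 1%,
sensitivity > 99% for genes with baseline TPM ≥ 50); enrichment
recovery over 20 seeds; mapper-vs-brute-force agreement over 50 random
references × 1,000 queries; and simulator calibration over 5 seeds at
depth 10^6. Ties in BH are handled by the standard cumulative minimum;
percentages in summary tables are ratios × 100 rounded to two decimals;
empty inputs (empty library, empty DE list, zero-depth request) raise
errors rather than returning degenerate results.

## Known limitations

Library-specific genes are certain to pass the fold threshold by
construction of the pseudocount, so their calls rest entirely on the
FDR criterion. The Audic–Claverie model assumes no biological
replication (each library is a single sample); with replicates a
dispersion-modelling framework would be preferable. The one-mismatch
neighbourhood treats all substitutions as equally likely, ignoring
instrument-specific error spectra. Multi-gene tags are discarded from
quantification, biasing against recently duplicated gene families.
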