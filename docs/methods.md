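# Methods

## Conversion quantification

For each gene, counting is restricted to a single annotated 3′UTR window
(BED6, 0-based half-open, strand-aware), matching 3′-end sequencing
protocols in which reads pile up over the 3′UTR. A read contributes only
to windows on its own strand: plus-strand windows take forward reads and
score reference `T` read as `C`; minus-strand windows take reverse-flagged
reads and score the plus-strand representation `A` read as `G`.

Per aligned read–base pair, a position is counted into a gene's
**T coverage** when all of the following hold, and additionally into its
**T>C count** when the read calls the converted base:

* the reference base at the position is sense-strand T;
* the aligned position lies inside the gene's window;
* the base call quality is at least `min_base_quality` (default 27);
* the position is at least `trim5` (default 12) bases from the read's 5′
  end — for reverse reads the 5′ end is the highest query index — removing
  adapter- and priming-contaminated read starts;
* the position is not SNP-masked (below).

Whole reads are discarded when unmapped, secondary/supplementary, or when
their `NH` tag exceeds `max_alignments` (default 100). Per-filter tallies
are attached to each count table and recorded in the run manifest. The
per-gene **T>C fraction** is the ratio of the two counts, undefined (NA)
at zero coverage.

### SNP masking

A germline T>C variant converts in every animal of both genotypes, while
labelling converts a minority of molecules in Cre⁺ animals only. The two
are separated on pooled evidence rather than per-sample variant calling
(littermates share genotype in expectation): in one pass over **all**
samples, every in-window sense-T site accumulates a pileup (untrimmed —
the variant is genomic, not a read-end artefact), and a site is masked
when pooled coverage ≥ `min_snp_coverage` (default 10) and the converted
fraction ≥ `min_var_fraction` (default 0.2). Masked sites are excluded
from both coverage and conversion counts. The 0.2 threshold sits far above
any plausible labelling signal (a labelled fraction of 0.2 at conversion
rate 0.025 yields ≈ 0.006) and far below a homozygous variant (≈ 1).

## Labelling statistics

### Model

For gene *g* and animal *i*, let *k* be the T>C count out of *n* T
observations. Within a replicate, conversions are modelled binomial with
probability *p*; across biological replicates *p* varies as
Beta(α, β), parameterised by the mean μ = α/(α+β) and the intra-class
correlation ρ = 1/(α+β+1), so that

    α = μ(1−ρ)/ρ,   β = (1−μ)(1−ρ)/ρ.

The marginal is beta-binomial with log-pmf

    log C(n,k) + B(k+α, n−k+β) − B(α, β)

(computed with `gammaln`/`betaln`); ρ → 0 recovers the binomial, and the
implementation switches to the exact binomial branch below ρ = 10⁻¹⁰ with
explicit 0·log 0 boundary handling.

### Test

Each gene is tested Cre⁺ (n=4) versus Cre⁻ (n=3) with a likelihood-ratio
test using a single dispersion shared across groups and hypotheses:

1. **H1 fit**: maximise the likelihood over (μ⁺, μ⁻, ρ) with group-specific
   means and common ρ.
2. **H0 fit**: with ρ held fixed at the H1 estimate, maximise over a single
   shared μ (closed form when ρ̂ = 0: the pooled rate).
3. Statistic 2(ℓ₁−ℓ₀), floored at 0, referred to χ²(1); p-values clamped
   to (10⁻³⁰⁰, 1].

Genes with zero conversions in every replicate carry no information about
a group difference and receive statistic 0, p = 1 deterministically. Genes
with zero T coverage in **any** replicate are removed before testing and
itemised in a filter report. Benjamini–Hochberg adjustment is applied
across tested genes, and a gene is called **labelled** when q < FDR
(default 0.05) *and* μ⁺ > μ⁻ (one-direction biological constraint applied
after the two-sided test).

### Numerics

The H1 likelihood is maximised with bounded L-BFGS-B on logit coordinates
(|logit μ| ≤ 34.5; ρ ∈ [10⁻⁸, 1−10⁻⁹]), initialised from method-of-moments
estimates. Because the MLE frequently sits on the ρ = 0 boundary (where
the logit coordinate diverges), the optimiser result is compared against
the closed-form binomial fit and the boundary solution is taken whenever
it is at least as good; ρ̂ ≤ 1.01×10⁻⁸ is snapped to 0. A Nelder–Mead
polish is applied if the line search fails. Derivative-free simplex
optimisation alone was evaluated and rejected: on null-heavy data ~34% of
genes failed to converge as the ρ coordinate ran toward −∞ on the logit
scale.

### Computed calibration properties

All figures below were measured with this package's own generators.

* **Type-I error.** At a sparse overdispersed null (μ = 0.001, ρ = 0.01,
  per-replicate coverage uniform on 200–2000, 4+3 replicates), the
  empirical P(p < 0.05) is 0.075 ± 0.003 (8 × 2,000 simulated genes): the
  χ²(1) reference is mildly anticonservative at 7 replicates. The profile
  construction (ρ from H1 held in H0) trades this slight liberality for
  power; re-maximising ρ under H0 is calibrated-to-conservative but lets
  the null absorb the group difference into dispersion, collapsing power
  (≈ 24% versus ≈ 64% recovery at a 0.0058-vs-0.001 effect).
* **Point mass at p = 1.** Under the same sparse null, ≈ 20% of genes have
  zero conversions in all 7 replicates and deterministically receive
  p = 1, so the p-value distribution is uniform-with-an-atom, not uniform;
  any distance-to-uniform statistic is bounded away from zero (measured
  Kolmogorov–Smirnov distance ≈ 0.27, atom mass ≈ 0.20).
* **Dispersion bias.** Mean ρ̂ under-recovers the generative ρ by the
  classic maximum-likelihood factor ≈ (n−1)/n at n = 7 replicates
  (0.02 → ≈ 0.017); the unit tests assert against the bias-adjusted
  target.

### Rank test helper

`groupwise_rate_test` provides a tie-corrected Mann–Whitney U alternative
on per-replicate fractions: for group sizes ≤ 8 the exact two-sided
p-value is computed by complete enumeration over midranks (tie-aware);
larger groups fall back to the normal approximation with tie correction.
All-identical inputs are degenerate and return p = 1.

## Synthetic experiment generator

The generator produces the computational input of a labelling experiment
with known truth; its defaults are the package's study conditions.

* **Reference.** One contig per gene: a 3′UTR window (length uniform on
  250–450 by default) flanked on both sides by `read_length − 1` bases, so
  every window position has identical expected coverage. Bases are i.i.d.
  with configurable GC content (default 0.5); windows are resampled until
  they contain at least one sense-strand T whenever the composition allows
  one. Strands are assigned at random (half minus-strand by default).
* **Design.** 4 Cre⁺ and 3 Cre⁻ animals. A chosen subset of genes is
  labelled with fraction *f* (default 0.2) in Cre⁺ and 0 in Cre⁻;
  optionally each animal's *f* is drawn from a Beta distribution around
  the group value to emulate biological variability.
* **Reads.** Per sample, read totals are multinomial across genes
  proportional to expression; starts are uniform over all placements
  overlapping the window; reads are emitted pre-aligned (single-M CIGAR,
  MAPQ 60, `NH:1`, Q40 bases) — read alignment is upstream of this
  package's scope, and true placements keep the counting layer testable
  in isolation.
* **Chemistry.** Two-level Bernoulli: a read comes from a labelled
  molecule with probability *f*; each sense-T of a labelled molecule is
  read as C with probability *c* (default 0.025). Independently every
  base not already converted is miscalled uniformly to one of the three
  other bases; `error_rate` (default 0.001) is the rate of one *specific*
  substitution, so the total per-base miscall rate is 3×`error_rate` and
  the expected per-base T>C probability is exactly
  f·(c + (1−c)·e) + (1−f)·e ≈ f·c + (1−f)·e to first order.
* **SNPs.** A configurable fraction of genes receives one homozygous
  genomic T>C variant at a random sense-T window position, applied to the
  molecules of **all** samples while `reference.fa` keeps the T — exactly
  the situation the SNP mask must detect. Variant offsets are recorded in
  the truth table.
* **Determinism.** All randomness flows from one seed through
  `numpy.random.SeedSequence` spawning (per-replicate child seeds reduced
  mod 2³¹−1); a config reproduces every output file byte-for-byte.

## Limitations

* The generator emits true alignments with pure-match CIGARs; alignment
  error, indels, soft-clipping, conversion-aware-mapping bias and
  multimapping structure are out of scope (the counting layer nevertheless
  handles arbitrary CIGARs and `NH` tags on real input).
* Reads are treated as molecules: no PCR duplicates or UMI structure.
* The beta-binomial test relies on the asymptotic χ²(1) reference at 7
  replicates, with the measured mild anticonservatism quoted above; genes
  with conversions in no replicate are uninformative by construction and
  receive p = 1.
* BH correction assumes the usual positive-dependence conditions across
  genes.
* Windows are taken as given; 3′UTR annotation error and internal priming
  are upstream concerns.
* GO-term enrichment and figure rendering are out of scope; the ranked
  gene list, overlap cardinalities (JSON) and plotting tables are emitted
  for external tools.
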