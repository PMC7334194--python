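# Methods

## Data model and coordinate conventions

Internal coordinates are 0-based half-open everywhere. VCF I/O uses 1-based
inclusive positions with POS as the first affected base (see
`docs/formats.md` for the one-base caveat against the padding-base symbolic
convention); BED output is 0-based half-open. Insertions are points
(`end == start`) whose `svlen` is the inserted length.

Breakends (BND) are parsed but quarantined: they appear in no analysis.
Multiallelic CNVs (MCNV) carry integer per-sample copy numbers and
participate only in per-genome counts and positional enrichment; every
statistic defined on biallelic dosage (SFS, HWE, APS, LD, PCA, burden)
excludes them. Allele counts (AC/AN) are always computed over the unrelated
sample subset; related samples exist only for trio checks.

## Synthetic cohorts

The generator produces the statistical structure the analyses assume, at
desk scale. What it emulates, and how:

* **Site counts and frequencies.** Per SV class, K ~ Poisson(θ_class · a_n)
  sites with allele counts i drawn with probability ∝ i^−(1+α). α = 0 is
  the neutral infinite-sites spectrum (singleton fraction 1/a_n); the
  default α = 0.8 is a growth-like tilt chosen so the default cohort lands
  in the regime real WGS SV cohorts report — roughly half of sites
  singletons and ~90% rare (AF < 1%). Per-category selection adds s to the
  tilt for affected sites (resampling weight ∝ i^−s), the minimal
  monotone-AF model a singleton-based selection metric needs.
* **Genotypes.** Each site's drawn allele count is preserved exactly: the
  copies are allocated among populations with multinomial weights
  ∝ n_pop · p_pop, where p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F) is the
  Balding–Nichols frequency around the global p, then placed uniformly on
  chromosomes within a population. Within-population genotypes satisfy HWE
  by exchangeability, and the realized spectrum equals the sampled one —
  a binomial redraw at p = 1/2N would have destroyed the singleton
  calibration. Default F per population is 0.02–0.10, enough for PCA to
  separate labels as in real cohorts.
* **Sizes.** Log-normal per class (median 1.5 kb deletions, 5 kb
  duplications, …); insertions are a 3-component log-normal mixture with
  modes at 300 bp / 2.1 kb / 6 kb and weights 0.60 / 0.25 / 0.15, the
  mobile-element (Alu / SVA / LINE-1) peaks.
* **Positions.** A 4-chromosome, 295-Mb synthetic genome with p/q arms and
  centromere gaps. Placement is uniform within arms with per-class
  telomeric/centromeric density multipliers (rejection sampling over the
  outer/inner 10% of each arm); deletions default to a mild telomeric
  excess.
* **Functional categories.** When gene models are supplied, a configured
  fraction of DEL/DUP sites is deliberately placed to realize an intended
  category (exon-covering DEL → pLoF, transcript-spanning DUP → copy-gain,
  intragenic full-exon DUP → IED, intron, promoter); the truth table
  records the intent, which the annotation decision table recovers for
  ≥ 99% of placements. Selection strengths attach to these categories
  (defaults: pLoF 0.35, copy-gain 0.15, IED 0.10).
* **Trios.** Children of disjoint parent couples by Mendelian transmission.
  Genotyping error flips any call to a random different genotype with
  probability e (default 2×10⁻⁴ per call, the order at which trio
  violation rates stay in the low percent range); e = 0 gives exactly zero
  Mendelian violations, and the violation rate is monotone in e.
* **Complex alleles.** Each CPX site gets a random resolved structure from
  the 11-subclass catalogue; the stored truth label must round-trip through
  the classifier (enforced by tests).

What it does **not** emulate: breakpoint sequence context, reference biases,
caller-specific artifacts, haplotype/recombination structure (LD pairs are
simulated directly as correlated dosage vectors), overlapping variation,
and relatedness beyond nuclear trios. Passing tests therefore demonstrate
the statistics are implemented correctly and recover injected signal under
the model's assumptions — not that any particular real callset satisfies
those assumptions.

Default scale is 500 unrelated samples (~20,000 sites, 50 trios), chosen so
a full pipeline run plus the test suite stay in the minutes range on one
core; everything is overridable through `SimulationConfig`.

## Population-genetic statistics

* **HWE**: chi-square with 1 df against (p², 2pq, q²) at the observed
  allele frequency; monomorphic sites return p = 1. An exact conditional
  test is available (`hwe_test_exact`) for small counts; the chi-square
  default is a speed choice at tens of thousands of sites. The
  cohort-level "fraction in HWE" counts sites with p ≥ 0.05 — the threshold
  is configurable because published summaries rarely state theirs.
* **Watterson/mutation rate**: θ̂ = K/a_n; per-birth rate 2·θ̂/(4·N_e).
  N_e defaults to 10,000 and is always echoed in the result — the rate is
  only as good as the N_e and the site filtering behind K, so both are
  explicit inputs. The CI is a parametric bootstrap K* ~ Poisson(θ̂·a_n).
* **Mendelian checks** are computed over trio-informative sites (any
  non-reference call in the trio), matching how violation rates are
  reported by genotyping pipelines.
* **Burden**: a gene counts once per sample per category if any carried
  allele hits it; "rare" is AF < 1%, "very rare" AF < 0.1%.
* **PCA**: column-centered dosages via SVD; deterministic sign convention
  (largest-magnitude loading positive). Missing dosages are mean-imputed.
* **LD**: squared Pearson correlation of dosages, defined within one
  population; zero-variance input is an error, not a zero.

## APS

Binomial GLM with logit link of the singleton indicator on SV-class
dummies, log10(svlen) and optional context flags, fitted on intergenic
biallelic PASS sites. The ML intercept makes the in-sample mean prediction
equal the observed singleton fraction, so the reference stratum scores
exactly APS = 0 — this is the calibration identity the tests assert, not a
tuned result. Covariates constant in the reference are dropped and recorded
in the serialized model schema; scoring data missing a model covariate is a
hard error. Query scores use 100-fold bootstrap CIs and a one-tailed t-test
of per-site residuals; Bonferroni counts come from the number of categories
actually tested in a run. Known limitation: strata whose covariate support
differs sharply from the reference (e.g. all sites the same size) can show
small spurious APS, which is precisely why the bootstrap CI and category
sizes are reported alongside the point estimate.

## Gene constraint

Poisson log-linear expectation (log10 transcript length, exon count, log10
intron length). With an intercept, the ML fit reproduces the total observed
count, so aggregate O/E = 1 by construction — per-gene and per-bin
*relative* depletion is the meaningful signal, and measuring *absolute*
injected depletion requires calibrating the expectation on neutral data
(the recovery test does exactly that). Genes with expected < 0.1 events are
flagged uninformative. Bin-level depletion uses summed counts
(1 − Σobs/Σexp), not averaged per-gene ratios, for stability at low means;
bins are ordered least→most constrained so constraint-linked depletion
gives a positive Spearman ρ.

## Meta-chromosome

100-kb source windows per arm, meta coordinate of the window center, 100
meta bins, per-class normalization to mean 1, centered 11-window rolling
mean truncated at the edges and renormalized (truncation would otherwise
bias edge bins). Positional classes: T within 0.10 of a telomere, C within
0.10 of the centromere, I otherwise — the 10% boundary is a convention,
exposed as a parameter. Positional t-tests use the unsmoothed bin
enrichments (smoothing correlates neighbors and would invalidate the
t-test); Welch's test, two-sided, Bonferroni over all class×position
comparisons actually run. Arms are averaged unweighted.

## Complex-SV classification

Structures are lists of non-overlapping source segments (orientation, copy
state, optional insertion locus). Canonicalization orders in-place segments
along the reference and emits a token signature; classification is a pure
lookup on the signature, so `classify ∘ canonicalize = classify` by
construction. Mirror pairs (delINV/INVdel, …) are kept distinct in the
core and collapsed only as a reporting option, with the three unambiguous
mirror pairs as the default aggregation map. Pure single-signature
structures route to canonical classes (a lone inverted segment is an
inversion, not a complex SV); unknown signatures are `unresolved`, never an
exception. Flank classes are assigned on token order without requiring
breakpoint adjacency — a gap between a flanking deletion and the inverted
segment does not change the signature.

## Clinical screens

Clopper–Pearson intervals throughout (exact coverage at small carrier
counts). Genomic-disorder carriers need a single CNV call of the locus's
dosage direction covering ≥ 50% of the critical region (single-call
coverage, not a union; the threshold is a parameter). The balanced/complex
share of large rare SVs is computed over qualifying sites observed in at
least one carrier. Large-SV and gene-list screens are pure functions of the
cohort and thresholds, so they are rerun-stable.

## Numerical and reproducibility choices

One `SeedSequence` per run spawns independent sub-streams per stage, so
changing one stage's workload does not perturb another's draws. Pipeline
JSON output rounds floats to 6 digits and sorts keys, making identical
configurations byte-identical. Bootstrap replicates default to 100
everywhere. Degenerate inputs follow explicit conventions documented at
each operation: monomorphic HWE p = 1, single-site APS CIs flagged
degenerate, constant conservation tracks flagged undefined rather than
correlated, empty meta-chromosome strata reported as NA.
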