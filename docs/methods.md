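# Methods

## Coordinates, formats, and calling rules

Site tables are 1-based (allc convention: chrom, pos, strand, context,
per-strain `mc`/`cov`); all intervals (segments, genes, chromatin states)
are 0-based half-open. The genome is tiled into non-overlapping windows of
2000 bp; a trailing partial window is kept, flagged, and its density uses
its true length. CpG density is the count of forward-strand CG
dinucleotides per kilobase, irrespective of methylation.

A site's methylation call requires coverage ≥ 5 reads; with adequate
coverage the site is called methylated when ≥ 10% of reads are methylated
and *unmethylated* otherwise — lack of evidence at adequate coverage is a
negative call, not a missing one. Both thresholds are configurable. Strand
handling: readers never merge the two strands of a symmetric CpG; an
explicit `collapse_symmetric_cpgs` utility pools reverse-strand records
onto the forward-strand C when the analyst wants strand-collapsed counts.

Coverage imbalance between two strains is corrected per window by thinning
the higher-coverage strain's methylated reads: each methylated read is kept
independently with probability (lower total)/(higher total), i.e. the
per-site thinned count is Binomial(mc, ratio). Bernoulli thinning is the
minimal-assumption reading of "randomly reduced proportionately"; it never
increases a count and leaves the lower-coverage strain untouched. All
stochastic steps take explicit seeds.

Cell-level QC keeps cells with mCCC < 0.03, global mCG > 0.5, global
mCH < 0.2, mapped reads > 100,000, mapping rate > 0.5 and percent genome
covered > 2 — all strict inequalities, all configurable; records with any
missing metric are reported as incomplete rather than failed.

## Conservation statistics

For a strain pair in one window, over sites callable in both strains:
`prop_pp` (methylated in both), `prop_qq` (unmethylated in both), their sum
the same-state probability, and the methylated-count ratio min/max
(undefined when both counts are zero; such windows are excluded from pooled
ratios). Pooling by integer density bin concatenates member windows' site
vectors — proportions become site-count-weighted sums and the pooled ratio
uses bin-total counts — rather than averaging per-window values. The
figure-level "probability" is taken as `prop_pp + prop_qq`; both components
are always emitted so a conditional convention can be recovered. A site
that is uncallable in one strain is dropped only for pairs involving that
strain.

## Mutation–expression analysis

Candidate mutations: sites where the reference strain carries a
called-methylated CpG (allele C) and the focal strain's allele is A or T,
so the site cannot be methylated on either strand. The mirrored reading
(methylated CpG in the focal strain) is available via `direction=
"focal_methylated"`; the active direction is logged. Density class is
*high* iff window density strictly exceeds 40 CpG/kb. Each mutation is
annotated with every overlapping extended gene interval ([txStart − 2 kb,
txEnd + 2 kb), strand-symmetric, clamped to chromosome bounds), one record
per mutation–gene pair, plus an optional chromatin-state label (first
overlapping interval of a 15-state track; labels can be gated on ≥ 10
pooled open-chromatin reads when an accessibility table is supplied).

The response is the gene's log2 fold change, inverse-normal transformed
over the whole analysis table (`Φ⁻¹((rank − 0.5)/n)`, average ranks for
ties, missing kept in place). Models:

* within one density class: `y ~ mutation + density` (density continuous
  within class; the binary class is used between classes);
* interaction: fit0 `y ~ covariates + class + mutation` vs. fit1 adding
  `class:mutation`, compared by a nested F test. Covariates: chromosome,
  standardized position, chromatin state.

**Inference default.** Every site of a gene carries the same expression
value, so per-site OLS residuals are clustered by gene and naive standard
errors are anticonservative. All model p-values therefore default to
cluster-robust (by gene) covariance; with clustering the nested comparison
is the robust Wald F for the added interaction term, which coincides with
the classical F when clusters are singletons. Naive errors remain available
(`cluster_by_gene=False`) for comparison with permutation results. The
degenerate design (a single density class, making the interaction
collinear) raises an error naming the cause.

Calibration is checked by permuting expression values among genes (each
gene's value moves with all its sites; labels stay fixed), recomputing the
statistic per permutation, reporting the add-one empirical p
`(b + 1)/(n_perm + 1)` and a KS test of the permuted nominal p-values
against Uniform(0,1).

The chromatin-state scan fits `y ~ mutation` per (state × class) cell and
reports counts, percent mutated and the mutation-term p, flagged at both
Bonferroni conventions (α/30 = 0.00167 and the printed 0.001); a cell with
no mutated sites reports a missing p, never 1. Sweeps refit the interaction
across density thresholds 14–60 (the sweep table records both the
effect-size argmax and the F argmax; the F peak is reported as the change
point because effect estimates at extreme thresholds, where one class is
tiny, are noise-dominated, while the two peaks coincide when the signal is
real) and across transcript-inclusion ceilings on |log2FC| (0.2–8),
analysing the excluded large-effect gene set separately with its own
mutation-term fit.

## Synthetic-data generator

`synthio` generates the full input bundle with a ground-truth ledger
sufficient to recompute every observable. Defaults are the package's study
conditions, echoing the printed magnitudes; all are overridable.

* **Genome**: 2-kb segments over a density spectrum of 14 target densities
  (5–120 CpG/kb) × 100 segments on 2 chromosomes; per segment the CpG count
  is Poisson(2 × target), CpGs placed uniformly on even offsets (so pairs
  never collide), background bases A/T (CpG-free by construction). Target
  densities above 500/kb are rejected as physically impossible.
* **Methylation**: ancestral state per site is Bernoulli of the
  density-level curve (0.86 below 25 CpG/kb, 0.50 in 25–40, 0.12 above 40).
  Below the conservation breakpoint (40) each strain relocates k methylated
  sites (off) and k unmethylated sites (on) per segment — counts preserved
  exactly — with k solving the expected-pairwise-mismatch equation
  `2(2k − k²(1/m + 1/u))/n = 1 − c` for target concordance c = 0.8; the
  collision term matters because the unmethylated class is small at high
  methylation levels (which also caps the low-band level at 0.86: expected
  mismatch cannot exceed ≈ 2(1 − f) under exact count conservation). Above
  the breakpoint each strain *drops* ancestrally methylated sites at a
  strain-specific rate (0.15 + 0.15 × strain index) and never gains any:
  surviving sites coincide while counts drift, so the same-state
  probability exceeds the pooled ratio. The regime switch is sharp at 40;
  the real transition appears gradual between 40 and 80 CpG/kb, so the
  generator's reversal begins earlier than the observed one — the orderings
  below 40 and above 80 are unaffected.
* **Reads**: coverage is negative-binomial (mean 20, size 10; the real
  depth profile is not parametrically described, NB is the standard
  overdispersed choice); methylated reads Binomial(cov, 0.8) at methylated
  sites and Binomial(cov, 0.01) otherwise.
* **Variants**: outgroup-lineage C→T divergence at CpGs with rates
  (methylated/unmethylated) 0.05/0.02 below 40 CpG/kb and 0.008/0.02 above
  — methylated excess below, reversal above. Divergence is placed on the
  outgroup so each strain's methylation call exists at every divergent
  site. Candidate mutations: focal-strain A/T at reference-methylated CpGs
  at rate 0.06, with the focal strain's coverage zeroed there (no C to map
  to). The spectrum size and candidate rate were sized so the high-density
  class holds several hundred candidate mutations — the order needed for
  the within-class effect to be detectable at all, as in the source data —
  while keeping a default run under ~15 s. A sprinkle of non-C background
  variants (rate 0.001) exercises the exclusion paths.
* **Expression**: per gene, log2FC = 0.16 × (high-density candidate
  mutations in the extended interval) + 0 × (low-density count) + density
  slope (default 0) × mean density + N(0, 1); 5% of genes get a structural
  offset −3.0 − 0.8 × (mutation count), giving the large-|FC| subset its
  negative mutation association. The DE p-value comes from an independent
  noisy re-measurement (z = (log2FC + N(0, σ))/(σ√2)), so filtering on it
  does not sharply truncate the response. With noise SD 1 the response is
  approximately standard normal, so the inverse-normal transform is close
  to an affine map and the fitted mutation coefficient is directly
  comparable to the generative 0.16.
* **Chromatin states**: a 500-bp partition labelled from the 15-state
  vocabulary (enhancer and quiescent weights boosted 4×). With
  `enhancer_effect=True` only high-density mutations inside "Active
  enhancers" carry the expression effect.
* **Seeding**: one master seed fans out per layer via
  `SeedSequence((seed, layer_index))` with fixed indices, so regenerating
  one layer never perturbs the others.

`sample_analysis_table` draws the per-site modelling table directly from
the same effect model (Poisson sites per gene, continuous densities,
Bernoulli mutations), skipping the sequence layers; calibration, recovery,
sweep-localization and scan studies use it because the sequence layers only
add runtime, not statistical content. Replicate counts and table sizes in
the test suite (e.g. 1,000 null replicates of 2,000 genes; 16,000 genes for
the scan study) were chosen so each check has adequate power at the default
effect sizes.

## What the generator does not emulate

Read-level artifacts (bisulfite conversion error beyond a flat 1% rate,
mapping bias), CH methylation dynamics, linkage between variants, cell-type
mixtures, realistic gene-length and density autocorrelation structure, and
count-based DE estimation. Passing tests therefore demonstrate the
pipeline's correctness and calibration under the stated generative model,
not performance on real single-nucleus data.

## Numerical choices and degenerate inputs

Ties in the inverse-normal transform take average ranks; an all-missing
vector is an error. `welch_t` requires ≥ 2 values per group. Zero-variance
predictors are dropped with a warning; a single gene cluster falls back to
nonrobust covariance with a warning. Sweep thresholds that empty one class
are flagged inestimable rather than failing. Pipeline runs are pure
functions of (inputs, config, seed): outputs land in a config-hash-named
directory with per-stage parameter hashes, so rerunning with only a
downstream parameter changed reuses upstream files byte-identically.

## Known limitations

* The pooled count ratio is insensitive to symmetric count noise (it uses
  bin totals), so only systematic count asymmetry — as in the high-density
  drop regime — moves it away from 1.
* The sharp regime switch at 40 CpG/kb makes the conservation reversal
  begin immediately above 40 rather than near 80.
* The chromatin-state scan assigns at most one label per site (first
  overlap); overlapping state tracks are not resolved probabilistically.
* With the DE p filter enabled, transcript selection depends on the
  (re-measured) fold change, so effect estimates on the filtered subset are
  mildly selection-biased — as they are in the emulated analysis; recovery
  checks run unfiltered.
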