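# Methods

This note records the statistical model behind each pipeline stage, the
design choices made where several defensible options existed, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that determine exact outputs.

## Meta-analysis and genomic control

Cohort summary statistics are combined per variant-trait by fixed-effect
inverse-variance weighting; Cochran's Q on k−1 df is reported but never used
as a filter. Before combination, records are aligned to the first cohort's
effect allele: swapped allele pairs flip the sign and complement the
frequency, strand flips are resolved through the base-complement map, and
palindromic (A/T, C/G) pairs — for which letters cannot distinguish a strand
flip from an allele swap — are oriented by which side of 0.5 their allele
frequency falls on, and dropped when either frequency lies in [0.42, 0.58].

Genomic-control lambda is the median association χ² divided by the χ²₁
median (≈0.4549), the standard median-based estimator; it is computed per
trait on the meta-analyzed p-values. Traits exceeding the threshold
(default 1.15) have χ² deflated by λ, implemented as SE inflation by √λ with
p recomputed — beta estimates are untouched, so downstream effect sizes are
scale-stable under correction. The correction is approximately idempotent:
recomputing λ after correction returns ≈1. An explicit `exclude_traits`
argument on the driver stands in for ad-hoc removal of pathologically
inflated phenotypes, rather than hard-coding any particular trait class.
P-values of exactly zero are floored at `sys.float_info.min` so −log10
transforms stay finite.

## Instruments

Per-variant strength uses PVE = 2β²q(1−q)/(2β²q(1−q) + se²·2n·q(1−q)) with
q = min(eaf, 1−eaf), and F = PVE(n−1−k)/((1−PVE)k); per-variant diagnostics
use k = 1, per-gene multi-instrument sets use the set size. F < 10 marks a
weak instrument; weak instruments are flagged, not removed, matching the
reporting-only role of the diagnostic. The z-score panel conversion
β = z/√(2p(1−p)(n+z²)) treats p as the effect-allele frequency; β/se
restores z exactly (tested to 1e−12). Argmin-p selection breaks ties by
(chrom, pos) then variant id so instrument sets are reproducible.

## Two-sample MR

- Wald ratio: β_out/β_exp with the first-order delta-method SE
  se_out/|β_exp| — the exposure uncertainty is deliberately ignored at first
  order, the convention of the field's two-sample MR tooling.
- IVW: weighted regression of outcome on exposure effects through the
  origin, weights 1/se_out². The default SE is the analytic fixed-effect
  1/√Σwβ_x². A multiplicative random-effects mode (`ivw_mode="mre"`)
  scales the SE by max(1, √(Q/(k−1))); it is offered as a configuration
  switch rather than the default because the fixed-effect convention is the
  one whose null p-values are exactly uniform — the property the null-world
  calibration suite asserts. Cochran's Q over the per-variant Wald ratios is
  algebraically identical to the weighted residual sum of squares of this
  regression, which is how the vectorized path computes it.
- MR-Egger: the same regression with a free intercept, after orienting all
  pairs so exposure effects are non-negative. SEs use the conventional
  multiplicative floor (max(1, σ̂)) and t-distribution p-values on k−2 df.
  Egger output is sensitivity-only: it never enters significance calls.

The production path (`mr_all`) evaluates all three estimators from grouped
weighted sums, so ~10⁵ gene-trait-source units run in seconds; unit tests
pin it to the scalar estimators and to `statsmodels` WLS at 1e−10.

Palindromic variants with outcome allele frequency in [0.42, 0.58] are
dropped during exposure-outcome harmonization (window configurable);
palindromic variants outside the window are oriented by frequency
concordance. Unresolvable allele sets are dropped and counted.

Significance is α divided by the number of unique gene-trait pairs actually
tested — recomputed from the data, never hard-coded — and a gene-trait-source
is significant if its primary (Wald/IVW) p-value passes.

## Selection rules

Multiple sources are never combined into one estimate. The concordance logic
is exactly rule-ordered: single significant source → accept; any significant
pQTL source → compare signs among significant pQTL sources only and carry the
pQTL layer forward; otherwise compare among all significant eQTL results
including every tissue; any disagreement → exclude. Exact-zero betas abstain
from the vote (a zero carries no direction; possible on synthetic data). The
representative estimate is the minimum-p result within the governing layer,
ties broken by source then tissue name. Consequences verified in simulation:
flipping the eQTL layer's sign against the pQTL layer (the generator's
`frac_discordant_sources`) never excludes a pair, because the rules compare
within, not between, layers.

## Colocalization

Per-variant Wakefield log-ABFs use W^(1/2) = 0.15·sdY for quantitative
traits and 0.2 (log-odds) for case-control — the conventional defaults; the
priors p1 = p2 = 1e−4, p12 = 1e−5 likewise. sdY, when not supplied, is
estimated by regressing 1/se² on 2·maf(1−maf)·n through the origin and
taking √(1/slope). The window boundary (±250 kb) is inclusive; the MAF
filter is strictly greater than 1%. Hypothesis sums are accumulated with
log-sum-exp throughout; the H3 term uses a log-space complement
log(e^{S1+S2} − e^{S12}) and degrades to −∞ for single-variant regions.
Posteriors are pinned to a brute-force enumeration of all (m+1)² causal
configurations at 1e−10.

## Phenotype mapping and novelty

Trait labels are embedded in 200 dimensions. The shipped encoder hashes
character trigrams into 200 bins with CRC32 (stable across processes, unlike
Python's salted `hash`) and L2-normalizes; any deterministic
label → 200-float callable can replace it, so a learned biomedical text
encoder plugs in without code changes. The top-3% neighborhood per source
group keeps ⌈0.03·|group|⌉ labels (never zero), ties at the cut broken
lexicographically. Distance matching is directional by construction and
documented as such. Novelty scoring searches a catalog for associations
within TSS − 250 kb to TES + 250 kb (window start floored at 1) whose trait
matches under the chosen scheme; 1 means already reported, 0 means novel.

## Drug annotation and benchmark

Catalog deduplication merges a target's indications that share an ontology
code or a parent term, keeping the maximum clinical phase over contributing
drugs. Classification per selected pair: approved (phase-4) indication match
→ rediscovery; phase 1–3 match → development match; approved target with no
matching indication → repurposing when the MR direction predicts benefit
under the drug's MoA, safety flag when it predicts harm. Synthetic traits
are oriented "higher = more disease risk", so an inhibitor is expected for a
risk-raising (β > 0) target; real-data orientation would enter as a
configuration column. MoA concordance over rediscoveries reports its own
denominator (pairs with a directional MoA) with a Clopper-Pearson interval
and exact binomial p against 0.5.

The benchmark pairs each approved target-indication (mapped to a trait by
exact code, else parent term) with 10 negative genes drawn without
replacement from the genes holding at least one significant MR result,
excluding genes positive for the same indication; when the universe is too
small, fewer negatives are emitted with a warning rather than sampling with
replacement. Benchmark sizes are always derived from the catalog at run
time. Matched non-selected controls for enrichment analyses share their
selected pair's source count, with control source identities drawn from the
empirical source distribution. Enrichment is single- or multi-covariate
logistic regression; complete separation is flagged and, optionally,
replaced by the 0.5-continuity-corrected 2×2 estimate.

## Ranking model

~40 features in seven families (MR summary, instrument strength,
colocalization, orthogonal evidence × matching scheme, novelty, PPI
neighborhood, druggability) are assembled through a registry, so families
toggle as whole column blocks; missing families impute to 0 with an explicit
is-missing indicator column. The classifier is XGBoost with the binary
logistic objective over the 3×3 grid (learning rate 0.01/0.1/0.3, depth
3/6/9, min child weight 1, subsample 1), 100 trees, no class reweighting.
Grid selection minimizes 5-fold stratified cross-validated log-loss — the
natural metric of the stated objective — on a stratified 80% split; PR-AUC
is reserved for the untouched 20% holdout. The PR-AUC estimator is the
step-wise (interpolation-free) threshold sweep, whose value on an
all-tied score vector equals the prevalence. Ranking sorts by predicted
probability with (gene, trait) tie-breaks, and PPV/NPV at a probability
cutoff are available for restrictive shortlists.

## The synthetic-data generator

The generator emulates the full input surface of a multi-biobank study with
planted ground truth. Defaults define the study conditions: 50 traits × 500
genes, three cohorts of 50k–200k samples, 2% of gene-trait pairs causal with
effects N(0, 0.35²) per unit exposure, between-cohort heterogeneity SD
0.002, five instrument sources at realistic panel sizes (670 to ~35k) with
1–3 mutually independent instruments per gene and source, MAF uniform on
(0.05, 0.5) and SE = 1/√(2·MAF(1−MAF)·n). Instrument z-magnitudes are drawn
uniform (7, 25) with a 5% weak tail (z 1.5–3) to exercise the F < 10 flag.
Outcome effects are true_effect × exposure beta plus heterogeneity and
sampling noise; traits are quantitative with sdY = 1. Inflation multiplies
null χ² by `inflation_lambda`. Ten percent of causal pairs have the eQTL
layer's sign flipped against the pQTL layer; 25% of outcome records are
emitted with swapped alleles, 10% strand-complemented, 5% of variants
palindromic — together these exercise every harmonization branch. The drug
catalog plants 120 approved target-indication pairs, 60% drawn from causal
pairs (`drug_overlap`), with MoA concordant with the planted direction 85%
of the time (a design-time choice of a realistic concordance level) and 10%
"other"; evidence catalogs include causal pairs at rate 0.30 versus 0.005
for null pairs; the association catalog covers 60% of causal pairs plus
background rows; PPI resources preferentially connect genes causal for the
same trait, with scored resources calibrated so the 0.8-quantile filter
retains most cluster edges.

Regional panels for colocalization are generated lazily per (gene, trait,
instrument) with a seed derived from the world seed and the pair identity,
sharing the causal variant exactly when the pair is causal. Storing dense
per-variant summary statistics for every gene × trait × cohort would
multiply memory severalfold without changing what any test measures; the
lazy regions are still deterministic and consistent with the truth table.

What the generator does not emulate — and hence what passing tests cannot
show about real data: linkage disequilibrium (instruments are independent by
construction, so no LD-aware sensitivity is exercised), genome builds and
liftover, imputation artifacts, ancestry structure, case-control traits in
the world tables (the case-control colocalization route is unit-tested on
direct fixtures), sample overlap between exposure and outcome studies, and
real ontology graphs (parent terms are consumed as tables; the toy encoder
captures lexical, not semantic, similarity).

A configuration with `frac_causal` strictly positive but an expected causal
count below one is rejected as underpowered plumbing; `frac_causal = 0` is
explicitly allowed as the null world used by the calibration suites.

## Problem sizes and determinism

The default study (50 traits × 500 genes, ~6,000 instruments, ~25,000
gene-trait pairs, ~150,000 MR units) runs end-to-end in about half a minute
and ~1 GB on one CPU; the calibration and recovery worlds use 120–150 genes
and 12–15 traits, sizes at which the asserted tolerances (binomial 99% CI,
3 SE on the recovery slope) are comfortably resolvable. All randomness flows
from explicit seeds: identical configurations produce byte-identical tables,
and model training is seed-deterministic including the grid choice.

## Known limitations

Single-variant colocalization (no SuSiE-style multi-causal support); no
weighted-median/mode MR estimators, Steiger filtering, or bidirectional MR;
no sample-overlap correction in the meta-analysis; druggability features
partially encode the benchmark's positive definition (approved targets), so
absolute PR-AUC values on synthetic worlds should be read as pipeline
plumbing checks, not transportable performance estimates.
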