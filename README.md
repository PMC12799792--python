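# targetmr

Genetics-driven therapeutic target discovery at desk scale: a tested
re-implementation of a multi-cohort, multi-QTL-source two-sample Mendelian
randomization (MR) pipeline that maps gene-trait causal evidence onto drug
catalogs and ranks candidate target-indications by their resemblance to
approved drugs.

## Who this is for

Statistical geneticists and drug-discovery informaticians who want a fully
inspectable, simulation-backed version of the "MR → concordance selection →
colocalization → drug mapping → learned ranking" workflow. Every stage runs on
synthetic worlds with planted ground truth, so each statistical claim the
pipeline makes is testable without any restricted biobank or proprietary
catalog download.

## The method

**Meta-analysis.** Per-cohort GWAS summary statistics are combined per variant
by fixed-effect inverse-variance weighting, β̂ = Σwᵢβᵢ/Σwᵢ with wᵢ = 1/seᵢ²,
se = 1/√Σwᵢ, with Cochran's Q heterogeneity on k−1 df. Genomic-control lambda
(median χ² over the χ²₁ median, 0.4549) is computed per trait; traits with
λ > 1.15 are GC-corrected by dividing χ² statistics by λ. Underflowed p-values
are floored at the smallest positive normal double (2.2250738585072014e−308).

**Instruments.** Five sources are modeled: a tissue-resolved eQTL panel (up to
5 conditional signals per gene-tissue at p < 5e−8), a blood eQTL panel
distributed as z-scores (converted by β = z/√(2p(1−p)(n+z²)),
se = 1/√(2p(1−p)(n+z²)); smallest-p variant per gene), and three curated
plasma pQTL panels. Strength per instrument: PVE = 2β²q(1−q) / (2β²q(1−q) +
se²·2n·q(1−q)) and F = PVE(n−1−k)/((1−PVE)k); F < 10 flags a weak instrument.

**MR.** After allele harmonization (swapped alleles flipped; strand
complements resolved; palindromic variants with allele frequency in
[0.42, 0.58] dropped), the causal effect per gene-trait-source is the Wald
ratio β_out/β_exp for one instrument, or the weighted zero-intercept
regression (IVW) for several; MR-Egger's free intercept is reported as a
pleiotropy sensitivity check for ≥3 instruments. Significance is Bonferroni:
α/number of unique gene-trait pairs tested.

**Selection rules.** A pair significant in one source is accepted. With
several significant sources, effect directions must agree — compared only
among pQTL sources when any pQTL is significant (transcript and protein
effects may legitimately disagree), otherwise among all significant eQTL
results including every tissue. Discordant pairs are excluded; the
representative estimate is the minimum-p result of the governing layer.

**Colocalization.** Around each instrument (±250 kb, MAF > 1%), per-variant
Wakefield approximate Bayes factors for the QTL and the outcome GWAS are
combined by enumeration over single-causal-variant configurations into
posteriors PP.H0–PP.H4 (priors p1 = p2 = 1e−4, p12 = 1e−5); PP.H4 > 0.8 is a
strong shared-variant call.

**Drug mapping and ranking.** Selected pairs are matched to a deduplicated
catalog of drug target-indications through three phenotype-matching schemes
(exact ontology code, shared parent term, top-3% cosine neighborhood of
200-dimensional label embeddings). Matches to approved indications are
rediscoveries — scored for direction against the drug's mechanism of action —
and unmatched approved targets split into repurposing opportunities versus
safety flags by predicted benefit. A benchmark of approved target-indications
(10 indication-matched negative controls per positive) trains an XGBoost
classifier (binary logistic; grid over learning rate 0.01/0.1/0.3 and depth
3/6/9; 5-fold CV on 80%, PR-AUC on the 20% holdout) that ranks every selected
pair.

## Worked example

```bash
python examples/end_to_end.py
```

prints (abridged):

```
tested gene-trait pairs: 1000; Bonferroni threshold 5.00e-05
selected: 49 (38 genes, 10 traits); excluded discordant: 0
of the selected, 49 are planted causal pairs (precision 1.00)

translational calls: {'rediscovery': 22, 'none': 15, 'safety-flag': 7, 'repurposing': 5}
MoA concordance among rediscoveries: 89% (17/19, 95% CI 67%-99%)

orthogonal-evidence enrichment (selected vs matched non-selected):
      omim: OR=15.3 p=1.5e-02
      plof: OR=48.8 p=7.5e-03

ranking model: holdout PR-AUC 0.52 (baseline = prevalence 0.091)
```

Reading this: of 1,000 tested gene-trait pairs the concordance rules selected
49, all of them planted causal effects. 22 selected pairs coincide with an
approved drug's target and indication (rediscoveries), and in 89% of those the
MR direction of effect predicts the approved mechanism (inhibitor for
risk-raising targets). Selected pairs are strongly enriched in the synthetic
OMIM-like and loss-of-function evidence catalogs, and the ranking model
separates approved target-indications from matched negatives well above the
9.1% prevalence baseline.

Other examples: `examples/simulate_world.py` (inspect the generated input
tables), `examples/mr_basics.py` (harmonization and the three estimators on a
hand-built fixture), `examples/coloc_demo.py` (shared vs distinct causal
variants).

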