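# Methods

This note documents the models, rules and numerical choices behind
`inflamark`, and what the synthetic study does and does not demonstrate.

## Ontology selection

Term search is a case-insensitive substring match on term *names* only;
synonyms and definitions are not searched (a config flag is reserved for
enabling synonyms). Manual curation — restricting keyword hits to human,
non-embryonic, endogenous, tissue-specific processes — is emulated by an
explicit whitelist of parent accessions in the run configuration, which
makes this inherently human step reproducible.

Descendant closure is reflexive and transitive over child edges, where
parent edges are read from `is_a` and `relationship: part_of` tags of an
OBO 1.2 file; other relationship types are ignored with a warning. The
parent graph must be acyclic.

A parent term is retained when its annotated gene set (after filtering
annotations to the configured species and object type) shares at least one
gene with the immune gene set — the union of genes annotated to the
closure of *immune system process* (GO:0002376), *inflammatory response*
(GO:0006954) and *cytokine production* (GO:0001816).

**Summary arithmetic.** Per-parent gene counts may overlap across parents;
tissue totals are the *sums of per-parent counts*, not the union — this
matches the arithmetic of the published selection table this stage
reproduces (e.g. 375 = Σ of the adipose rows). Percentages are rounded
half-up to integers (37.5% prints as 38%).

## Tissue-specificity (atlas) rule

With tissues sorted by descending expression (name breaks ties), a gene is
*tissue-enriched* when the top level is ≥ `fold` (default 4, inclusive)
times the comparison level of the remaining tissues, and *group-enriched*
for the smallest descending-prefix group of 2–5 tissues clearing the same
bar. Only prefix groups need to be checked: any qualifying subset must
contain the top-|S| levels, so prefix search is equivalent to exhaustive
subset search (the test suite verifies this against a brute-force oracle).
The comparison level is the *maximum* of the non-members by default — the
stricter reading — with the mean selectable by configuration. An all-zero
profile is not-specific; no division is attempted. Scaling a profile by a
positive constant cannot change the call.

Gene symbols are upper-cased before any set operation, since human and
mouse symbol casing differs.

## Candidate selection

A gene qualifies as a blood protein biomarker if at least one database
record matches on marker type `proteome`, substrate `plasma`/`serum`, and
evidence `early human studies` / `late human studies` /
`recommended/approved`. Matching prefers the UniProt accession when both
sides carry one, else the upper-cased symbol.

Novelty is a pure function of three booleans — disease-list condition,
commonly-analyzed, diagnostic-use-in-listed-disease — with *curated*
requiring all three. The disease list defaults to the ten low-grade
inflammation conditions (metabolic syndrome, type 2 diabetes,
hyperglycemia, prediabetes, insulin resistance, glucose intolerance,
dyslipidemia, hyperlipidemia, hypertriglyceridemia, atherosclerosis).

Candidates retain their per-parent provenance; a gene listed under several
parents appears in each row but counts once in the deduplicated union.
Ontology-derived candidates are admitted because their *parent term*
overlaps the immune set — the per-gene immune flag is carried as
information, not used as a filter; atlas-derived additions are
individually immune-filtered: `(atlas-specific ∩ immune) \ ontology`.
Both novel and curated candidates proceed to verification by default
(novelty is carried as a column); restricting to curated is a config
switch.

## Cohort verification

**Normalization.** Median-of-ratios size factors, computed over genes with
positive counts in every sample, then standardized to geometric mean 1 so
that normalization is idempotent (the median-of-ratios of the normalized
matrix is exactly 1 per sample). Each tissue's matrix is normalized
independently — the two tissues are separate sequencing experiments.

**Differential expression.** Per-gene negative-binomial log-linear
regression with an intercept and a diet-group indicator, size factors as
offsets. The dispersion α (variance = μ + αμ²) is a per-gene
method-of-moments estimate from the pooled within-group variance of
normalized counts, with the sampling part removed via the mean reciprocal
size factor, floored at 1e-8; there is no empirical-Bayes sharing — a
documented simplification. Coefficients are fitted by IRLS (tolerance
1e-8 on the update, at most 100 iterations, coefficients capped at ±30 to
guard all-zero groups), vectorized across genes; the Wald statistic
(coefficient / SE) is referred to the standard normal, two-sided, and
adjusted by Benjamini–Hochberg. No fold-change shrinkage or independent
filtering. All-zero genes are flagged not-detected with undefined
p-values. In the small-dispersion limit the fit coincides with Poisson
regression (checked against statsmodels in the tests), and on null NB data
at the design size (10 vs 17, dispersion 0.1) the nominal-0.05 rejection
rate calibrates to ≈ 0.05–0.07.

**Selection criteria.** (a) detected: mean normalized count ≥ 1 in at
least one diet group of the target tissue; (b) FDR-adjusted p < 0.01 in
the target tissue; (c) mean normalized count across the *HFD* animals of
the target tissue exceeds that of the non-target tissue — the inflamed
state is the relevant contrast; comparing across all animals is a config
option. A candidate with no murine analog in the target matrix simply
fails (a).

**Correlation and classification.** Spearman correlation (mean ranks for
ties) of size-factor-normalized expression with the tissue's histology
score, pooling chow and HFD animals (n = 27 in the reference design;
HFD-only is a config option — which animals entered the published
correlations is not stated, and "absolute expression" is read as
normalized counts for cross-sample comparability). The cutoff is strict:
|ρ| > 0.60 passes; the closed band [−0.60, 0.60] is "no relation". A gene
is *hepatic* when it passes in liver only, *adipose* when in WAT only,
*both*/*none* otherwise; *both* markers are reported in their own section
(the rule must be total even though the reference analysis produced no
such case).

## Confirmation rubric

Level 3 iff all three literature conditions hold; level 2 for any two;
level 1 for exactly one of (mechanism, tissue-disease); level 0 otherwise
— in particular, the metabolic-disorder condition alone confirms nothing.
Verified markers without an evidence record are reported with level −1
(unknown), never dropped.

## Synthetic study

The generator's defaults are the reference study conditions: 10 chow vs 17
HFD animals; lognormal histology scores with multiplicative effects 31.6
(liver aggregates/mm²) and 9.1 (WAT CLS/1000 adipocytes) and within-group
log-SD 0.15 (chosen so the estimated fold changes stay within a
[25, 40] / [7, 12] sampling envelope across seeds); NB counts with
dispersion 0.1, lognormal gene baselines (median 100) and lognormal sample
depth factors (log-SD 0.2); 2,000 genes, which keeps a full pipeline run
around one second.

Planted markers (10 per tissue, alternating up/down direction) have
log-mean expression affine in the standardized log histology score of
their tissue and a flat profile in the other tissue (baseline 200 vs 20,
satisfying criterion c in both directions). The slope is solved in closed
form for a target pooled |Spearman| of 0.8: because the histology scores
form two well-separated diet clusters, the pooled Spearman is
1 − K(1 − ρ_within) with K = Σ m(m²−1)/(n(n²−1)) over cluster sizes, and
the within-cluster Pearson target follows from the Gaussian grade relation
ρ_s = (6/π)·asin(r/2); the log-scale noise is the NB sampling deviation
√(α + 1/μ). Empirically the planted |ρ| averages ≈ 0.79. With
`count_noise=False` counts follow the mean exactly (stored ×1024 to keep
the monotone link through integer storage) and the planted ρ is ±1.

The ontology generator plants keyword-named parents (plus
embryonic-named decoys excluded by the whitelist and wrong-taxon decoy
annotations), and gives each tissue gene an independent 44% chance of an
immune annotation, so the pipeline's overall immune percentage converges
to the configured overlap. The atlas generator gives planted genes a
5-fold separation and *compresses* background profiles toward their
geometric mean whenever noise would let them clear 90% of the four-fold
bar, so planted precision and recall are exactly 1 at default settings.
The biomarker generator always gives planted markers a qualifying record,
plants known novelty patterns, and adds decoys with urine substrate or
preclinical evidence. The plasma analyte is linear in the liver histology
score with Gaussian noise scaled from the realized signal variance to a
target R² of 0.68 (clipped at zero; the intercept keeps clipping
negligible).

One integer seed drives fixed, independent sub-streams per generator
(ontology 1, atlas 2, biomarker 3, cohort 4, evidence 5), so regenerating
one input never perturbs another, and the whole workflow is byte-for-byte
deterministic per seed.

**What the synthetic study does not show.** Real GO term names, evidence
codes and annotation redundancy are not mimicked; atlas noise never
creates borderline specificity calls; cohort counts have no batch or
sex structure, no outlier animals, and gene-gene correlation only through
the shared histology driver. Passing recovery tests therefore demonstrates
the pipeline's logic and calibration under its stated model, not
performance on real snapshots — the published database-dependent gene
counts (e.g. 79/359 atlas-specific genes) depend on a specific snapshot
date and are not reproducible targets.

## Reference tables

The curated reference tables (`inflamark.reference_tables`) transcribe the
published per-parent selection counts, candidate lists, marker
correlations and confirmation levels; the package's arithmetic on them
(row sums 375/174, immune percentages 43%/45%, pools 404/305, deduplicated
candidate counts 44/73, 16 hepatic + 2 adipose markers, 11 at level 3) is
exercised by the test suite and recomputed by `scripts/acceptance.py`.

## Known limitations

* The DE test uses per-gene moment dispersions and unshrunk Wald
  statistics; with very few replicates it is slightly anti-conservative
  compared to shrinkage-based estimators.
* Group-enriched atlas calls use min-over-group vs max-of-rest, one of
  several possible readings of the four-fold rule; the mean denominator is
  available but group definitions beyond 2–5 tissues are not.
* Evidence booleans are manual inputs; no literature mining is attempted.
* The Mann–Whitney exact p-value is used only for tie-free samples with
  n ≤ 12; larger or tied samples use the tie/continuity-corrected normal
  approximation.
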