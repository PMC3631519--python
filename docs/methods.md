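# Methods

This note documents the statistical models behind `forensnp`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Genotype model and quality control

Genotypes are alternate-allele dosages: {0, 1, 2} for diploid marker
classes (autosomal, X-specific, XY-pseudoautosomal) and {0, 1} for haploid
classes (Y, mtDNA), with missing calls as NaN throughout — nothing is
imputed. Diploid-coded haploid input (a `1/1` Y call) is coerced to the
haploid state with a warning; a heterozygous call on a haploid marker is
set missing, since no single-source haploid state can explain it.

A sample fails QC when strictly more than 10 % of its calls are missing
(call rate < 90 %). The gate is a flag, not a hard stop: downstream stages
that pool many markers (ancestry, kinship) remain usable well past it, and
the pipeline runs them on failed samples with the flag attached.

Marker filtering keeps markers with minor allele frequency strictly above
1 % and missingness strictly below 5 %, computed on the analysis cohort
itself. Optional LD pruning is greedy and windowed (default r² > 0.2
within 50-marker windows advancing by 5): the later marker of an offending
pair is dropped. The low-LD autosomal subset used for ancestry is exactly
"`filter_markers` with pruning on the autosomal class", carried as a panel
tag; no published subset is reproduced.

## Sex inference

The X statistic is the observed heterozygous fraction over non-missing
X-specific calls **divided by the heterozygosity expected of a diploid
genome at the same markers under Hardy–Weinberg** (`mean 2p(1−p)`), then
clamped to [0, 1]. The normalisation matters: the raw heterozygous
fraction cannot exceed 0.5 in expectation at biallelic SNPs, so the
female threshold of 0.8 is only meaningful on the normalised scale, where
females sit near 1 and males (haploid X read out as homozygous diploid
calls) near 0. Frequencies default to cohort estimates; a reference
frequency vector can be supplied for single-sample use. At least 100
informative X calls are required (configurable); fewer yields an
inconclusive-by-data signal rather than a call.

Thresholds: < 0.2 male, > 0.8 female, the closed interval [0.2, 0.8]
inconclusive (the boundary semantics were open; closed on both ends was
chosen so the thresholds themselves never produce a call). The Y prong is
a called Y haplogroup, or — as a fallback for degraded data — a Y-marker
call rate ≥ 0.5. A full call needs both prongs to agree; one prong alone
gives the call a single-evidence caveat; contradictory prongs (high X
heterozygosity *with* Y evidence, e.g. a male/female mixture) are
inconclusive. Mixture deconvolution is out of scope. Calls are compared
against recorded sex and conflicts flagged, never silently resolved.

## Ancestry

**Reference space.** Reference genotypes with population labels are
centred by `2p` and scaled by `sqrt(2p(1−p))` per marker (`p` the overall
reference frequency), mean-imputed at missing calls, and decomposed by
SVD. Three components are kept by default — enough to separate five
continental-style groups in practice while matching the dimensionality
used for visual inspection; configurable. Per-population centroids are
mean reference coordinates; per-population frequencies are within-group
estimates clamped to [0.001, 0.999] so likelihoods stay finite.

**Projection.** A query sample is projected by least squares on the
loading rows where it has calls, which renormalises the scaling exactly
rather than approximately; with complete data this equals the orthonormal
projection. Assignment is Euclidean nearest centroid with ties broken by
label order under a logged warning; no rejection radius is applied (the
quantitative route carries the uncertainty statement instead).

**Supervised admixture.** With `f_kj` fixed, the log-likelihood
`ℓ(q) = Σ_j g_j log π_j + (2−g_j) log(1−π_j)`, `π_j = Σ_k q_k f_kj`, is
maximised by EM: each of the sample's 2M allele draws is attributed to
population k with responsibility ∝ `q_k f_kj` (alternate allele) or
`q_k (1−f_kj)` (reference allele), and the M-step averages the
responsibilities. The likelihood is monotone non-decreasing; iteration
stops when the improvement falls below 1e-6 or after 500 iterations, in
which case the current estimate is returned with a non-convergence flag
(the estimate is typically fine — convergence in q is much faster than the
last decimals of ℓ). Missing markers are skipped. Supervised estimation
(fixed reference frequencies) was chosen over joint clustering because the
pipeline always runs against a labelled reference; the "probability" in
the 0.70 single-group rule is interpreted as the admixture proportion
`q_k`, and the rule is strict: `q_k > 0.70` assigns the single group,
anything else "multiple groups".

Cohort summaries are Tukey box statistics (quartiles, 1.5-IQR whiskers)
per ancestry component. Two cohorts with the same mean composition give
indistinguishable summaries — a geographically intermediate population
cannot be told from recent admixture by these first-pass statistics, and
the tests assert that limitation rather than hide it.

## Uniparental lineage

A haplogroup tree is a rooted phylogeny whose edges carry defining
variants; nodes carry geographic labels. Calling evaluates every node:
among the non-missing variants on the node's root path the derived
fraction must reach 0.8, off-path derived states must not exceed 1, and —
so that wholly unobserved branches are never descended on vacuous support
— at least one variant on the node's own defining edge must be observed
derived. The deepest qualifying node wins; ties break on support fraction,
then name. No observed tree markers at all yields no call, which for the Y
tree doubles as absence-of-male-DNA evidence. Recurrent mutation and
heteroplasmy are not modelled.

The shipped trees are **synthetic fixtures** (24 nodes, 46 defining
variants each, abstract clade names, continental geography labels); real
phylogenies load through the same newick + TSV format. The consistency
check cross-tabulates uniparental geographies against the biparental
assignment: a uniparental origin not matching any ancestry component above
0.2 raises a parental-line-admixture flag — an informative signal, never
an error.

## Eye and hair colour

Both traits are multinomial logistic models over effect-allele dosages:
eye with the 6 canonical predictor SNPs and categories blue / intermediate
/ brown; hair with the 18 predictors assayable on a genome-wide chip (the
four MC1R variants of the full 22-variant panel cannot be typed there) and
categories black-dark-brown / brown-light-brown / blonde-dark-blonde /
red. Fitting is L2-penalised maximum likelihood (ridge weight 1e-4,
intercepts unpenalised) via scikit-learn's lbfgs solver — convex, hence
deterministic; coefficients are stored in reference-category
parametrisation. An independent statsmodels fit serves as a cross-check in
the tests, agreeing to < 1e-3 mean absolute probability difference.

Calling rules: any prediction requires the full predictor complement
non-missing. Eye calls require the top probability to exceed 0.7 strictly,
else "undetermined". Hair calls go through a prediction-guide rule table:
by default plain argmax, with exact ties resolved toward the lighter shade
(ordering black < brown < red < blonde — red's position is a documented
convention) under a logged warning; per-category probability floors are
configurable and the guide serialises to JSON so a published guide can be
encoded.

The shipped default models are fitted on a planted-parameter synthetic
cohort and are **not** the published coefficients — they exercise the
machinery with realistic structure (each non-reference category driven by
one major locus of per-allele log-odds 3 plus moderate modifiers,
mirroring how one HERC2 variant dominates blue/brown eyes and MC1R
variants dominate red hair). File names and docstrings say "synthetic"
loudly. Evaluation builds predicted-by-reported confusion tables (samples
without a call excluded), collapses reported shades via an explicit total
mapping, supports column exclusion (e.g. dropping unreliable self-reported
intermediate eye colour), and reports exact fractions plus round-half-up
integer percentages.

## Relatedness

For each pair, autosomal markers called in both samples yield IBS state
counts (state = 2 − |g_a − g_b|; opposite homozygotes land in state 0).
Markers with degenerate cohort frequencies are dropped first. The method
of moments converts counts to IBD class weights using the closed-form IBS
expectations for unrelated pairs (`P(IBS0|IBD0) = 2p²q²` etc.) and
`π̂ = k₂ + k₁/2`. Only the final `π̂` is truncated to [0, 1]: clamping the
intermediate class weights individually biases unrelated pairs upward
(measured: mean 0.012 vs 0.004 at 20k markers), because their symmetric
sampling noise can no longer cancel.

Degree bins are midpoints between adjacent pedigree expectations: first ≥
0.375, second ≥ 0.1875, third ≥ 0.09375, fourth ≥ 0.046875, below that
unrelated. Arithmetic rather than geometric midpoints were chosen so that
an observed 9 % genome share classifies as fourth degree, matching the
interpretation forensic practice attaches to such a pair; the bins are
configurable. Both the mean IBS fraction and `π̂` are reported —
published discussions of "genome shared IBS" at the ~10 % level are on the
IBD scale, and classification is driven by `π̂`. Frequencies for the
moments estimator default to the analysis cohort; a reference vector
should be supplied for very small cohorts (two samples cannot estimate
their own frequencies). Judging pairs from a drifted, isolated
subpopulation against pooled frequencies inflates `π̂` — the
known overprediction of distant relatives in isolates — and a test asserts
that direction. No LD pruning is applied before kinship by default.

## Synthetic-data generator

The generator defines the study conditions the tests and acceptance run
under:

- **Populations.** K = 5 by default (labels AFR/EUR/EAS/SAS/AMR standing
  in for continental reference groups), drift F per population spanning
  0.02–0.15 — from within-continent to between-continent differentiation.
  Balding–Nichols: ancestral frequencies uniform on (0.05, 0.95),
  population frequencies Beta-distributed around them, clamped to
  [0.001, 0.999]. The expected Hudson FST between two such populations is
  F itself (verified against a 2×10⁵-replicate Monte-Carlo oracle before
  the corresponding test was frozen at 0.20 ± 0.05 for F = 0.2).
- **Individuals.** Autosomal dosage ~ Binomial(2, Σ_k q_k f_kj) — a pooled
  admixture model without ancestry tracts. X markers are diploid in
  females and haploid in males, rendered as homozygous diploid calls the
  way a chip reports them. Y content exists only in males; Y and mtDNA
  states follow one root-to-node path of the fixture trees, with
  per-population haplogroup repertoires so lineage geography matches
  autosomal ancestry.
- **Relative pairs.** Gene-dropping through minimal pedigrees
  (parent–offspring / full sibs; half-sib / avuncular / grandparent;
  first cousin / great-avuncular; first cousin once removed), one
  independent meiosis per marker, founder-gamete labels tracked so the
  realised IBD share is recorded exactly. The packaged relatedness study
  is 81 samples whose 3,240 pairs contain 27 first-, 10 second- (4
  avuncular, 5 grandparent, 1 half-sib), 3 third-, 1 fourth-degree and
  3,199 unrelated pairs. Founders come from one population; admixed
  pedigrees are out of scope, and only the autosomal content of a pair is
  pedigree-faithful (sex and lineage are drawn independently per member).
- **Quality loss.** Independent per-call missingness, then symmetric
  category flips at an error rate; the error default is 0 (degraded-input
  profiles are characterised by missingness, error behaviour being
  unknown) and configurable.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage disequilibrium (markers are
independent given the population, consistent with a pipeline operating on
an LD-pruned subset), ancestry tracts in admixed genomes, genotyping
chemistry artefacts (allele-specific dropout, intensity clustering),
population substructure within reference groups, and real haplogroup
nomenclature. Recovery rates measured here are upper bounds for chip data
of equal marker count.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen to keep the full
suite under a couple of minutes while leaving the statistical conclusions
stable: 20,000 autosomal markers where recovery tolerances are asserted
(admixture ±0.05, kinship sweep 100 %), 2,000 markers for structural
checks, reference cohorts of 25–30 per population. EM tolerance 1e-6 / 500
iterations; frequency clamps 0.001/0.999; accuracy percentages
round-half-up to match published-table conventions. The ±0.15 per-entry
bound on multinomial coefficient recovery is asserted on a canonical
frozen instance (n = 5,000); asymptotic standard errors reach ~0.11 for
intercept entries, so that bound is ~1.4σ at the worst entries and is a
regression check on the frozen instance, not a uniform guarantee over
replicates.

## Known limitations

- The shipped phenotype coefficients and haplogroup trees are synthetic;
  casework use requires loading real models and phylogenies.
- No subcontinental ancestry, no admixture-tract/LD-block modelling, no
  likelihood-based (KING-style) kinship, no X-chromosome kinship, no
  inbreeding estimation, no mixture deconvolution.
- MAF and kinship frequencies default to the analysis cohort; small
  cohorts need external frequencies.
- The pipeline is single-threaded and in-memory; cohorts of thousands of
  samples at chip scale (~200k markers) fit, but pairwise kinship grows
  quadratically in samples.
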