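# forensnp

Forensic DNA intelligence from genome-wide SNP genotypes.

Given a multi-sample genotype matrix from a dense forensic SNP array,
`forensnp` jointly infers, per sample and per pair:

- **sex** — two-pronged: normalised X-chromosome heterozygosity
  (< 0.2 male, > 0.8 female, intermediate inconclusive) cross-checked
  against Y-chromosome evidence, with conflicts against recorded sex
  flagged rather than overwritten;
- **biparental continental ancestry** — categorical (PCA projection into a
  labelled reference space, nearest-centroid assignment) and quantitative
  (supervised admixture: EM maximisation of the binomial likelihood
  `ℓ(q) = Σ_j g_j log π_j + (2−g_j) log(1−π_j)` with
  `π_j = Σ_k q_k f_kj` over the probability simplex, fixed per-population
  frequencies `f_kj`); a sample is assigned to a single group only when its
  largest component strictly exceeds 0.70, otherwise to "multiple groups";
- **uniparental lineage** — Y and mtDNA haplogroup calls against a
  marker-annotated phylogeny with geographic-origin labels, plus a
  consistency cross-check against the biparental result (disagreements are
  flagged as parental-line admixture, not errors);
- **eye and hair colour** — multinomial logistic (softmax) prediction from
  6 eye / 18 hair predictor SNPs; eye calls require p > 0.7, hair calls go
  through a configurable prediction guide; predictions require the full
  predictor complement non-missing;
- **pairwise relatedness** — genome-wide IBS state counts converted to an
  IBD genome-share estimate `π̂ = P(IBD=2) + P(IBD=1)/2` by the method of
  moments, classified into first- to fourth-degree or unrelated bins
  around the pedigree expectations 1/2, 1/4, 1/8, 1/16.

Because real chip data cannot ship with the package, a first-class
**synthetic-data module** generates everything the stack consumes with
known ground truth: Balding–Nichols drifted reference populations, admixed
individuals, relative pairs by pedigree gene-dropping, sexed X/Y/mtDNA
content tied to fixture haplogroup trees, and dilution/degradation-style
quality loss (missingness + genotype errors). Every generator is
deterministic under a fixed seed.

Who this is for: forensic genetics researchers and method developers who
want a transparent, testable reference implementation of the all-in-one
chip-inference stack — not a validated casework tool. The shipped
phenotype-model coefficients in particular are **synthetic** (fitted on a
planted-parameter simulated cohort); real published coefficients load
through the same file format.

## Worked example

Simulate a five-population reference and an individual with an African
father and a European mother, then run both ancestry routes
(`examples/02_ancestry_admixture.py`):

```text
true admixture: 0.50 AFR / 0.50 EUR
estimated q:
  AFR: 0.470
  AMR: 0.014
  EAS: 0.025
  EUR: 0.475
  SAS: 0.015
nearest PCA centroid: AFR (distance 7.7)
quantitative assignment: 'multiple groups'
```

The EM estimate recovers both parental components within 0.03; no single
component exceeds 0.70, so the categorical answer is "multiple groups" —
exactly the behaviour wanted for a mixed-ancestry donor, where the
nearest-centroid answer alone ("AFR") would mislead. The other scripts in
`examples/` walk one capability each: reference simulation, sex + lineage
with the consistency cross-check, phenotype calling rules, kinship degrees,
and the full orchestrated pipeline.

## Command line

A thin CLI wraps the library for shell use:

```bash
forensnp simulate --seed 1 --outdir simulated/
forensnp run-all --input simulated/cohort.tsv \
    --reference simulated/reference.tsv \
    --labels simulated/reference_labels.tsv --outdir out/
```

`run-all` executes QC → lineage → sex → ancestry → phenotype → kinship,
writes per-stage TSVs plus a consolidated `report.json`/`report.tsv`, and
isolates per-sample failures instead of aborting the cohort. Samples
failing the 10 % missingness QC gate still get an ancestry attempt (the
pooled-marker likelihood tolerates low call rates) but carry a flag.
Subcommands `qc`, `sex`, `ancestry`, `lineage`, `phenotype`, `kinship`,
`validate-config` and `report` run the stages individually.

## File formats

- **Genotypes**: standard VCF (GT field; contigs 1–22, X, Y, MT, XY give
  the chromosome class), or an internal TSV dialect — one row per marker
  with columns `marker_id`, `chrom_class`, `position`, `ref`, `alt`,
  `tags`, then one dosage column per sample (`.` = missing; haploid Y/mt
  markers use {0,1}).
- **Reference panel**: TSV bundle (frequencies, loadings, centroids) plus
  a JSON manifest.
- **Phenotype models**: coefficient TSV (trait, category, term, effect
  allele, beta) plus a JSON manifest; prediction guide as JSON.
- **Haplogroup trees**: newick topology plus a TSV of (node, marker,
  derived allele, geography). Small synthetic fixture trees ship in
  `src/forensnp/data/`.

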