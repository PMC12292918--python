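# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions and the open design choices behind `repqtl`.

## Repertoire traits

**Unique-clone semantics.** A clone is keyed by (chain, V-gene, CDR3 amino
acids). Bulk clone tables do not carry nucleotide-level rearrangements in
this schema, so amino-acid identity is used consistently for trait
construction, longitudinal tracking and HLA matching. Clone multiplicity
(the `count` column) never enters the traits: V-gene usage is the
cardinality of the per-individual clone set per V-gene, which weights a
singlet and a hugely expanded clone equally and therefore reads on clonal
*formation* rather than expansion.

**7-mer usage.** CDR3s of length 12–18 are scanned with a sliding window of
seven residues (an ITAM-sized motif; a CDR3 of length L yields L−6 windows).
A 7-mer's count for an individual is the number of distinct clones whose
CDR3 contains it — presence per clone, not window occurrences — so the trait
remains a clone-set cardinality like V-gene usage. Because the generator's
CDR3s are random strings over the 20-letter alphabet, almost every 7-mer is
private to one clone at synthetic scale; `count_kmers` therefore accepts a
`min_prevalence` filter (fraction of individuals with a nonzero count) and
the pipeline and recovery harnesses use 0.2. Real repertoires are far more
structured, so the default is 0 (no filter). Whether occurrence-weighted
counting is preferable is genuinely open; presence is the default and the
window machinery exposes everything needed to add weighting.

**Normalisation chain** (enforced stage order, violations raise):

1. `raw_counts` — non-negative integers;
2. TMM: reference sample = closest upper-quartile/library ratio to the mean;
   per-sample factor = weighted (inverse asymptotic binomial variance)
   doubly-trimmed (30% on M, 5% on A) mean of log2 ratios; factors rescaled
   to geometric mean 1. The implementation is verified to 1e-10 against
   Bioconductor edgeR `calcNormFactors` on fixtures (frozen values plus a
   live `Rscript` cross-check in the tests);
3. `normalized` — counts per million on the effective (factor-scaled)
   library;
4. `batch_corrected` — per-feature least-squares removal of batch main
   effects (largest batch as reference level; a batch with a single
   individual is refused as confounded);
5. `inrt` — rank-based inverse normal transform, Blom offset:
   Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks on ties, constant columns map to
   zero with a warning.

TCR principal components are computed from the batch-corrected normalised
usage matrix (pre-INRT), pooling chains in the pipeline; the stage is a
design choice — rank transformation would discard the scale information the
PCs are meant to absorb.

## Association

All tests are ordinary least squares on the INRT scale with covariates
{two genetic PCs, two TCR PCs, age, sex, cancer type}; categorical
covariates are encoded as indicators with the largest level as reference.
`scan` uses the Frisch–Waugh–Lovell decomposition (residualise phenotypes
and dosages against covariates once, then per-pair simple regression), which
is algebraically identical to the full fit and is tested to 1e-10 against
both `fit_additive` (explicit least squares) and a pseudo-inverse oracle.
Missing dosages are mean-imputed inside `scan`; `fit_additive` is
complete-case. Zero-variance predictors become flagged `untestable` rows;
p-values are floored at 1e-300 and flagged.

**Omnibus test.** At an HLA amino-acid position with k observed residues,
residue dosages (sums of carrying 4-digit allele dosages; they sum to 2 per
individual) enter jointly with the most common residue dropped as reference;
the F(k−1, residual df) comparison against the covariate-only model reduces
exactly to the squared t-test when k = 2, an identity asserted to 1e-10.
Residue columns collinear with covariates are dropped with a warning and the
numerator df reduced.

**Permutation threshold.** One random row permutation of the whole phenotype
matrix per round, B rounds (default 1000; B < 20 refused), against fixed
genotypes and covariates — all features move together, so inter-trait
correlation survives under the null, and covariates stay with genotypes so
covariate–genotype structure is preserved. The minimum p is taken jointly
over features × predictors (the multiplicity being controlled spans both),
and the threshold is the α-quantile of the B minima with linear
interpolation between order statistics, making thresholds bit-reproducible
given the seed. A Freedman–Lane variant (permuting covariate-residualised
phenotypes) is available behind `method="freedman-lane"`. Under the global
null the empirical family-wise error rate at the threshold is checked to lie
in [0.02, 0.10] over 200 replicate cohorts (n = 100, 200 variants, 20
traits, B = 200).

**Conditional analysis** appends the conditioning dosages to the covariates;
testing a conditioned predictor returns an `untestable` flag rather than a
meaningless number. The behavioural check uses a tight LD proxy
(r² ≈ 0.95): a literal dosage copy would be exactly collinear after
conditioning, so "perfect LD" is operationalised as near-perfect.

## Clone dynamics, single cells, survival

Paired C1/C2 clone sets partition into unstable (C1∖C2), novel (C2∖C1) and
persistent (C1∩C2) per individual. An HLA-matched clone pairs a V-gene with
a classical allele (2- or 4-digit) the individual carries at dosage ≥ 1;
match rules are normally extracted from an association table as the top
allele per significant V-gene (smallest p, ties broken lexicographically).
Matched proportions are unique-clone fractions (consistent with the traits).
Group contrasts use the paired Wilcoxon signed-rank test: zeros dropped,
exact distribution for ≤ 25 untied informative pairs (verified against full
2ⁿ enumeration for n ≤ 12), tie-corrected normal approximation with
continuity correction above.

Cells are included with ≥ 300 transcripts, ≤ 20% mitochondrial fraction and
a 1α1β or 2α1β chain configuration. A single-cell clone is a distinct
α+β CDR3 combination within an individual; expanded clones have ≥ 2 cells.
The TRS is the standardised (mean 0, SD 1; globally by default, per protocol
behind a flag) sum of a user-supplied 20-gene panel over pre-normalised
expression; the generator ships its own named panel since the panel is an
input, not a constant. TRS vs matching status is a nested-model F-test with
experimental protocol as fixed indicator columns — with few protocol levels
a fixed effect is the identifiable choice over a random effect; a
variance-component option is future work. With a single protocol level the
test reduces exactly to the pooled two-sample t-test. TCR PCs entering
cell-level usage models are first residualised on protocol, with which they
are otherwise collinear.

Survival uses the Kaplan–Meier product-limit estimator (ties: events before
censorings, stated for bit-reproducibility) and the standard log-rank
statistic with hypergeometric variance, both cross-checked against lifelines
and hand-stepped tables. Carrier status = ≥ 1 HLA-matched clone at any
included timepoint. Analysis-population subsetting (e.g. metastatic disease
only) is a user-supplied filter, not inferred. The overall-survival clock
starts at the first infusion by assumption.

## The synthetic cohort generator

The generator defines the study conditions; its defaults are fixed once:

| parameter | default | rationale |
|---|---|---|
| n_individuals | 250 | cohort size of the emulated study design |
| cancer mix | 92.4/6.8/0.8% | melanoma/renal/colorectal composition |
| n_vgenes (α/β) | 42/47 | V-gene counts analysed per chain |
| n_variants | 1000 | desk-scale stand-in for a genome-wide array |
| clones_per_sample | 2000 | order of unique clones per sample per chain |
| CDR3 lengths | 10–20, mass on 12–18 | realistic CDR3 length profile |
| usage_noise_sd | 1.0 | unit log-normal overdispersion per (individual, V-gene) |
| batch_effect_sd | 0.25, 2 batches | mild technical structure for the correction step |
| persistence | 0.10 baseline × 0.5 if matched | matched clones less stable across treatment |
| C4 redetection | 0.0664/0.0793/0.651 | per-group resampling probabilities at cycle 4 |
| HLA catalogue | 8 A + 9 B alleles, 4-digit | enough to exercise 2/4-digit resolution and the residue map |
| trs_shift | 0.3 | planted matched-cell TRS difference |
| survival HR | 0.5 | carrier hazard multiplier; exponential times, uniform censoring on [0, 1095] d |

V-gene clone counts are multinomial over V-genes with log-linear weights
(baseline + Σ cis β·dosage + Σ trans β·HLA dosage + batch offset +
individual noise); clone multiplicities are geometric (the empirical
clone-size law is unknown at this layer, so the simplest discrete choice is
used and is configurable). CDR3s carry chain-typical prefixes/suffixes
("CASS…EQYF" for β), which both mimics real junctions and gives the k-mer
matrix a shared background vocabulary; planted 7-mers overwrite a random
window in β-chain clones of carriers at rate
`motif_base_rate · exp(β·dosage + noise)`. Persistence is Bernoulli per
unique clone, ignoring clone size, matching the unique-clone-set treatment
throughout; C4 is generated directly from per-group redetection
probabilities (an emulation of the later-cycle resampling analysis, not a
mechanistic longevity model). Cells sample β clones weighted by bulk count
(creating singlets and expanded clones), keep one α partner per clone, and
add the TRS shift split evenly across the panel genes with per-gene SD 0.8,
so the planted shift is expressed in TRS standard deviations. Everything is
reproducible from a single integer seed.

**Scale mapping of planted effects.** Recovery is assessed on the INRT
scale. A log-weight effect β maps to approximately
β / √(1 + β²·Var(dosage) + sampling noise) there, so a planted 0.5 at
MAF 0.3 recovers around 0.44–0.47 — within the ±0.1 recovery band used by
the acceptance suite, with the small attenuation an intrinsic property of
rank-normalised compositional traits, not an estimator bias (the latent
log-count slope recovers 0.5 directly).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium between background
variants (proxies are constructed explicitly where needed), population
structure beyond exchangeable genotypes, V(D)J sequence biology beyond
junction prefixes, shared public clones between individuals, clone-size
dependent persistence, and covariate effects on the repertoire. The
statistical machinery is validated here; scientific conclusions on real
cohorts still depend on those unmodelled features.

## Problem sizes

The default test run simulates cohorts of 25–250 individuals with 150–2000
clones per sample; the family-wise calibration uses 200 replicate null
cohorts (n = 100, 200 variants, 20 traits, B = 200) and the recovery
harnesses 50 seeds at n = 250, chosen as the smallest sizes at which the
Monte-Carlo bands in the acceptance criteria are stable.
`scripts/acceptance.py` re-runs the same analyses at 10–100 seeds per
quantity.

## Known limitations

- No mixed-model association or relatedness handling; individuals are
  assumed unrelated.
- HWE exact test uses plain (not mid-) p; imputed fractional dosages are
  excluded from HWE counts but retained for regression.
- No LD pruning before genotype PCA (negligible at these scales; matrices
  are standardised and mean-imputed).
- The permutation null assumes exchangeable individuals; confounding that
  breaks exchangeability (e.g. strong stratification) is only partially
  absorbed by the PCs.
- Cox regression and covariate-adjusted survival are out of scope; the
  survival module is KM + log-rank only.
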