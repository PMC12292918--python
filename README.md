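# repqtl

Genetic determinants of the CD8+ T cell receptor (TCR) repertoire in
patients receiving immune checkpoint blockade (ICB), as a tested, reusable
analysis pipeline.

## The problem

The composition of a person's CD8+ TCR repertoire — which variable (V) gene
segments their clones use, and which CDR3 amino-acid motifs those clones
carry — is shaped by germline genetics: *cis* variants near the TRAV/TRBV
loci influence recombination propensity, and *trans* variants in the MHC
(classical HLA alleles and individual amino-acid positions in the
peptide-binding groove) influence which clones survive selection and
antigen-driven expansion. In an ICB cohort this matters clinically: clones
whose V-gene pairs with an HLA allele the patient carries ("HLA-matched"
clones) behave differently across treatment, score higher on tumour
reactivity at the single-cell level, and their carriage stratifies overall
survival.

`repqtl` implements that analysis end to end, for anyone with

- per-individual clone tables (AIRR-style rearrangement TSV),
- a genotype dosage matrix and imputed classical-HLA table,
- covariates, a single-cell table and survival times,

and ships a synthetic-cohort generator that emulates all of these with
planted effects, so every statistical component is testable against known
truth.

## The model

V-gene usage is a quantitative trait: the number of **unique** clones
(identity key: chain + V-gene + CDR3 amino acids; read counts ignored) per
V-gene per individual, normalised by trimmed mean of M-values (TMM),
batch-corrected, and mapped through the rank-based inverse normal transform
(INRT, Blom offset). Each trait is tested against each variant with additive
ordinary least squares:

```
usage ~ dosage + genetic PC1 + genetic PC2 + TCR PC1 + TCR PC2 + age + sex + cancer type
```

Family-wise significance is calibrated by permutation: the whole phenotype
matrix is row-permuted B times against fixed genotypes and covariates
(preserving inter-trait correlation), and the threshold is the 5% quantile
of the per-permutation minimum p-values. CDR3 7-mer usage (sliding windows
over CDR3s of length 12–18, counted as clone presence) is tested against HLA
alleles with the same machinery, and amino-acid positions get a
multi-residue omnibus F-test. Longitudinal clone tracking partitions paired
pre/post clone sets into unstable / novel / persistent groups and compares
per-individual HLA-matched proportions by paired Wilcoxon tests; single-cell
analysis scores each cell with a standardised 20-gene tumour reactivity
score (TRS) and tests it against HLA-matching status by nested-model ANOVA;
survival is Kaplan–Meier + log-rank between carriers and non-carriers of
HLA-matched clones.

## Worked example

Simulate a 250-patient cohort with one planted cis effect (β = 0.5 on the
multinomial log-weight scale, MAF 0.3) and one trans HLA effect, build the
β-chain phenotype, and scan 47 V-genes × 300 variants:

```python
from repqtl import association as assoc, phenotypes as ph, qc
from repqtl.simulate import SimConfig, simulate_cohort

cfg = SimConfig(
    n_individuals=250, n_variants=300, clones_per_sample=2000,
    cis_effects=[("var00000", "TRBV5", 0.5)],
    trans_effects=[("B*44", "TRBV7", 0.5)],
    maf_overrides={"var00000": 0.3},
    timepoints=("C1",), n_cells=0, seed=7,
)
co = simulate_cohort(cfg)
pm, corrected = ph.vgene_phenotype_pipeline(
    co.clones, "beta", co.covariates["batch"], "C1",
    list(co.genotypes.individuals))
cov = (assoc.encode_covariates(co.covariates[["age", "sex", "cancer_type"]])
       .join(qc.genetic_pcs(co.genotypes, 2))
       .join(ph.tcr_pcs(corrected, 2)))
res = assoc.scan(pm, co.genotypes, cov)
top = res.nsmallest(3, "p")[["feature", "predictor", "beta", "se", "p"]]
print(top.to_string(index=False))
null = assoc.permutation_threshold(pm, co.genotypes, cov,
                                   B=200, alpha=0.05, seed=8)
print(f"threshold: {null.threshold:.3e}; "
      f"hits: {(res.p < null.threshold).sum()}")
```

Output:

```
feature predictor      beta       se            p
  TRBV5  var00000  0.453862 0.089122 7.144236e-07
 TRBV38  var00202 -0.377518 0.089754 3.670759e-05
  TRBV3  var00030 -0.392577 0.095838 5.744213e-05
threshold: 2.589e-06; hits: 1
```

The planted variant is the top association, its estimate (0.45) sits near
the planted 0.5 on the INRT scale, and it is the only pair that survives the
permutation-derived family-wise threshold — the 200 null minima put 5% of
their mass below 2.6 × 10⁻⁶, so one hit among 14,100 tests is a genuine
discovery, not multiplicity.

The same analysis is available from the shell:

```bash
repqtl simulate --seed 7 --out sim/
repqtl qc --dosage sim/dosage.tsv --out qc/
repqtl phenotype --clones sim/clones.tsv --covariates sim/covariates.tsv \
    --feature vgene --chain beta --out pheno.tsv
repqtl run --seed 7 --out run/          # full pipeline + manifest
```

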