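# cpca — combinatorial PCA for biomarker panels

Single biomarkers often summarize a disease process poorly: chronic kidney
disease, for example, is tracked clinically through estimated glomerular
filtration rate (eGFR), yet many other routinely measured traits
(cystatin C, HbA1c, albumin, lipids, …) carry complementary signal.
**cpca** implements *combinatorial principal component analysis*: given a
panel of k quantitative biomarkers, it enumerates **every** subset of
2..k traits (2ᵏ − k − 1 of them; 2,097,130 for k = 21), extracts the
first principal component of each subset's correlation matrix as a
*composite phenotype* (CP), and screens all CPs for significantly better
disease classification than a chosen reference biomarker. The winning
composites then feed two genetic analyses: a per-variant association scan
of each CP, intersected into *consensus loci* (windows genome-wide
significant in every selected CP), and approximate-Bayes-factor
colocalization of a CP signal with the reference trait's signal at each
locus.

The package is aimed at biostatisticians and genetic epidemiologists who
want to run this workflow on their own cohort data, or to study its
operating characteristics on simulated cohorts before committing to a
biobank-scale run.

## Method at a glance

For a subset S of the panel with training correlation submatrix R_S, the
composite phenotype is

    CP_S(x) = o · Σ_{j∈S} v_j (x_j − m_j) / s_j,

where (v, λ₁) is the top eigenpair of R_S (‖v‖₂ = 1, λ₁ ≥ 1), m, s are
training means/SDs, and o ∈ {±1} orients the score so non-cases score
higher ("protective" direction). Classification is measured by the
midrank Mann–Whitney AUC, with stratified-bootstrap confidence intervals
and a studentized-bootstrap (or DeLong) p-value for the paired
CP-vs-reference ROC comparison, Bonferroni-corrected over the number of
enumerated subsets. CPs are fit on a stratified 70% training split and
validated on the held-out 30%. Association scans inverse-normal transform
the phenotype and regress it on each dosage with age, sex and optional
genetic PCs as covariates; colocalization apportions posterior mass over
the five standard hypotheses (PP0–PP4) from Wakefield log Bayes factors,
calling a locus colocalized when PP4 > 0.7.

## Worked example

Simulate a 20,000-sample cohort with five correlated traits where traits
A and B jointly drive disease risk, then screen all 26 subsets against
the best single marker A:

```python
import numpy as np
from cpca import (CohortConfig, ScreenConfig, simulate_cohort, run_screen,
                  top_candidates, component_frequency)

R = np.full((5, 5), 0.2); np.fill_diagonal(R, 1.0)
cohort = simulate_cohort(CohortConfig(
    n_samples=20_000, trait_names=list("ABCDE"), trait_correlation=R,
    disease_weights={"A": -1.0, "B": -0.8}, target_prevalence=0.1,
    rng_seed=42))
table = run_screen(cohort.panel, cohort.disease_status,
                   ScreenConfig(reference_trait="A", n_boot=500, seed=0))
print(f"reference test AUC: {table.attrs['reference_test_auc']:.3f}")
print(f"Bonferroni threshold: {table.attrs['threshold']:.3g}")
print(f"selected: {int(table['selected'].sum())} of {len(table)}")
print(top_candidates(table, 3)[["rank", "subset", "test_auc",
                                "p_vs_reference"]].to_string(index=False))
print(component_frequency(table.loc[table["selected"], "subset"], 1)
      .to_string(index=False))
```

Output:

```
reference test AUC: 0.778
Bonferroni threshold: 0.00192
selected: 3 of 26
 rank subset  test_auc  p_vs_reference
    1    A|B  0.826110    2.832597e-26
    2  A|B|C  0.799832    3.688577e-04
    3  A|B|E  0.797782    9.510266e-04
members  count  fraction
      A      3  1.000000
      B      3  1.000000
      C      1  0.333333
      E      1  0.333333
```

The screen recovers exactly the right structure: the composite of the two
disease-driving traits tops the ranking (test AUC 0.826 vs 0.778 for the
reference alone, bootstrap p ≈ 3×10⁻²⁶), the three selected composites
all contain both drivers (order-1 frequencies 3/3 for A and B), and the
pure-noise traits only ride along, never carry a selection.

The same workflow is available from the shell:

```sh
cpca simulate --config cohort.yaml --out-dir sim --seed 42
cpca screen --panel sim/panel.tsv --status sim/status.tsv \
     --reference A --boot 500 --seed 0 --out candidates.tsv
cpca report --candidates candidates.tsv
cpca gwas --genotypes sim/genotypes.tsv --variants sim/variants.tsv \
     --phenotype cp_scores.tsv --covariates sim/covariates.tsv --out cp_gwas.tsv
cpca consensus --stats cp1.tsv --stats cp2.tsv --out loci.tsv
cpca coloc --stats-a cp_gwas.tsv --stats-b ref_gwas.tsv --lead rs00001
cpca run --config run.yaml --seed 7        # all stages + manifest
```

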