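# tsimpute

Two-step genotype imputation for removing array-specific batch effects in
GWAS mega-analyses.

## The problem

Pooling individual-level genotype data from cohorts typed on *different*
genotyping arrays (a mega-analysis) increases power, but each array interrogates
its own density- and MAF-biased subset of SNVs. Imputing each array separately
against a common reference panel leaves array-specific patterns of dosage
shrinkage in the combined data: principal components of the merged genotypes
cluster samples by array rather than by ancestry, and a GWAS with the array
label as outcome is grossly inflated. Restricting the analysis to variants
typed on *all* arrays removes the clustering but throws away the tag SNVs that
make imputation work.

`tsimpute` implements a two-step workflow that harmonizes the arrays before
the final imputation, together with both comparator approaches and the full
evaluation battery, exercisable end to end on synthetic multi-array cohorts.

## The method

Let K arrays carry QC'd, phased genotype sets G_1 ... G_K from one population.

1. **Pairwise imputation.** Every target array t is imputed against every other
   array s used as a reference panel, giving K(K−1) dosage sets with
   per-variant estimated quality R̂².
2. **Intermediate panel.** Per array, a variant *qualifies* if it is directly
   typed (R̂² := 1) or cross-imputed from some source with R̂² ≥ 0.9. The
   intermediate panel is the **intersection** of the per-array qualifying
   sets — one identical variant list for every array — with each variant's
   phased best-guess genotypes taken from the highest-R̂² source.
3. **Final imputation.** Each array's intermediate panel is imputed against the
   common external reference panel, with no further quality filter. Because
   every array now enters with the same variant set drawn from the same
   population, array-specific shrinkage cancels and the batch effect vanishes.

The imputation engine is a haploid Li–Stephens copying HMM: the hidden state
at each reference site is the reference haplotype being copied, transitions
are P(j→k) = (1−ρ)·1[j=k] + ρ/H, typed sites emit the observed allele with
mismatch probability ε, and dosages are forward–backward posterior means.
Per-variant quality is the minimac-style R̂² = Var(haploid dosages) / p(1−p).

Evaluation: genetic PCA (EIGENSTRAT scaling: (g−2p)/√(2p(1−p)) after
missingness/HWE/MAF/LD-pruning filters) with a per-PC array-label association
R² = SSB/SST; MAF-binned median R̂²; |ΔAF| and AF correlation between modes;
truth-set concordance by genotype class; per-variant Wald association tests
(OLS / logistic IRLS), inverse-variance meta-analysis, genomic-control
λ = median(χ²₁)/0.456, and greedy LD clumping.

## Worked example

```python
import numpy as np
import tsimpute as ts

# one homogeneous population, three virtual arrays with densities
# 0.2/0.4/0.6 and MAF-bias exponents 0/1/2, 100 samples per array,
# a 2000-variant universe and a 100-haplotype external reference panel
scenario = ts.default_scenario(seed=0)

results = {}
for mode in ("conventional", "twostep"):
    run = ts.run_workflow(mode, scenario.array_datasets, scenario.reference_panel)
    pca = ts.genetic_pca(run.combined, n_components=10)
    _, max_r2 = ts.array_association(pca, n_pcs=10)
    print(f"{mode:>12}: max array-label R^2 over 10 PCs = {max_r2:.3f}")
    results[mode] = run

print("intermediate panel size:", len(results["twostep"].intermediate.variants))

_, af = ts.af_difference(results["twostep"].combined, results["conventional"].combined)
print(f"AF agreement between modes: r^2 = {af['af_r2']:.4f}")

labels = results["conventional"].combined.array_labels
keep = np.flatnonzero(np.isin(labels, ["array0", "array1"]))
for mode, run in results.items():
    lam = ts.batch_outcome_gwas(run.combined.subset_samples(keep))
    print(f"{mode:>12}: batch-outcome lambda_GC = {lam['dosage']['lambda_all']:.2f}")
```

prints

```
conventional: max array-label R^2 over 10 PCs = 0.319
     twostep: max array-label R^2 over 10 PCs = 0.011
intermediate panel size: 148
AF agreement between modes: r^2 = 0.9958
conventional: batch-outcome lambda_GC = 1.80
     twostep: batch-outcome lambda_GC = 0.98
```

Read: after conventional per-array imputation, one of the first ten principal
components of the combined data is strongly associated with the array label
(R² = 0.32 — clear batch clustering), and a GWAS against the array label is
inflated (λ = 1.80). After the two-step workflow the association is at the
permutation-null level (0.011) and the label GWAS is clean (λ = 0.98), while
allele frequencies of the two imputation routes agree at r² > 0.99.

A command-line surface wraps the same functions: `tsimpute simulate`,
`tsimpute qc`, `tsimpute impute`, `tsimpute twostep run`, `tsimpute evaluate`,
`tsimpute gwas run`. See `--help` on each.

## The acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the reference scenario from the given seed and recomputes the
whole study: all three workflow modes, the PCA batch-effect association,
MAF-binned imputation quality, allele-frequency agreement, truth-set
concordance, the batch-outcome GWAS λs, and the mega- vs meta-analysis
comparison, printing a summary of every quantity it measures.

## Scope notes

The engine replaces external phasing/imputation tooling so the workflow is
self-contained and testable at desk scale; it is site-indexed (no genetic
map) and has no state-space compression, so it is not a whole-genome tool.
Statistical phasing is out of scope (the simulator emits phase; unphased hard
calls are accepted through a clearly-labelled heuristic only). See
`docs/methods.md` for the model, parameter defaults, and known limitations.
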