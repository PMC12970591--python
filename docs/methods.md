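# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `tsimpute`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## 1. The imputation engine

A haploid Li–Stephens copying model. Given a reference panel of H phased
haplotypes over M biallelic sites, a target haplotype is modelled as an
imperfect mosaic of the panel:

* hidden state at site m: the panel haplotype being copied;
* transition between adjacent sites: stay with probability 1−ρ, otherwise
  switch to a uniformly chosen haplotype *including the current one*,
  i.e. P(j→k) = (1−ρ)·1[j=k] + ρ/H;
* emission at a typed, non-missing site: the observed allele matches the
  copied allele with probability 1−ε;
* untyped or missing sites emit nothing (likelihood 1), so they live in the
  chain and receive exact posteriors — no post-hoc interpolation.

Posterior alt-allele probabilities come from the scaled forward–backward
recursion; the per-site scaling factors also give the exact log-likelihood.
Sample dosage is the sum of the two haploid posteriors; typed, observed
alleles overwrite their posterior (dosage = observation). The recursion is
vectorized over target haplotypes and processed in blocks bounded at
~190 MB of stored forward probabilities.

**Exactness.** For every instance with ≤ 4 haplotypes × ≤ 6 sites the
posteriors and log-likelihood match exhaustive path enumeration to < 1e-10
(`tests/test_acceptance.py`); the forward–backward is exact for all sizes,
this just bounds the verification.

**Defaults.** ρ = 0.01 per inter-site interval and ε = 0.005. Transitions are
site-indexed, not genetic-map-scaled: the synthetic cohorts recombine per
interval, and at desk scale a map would add a parameter without adding
information. ε absorbs genotype error plus recurrent mutation.

**Estimated quality.** R̂² = Var(haploid dosages) / (p(1−p)) with p the mean
haploid dosage, clamped to [0, 1] (the raw ratio can exceed 1 in finite
samples); monomorphic estimates return 0. This is the minimac-style
variance-ratio estimator: 1 means fully confident (all posteriors at 0/1),
0 means the posterior everywhere equals the panel frequency. All R²-threshold
behaviour in the workflow is defined with respect to this estimator.

**Phasing.** The engine requires phased targets. The simulator always emits
phase. For unphased hard calls a fallback (`allow_phase_fallback=True`)
phases each sample by Viterbi-decoding the copying path from homozygous sites
and orienting heterozygotes along the copied allele. It is a labelled
heuristic with untuned switch error, provided so real unphased input is not a
hard stop; it is not a statistical phaser.

## 2. The two-step workflow

* **Pairwise step:** each QC'd array is imputed against every other array's
  haplotypes used as a reference panel (targets restricted to sites present
  on the source panel, as an imputation server would). K arrays → K(K−1)
  imputed sets.
* **Qualification:** per target array, a variant qualifies if directly typed
  (assigned R̂² = 1, source tag `typed`) or imputed from *some* source with
  R̂² ≥ r2_min (default 0.9; 0.8 is exercised by tests). A stricter reading —
  every source carrying the variant must pass — is available via
  `strict=True`. The lenient reading is the default because the intersection
  of per-array qualifying sets then yields the identical per-array variant
  count that the workflow's design calls for while retaining the most
  variants.
* **Intermediate panel:** the intersection of qualifying sets across arrays;
  per variant and array, phased best-guess hard calls from the winning source
  (typed beats imputed; R̂² ties break to the lexicographically smallest
  source name — determinism requires *some* rule and source names are stable).
* **Second step:** each intermediate panel is imputed against the common
  external panel with no further R² filtering. Phase comes from step 1's
  per-haplotype posteriors; no re-phasing.
* Comparators: **conventional** (each array straight to the common panel) and
  **overlap-only** (arrays first restricted to the variants typed on all of
  them).

Reference-panel construction from a genotype dataset fills residual missing
haplotype alleles with the major allele — deterministic, and negligible at
the ≤ ~1% missingness the QC allows through.

## 3. Quality control

Standard array-QC rules with strict-inequality boundaries exactly as printed
in common pipelines: samples with call rate < 94%; variants with missingness
> 5%, exact Hardy–Weinberg P < 1e-4, monomorphic sites, singletons
(minor-allele count exactly 1). Filters apply in the order missingness → HWE
→ monomorphic → singleton and each variant is reported under the first rule
it fails; the chain is idempotent.

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count's conditional distribution is enumerated and the two-sided
p is the sum of probabilities of all outcomes no more probable than the
observed one. Computed with log-factorials; it matches exact-rational
enumeration for all count triples with total ≤ 50 to < 1e-12. An exact (not
asymptotic chi-square) test is used because that is what genotype-QC tooling
conventionally applies; which one the original pipeline used is not stated
anywhere, so the choice is documented here.

PCA input additionally drops MAF < 1% and LD-prunes with a 50-variant window,
step 5, pairwise r² > 0.2 (remove the lower-MAF variant; ties → later
position — another determinism rule the underlying tools leave unspecified).

## 4. Batch-effect and performance evaluation

* **PCA:** EIGENSTRAT-style standardization (g − 2p)/√(2p(1−p)); residual
  missing values become 0 after centering (mean imputation); covariance
  eigendecomposition via SVD. Explained fractions are eigenvalues over the
  trace of the standardized covariance. Dosage datasets enter as dosages
  (hard calls are rounded only for the HWE/missingness counting filters).
* **Array association:** per PC, R² = between-array sum of squares over total
  sum of squares — a quantitative surrogate for "do the PCs cluster by
  array", which the source workflow assessed visually. Under random labels
  E[R²] = (K−1)/(N−1) ≈ 0.007 at K=3, N=300; the headline threshold 0.1 is
  ~15× that null.
* **Quality tables:** median R̂² by folded-MAF bin (bins (0,0.001] ...
  (0.05,0.5]), imputed variants only. True accuracy on synthetic data is the
  per-variant squared Pearson correlation between dosage and the simulated
  true genotype.
* **Concordance:** hard-call match percentages overall and within truth
  genotype classes (HomRef/Het/HomAlt). The per-class correlation is the
  Pearson r *across variants* of the per-variant class frequency (imputed vs
  truth): within a truth class the truth genotype is constant, so a
  within-class genotype correlation would be undefined. No numeric
  comparability with externally reported per-class correlations is claimed.

## 5. GWAS module

Per-variant Wald tests throughout: OLS (t-test, residualizing covariates once
via QR — exact and vectorized) and logistic Newton/IRLS (z-test;
non-convergence or |β| blow-up flags the variant as skipped and removes it
from λ and clumping — no Firth correction). Inverse-variance meta-analysis
uses w = SE⁻²; λ_GC = median(χ²₁)/0.45494 with p→χ² via the inverse survival
function; clumping is greedy by ascending p with r² > 0.01 within 1 Mb. The
genome-wide threshold is fixed at 5e-8. The batch-outcome GWAS regresses the
array label on dosage (and on best-guess genotypes for the robustness
check), reporting λ on all variants and on the MAF > 0.01 stratum.

## 6. The synthetic world

One genetically homogeneous population built as mosaics of founder
haplotypes: per-variant alt-allele frequencies ~ Beta(0.5, 0.5) truncated to
[0.005, 0.995] (both common and low-frequency variants, as a MAF-binned
evaluation needs); each sample haplotype copies a uniformly chosen founder,
switching per inter-variant interval with probability `recomb_prob` and
flipping each allele with probability `mutation_prob`. Arrays are variant
subsets sampled without replacement with weight MAF^maf_bias — the
"SNV selection and density" hypothesis for the batch effect, and only that
hypothesis (no per-array error rates, no intensity-level artifacts, no
array-private variants). Genotyping adds missingness (1%) and genotype error
(0.1%) uniformly.

Reference scenario (`default_scenario`): 2000-variant universe on one
contig, K=3 arrays with densities 0.2/0.4/0.6 and maf_bias 0/1/2, 100 samples
per array from one cohort of 300, a 100-haplotype external reference panel
from the same founders, truth genotypes for all samples.

**Calibration.** The free parameters are the founder count and the
recombination rate; the defaults (50 founders, ρ_sim = 0.02) are set so the
generator exhibits its defining contract: conventional per-array imputation
followed by combined PCA clusters samples by array (max per-PC label R² > 0.1)
and the two-step workflow removes the clustering. This puts the world in a
*moderate-quality* imputation regime (median R̂² ≈ 0.2–0.4): with 300 samples
and ~900 post-filter PCA variants, array clustering is only detectable above
Marchenko–Pastur noise when per-array dosage shrinkage differences are large,
i.e. when imputation is imperfect.

**What a green test does and does not establish.** The synthetic world
reproduces the *mechanism* (array-specific SNV selection → PC clustering →
label-GWAS inflation → removal by harmonization), not the *operating point* of
a real study (thousands of samples, millions of variants, 5000-haplotype
panels, median R̂² ≈ 0.99). Two consequences, verified by parameter sweeps and
recorded as known limitations:

1. At desk scale, high cross-imputation quality (needed for the R̂² ≥ 0.9
   intermediate panel to outgrow a sparse array's own typed set) and a
   PCA-detectable batch effect are mutually exclusive — the same
   anchors-per-LD-segment quantity controls both. The two-step mode therefore
   removes the batch effect here by harmonizing to the qualifying
   intersection, at some cost in true accuracy for the sparse array, whereas
   at real scale it also *gains* accuracy. The per-bin quality ordering
   two-step ≥ conventional is asserted in the acceptance suite and is
   expected red in this world.
2. Genomic-control λ on *best-guess* genotypes is deflated relative to dosage
   λ (integer genotypes produce exact case/control ties, i.e. Wald p = 1
   atoms, and near-constant columns): the "virtually unchanged under
   best-guess" property of a high-quality regime does not transfer, and its
   acceptance assertion is likewise expected red.

## 7. Numerical conventions

* VCF is 1-based; internal indices 0-based. Hard calls {0,1,2}, −1 missing.
* Only biallelic SNVs; multiallelic and symbolic records are rejected with
  counts reported. Strand-ambiguous (A/T, C/G) allele-swapped matches are
  dropped during alignment; plain swaps are recoded 0↔2 / d→2−d.
* VCF float fields are written at 6 decimals so the GT/DS/R2/AF round trip is
  lossless at 6 decimal places; record order is (chrom, pos, ref, alt);
  repeated runs are byte-identical.
* Best-guess alleles: posterior > 0.5 → alt; an exact 0.5 tie goes to the
  reference allele.
* All simulator randomness flows through one integer seed per operation
  (numpy `SeedSequence`); the workflow itself has no randomness.
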