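"""Synthetic multi-array cohorts with the LD structure that produces array batch effects.

The generator builds a single genetically homogeneous population as a mosaic of
founder haplotypes (a copying model: cheap, seedable, and rich enough in linkage
disequilibrium for a haplotype-copying HMM to exploit). Several virtual arrays
then genotype density- and MAF-biased subsets of the common variant universe.
Imputing each array separately against one external panel and running a combined
PCA reproduces the array-label clustering that motivates the two-step workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    ArrayDesign,
    GenotypeDataset,
    HaplotypePanel,
    SimConfig,
    variant_frame,
)

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def _default_variants(n_variants: int, rng: np.random.Generator) -> pd.DataFrame:
    pos = np.arange(1, n_variants + 1) * 100  # even 100 bp spacing on one contig
    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_variants)) % 4
    ids = np.array([f"var{i}" for i in range(n_variants)], dtype=object)
    return variant_frame(np.repeat("1", n_variants), pos, _BASES[ref_idx], _BASES[alt_idx], ids=ids)


def simulate_founders(
    n_founders: int = 50,
    n_variants: int = 2000,
    maf_spectrum=(0.5, 0.5),
    seed: int = 0,
) -> HaplotypePanel:
    """Draw founder haplotypes with Beta-distributed allele frequencies.

    ``maf_spectrum`` is either the (a, b) shape of the Beta law for the
    per-variant alt-allele frequency — truncated to [0.005, 0.995] so that the
    universe contains both common and low-frequency variants — or an explicit
    array of per-variant frequencies. Each founder allele is an independent
    Bernoulli draw at that frequency.
    """
    if n_founders < 2 or n_variants < 1:
        raise ValueError("need n_founders >= 2 and n_variants >= 1")
    rng = _rng(seed)
    spectrum = np.asarray(maf_spectrum, dtype=float)
    if spectrum.shape == (n_variants,) and n_variants != 2:
        freqs = spectrum
        if freqs.min() < 0 or freqs.max() > 1:
            raise ValueError("explicit frequencies must lie in [0, 1]")
    else:
        if spectrum.shape != (2,):
            raise ValueError("maf_spectrum must be (a, b) or per-variant frequencies")
        a, b = spectrum
        if a <= 0 or b <= 0:
            raise ValueError("Beta spectrum parameters must be positive")
        freqs = np.clip(rng.beta(a, b, size=n_variants), 0.005, 0.995)
    haps = (rng.random((2 * n_founders, n_variants)) < freqs).astype(np.int8)
    variants = _default_variants(n_variants, rng)
    ids = [f"founder{i}" for i in range(n_founders)]
    return HaplotypePanel(haps, variants, sample_ids=ids, name="founders")


def simulate_cohort(
    founders: HaplotypePanel,
    n_samples: int,
    recomb_prob: float = 0.02,
    mutation_prob: float = 0.001,
    seed: int = 0,
    sample_prefix: str = "s",
    return_paths: bool = False,
):
    """Simulate sample haplotypes as imperfect mosaics of the founders.

    At each inter-variant interval a haplotype switches to a uniformly chosen
    founder haplotype (including the current one) with probability
    ``recomb_prob``; every emitted allele is flipped with probability
    ``mutation_prob``. With ``return_paths`` the (2N, M) founder copy path is
    returned alongside the panel for diagnostic use.
    """
    rng = _rng(seed)
    F, M = founders.haplotypes.shape
    H = 2 * n_samples
    # copy path: start uniform; switch events re-draw the founder uniformly
    paths = np.empty((H, M), dtype=np.int64)
    paths[:, 0] = rng.integers(0, F, size=H)
    if M > 1:
        switch = rng.random((H, M - 1)) < recomb_prob
        draws = rng.integers(0, F, size=(H, M - 1))
        for m in range(1, M):
            paths[:, m] = np.where(switch[:, m - 1], draws[:, m - 1], paths[:, m - 1])
    alleles = founders.haplotypes[paths, np.arange(M)]
    flips = rng.random((H, M)) < mutation_prob
    alleles = np.where(flips, 1 - alleles, alleles).astype(np.int8)
    ids = [f"{sample_prefix}{i}" for i in range(n_samples)]
    panel = HaplotypePanel(alleles, founders.variants.copy(), sample_ids=ids, name="cohort")
    if return_paths:
        return panel, paths
    return panel


def design_array(
    universe_variants: pd.DataFrame,
    density: float,
    maf_bias: float = 0.0,
    seed: int = 0,
    name: str | None = None,
    universe_maf: np.ndarray | None = None,
) -> ArrayDesign:
    """Select a density- and MAF-biased variant subset as a virtual array.

    Variants are sampled without replacement with weight ``MAF ** maf_bias``;
    a positive bias favours common variants, emulating how commercial array
    designs differ in SNV selection and density. ``universe_maf`` defaults to
    the ``af`` column of ``universe_variants`` (folded).
    """
    M = len(universe_variants)
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    k = int(round(density * M))
    if k < 1:
        raise ValueError("density * n_variants must be at least 1")
    if universe_maf is None:
        if "af" not in universe_variants.columns:
            raise ValueError("universe variants need an 'af' column or explicit universe_maf")
        universe_maf = np.minimum(universe_variants["af"].to_numpy(), 1 - universe_variants["af"].to_numpy())
    maf = np.maximum(np.asarray(universe_maf, dtype=float), 1e-6)
    w = maf**maf_bias
    rng = _rng(seed)
    idx = rng.choice(M, size=k, replace=False, p=w / w.sum())
    idx.sort()
    return ArrayDesign(
        name=name or f"array_d{density:g}_b{maf_bias:g}",
        variant_index=idx,
        density=density,
        maf_bias=maf_bias,
    )


def genotype_on_array(
    cohort: HaplotypePanel,
    design: ArrayDesign,
    missing_rate: float = 0.01,
    error_rate: float = 0.001,
    seed: int = 0,
    sample_index: np.ndarray | None = None,
) -> GenotypeDataset:
    """Genotype a cohort (or a subset of its samples) on one virtual array.

    Each genotype is set missing with probability ``missing_rate``; each
    retained genotype is perturbed to a uniformly chosen *different* value with
    probability ``error_rate`` (phase is dropped at perturbed entries).
    """
    if design.variant_index.max(initial=-1) >= cohort.n_variants:
        raise ValueError("design indices exceed cohort variant universe")
    rng = _rng(seed)
    full = cohort.to_genotypes(array_label=design.name)
    if sample_index is not None:
        full = full.subset_samples(np.asarray(sample_index))
    ds = full.subset_variants(design.variant_index)
    n, m = ds.calls.shape
    calls = ds.calls.copy()
    phase = ds.phase.copy()
    miss = rng.random((n, m)) < missing_rate
    err = rng.random((n, m)) < error_rate
    # perturbation: shift by 1 or 2 mod 3 gives a uniform choice over the other values
    shift = rng.integers(1, 3, size=(n, m)).astype(np.int8)
    perturbed = ((calls + shift) % 3).astype(np.int8)
    do_err = err & ~miss
    calls = np.where(do_err, perturbed, calls)
    phase[do_err | miss] = MISSING
    calls[miss] = MISSING
    # erroneous hets get an arbitrary (0,1) orientation so the dataset stays phased
    err_het = do_err & (calls == 1)
    phase[err_het] = np.array([0, 1], dtype=np.int8)
    err_hom = do_err & (calls != 1)
    phase[err_hom] = np.stack([calls[err_hom] // 2, calls[err_hom] // 2], axis=-1)
    return GenotypeDataset(
        calls=calls,
        variants=ds.variants,
        sample_ids=ds.sample_ids,
        phase=phase,
        array_labels=np.repeat(design.name, n),
    )


def make_truth_subset(cohort: HaplotypePanel, n_subset: int, seed: int = 0) -> GenotypeDataset:
    """Full-universe genotypes for a random sample subset (the WGS stand-in)."""
    n = len(cohort.sample_ids)
    if n_subset > n:
        raise ValueError("n_subset exceeds cohort size")
    rng = _rng(seed)
    idx = np.sort(rng.choice(n, size=n_subset, replace=False))
    full = cohort.to_genotypes(array_label="truth")
    sub = full.subset_samples(idx)
    sub.phase = None  # truth set is exported as unphased hard calls
    return sub


@dataclass
class Scenario:
    """A complete simulated world: cohorts per array, reference panel, truth."""

    config: SimConfig
    founders: HaplotypePanel
    cohort: HaplotypePanel
    designs: list[ArrayDesign]
    array_datasets: dict[str, GenotypeDataset]
    sample_assignment: dict[str, np.ndarray]
    reference_panel: HaplotypePanel
    truth: GenotypeDataset

    def truth_for(self, sample_ids) -> GenotypeDataset:
        order = {s: i for i, s in enumerate(self.truth.sample_ids)}
        idx = np.array([order[s] for s in sample_ids])
        return self.truth.subset_samples(idx)


def default_scenario(
    seed: int = 0,
    config: SimConfig | None = None,
    densities=(0.2, 0.4, 0.6),
    maf_biases=(0.0, 1.0, 2.0),
    n_reference_haplotypes: int = 100,
) -> Scenario:
    """The reference batch-effect scenario.

    One population, K = 3 virtual arrays with densities 0.2/0.4/0.6 and MAF
    bias exponents 0/1/2, 100 samples per array drawn from one cohort, a
    2000-variant universe and a 100-haplotype external reference panel.
    Conventional per-array imputation followed by combined PCA clusters the
    samples by array label; the two-step workflow removes the clustering.
    """
    cfg = config or SimConfig(seed=seed)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    founders = simulate_founders(cfg.n_founders, cfg.n_variants, seed=seeds[0])
    K = len(densities)
    n_total = cfg.n_samples_per_array * K
    cohort = simulate_cohort(
        founders, n_total, cfg.recomb_prob, cfg.mutation_prob, seed=seeds[1]
    )
    universe_maf = np.minimum(cohort.allele_freq(), 1 - cohort.allele_freq())
    designs = [
        design_array(
            cohort.variants,
            density=d,
            maf_bias=b,
            seed=seeds[2] + i,
            name=f"array{i}",
            universe_maf=universe_maf,
        )
        for i, (d, b) in enumerate(zip(densities, maf_biases))
    ]
    rng = _rng(seeds[3])
    perm = rng.permutation(n_total)
    array_datasets: dict[str, GenotypeDataset] = {}
    assignment: dict[str, np.ndarray] = {}
    for i, design in enumerate(designs):
        block = np.sort(perm[i * cfg.n_samples_per_array : (i + 1) * cfg.n_samples_per_array])
        assignment[design.name] = block
        array_datasets[design.name] = genotype_on_array(
            cohort,
            design,
            missing_rate=cfg.missing_rate,
            error_rate=cfg.genotype_error_rate,
            seed=seeds[4] + i,
            sample_index=block,
        )
    ref = simulate_cohort(
        founders,
        n_reference_haplotypes // 2,
        cfg.recomb_prob,
        cfg.mutation_prob,
        seed=seeds[5],
        sample_prefix="ref",
    )
    ref.name = "reference"
    truth = make_truth_subset(cohort, n_subset=n_total, seed=seeds[6])
    return Scenario(
        config=cfg,
        founders=founders,
        cohort=cohort,
        designs=designs,
        array_datasets=array_datasets,
        sample_assignment=assignment,
        reference_panel=ref,
        truth=truth,
    )
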