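"""Pre-imputation genotype QC and PCA-input filters.

Filters follow standard array-QC practice: samples with call rate < 94% and
variants with missingness > 5%, exact Hardy-Weinberg P < 1e-4, monomorphic
sites and singletons are removed before imputation; PCA input additionally
drops MAF < 1% and LD-prunes with a 50-SNV window, step 5, r^2 > 0.2. All
removal conditions use strict inequalities; boundaries are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset


@dataclass
class QcThresholds:
    min_sample_call_rate: float = 0.94
    max_variant_missing: float = 0.05
    hwe_p_min: float = 1e-4
    drop_monomorphic: bool = True
    drop_singletons: bool = True
    pca_maf_min: float = 0.01
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2

    def __post_init__(self) -> None:
        for nm in ("min_sample_call_rate", "max_variant_missing", "pca_maf_min"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if not self.ld_window >= self.ld_step >= 1:
            raise ValueError("need ld_window >= ld_step >= 1")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts (same parity as the minor-allele count) whose
    conditional probability does not exceed that of the observed count.
    Computed with log-factorials for numerical range; exact for any counts.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_minor = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = np.array([_log_hwe_prob(h, n_minor, n) for h in hets])
    logp -= max(logp)
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    # tolerance guards against float round-off excluding ties
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _log_hwe_prob(n_het: int, n_minor: int, n: int) -> float:
    """Unnormalized log P(het = n_het | minor allele count, n diploids)."""
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = n - n_het - n_hom_minor
    if n_hom_minor < 0 or n_hom_major < 0:
        return -math.inf
    return (
        n_het * math.log(2.0)
        - math.lgamma(n_hom_minor + 1)
        - math.lgamma(n_het + 1)
        - math.lgamma(n_hom_major + 1)
    )


def hwe_pvalues(ds: GenotypeDataset) -> np.ndarray:
    """Exact HWE p-value per variant (monomorphic sites return 1)."""
    out = np.ones(ds.n_variants)
    for j in range(ds.n_variants):
        col = ds.calls[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        out[j] = hwe_exact_test(int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()))
    return out


# ---------------------------------------------------------------------------
# filters


@dataclass
class QcReport:
    removed_samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    removed_variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: dict = field(default_factory=dict)


def sample_call_rate_filter(ds: GenotypeDataset, min_rate: float = 0.94):
    """Drop samples whose non-missing fraction is strictly below ``min_rate``."""
    rate = 1.0 - ds.missing_mask().mean(axis=1)
    keep = rate >= min_rate
    if not keep.any():
        raise ValueError("sample call-rate filter removed every sample")
    removed = pd.DataFrame(
        {"sample_id": [s for s, k in zip(ds.sample_ids, keep) if not k], "call_rate": rate[~keep]}
    )
    out = ds.subset_samples(np.flatnonzero(keep))
    rep = QcReport(removed_samples=removed, counts={"samples_removed": int((~keep).sum())})
    return out, rep


def variant_qc(ds: GenotypeDataset, thresholds: QcThresholds | None = None):
    """Drop variants failing missingness, HWE, monomorphic and singleton rules.

    Filters apply in order missingness -> HWE -> monomorphic -> singleton;
    each variant is reported under the first rule it fails.
    """
    th = thresholds or QcThresholds()
    miss = ds.missing_mask().mean(axis=0)
    obs = ds.calls != MISSING
    alt_count = np.where(obs, ds.calls, 0).sum(axis=0)
    n_obs_alleles = 2 * obs.sum(axis=0)
    mac = np.minimum(alt_count, n_obs_alleles - alt_count)

    reason = np.full(ds.n_variants, "", dtype=object)
    fail_miss = miss > th.max_variant_missing
    reason[fail_miss] = "missingness"
    todo = ~fail_miss
    if th.hwe_p_min > 0:
        pvals = np.ones(ds.n_variants)
        for j in np.flatnonzero(todo):
            col = ds.calls[:, j]
            o = col[col != MISSING]
            if o.size:
                pvals[j] = hwe_exact_test(int((o == 0).sum()), int((o == 1).sum()), int((o == 2).sum()))
        fail_hwe = todo & (pvals < th.hwe_p_min)
        reason[fail_hwe] = "hwe"
        todo &= ~fail_hwe
    if th.drop_monomorphic:
        fail_mono = todo & (mac == 0)
        reason[fail_mono] = "monomorphic"
        todo &= ~fail_mono
    if th.drop_singletons:
        fail_single = todo & (mac == 1)
        reason[fail_single] = "singleton"
        todo &= ~fail_single

    keep = reason == ""
    ids = ds.variants["id"] if "id" in ds.variants.columns else ds.variants["pos"].astype(str)
    removed = pd.DataFrame(
        {
            "variant": ids.to_numpy()[~keep],
            "chrom": ds.variants["chrom"].to_numpy()[~keep],
            "pos": ds.variants["pos"].to_numpy()[~keep],
            "reason": reason[~keep],
        }
    )
    counts = {r: int((reason == r).sum()) for r in ("missingness", "hwe", "monomorphic", "singleton")}
    counts["kept"] = int(keep.sum())
    return ds.subset_variants(np.flatnonzero(keep)), QcReport(removed_variants=removed, counts=counts)


def maf_filter(ds: GenotypeDataset, maf_min: float = 0.01) -> GenotypeDataset:
    """Drop variants with minor allele frequency strictly below ``maf_min``."""
    maf = ds.maf()
    keep = ~(maf < maf_min)  # NaN (all-missing) variants are retained here
    return ds.subset_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    genotypes: np.ndarray,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning on a (N, M) genotype/dosage matrix.

    Missing entries (negative or NaN) are mean-imputed per variant. Within
    each window of ``window`` surviving variants (advancing by ``step``), one
    variant of every pair with squared Pearson correlation > ``r2_max`` is
    removed - the one with lower MAF, ties going to the later position. The
    returned sorted index set has all within-window pairwise r^2 <= r2_max.
    """
    g = np.asarray(genotypes, dtype=float).copy()
    g[g < 0] = np.nan
    mu = np.nanmean(g, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    nanmask = np.isnan(g)
    g[nanmask] = np.broadcast_to(mu, g.shape)[nanmask]
    m = g.shape[1]
    af = mu / 2.0
    maf = np.minimum(af, 1.0 - af)

    alive = np.ones(m, dtype=bool)
    start = 0
    while True:
        idx = np.flatnonzero(alive)
        if start >= len(idx):
            break
        win = idx[start : start + window]
        last_window = start + window >= len(idx)
        if len(win) > 1:
            sub = g[:, win]
            sd = sub.std(axis=0)
            ok = sd > 0
            if ok.sum() > 1:
                c = np.corrcoef(sub[:, ok], rowvar=False)
                r2 = c**2
                np.fill_diagonal(r2, 0.0)
                wok = win[ok]
                # repeatedly drop from the worst pair until the window is clean
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    vi, vj = wok[i], wok[j]
                    if maf[vi] < maf[vj]:
                        drop = i
                    elif maf[vj] < maf[vi]:
                        drop = j
                    else:
                        drop = i if vi > vj else j  # tie -> later position
                    alive[wok[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
        if last_window:
            break
        start += step
    return np.flatnonzero(alive)


def pca_input_filter(ds, thresholds: QcThresholds | None = None):
    """Apply the PCA-input filter chain; returns (matrix, kept index, report).

    Accepts hard calls or dosages. Missingness and HWE operate on hard calls
    (dosages are rounded for counting); MAF and LD pruning operate on the
    original values.
    """
    from .datatypes import DosageDataset

    th = thresholds or QcThresholds()
    if isinstance(ds, DosageDataset):
        mat = ds.dosages
        calls = np.clip(np.rint(ds.dosages), 0, 2).astype(np.int8)
        miss = np.zeros(ds.n_variants)
    else:
        mat = ds.calls.astype(float)
        mat[mat < 0] = np.nan
        calls = ds.calls
        miss = ds.missing_mask().mean(axis=0)

    report: dict = {"n_input": ds.n_variants}
    keep = miss <= th.max_variant_missing
    report["removed_missingness"] = int((~keep).sum())

    pvals = np.ones(ds.n_variants)
    for j in np.flatnonzero(keep):
        col = calls[:, j]
        o = col[col != MISSING]
        if o.size:
            pvals[j] = hwe_exact_test(int((o == 0).sum()), int((o == 1).sum()), int((o == 2).sum()))
    fail_hwe = keep & (pvals < th.hwe_p_min)
    report["removed_hwe"] = int(fail_hwe.sum())
    keep &= ~fail_hwe

    with np.errstate(invalid="ignore"):
        af = np.nanmean(mat, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    fail_maf = keep & ((maf < th.pca_maf_min) | np.isnan(maf))
    report["removed_maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    idx = np.flatnonzero(keep)
    sub = np.nan_to_num(mat[:, idx], nan=-1.0)
    pruned_local = ld_prune(sub, th.ld_window, th.ld_step, th.ld_r2_max)
    report["removed_ld"] = int(len(idx) - len(pruned_local))
    kept = idx[pruned_local]
    report["n_kept"] = int(len(kept))
    out = mat[:, kept]
    return out, kept, report
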