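"""Batch-effect and imputation-performance evaluation.

Quantifies what the workflow is supposed to fix: genetic PCA of the combined
imputed data with a per-component array-label association statistic (the
between-array fraction of score variance), MAF-stratified median imputation
quality, allele-frequency agreement between imputation modes, and hard-call
concordance against a truth set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, DosageDataset, GenotypeDataset, variant_keys
from .qc import QcThresholds, pca_input_filter

#: MAF strata used for the quality comparison (lower-exclusive, upper-inclusive)
DEFAULT_MAF_BINS = (
    (0.0, 0.001),
    (0.001, 0.005),
    (0.005, 0.01),
    (0.01, 0.02),
    (0.02, 0.03),
    (0.03, 0.04),
    (0.04, 0.05),
    (0.05, 0.5),
)


@dataclass
class PcaResult:
    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    variant_count: int
    filter_report: dict = field(default_factory=dict)
    sample_ids: list = field(default_factory=list)
    array_labels: np.ndarray | None = None


def genetic_pca(
    combined_ds,
    thresholds: QcThresholds | None = None,
    n_components: int = 20,
) -> PcaResult:
    """Genetic PCA of a combined genotype or dosage dataset.

    Input passes the PCA filter chain (missingness, exact HWE, MAF >= 1%,
    LD pruning 50/5/0.2), then every variant is standardized
    (g - 2p) / sqrt(2p(1-p)) with residual missing values set to 0 after
    centering, and the sample covariance is eigendecomposed (via SVD).
    Explained fractions are on the trace-of-covariance denominator.
    """
    mat, kept, report = pca_input_filter(combined_ds, thresholds)
    n, m = mat.shape
    if m < n_components:
        raise ValueError(f"only {m} variants survive filtering; need >= {n_components}")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(mat, axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    x = (mat - 2.0 * p) / denom
    x = np.nan_to_num(x, nan=0.0)
    x = x - x.mean(axis=0)  # exact column centering after mean-imputation
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    total_var = x.var(axis=0, ddof=1).sum()
    c = min(n_components, len(eig))
    scores = u[:, :c] * s[:c]
    return PcaResult(
        scores=scores,
        eigenvalues=eig[:c],
        explained_fraction=eig[:c] / total_var,
        variant_count=m,
        filter_report=report,
        sample_ids=list(combined_ds.sample_ids),
        array_labels=None if combined_ds.array_labels is None else combined_ds.array_labels.copy(),
    )


def array_association(
    pca: PcaResult, array_labels=None, n_pcs: int | None = None
) -> tuple[np.ndarray, float]:
    """Between-array variance fraction (R^2) per principal component.

    For each PC, R^2 = between-array sum of squares / total sum of squares of
    the scores - 1.0 when scores are constant within arrays and distinct
    across them, ~(K-1)/(N-1) in expectation under random labels. Returns the
    per-PC values and their maximum over the first ``n_pcs`` components.
    """
    if array_labels is None:
        array_labels = pca.array_labels
    if array_labels is None:
        raise ValueError("labels must cover all samples")
    labels = np.asarray(array_labels)
    if labels.shape[0] != pca.scores.shape[0]:
        raise ValueError("labels must cover all samples")
    uniq = np.unique(labels)
    c = pca.scores.shape[1] if n_pcs is None else min(n_pcs, pca.scores.shape[1])
    if len(uniq) < 2:
        warnings.warn("single array label: association R^2 is undefined, returning 0")
        return np.zeros(c), 0.0
    r2 = np.empty(c)
    for j in range(c):
        x = pca.scores[:, j]
        mu = x.mean()
        sst = ((x - mu) ** 2).sum()
        ssb = sum(len(x[labels == g]) * (x[labels == g].mean() - mu) ** 2 for g in uniq)
        r2[j] = 0.0 if sst == 0 else ssb / sst
    return r2, float(r2.max())


def median_by_maf_bin(
    maf: np.ndarray, values: np.ndarray, bins=DEFAULT_MAF_BINS
) -> pd.DataFrame:
    """Median of ``values`` per MAF stratum (lower-exclusive, upper-inclusive)."""
    maf = np.asarray(maf, dtype=float)
    values = np.asarray(values, dtype=float)
    rows = []
    for lo, hi in bins:
        sel = (maf > lo) & (maf <= hi) & ~np.isnan(values)
        rows.append(
            {
                "maf_low": lo,
                "maf_high": hi,
                "n_variants": int(sel.sum()),
                "median": float(np.median(values[sel])) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def median_r2_by_maf_bin(result: DosageDataset, bins=DEFAULT_MAF_BINS) -> pd.DataFrame:
    """Median estimated imputation R^2 by MAF stratum, imputed variants only."""
    imputed = ~result.typed
    df = median_by_maf_bin(result.maf()[imputed], result.rsq[imputed], bins)
    return df.rename(columns={"median": "median_rsq"})


def true_dosage_r2(result: DosageDataset, truth: GenotypeDataset) -> np.ndarray:
    """Per-variant squared Pearson correlation of dosage vs truth genotype.

    Samples are matched by id; variants by (chrom, pos, ref, alt) position in
    ``result`` (NaN where the variant is absent from the truth set or
    monomorphic in it).
    """
    order = {s: i for i, s in enumerate(truth.sample_ids)}
    rows = [order[s] for s in result.sample_ids if s in order]
    res_rows = [i for i, s in enumerate(result.sample_ids) if s in order]
    if not rows:
        raise ValueError("no overlapping samples between result and truth")
    tkeys = variant_keys(truth.variants)
    rkeys = variant_keys(result.variants)
    col = tkeys.get_indexer(rkeys)
    out = np.full(result.n_variants, np.nan)
    d = result.dosages[res_rows]
    g_all = truth.calls[rows].astype(float)
    g_all[g_all == MISSING] = np.nan
    for j in np.flatnonzero(col >= 0):
        g = g_all[:, col[j]]
        ok = ~np.isnan(g)
        if ok.sum() < 2 or g[ok].std() == 0 or d[ok, j].std() == 0:
            continue
        r = np.corrcoef(d[ok, j], g[ok])[0, 1]
        out[j] = r * r
    return out


def af_difference(dsA, dsB):
    """Per-variant |dAF| between two datasets plus summary statistics.

    Variants are matched on the full (chrom, pos, ref, alt) key; datasets with
    unfixed swapped allele coding share no keys and raise, which is the guard
    against comparing misaligned data. Returns (per-variant table, summary)
    where summary holds the median and max |dAF| and the squared Pearson
    correlation of the AF pairs.
    """
    afA = dsA.af if isinstance(dsA, DosageDataset) else dsA.allele_freq()
    afB = dsB.af if isinstance(dsB, DosageDataset) else dsB.allele_freq()
    keysA = variant_keys(dsA.variants)
    keysB = variant_keys(dsB.variants)
    shared = keysA.intersection(keysB).sort_values()
    if len(shared) == 0:
        raise ValueError("no shared variants; align the datasets first")
    ia = keysA.get_indexer(shared)
    ib = keysB.get_indexer(shared)
    a, b = afA[ia], afB[ib]
    table = pd.DataFrame(list(shared), columns=["chrom", "pos", "ref", "alt"])
    table["af_a"] = a
    table["af_b"] = b
    table["abs_daf"] = np.abs(a - b)
    if np.std(a) == 0 or np.std(b) == 0:
        r2 = np.nan
    else:
        r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
    summary = {
        "n_variants": int(len(shared)),
        "median_abs_daf": float(np.median(table["abs_daf"])),
        "max_abs_daf": float(np.max(table["abs_daf"])),
        "af_r2": r2,
    }
    return table, summary


@dataclass
class ConcordanceReport:
    overall_pct: float
    per_class_pct: dict
    per_class_n: dict
    class_freq_r: dict
    n_compared: int
    by_maf_bin: pd.DataFrame | None = None


_CLASSES = {0: "HomRef", 1: "Het", 2: "HomAlt"}


def concordance(
    imputed_hard: GenotypeDataset,
    truth: GenotypeDataset,
    maf_bins=None,
) -> ConcordanceReport:
    """Hard-call concordance with a truth set, overall and per genotype class.

    Classes (HomRef/Het/HomAlt) are defined from the *truth* genotype. The
    per-class correlation is the Pearson r across variants between the
    per-variant class frequency in the imputed calls and in the truth calls
    (the truth genotype is constant within a class, so a within-class
    genotype correlation would be undefined).
    """
    order = {s: i for i, s in enumerate(truth.sample_ids)}
    imp_rows = [i for i, s in enumerate(imputed_hard.sample_ids) if s in order]
    tr_rows = [order[imputed_hard.sample_ids[i]] for i in imp_rows]
    ikeys = variant_keys(imputed_hard.variants)
    tkeys = variant_keys(truth.variants)
    shared = ikeys.intersection(tkeys).sort_values()
    if not imp_rows or len(shared) == 0:
        raise ValueError("no overlapping samples/variants between imputed and truth")
    gi = imputed_hard.calls[np.ix_(imp_rows, ikeys.get_indexer(shared))]
    gt = truth.calls[np.ix_(tr_rows, tkeys.get_indexer(shared))]
    ok = (gi != MISSING) & (gt != MISSING)
    n_comp = int(ok.sum())
    match = (gi == gt) & ok
    overall = 100.0 * match.sum() / n_comp if n_comp else np.nan
    per_pct, per_n, per_r = {}, {}, {}
    for c, name in _CLASSES.items():
        sel = ok & (gt == c)
        per_n[name] = int(sel.sum())
        per_pct[name] = 100.0 * (match & sel).sum() / sel.sum() if sel.any() else np.nan
        fi = ((gi == c) & ok).sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
        ft = ((gt == c) & ok).sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
        if fi.std() > 0 and ft.std() > 0:
            per_r[name] = float(np.corrcoef(fi, ft)[0, 1])
        else:
            per_r[name] = np.nan
    by_bin = None
    if maf_bins is not None:
        with np.errstate(invalid="ignore"):
            af = np.where(gt == MISSING, np.nan, gt).astype(float)
            af = np.nanmean(af, axis=0) / 2.0
        maf = np.minimum(af, 1 - af)
        pct = np.where(ok.sum(axis=0) > 0, 100.0 * match.sum(axis=0) / np.maximum(ok.sum(axis=0), 1), np.nan)
        by_bin = median_by_maf_bin(maf, pct, maf_bins).rename(columns={"median": "median_pct"})
    return ConcordanceReport(
        overall_pct=float(overall),
        per_class_pct=per_pct,
        per_class_n=per_n,
        class_freq_r=per_r,
        n_compared=n_comp,
        by_maf_bin=by_bin,
    )


def plot_pcs(pca: PcaResult, path, pcs=(0, 1)) -> None:
    """Scatter of two PCs colored by array label (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = pca.array_labels if pca.array_labels is not None else np.repeat("all", len(pca.scores))
    for g in np.unique(labels):
        sel = labels == g
        ax.scatter(pca.scores[sel, pcs[0]], pca.scores[sel, pcs[1]], s=8, label=str(g), alpha=0.7)
    ax.set_xlabel(f"PC{pcs[0] + 1} ({pca.explained_fraction[pcs[0]]:.1%})")
    ax.set_ylabel(f"PC{pcs[1] + 1} ({pca.explained_fraction[pcs[1]]:.1%})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
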