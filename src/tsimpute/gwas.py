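"""Association testing on dosages, meta-analysis, genomic control and clumping.

Per-variant linear association is ordinary least squares of the phenotype on
dosage plus covariates (Wald t-test); logistic association is Newton/IRLS with
a Wald z-test. Study-level summary statistics combine by inverse-variance
weighting. Genomic control lambda is the median association chi-square over
the null chi-square(1) median; clumping greedily reduces significant variants
to LD-independent leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))
GENOME_WIDE_P = 5e-8


def _variant_columns(variants: pd.DataFrame | None, m: int) -> pd.DataFrame:
    if variants is None:
        return pd.DataFrame(
            {"chrom": np.repeat("1", m), "pos": np.arange(1, m + 1), "id": [f"v{j}" for j in range(m)]}
        )
    out = variants[["chrom", "pos"]].copy()
    out["id"] = variants["id"] if "id" in variants.columns else (
        variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
    )
    if "alt" in variants.columns:
        out["a1"] = variants["alt"]
    return out.reset_index(drop=True)


def assoc_linear(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage + covariates + intercept.

    Uses Frisch-Waugh partialling: covariates (and the intercept) are
    residualized out of both phenotype and dosages once, giving exact OLS
    betas/SEs for every variant in one vectorized pass. Variants with zero
    dosage variance after residualization are skipped (flagged, beta=NaN).
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = d.shape
    if y.shape[0] != n:
        raise ValueError("phenotype length must equal sample count")
    if np.isnan(y).any():
        raise ValueError("missing phenotype values are not allowed")
    X = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    k = X.shape[1]
    Q, _ = np.linalg.qr(X)
    yr = y - Q @ (Q.T @ y)
    dr = d - Q @ (Q.T @ d)
    sxx = (dr**2).sum(axis=0)
    ok = sxx > 1e-12
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    dof = n - k - 1
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    beta[ok] = (dr[:, ok] * yr[:, None]).sum(axis=0) / sxx[ok]
    rss = (yr**2).sum() - beta[ok] ** 2 * sxx[ok]
    sigma2 = np.maximum(rss, 0.0) / dof
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t), dof)
    out = _variant_columns(variants, m)
    out["af"] = d.mean(axis=0) / 2.0
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.minimum(np.where(np.isnan(p), np.nan, np.maximum(p, 5e-324)), 1.0)
    out["n"] = n
    out["model"] = "linear"
    out["skipped"] = ~ok
    return out


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10):
    """Newton/IRLS logistic fit; returns (beta, se, converged, separated)."""
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log(max(y.mean(), 1e-9) / max(1 - y.mean(), 1e-9))
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            return beta, np.full(k, np.inf), False, True
        XtW = X.T * w
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.inf), False, True
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        return beta, np.full(k, np.inf), False, False
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, np.full(k, np.inf), False, True
    se = np.sqrt(np.diag(cov))
    separated = bool(np.abs(beta).max() > 15 or np.min(w) < 1e-10 and np.abs(beta[-1]) > 10)
    return beta, se, True, separated


def assoc_logistic(
    dosages: np.ndarray,
    case_control: np.ndarray,
    covariates: np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant logistic regression of case/control status on dosage.

    Wald z-test on the dosage coefficient. Variants whose fit does not
    converge or shows (quasi-)separation are flagged ``skipped`` and should be
    excluded from lambda and clumping.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(case_control, dtype=float)
    n, m = d.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("case_control must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    base = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    k = base.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    skipped = np.zeros(m, dtype=bool)
    X = np.column_stack([base, np.zeros(n)])
    for j in range(m):
        if d[:, j].std() < 1e-12:
            skipped[j] = True
            continue
        X[:, k] = d[:, j]
        b, s, conv, sep = _logistic_fit(X, y)
        if not conv or sep or not np.isfinite(s[k]):
            skipped[j] = True
            continue
        beta[j], se[j] = b[k], s[k]
    with np.errstate(invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = _variant_columns(variants, m)
    out["af"] = d.mean(axis=0) / 2.0
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.minimum(np.where(np.isnan(p), np.nan, np.maximum(p, 5e-324)), 1.0)
    out["n"] = n
    out["model"] = "logistic"
    out["skipped"] = skipped
    return out


def ivw_meta(per_study: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Inverse-variance weighted fixed-effect combination of (beta, SE) pairs."""
    pairs = [(b, s) for b, s in per_study if np.isfinite(s) and s > 0]
    if not pairs:
        raise ValueError("no study with a finite standard error")
    w = np.array([s**-2 for _, s in pairs])
    b = np.array([b for b, _ in pairs])
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def ivw_meta_table(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Row-wise IVW meta-analysis of association tables sharing variant ids.

    Variants are joined on (chrom, pos, id); rows flagged ``skipped`` or with
    non-finite SE in a study are excluded from that study's contribution.
    """
    frames = []
    for i, df in enumerate(studies):
        sub = df.loc[~df["skipped"] & np.isfinite(df["se"]), ["chrom", "pos", "id", "beta", "se"]]
        frames.append(sub.rename(columns={"beta": f"beta{i}", "se": f"se{i}"}))
    joined = frames[0]
    for f in frames[1:]:
        joined = joined.merge(f, on=["chrom", "pos", "id"], how="inner")
    betas = joined[[c for c in joined.columns if c.startswith("beta")]].to_numpy()
    ses = joined[[c for c in joined.columns if c.startswith("se")]].to_numpy()
    w = ses**-2.0
    beta = (w * betas).sum(axis=1) / w.sum(axis=1)
    se = w.sum(axis=1) ** -0.5
    out = joined[["chrom", "pos", "id"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = 2.0 * stats.norm.sf(np.abs(beta / se))
    out["n_studies"] = betas.shape[1]
    return out


def lambda_gc(p_values=None, chi2=None) -> float:
    """Genomic control lambda: median chi-square(1) over its null median."""
    if chi2 is None:
        if p_values is None:
            raise ValueError("provide p_values or chi2")
        p = np.asarray(p_values, dtype=float)
        p = p[np.isfinite(p)]
        chi2 = stats.chi2.isf(p, 1)
    chi2 = np.asarray(chi2, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def clump(
    results: pd.DataFrame,
    ld_genotypes: np.ndarray,
    ld_variants: pd.DataFrame | None = None,
    p_max: float = GENOME_WIDE_P,
    r2_min: float = 0.01,
    dist_bp: float = 1e6,
) -> pd.DataFrame:
    """Greedy reduction of significant hits to LD-independent lead variants.

    Significant variants (p < ``p_max``) are scanned in ascending p; each lead
    removes every remaining significant variant within ``dist_bp`` on the same
    chromosome whose squared genotype correlation with the lead exceeds
    ``r2_min``. ``ld_genotypes`` is the (N, M) matrix the r^2 is computed on,
    column-matched to ``results`` rows (or to ``ld_variants``).
    """
    res = results.reset_index(drop=True)
    g = np.asarray(ld_genotypes, dtype=float)
    if ld_variants is not None:
        key = ld_variants["chrom"].astype(str) + ":" + ld_variants["pos"].astype(str)
        colmap = {k: i for i, k in enumerate(key)}
        cols = (res["chrom"].astype(str) + ":" + res["pos"].astype(str)).map(colmap)
        if cols.isna().any():
            raise ValueError("results contain variants absent from the LD source")
        cols = cols.to_numpy(dtype=int)
    else:
        if g.shape[1] != len(res):
            raise ValueError("LD matrix columns must match results rows")
        cols = np.arange(len(res))
    sig = res.index[(res["p"] < p_max) & ~res.get("skipped", pd.Series(False, index=res.index))].tolist()
    sig.sort(key=lambda i: (res.at[i, "p"], res.at[i, "chrom"], res.at[i, "pos"]))
    alive = set(sig)
    leads = []
    for i in sig:
        if i not in alive:
            continue
        leads.append(i)
        alive.discard(i)
        xi = g[:, cols[i]]
        for j in list(alive):
            if res.at[j, "chrom"] != res.at[i, "chrom"]:
                continue
            if abs(int(res.at[j, "pos"]) - int(res.at[i, "pos"])) > dist_bp:
                continue
            xj = g[:, cols[j]]
            if xi.std() == 0 or xj.std() == 0:
                continue
            if np.corrcoef(xi, xj)[0, 1] ** 2 > r2_min:
                alive.discard(j)
    return res.loc[leads].reset_index(drop=True)


def batch_outcome_gwas(combined, array_labels=None, maf_min: float = 0.01) -> dict:
    """GWAS with the array label itself as outcome; lambda per MAF stratum.

    Runs an unadjusted logistic association of array membership on dosage,
    once on dosages and once on best-guess genotypes, reporting lambda on all
    variants and on the MAF > ``maf_min`` subset. With more than two labels,
    each label is tested one-vs-rest and the maximum lambda is reported.
    """
    from .impute import best_guess

    labels = np.asarray(array_labels if array_labels is not None else combined.array_labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("batch-outcome GWAS needs at least two array labels")
    targets = [uniq[0]] if len(uniq) == 2 else list(uniq)
    maf = combined.maf()
    matrices = {"dosage": combined.dosages}
    if combined.hap_dosages is not None:
        matrices["best_guess"] = best_guess(combined).calls.astype(float)
    out: dict = {}
    for kind, mat in matrices.items():
        lam_all, lam_common = [], []
        for lab in targets:
            y = (labels == lab).astype(float)
            res = assoc_logistic(mat, y)
            keep = ~res["skipped"] & np.isfinite(res["p"])
            lam_all.append(lambda_gc(res.loc[keep, "p"]))
            common = keep & (maf > maf_min)
            lam_common.append(lambda_gc(res.loc[common, "p"]))
        out[kind] = {
            "lambda_all": float(max(lam_all)),
            "lambda_common": float(max(lam_common)),
        }
    return out


def compare_mega_meta(mega: pd.DataFrame, meta: pd.DataFrame):
    """Join mega-analysis and meta-analysis results and summarize differences.

    Returns (per-variant table with d_beta, d_se, d_neglog10p; summary of
    quantiles of each difference). Raises when the variant sets are disjoint.
    """
    cols = ["chrom", "pos", "id", "beta", "se", "p"]
    a = mega[cols].rename(columns={"beta": "beta_mega", "se": "se_mega", "p": "p_mega"})
    b = meta[cols].rename(columns={"beta": "beta_meta", "se": "se_meta", "p": "p_meta"})
    joined = a.merge(b, on=["chrom", "pos", "id"], how="inner").dropna(subset=["beta_mega", "beta_meta"])
    if joined.empty:
        raise ValueError("mega and meta results share no variants")
    joined["d_beta"] = joined["beta_mega"] - joined["beta_meta"]
    joined["d_se"] = joined["se_mega"] - joined["se_meta"]
    with np.errstate(divide="ignore"):
        joined["d_neglog10p"] = -np.log10(joined["p_mega"]) + np.log10(joined["p_meta"])
    qs = [0.25, 0.5, 0.75]
    summary = {
        f"{col}_q{int(q * 100)}": float(joined[col].quantile(q))
        for col in ("d_beta", "d_se", "d_neglog10p")
        for q in qs
    }
    summary["n_variants"] = int(len(joined))
    return joined, summary


def write_summary_stats(results: pd.DataFrame, path) -> None:
    """Tab-delimited summary statistics (CHR POS ID A1 AF BETA SE P N)."""
    out = pd.DataFrame(
        {
            "CHR": results["chrom"],
            "POS": results["pos"],
            "ID": results["id"],
            "A1": results.get("a1", "."),
            "AF": results["af"] if "af" in results else np.nan,
            "BETA": results["beta"],
            "SE": results["se"],
            "P": results["p"],
            "N": results["n"] if "n" in results else np.nan,
        }
    )
    out.to_csv(path, sep="\t", index=False)
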