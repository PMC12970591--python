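"""Haplotype-copying (Li-Stephens) imputation engine.

Each target haplotype is modelled as an imperfect mosaic of the reference
haplotypes: the hidden state at every reference site is the haplotype being
copied; between adjacent sites the chain stays with probability 1 - rho and
otherwise switches to a uniformly chosen haplotype (including itself), i.e.
P(j -> k) = (1 - rho) * 1[j = k] + rho / H. Typed, non-missing sites emit the
observed allele with mismatch probability eps; untyped or missing sites are
uninformative. Posterior alt-allele probabilities at every reference site come
from the scaled forward-backward recursion; with zero typed sites they reduce
to the reference allele frequency.

Transitions are site-indexed (no genetic map): rho is a per-interval switch
probability, matching how the synthetic cohorts are generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    MISSING,
    DosageDataset,
    GenotypeDataset,
    HaplotypePanel,
    variant_keys,
)

_UNOBSERVED = -9  # internal emission code: site carries no information

# memory budget for the stored forward pass, in float64 elements
_BLOCK_ELEMENTS = 24_000_000


@dataclass
class HmmParams:
    """Copying-model parameters.

    ``switch_prob`` (rho): per-interval probability of switching template;
    0.01 matches the default simulated recombination rate. ``error_prob``
    (eps): allele mismatch probability at typed sites; 0.005 absorbs genotype
    error and recurrent mutation.
    """

    switch_prob: float = 0.01
    error_prob: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 < self.switch_prob < 1.0:
            raise ValueError("switch_prob must lie in (0, 1)")
        if not 0.0 <= self.error_prob < 0.5:
            raise ValueError("error_prob must lie in [0, 0.5)")


def _emission_block(obs_col: np.ndarray, ref_col: np.ndarray, eps: float) -> np.ndarray:
    """(T, H) emission likelihoods at one site; unobserved targets emit 1."""
    match = obs_col[:, None] == ref_col[None, :]
    e = np.where(match, 1.0 - eps, eps)
    e[obs_col == _UNOBSERVED, :] = 1.0
    return e


def _forward_backward(obs: np.ndarray, ref: np.ndarray, rho: float, eps: float):
    """Scaled forward-backward for a block of target haplotypes.

    ``obs`` is (T, M) with alleles in {0, 1} and ``_UNOBSERVED`` elsewhere;
    ``ref`` is (H, M). Returns (allele posterior (T, M), log-likelihood (T)).
    """
    T, M = obs.shape
    H = ref.shape[0]
    refT = ref.T.astype(float)  # (M, H)
    fwd = np.empty((M, T, H))
    scale = np.empty((M, T))
    f = np.full((T, H), 1.0 / H) * _emission_block(obs[:, 0], ref[:, 0], eps)
    s = f.sum(axis=1)
    f /= s[:, None]
    fwd[0], scale[0] = f, s
    for m in range(1, M):
        f = (1.0 - rho) * f + (rho / H) * f.sum(axis=1, keepdims=True)
        f *= _emission_block(obs[:, m], ref[:, m], eps)
        s = f.sum(axis=1)
        f /= s[:, None]
        fwd[m], scale[m] = f, s
    loglik = np.log(scale).sum(axis=0)

    post_allele = np.empty((T, M))
    b = np.ones((T, H))
    post = fwd[M - 1] * b
    post /= post.sum(axis=1, keepdims=True)
    post_allele[:, M - 1] = post @ refT[M - 1]
    for m in range(M - 2, -1, -1):
        eb = _emission_block(obs[:, m + 1], ref[:, m + 1], eps) * b
        b = (1.0 - rho) * eb + (rho / H) * eb.sum(axis=1, keepdims=True)
        b /= b.sum(axis=1, keepdims=True)  # rescale; posterior is normalized anyway
        post = fwd[m] * b
        post /= post.sum(axis=1, keepdims=True)
        post_allele[:, m] = post @ refT[m]
    return post_allele, loglik


def impute_haplotypes(
    obs: np.ndarray, ref_haplotypes: np.ndarray, params: HmmParams | None = None
):
    """Posterior alt-allele probability for each target haplotype at all sites.

    ``obs``: (T, M) over the full reference site list, with ``_UNOBSERVED``
    (or any negative value) at untyped/missing sites. Processed in blocks to
    bound the memory of the stored forward pass.
    """
    p = params or HmmParams()
    ref = np.asarray(ref_haplotypes, dtype=np.int8)
    if ref.ndim != 2 or ref.shape[0] < 1:
        raise ValueError("reference panel must be a non-empty (H, M) matrix")
    obs = np.asarray(obs)
    if obs.ndim != 2 or obs.shape[1] != ref.shape[1]:
        raise ValueError("obs must be (T, M) over the reference site list")
    obs = np.where(obs < 0, _UNOBSERVED, obs).astype(np.int8)
    T, M = obs.shape
    H = ref.shape[0]
    block = max(1, _BLOCK_ELEMENTS // max(1, M * H))
    out = np.empty((T, M))
    logl = np.empty(T)
    for lo in range(0, T, block):
        hi = min(T, lo + block)
        out[lo:hi], logl[lo:hi] = _forward_backward(obs[lo:hi], ref, p.switch_prob, p.error_prob)
    return out, logl


def impute_haplotype(
    target_alleles_at_typed_sites: np.ndarray,
    typed_site_index: np.ndarray,
    ref_panel: HaplotypePanel | np.ndarray,
    params: HmmParams | None = None,
) -> np.ndarray:
    """Impute one haplotype given its alleles at a subset of reference sites."""
    ref = ref_panel.haplotypes if isinstance(ref_panel, HaplotypePanel) else np.asarray(ref_panel)
    typed = np.asarray(typed_site_index, dtype=int)
    if typed.size and (typed.min() < 0 or typed.max() >= ref.shape[1]):
        raise ValueError("typed site index outside the reference site list")
    obs = np.full((1, ref.shape[1]), _UNOBSERVED, dtype=np.int8)
    obs[0, typed] = np.asarray(target_alleles_at_typed_sites, dtype=np.int8)
    post, _ = impute_haplotypes(obs, ref, params)
    return post[0]


def estimated_r2(hap_dosages: np.ndarray, af: np.ndarray | None = None) -> np.ndarray:
    """Minimac-style imputation quality estimate per variant.

    Ratio of the empirical variance of the haploid dosages to the Bernoulli
    variance af * (1 - af) expected under perfect information, clamped to
    [0, 1]; monomorphic estimates (af in {0, 1}) return 0.
    """
    hd = np.asarray(hap_dosages, dtype=float)
    if af is None:
        af = hd.mean(axis=0)
    af = np.asarray(af, dtype=float)
    var = hd.var(axis=0)
    denom = af * (1.0 - af)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, var / denom, 0.0)
    return np.clip(r2, 0.0, 1.0)


def impute_dataset(
    target: GenotypeDataset,
    ref_panel: HaplotypePanel,
    params: HmmParams | None = None,
    allow_phase_fallback: bool = False,
) -> DosageDataset:
    """Impute a phased genotype dataset against a reference panel.

    The output covers every reference site. Typed sites keep their observed
    alleles (haploid dosage overwritten with the observation where present);
    per-variant quality is the :func:`estimated_r2` of the haploid dosages.
    Unphased targets are rejected unless ``allow_phase_fallback`` is set, in
    which case a documented Viterbi re-phasing heuristic is applied first.
    """
    p = params or HmmParams()
    if not target.is_phased():
        if target.phase is None and not (target.calls == 1).any():
            target = _phase_homozygous(target)
        elif allow_phase_fallback:
            target = phase_by_viterbi(target, ref_panel, p)
        else:
            raise ValueError("target is unphased; pass allow_phase_fallback=True for the heuristic")
    tkeys = variant_keys(target.variants)
    rkeys = variant_keys(ref_panel.variants)
    col = rkeys.get_indexer(tkeys)
    if (col < 0).any():
        raise ValueError("typed sites missing from the reference panel; align first")
    N, Mt = target.calls.shape
    M = ref_panel.n_variants
    obs = np.full((2 * N, M), _UNOBSERVED, dtype=np.int8)
    haps = target.haplotypes()  # (2N, Mt), -1 where missing
    obs[:, col] = np.where(haps == MISSING, _UNOBSERVED, haps)
    hap_dos, _ = impute_haplotypes(obs, ref_panel.haplotypes, p)
    observed = obs[:, col] != _UNOBSERVED
    hap_dos[:, col] = np.where(observed, obs[:, col], hap_dos[:, col])
    dosages = hap_dos[0::2] + hap_dos[1::2]
    af = hap_dos.mean(axis=0)
    rsq = estimated_r2(hap_dos, af)
    typed = np.zeros(M, dtype=bool)
    typed[col] = True
    return DosageDataset(
        dosages=np.clip(dosages, 0.0, 2.0),
        variants=ref_panel.variants.copy(),
        sample_ids=list(target.sample_ids),
        rsq=rsq,
        af=af,
        typed=typed,
        hap_dosages=np.clip(hap_dos, 0.0, 1.0),
        source_tag=np.repeat(ref_panel.name, M).astype(object),
        array_labels=target.array_labels.copy(),
    )


def best_guess(result: DosageDataset) -> GenotypeDataset:
    """Phased hard calls from posterior haploid dosages.

    Per-haplotype allele is 1 when its posterior exceeds 0.5 (exact ties go to
    the reference allele); the genotype is the sum of the two alleles.
    """
    if result.hap_dosages is None:
        raise ValueError("best_guess requires haploid dosages")
    alleles = (result.hap_dosages > 0.5).astype(np.int8)
    n = result.n_samples
    phase = np.stack([alleles[0::2], alleles[1::2]], axis=2)
    calls = phase.sum(axis=2).astype(np.int8)
    return GenotypeDataset(
        calls=calls,
        variants=result.variants.copy(),
        sample_ids=list(result.sample_ids),
        phase=phase,
        array_labels=result.array_labels.copy(),
    )


# ---------------------------------------------------------------------------
# heuristic phasing fallback


def _phase_homozygous(ds: GenotypeDataset) -> GenotypeDataset:
    phase = np.full((*ds.calls.shape, 2), MISSING, dtype=np.int8)
    hom = (ds.calls == 0) | (ds.calls == 2)
    phase[..., 0] = np.where(hom, ds.calls // 2, phase[..., 0])
    phase[..., 1] = np.where(hom, ds.calls // 2, phase[..., 1])
    out = GenotypeDataset(
        calls=ds.calls.copy(),
        variants=ds.variants.copy(),
        sample_ids=list(ds.sample_ids),
        phase=phase,
        array_labels=ds.array_labels.copy(),
    )
    return out


def _viterbi_path(obs: np.ndarray, ref: np.ndarray, rho: float, eps: float) -> np.ndarray:
    """Most likely copying path for one haplotype (log-space Viterbi)."""
    H, M = ref.shape
    log_stay = np.log((1.0 - rho) + rho / H)
    log_switch = np.log(rho / H)
    delta = np.full(H, -np.log(H))
    delta += _log_emit(obs[0], ref[:, 0], eps)
    back = np.zeros((M, H), dtype=np.int32)
    for m in range(1, M):
        stay = delta + log_stay
        jump = delta.max() + log_switch
        best_prev = int(np.argmax(delta))
        take_stay = stay >= jump
        nd = np.where(take_stay, stay, jump)
        back[m] = np.where(take_stay, np.arange(H), best_prev)
        delta = nd + _log_emit(obs[m], ref[:, m], eps)
    path = np.empty(M, dtype=np.int32)
    path[M - 1] = int(np.argmax(delta))
    for m in range(M - 1, 0, -1):
        path[m - 1] = back[m, path[m]]
    return path


def _log_emit(o: int, ref_col: np.ndarray, eps: float) -> np.ndarray:
    if o == _UNOBSERVED:
        return np.zeros(ref_col.shape)
    return np.where(ref_col == o, np.log(1.0 - eps), np.log(max(eps, 1e-300)))


def phase_by_viterbi(
    target: GenotypeDataset, ref_panel: HaplotypePanel, params: HmmParams | None = None
) -> GenotypeDataset:
    """Heuristic phasing of hard calls against a reference panel.

    For each sample, the first haplotype's copying path is decoded by Viterbi
    using homozygous sites only; heterozygote orientation is then taken from
    the copied allele, the second haplotype receiving the complement. This is
    a labelled heuristic, not a statistical phaser: switch-error rates are
    untuned and it exists so that unphased hard-call input remains usable.
    """
    p = params or HmmParams()
    tkeys = variant_keys(target.variants)
    rkeys = variant_keys(ref_panel.variants)
    col = rkeys.get_indexer(tkeys)
    if (col < 0).any():
        raise ValueError("typed sites missing from the reference panel; align first")
    N, Mt = target.calls.shape
    phase = np.full((N, Mt, 2), MISSING, dtype=np.int8)
    for i in range(N):
        calls = target.calls[i]
        obs_full = np.full(ref_panel.n_variants, _UNOBSERVED, dtype=np.int8)
        hom = (calls == 0) | (calls == 2)
        obs_full[col[hom]] = (calls[hom] // 2).astype(np.int8)
        path = _viterbi_path(obs_full, ref_panel.haplotypes, p.switch_prob, p.error_prob)
        copied = ref_panel.haplotypes[path, np.arange(ref_panel.n_variants)][col]
        het = calls == 1
        phase[i, hom, 0] = (calls[hom] // 2).astype(np.int8)
        phase[i, hom, 1] = (calls[hom] // 2).astype(np.int8)
        phase[i, het, 0] = copied[het]
        phase[i, het, 1] = (1 - copied[het]).astype(np.int8)
    return GenotypeDataset(
        calls=target.calls.copy(),
        variants=target.variants.copy(),
        sample_ids=list(target.sample_ids),
        phase=phase,
        array_labels=target.array_labels.copy(),
    )
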