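"""Workflow orchestration: two-step, conventional, and overlap-only imputation.

The two-step mode is the core algorithm. Every array's QC'd genotypes are
imputed pairwise against each other array's haplotypes (K arrays -> K*(K-1)
imputed datasets). Per array, a variant qualifies when it is directly typed
(quality 1) or cross-imputed from at least one other array with estimated
R^2 >= r2_min (default 0.9); the *intermediate panel* is the intersection of
the per-array qualifying sets, with each variant's genotypes taken from the
best-quality source as phased best-guess hard calls. The intermediate panels -
now one identical variant list for every array - are then imputed against the
common external reference panel with no further quality filtering. Because all
arrays enter the final imputation with the same variant set drawn from the
same underlying population, array-specific dosage-shrinkage patterns (the
batch effect) cancel.

Comparators: ``conventional`` imputes each array directly against the common
panel; ``overlap`` first restricts every array to the variants typed on all
arrays (which removes the batch effect but discards most tag SNVs and hence
most imputation quality).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    DosageDataset,
    GenotypeDataset,
    HaplotypePanel,
    variant_keys,
)
from .genotype_io import merge_samples
from .impute import HmmParams, best_guess, impute_dataset
from .qc import QcThresholds, sample_call_rate_filter, variant_qc


def as_reference_panel(ds: GenotypeDataset, name: str) -> HaplotypePanel:
    """Use a phased genotype dataset as a haplotype reference panel.

    Reference haplotypes must be complete; residual missing alleles are filled
    deterministically with the major allele (datasets here carry ~1%
    missingness at most, so the distortion is negligible and reproducible).
    """
    haps = ds.haplotypes().astype(np.int8)
    if (haps == MISSING).any():
        af = ds.allele_freq()
        fill = (np.nan_to_num(af, nan=0.0) >= 0.5).astype(np.int8)
        haps = np.where(haps == MISSING, np.broadcast_to(fill, haps.shape), haps)
    return HaplotypePanel(haps, ds.variants.copy(), sample_ids=list(ds.sample_ids), name=name)


def pairwise_impute(
    array_datasets: dict[str, GenotypeDataset],
    params: HmmParams | None = None,
) -> dict[tuple[str, str], DosageDataset]:
    """Impute every array against every other array's haplotypes.

    For each ordered pair (target, source) of distinct arrays, the target is
    restricted to the sites present on the source and imputed at all source
    sites; K arrays yield exactly K*(K-1) results keyed (target, source).
    """
    names = sorted(array_datasets)
    if len(names) < 2:
        raise ValueError("pairwise imputation needs at least two arrays")
    out: dict[tuple[str, str], DosageDataset] = {}
    panels = {s: as_reference_panel(array_datasets[s], name=s) for s in names}
    for t, s in itertools.permutations(names, 2):
        target = array_datasets[t]
        tkeys = variant_keys(target.variants)
        skeys = variant_keys(panels[s].variants)
        shared = tkeys.get_indexer_for(tkeys.intersection(skeys))
        restricted = target.subset_variants(np.sort(shared))
        out[(t, s)] = impute_dataset(restricted, panels[s], params)
    return out


@dataclass
class IntermediatePanel:
    """Per-array phased hard calls over one shared high-confidence variant set."""

    datasets: dict[str, GenotypeDataset]
    source_tag: dict[str, np.ndarray]
    rsq: dict[str, np.ndarray]
    variants: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        names = sorted(self.datasets)
        base = self.datasets[names[0]].variants[["chrom", "pos", "ref", "alt"]]
        for nm in names[1:]:
            if not self.datasets[nm].variants[["chrom", "pos", "ref", "alt"]].equals(base):
                raise ValueError("intermediate panels must share one variant list")
        if self.variants.empty:
            self.variants = self.datasets[names[0]].variants.copy()


def build_intermediate_panels(
    pairwise_set: dict[tuple[str, str], DosageDataset],
    array_datasets: dict[str, GenotypeDataset],
    r2_min: float = 0.9,
    strict: bool = False,
) -> IntermediatePanel:
    """Merge pairwise imputations into per-array intermediate panels.

    Per array, a variant qualifies if directly typed (quality 1, tag
    ``typed``) or, in the default lenient reading, imputed from *some* source
    with estimated R^2 >= ``r2_min``; with ``strict=True`` every source panel
    carrying the variant must pass. The shared set is the intersection of the
    per-array qualifying sets, so all output panels list identical variants.
    Genotypes come from the winning source (typed beats imputed; ties on R^2
    go to the lexicographically smallest source name) as phased hard calls.
    """
    if not 0.0 <= r2_min <= 1.0:
        raise ValueError("r2_min must lie in [0, 1]")
    names = sorted(array_datasets)
    per_array_qual: dict[str, pd.Index] = {}
    per_array_best: dict[str, dict] = {}
    for t in names:
        typed_keys = variant_keys(array_datasets[t].variants)
        best: dict[tuple, tuple[float, str]] = {k: (1.0, "typed") for k in typed_keys}
        seen: dict[tuple, list[float]] = {}
        for s in names:
            if s == t:
                continue
            res = pairwise_set[(t, s)]
            keys = variant_keys(res.variants)
            for k, r2 in zip(keys, res.rsq):
                seen.setdefault(k, []).append(r2)
                cur = best.get(k)
                if cur is not None and cur[1] == "typed":
                    continue  # direct observations always win
                if cur is None or r2 > cur[0] or (r2 == cur[0] and s < cur[1]):
                    best[k] = (float(r2), s)
        if strict:
            qual = {
                k
                for k, (r2, src) in best.items()
                if src == "typed" or all(v >= r2_min for v in seen.get(k, [0.0]))
            }
        else:
            qual = {k for k, (r2, src) in best.items() if src == "typed" or r2 >= r2_min}
        per_array_qual[t] = pd.Index(sorted(qual))
        per_array_best[t] = best

    shared = per_array_qual[names[0]]
    for t in names[1:]:
        shared = shared.intersection(per_array_qual[t])
    if len(shared) == 0:
        raise ValueError(
            "no variant qualifies on every array; lower r2_min or check inputs"
        )
    shared = sorted(shared)

    datasets: dict[str, GenotypeDataset] = {}
    tags: dict[str, np.ndarray] = {}
    rsqs: dict[str, np.ndarray] = {}
    for t in names:
        best = per_array_best[t]
        tag = np.array([best[k][1] for k in shared], dtype=object)
        r2 = np.array([best[k][0] for k in shared], dtype=float)
        n = array_datasets[t].n_samples
        calls = np.empty((n, len(shared)), dtype=np.int8)
        phase = np.empty((n, len(shared), 2), dtype=np.int8)
        # gather typed columns from the QC'd array data
        tkeys = variant_keys(array_datasets[t].variants)
        typed_cols = {k: j for j, k in enumerate(tkeys)}
        hard: dict[str, GenotypeDataset] = {}
        src_keys: dict[str, pd.Index] = {}
        for s in names:
            if s == t:
                continue
            hard[s] = best_guess(pairwise_set[(t, s)])
            src_keys[s] = variant_keys(hard[s].variants)
        for j, k in enumerate(shared):
            src = tag[j]
            if src == "typed":
                col = typed_cols[k]
                calls[:, j] = array_datasets[t].calls[:, col]
                phase[:, j, :] = array_datasets[t].phase[:, col, :]
            else:
                col = src_keys[src].get_loc(k)
                calls[:, j] = hard[src].calls[:, col]
                phase[:, j, :] = hard[src].phase[:, col, :]
        variants = pd.DataFrame(shared, columns=["chrom", "pos", "ref", "alt"])
        base = array_datasets[t].variants
        if "id" in base.columns:
            idmap = dict(zip(variant_keys(base), base["id"]))
            variants["id"] = [idmap.get(k, f"{k[0]}:{k[1]}:{k[2]}:{k[3]}") for k in shared]
        datasets[t] = GenotypeDataset(
            calls=calls,
            variants=variants,
            sample_ids=list(array_datasets[t].sample_ids),
            phase=phase,
            array_labels=array_datasets[t].array_labels.copy(),
        )
        tags[t] = tag
        rsqs[t] = r2
    return IntermediatePanel(datasets=datasets, source_tag=tags, rsq=rsqs)


def second_step_impute(
    intermediate: IntermediatePanel,
    common_ref: HaplotypePanel,
    params: HmmParams | None = None,
) -> dict[str, DosageDataset]:
    """Impute each intermediate panel against the common reference panel.

    No quality filter is applied to the output of this stage.
    """
    out = {}
    for name, ds in intermediate.datasets.items():
        out[name] = impute_dataset(ds, common_ref, params)
    return out


def conventional_impute(
    array_datasets: dict[str, GenotypeDataset],
    common_ref: HaplotypePanel,
    params: HmmParams | None = None,
) -> dict[str, DosageDataset]:
    """Single-step imputation of each array directly against the common panel."""
    out = {}
    rkeys = variant_keys(common_ref.variants)
    for name, ds in array_datasets.items():
        tkeys = variant_keys(ds.variants)
        keep = np.flatnonzero(rkeys.get_indexer(tkeys) >= 0)
        out[name] = impute_dataset(ds.subset_variants(keep), common_ref, params)
    return out


def overlap_only_impute(
    array_datasets: dict[str, GenotypeDataset],
    common_ref: HaplotypePanel,
    params: HmmParams | None = None,
) -> dict[str, DosageDataset]:
    """Restrict every array to the variants typed on all arrays, then impute."""
    names = sorted(array_datasets)
    if len(names) < 2:
        raise ValueError("overlap-only mode needs at least two arrays")
    shared = variant_keys(array_datasets[names[0]].variants)
    for nm in names[1:]:
        shared = shared.intersection(variant_keys(array_datasets[nm].variants))
    if len(shared) == 0:
        raise ValueError("array designs share no variants")
    restricted = {}
    for nm in names:
        keys = variant_keys(array_datasets[nm].variants)
        idx = np.sort(keys.get_indexer_for(shared.intersection(keys)))
        restricted[nm] = array_datasets[nm].subset_variants(idx)
    return conventional_impute(restricted, common_ref, params)


@dataclass
class WorkflowResult:
    """Everything one workflow mode produced, plus per-stage reports."""

    mode: str
    combined: DosageDataset
    per_array: dict[str, DosageDataset]
    intermediate: IntermediatePanel | None
    reports: dict


def run_workflow(
    mode: str,
    array_datasets: dict[str, GenotypeDataset],
    common_ref: HaplotypePanel,
    params: HmmParams | None = None,
    thresholds: QcThresholds | None = None,
    r2_min: float = 0.9,
    strict_overlap: bool = False,
    apply_qc: bool = True,
) -> WorkflowResult:
    """QC the array datasets, run one imputation mode, and merge the outputs.

    Modes: ``twostep`` (pairwise -> intermediate panel -> common panel),
    ``conventional`` (per-array single step), ``overlap`` (typed-intersection
    single step). The combined dataset is the sample-wise merge over the
    variant intersection. Fully deterministic: the engine has no RNG.
    """
    if mode not in ("twostep", "conventional", "overlap"):
        raise ValueError("mode must be twostep|conventional|overlap")
    th = thresholds or QcThresholds()
    reports: dict = {"mode": mode, "qc": {}, "stages": {}}
    clean: dict[str, GenotypeDataset] = {}
    for name, ds in array_datasets.items():
        if apply_qc:
            ds1, srep = sample_call_rate_filter(ds, th.min_sample_call_rate)
            ds2, vrep = variant_qc(ds1, th)
            reports["qc"][name] = {
                "samples_removed": srep.counts["samples_removed"],
                **vrep.counts,
            }
            clean[name] = ds2
        else:
            clean[name] = ds
        reports["stages"][f"input_variants_{name}"] = clean[name].n_variants

    intermediate = None
    if mode == "twostep":
        if len(clean) < 2:
            raise ValueError("twostep mode needs at least two arrays")
        pw = pairwise_impute(clean, params)
        reports["stages"]["pairwise_imputations"] = len(pw)
        intermediate = build_intermediate_panels(pw, clean, r2_min=r2_min, strict=strict_overlap)
        reports["stages"]["intermediate_variants"] = len(intermediate.variants)
        per_array = second_step_impute(intermediate, common_ref, params)
    elif mode == "conventional":
        per_array = conventional_impute(clean, common_ref, params)
    else:
        per_array = overlap_only_impute(clean, common_ref, params)
        reports["stages"]["overlap_variants"] = per_array[sorted(per_array)[0]].typed.sum()

    for name, res in per_array.items():
        reports["stages"][f"output_variants_{name}"] = res.n_variants
    combined = merge_samples([per_array[k] for k in sorted(per_array)], mode="intersection")
    reports["stages"]["combined_variants"] = combined.n_variants
    reports["stages"]["combined_samples"] = combined.n_samples
    return WorkflowResult(
        mode=mode,
        combined=combined,
        per_array=per_array,
        intermediate=intermediate,
        reports=reports,
    )
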