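"""Shared in-memory containers for haplotype panels, genotype and dosage datasets.

Conventions
-----------
* Coordinates: VCF positions are 1-based; all internal indices are 0-based.
* Genotype hard calls are ``int8`` with values ``{0, 1, 2}`` and ``-1`` for missing.
* Phase is stored as an ``(N, M, 2)`` array of per-haplotype alleles in ``{0, 1}``
  (``-1`` missing); where present, the two alleles sum to the hard call.
* Variant metadata is a :class:`pandas.DataFrame` with columns
  ``chrom, pos, ref, alt`` (and optionally ``id``, ``af``), sorted by
  ``(chrom, pos, ref, alt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


def variant_frame(
    chrom, pos, ref, alt, ids=None, af=None
) -> pd.DataFrame:
    """Assemble a canonical variant metadata frame."""
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "alt": np.asarray(alt, dtype=object),
        }
    )
    if ids is not None:
        df["id"] = np.asarray(ids, dtype=object)
    if af is not None:
        df["af"] = np.asarray(af, dtype=float)
    return df


def variant_keys(variants: pd.DataFrame) -> pd.Index:
    """Index of (chrom, pos, ref, alt) tuples, usable for set operations."""
    return pd.MultiIndex.from_frame(variants[VARIANT_KEY])


def _check_variants(variants: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_KEY if c not in variants.columns]
    if missing:
        raise ValueError(f"variant metadata lacks columns {missing}")
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on contig {chrom}")


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix with variant metadata.

    ``haplotypes`` is ``(H, M)`` with alleles in {0, 1}; haplotypes come in
    consecutive pairs per sample when ``sample_ids`` is given (H = 2 * samples).
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    sample_ids: Optional[list[str]] = None
    name: str = "panel"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        _check_variants(self.variants)
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype width does not match variant count")
        if self.sample_ids is not None and 2 * len(self.sample_ids) != self.n_haplotypes:
            raise ValueError("sample-paired panel requires H = 2 * n_samples")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant."""
        return self.haplotypes.mean(axis=0)

    def subset_variants(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        return HaplotypePanel(
            self.haplotypes[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            sample_ids=self.sample_ids,
            name=self.name,
        )

    def to_genotypes(self, array_label: str = "panel") -> "GenotypeDataset":
        """Collapse haplotype pairs into a phased genotype dataset."""
        if self.sample_ids is None:
            raise ValueError("panel is not sample-paired")
        h = self.haplotypes.reshape(len(self.sample_ids), 2, self.n_variants)
        phase = np.moveaxis(h, 1, 2)  # (N, M, 2)
        calls = h.sum(axis=1).astype(np.int8)
        return GenotypeDataset(
            calls=calls,
            variants=self.variants.copy(),
            sample_ids=list(self.sample_ids),
            phase=phase.astype(np.int8),
            array_labels=np.repeat(array_label, len(self.sample_ids)),
        )


@dataclass
class GenotypeDataset:
    """Hard-call genotypes (optionally phased) for one or more arrays."""

    calls: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]
    phase: Optional[np.ndarray] = None
    array_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        if not np.isin(self.calls, (MISSING, 0, 1, 2)).all():
            raise ValueError("calls must be in {0,1,2} or -1 (missing)")
        _check_variants(self.variants)
        n, m = self.calls.shape
        if m != len(self.variants):
            raise ValueError("call width does not match variant count")
        if n != len(self.sample_ids):
            raise ValueError("call height does not match sample count")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.int8)
            if self.phase.shape != (n, m, 2):
                raise ValueError("phase must have shape (N, M, 2)")
            obs = self.calls != MISSING
            ok = self.phase.sum(axis=2)[obs] == self.calls[obs]
            phased = (self.phase[..., 0] != MISSING)[obs]
            if not ok[phased].all():
                raise ValueError("phase alleles must sum to the hard call")
        if self.array_labels is None:
            self.array_labels = np.repeat("array0", n)
        else:
            self.array_labels = np.asarray(self.array_labels, dtype=object)
            if self.array_labels.shape[0] != n:
                raise ValueError("array_labels length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            num = np.where(obs, self.calls, 0).sum(axis=0).astype(float)
            den = 2.0 * obs.sum(axis=0)
            return np.divide(num, den, out=np.full(self.n_variants, np.nan), where=den > 0)

    def maf(self) -> np.ndarray:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)

    def is_phased(self) -> bool:
        if self.phase is None:
            return False
        het = self.calls == 1
        return bool((self.phase[..., 0][het] != MISSING).all())

    def haplotypes(self) -> np.ndarray:
        """``(2N, M)`` haplotype matrix, -1 where missing/unphased."""
        if self.phase is None:
            raise ValueError("dataset carries no phase information")
        return np.moveaxis(self.phase, 2, 1).reshape(2 * self.n_samples, self.n_variants)

    def to_panel(self, name: str = "panel") -> HaplotypePanel:
        haps = self.haplotypes()
        if (haps == MISSING).any():
            raise ValueError("panel conversion requires fully observed, phased data")
        return HaplotypePanel(haps, self.variants.copy(), sample_ids=list(self.sample_ids), name=name)

    def subset_variants(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            calls=self.calls[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            phase=None if self.phase is None else self.phase[:, index, :],
            array_labels=self.array_labels.copy(),
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            calls=self.calls[index],
            variants=self.variants.copy(),
            sample_ids=[self.sample_ids[i] for i in index],
            phase=None if self.phase is None else self.phase[index],
            array_labels=self.array_labels[index],
        )


@dataclass
class DosageDataset:
    """Expected alt-allele dosages with per-variant imputation metadata."""

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]
    rsq: np.ndarray
    af: np.ndarray
    typed: np.ndarray
    hap_dosages: Optional[np.ndarray] = None
    source_tag: Optional[np.ndarray] = None
    array_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if self.dosages.min(initial=0.0) < -1e-9 or self.dosages.max(initial=0.0) > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        _check_variants(self.variants)
        if m != len(self.variants) or n != len(self.sample_ids):
            raise ValueError("dosage matrix shape does not match metadata")
        self.rsq = np.asarray(self.rsq, dtype=float)
        self.af = np.asarray(self.af, dtype=float)
        self.typed = np.asarray(self.typed, dtype=bool)
        for arr, nm in ((self.rsq, "rsq"), (self.af, "af"), (self.typed, "typed")):
            if arr.shape != (m,):
                raise ValueError(f"{nm} must be per-variant (length {m})")
        if ((self.rsq < -1e-9) | (self.rsq > 1 + 1e-9)).any():
            raise ValueError("rsq must lie in [0, 1]")
        if self.hap_dosages is not None:
            self.hap_dosages = np.asarray(self.hap_dosages, dtype=float)
            if self.hap_dosages.shape != (2 * n, m):
                raise ValueError("hap_dosages must have shape (2N, M)")
        if self.source_tag is None:
            self.source_tag = np.repeat("", m).astype(object)
        else:
            self.source_tag = np.asarray(self.source_tag, dtype=object)
        if self.array_labels is None:
            self.array_labels = np.repeat("array0", n)
        else:
            self.array_labels = np.asarray(self.array_labels, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        return np.minimum(self.af, 1.0 - self.af)

    def subset_samples(self, index: np.ndarray) -> "DosageDataset":
        index = np.asarray(index)
        hap_index = np.column_stack([2 * index, 2 * index + 1]).ravel()
        return DosageDataset(
            dosages=self.dosages[index],
            variants=self.variants.copy(),
            sample_ids=[self.sample_ids[i] for i in index],
            rsq=self.rsq.copy(),
            af=self.af.copy(),
            typed=self.typed.copy(),
            hap_dosages=None if self.hap_dosages is None else self.hap_dosages[hap_index],
            source_tag=self.source_tag.copy(),
            array_labels=self.array_labels[index],
        )

    def subset_variants(self, index: np.ndarray) -> "DosageDataset":
        index = np.asarray(index)
        return DosageDataset(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            rsq=self.rsq[index],
            af=self.af[index],
            typed=self.typed[index],
            hap_dosages=None if self.hap_dosages is None else self.hap_dosages[:, index],
            source_tag=self.source_tag[index],
            array_labels=self.array_labels.copy(),
        )


@dataclass
class ArrayDesign:
    """A named SNV subset standing in for a commercial genotyping array."""

    name: str
    variant_index: np.ndarray
    density: float
    maf_bias: float

    def __post_init__(self) -> None:
        self.variant_index = np.asarray(self.variant_index, dtype=np.int64)
        if len(np.unique(self.variant_index)) != len(self.variant_index):
            raise ValueError("design indices must be unique")
        if np.any(np.diff(self.variant_index) < 0):
            raise ValueError("design indices must be sorted")

    @property
    def n_variants(self) -> int:
        return len(self.variant_index)


@dataclass
class SimConfig:
    """Knobs for the synthetic multi-array scenario generator."""

    n_founders: int = 50
    n_variants: int = 2000
    n_samples_per_array: int = 100
    recomb_prob: float = 0.02
    mutation_prob: float = 0.001
    missing_rate: float = 0.01
    genotype_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("recomb_prob", "mutation_prob", "missing_rate", "genotype_error_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        for nm in ("n_founders", "n_variants", "n_samples_per_array"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be >= 1")
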