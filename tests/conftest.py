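"""Shared fixtures: tiny hand-built datasets and the reference synthetic world."""

import numpy as np
import pandas as pd
import pytest

import tsimpute as ts
from tsimpute.datatypes import variant_frame


def make_genotypes(calls, phased=True, labels=None, chrom="1", pos=None, prefix="s"):
    """Hand-rolled genotype dataset from a small 0/1/2/-1 matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pos = np.arange(1, m + 1) * 10 if pos is None else np.asarray(pos)
    variants = variant_frame(
        np.repeat(chrom, m), pos, np.repeat("A", m), np.repeat("G", m),
        ids=[f"v{j}" for j in range(m)],
    )
    phase = None
    if phased:
        phase = np.full((n, m, 2), -1, dtype=np.int8)
        hom = (calls == 0) | (calls == 2)
        het = calls == 1
        phase[..., 0][hom] = calls[hom] // 2
        phase[..., 1][hom] = calls[hom] // 2
        phase[..., 0][het] = 0
        phase[..., 1][het] = 1
    return ts.GenotypeDataset(
        calls=calls,
        variants=variants,
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        phase=phase,
        array_labels=None if labels is None else np.asarray(labels, dtype=object),
    )


@pytest.fixture(scope="session")
def toy_multiarray():
    """A small 5-array world for workflow counting laws (fast)."""
    founders = ts.simulate_founders(15, 300, seed=11)
    cohort = ts.simulate_cohort(founders, 100, recomb_prob=0.02, seed=12)
    maf = np.minimum(cohort.allele_freq(), 1 - cohort.allele_freq())
    designs = [
        ts.design_array(cohort.variants, density=d, maf_bias=b, seed=13 + i,
                        name=f"a{i}", universe_maf=maf)
        for i, (d, b) in enumerate(zip((0.3, 0.4, 0.5, 0.6, 0.7), (0, 0.5, 1, 1.5, 2)))
    ]
    blocks = np.array_split(np.arange(100), 5)
    arrays = {
        d.name: ts.genotype_on_array(cohort, d, missing_rate=0.0, error_rate=0.0,
                                     seed=20 + i, sample_index=blocks[i])
        for i, d in enumerate(designs)
    }
    ref = ts.simulate_cohort(founders, 40, recomb_prob=0.02, seed=30, sample_prefix="r")
    ref.name = "ref"
    return {"cohort": cohort, "arrays": arrays, "ref": ref}


@pytest.fixture(scope="session")
def default_world():
    """The reference batch-effect scenario plus all three workflow runs.

    This is the expensive shared state behind the end-to-end acceptance tests;
    built once per session (roughly 20 s).
    """
    scen = ts.default_scenario(seed=0)
    runs = {
        mode: ts.run_workflow(mode, scen.array_datasets, scen.reference_panel)
        for mode in ("conventional", "twostep", "overlap")
    }
    return {"scenario": scen, "runs": runs}
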