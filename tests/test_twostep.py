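"""Workflow orchestration: counting laws, merge semantics, mode equivalences."""

import numpy as np
import pytest

import tsimpute as ts
from tsimpute.datatypes import variant_frame
from tsimpute.twostep import as_reference_panel

from conftest import make_genotypes


def tiny_arrays(k=2, n_samples=8, m=80, densities=None, seed=0):
    founders = ts.simulate_founders(8, m, seed=seed)
    cohort = ts.simulate_cohort(founders, k * n_samples, recomb_prob=0.03, seed=seed + 1)
    maf = np.minimum(cohort.allele_freq(), 1 - cohort.allele_freq())
    densities = densities or [0.5] * k
    arrays = {}
    for i in range(k):
        d = ts.design_array(cohort.variants, densities[i], 0.0, seed=seed + 2 + i,
                            name=f"a{i}", universe_maf=maf)
        block = np.arange(i * n_samples, (i + 1) * n_samples)
        arrays[f"a{i}"] = ts.genotype_on_array(cohort, d, 0.0, 0.0, seed=seed + 10 + i,
                                               sample_index=block)
    ref = ts.simulate_cohort(founders, 20, recomb_prob=0.03, seed=seed + 30, sample_prefix="r")
    ref.name = "ref"
    return cohort, arrays, ref


class TestPairwiseImpute:
    def test_two_arrays_give_two_results(self):
        _, arrays, _ = tiny_arrays(k=2)
        pw = ts.pairwise_impute(arrays)
        assert set(pw) == {("a0", "a1"), ("a1", "a0")}

    def test_five_arrays_give_twenty_results(self, toy_multiarray):
        pw = ts.pairwise_impute(toy_multiarray["arrays"])
        assert len(pw) == 5 * 4

    def test_identical_designs_reproduce_inputs(self):
        founders = ts.simulate_founders(6, 40, seed=3)
        cohort = ts.simulate_cohort(founders, 12, seed=4)
        maf = np.minimum(cohort.allele_freq(), 1 - cohort.allele_freq())
        d = ts.design_array(cohort.variants, 0.5, 0.0, seed=5, universe_maf=maf)
        arrays = {
            "x": ts.genotype_on_array(cohort, d, 0.0, 0.0, seed=6, sample_index=np.arange(6)),
            "y": ts.genotype_on_array(cohort, d, 0.0, 0.0, seed=7, sample_index=np.arange(6, 12)),
        }
        pw = ts.pairwise_impute(arrays)
        for (t, s), res in pw.items():
            assert res.typed.all()
            np.testing.assert_allclose(res.dosages, arrays[t].calls.astype(float), atol=1e-12)

    def test_single_array_rejected(self):
        _, arrays, _ = tiny_arrays(k=2)
        with pytest.raises(ValueError):
            ts.pairwise_impute({"a0": arrays["a0"]})


class TestIntermediatePanels:
    def test_typed_everywhere_tagged_typed(self):
        _, arrays, _ = tiny_arrays(k=2, densities=[1.0, 1.0])
        pw = ts.pairwise_impute(arrays)
        panel = ts.build_intermediate_panels(pw, arrays, r2_min=0.9)
        for t in arrays:
            assert (panel.source_tag[t] == "typed").all()
            assert (panel.rsq[t] == 1.0).all()

    def test_shared_variant_list_identical(self):
        _, arrays, _ = tiny_arrays(k=3, densities=[0.4, 0.6, 0.8])
        pw = ts.pairwise_impute(arrays)
        panel = ts.build_intermediate_panels(pw, arrays, r2_min=0.5)
        lists = [panel.datasets[t].variants[["chrom", "pos", "ref", "alt"]] for t in arrays]
        assert all(l.equals(lists[0]) for l in lists[1:])

    def test_below_threshold_excluded_for_all_arrays(self):
        _, arrays, _ = tiny_arrays(k=2, densities=[0.3, 0.9], seed=5)
        pw = ts.pairwise_impute(arrays)
        # a variant only typed on a1 whose best imputation into a0 is < r2_min
        # must be excluded from the shared set entirely
        panel = ts.build_intermediate_panels(pw, arrays, r2_min=0.9)
        res = pw[("a0", "a1")]
        from tsimpute.datatypes import variant_keys

        a0_typed = set(variant_keys(arrays["a0"].variants))
        weak = [
            k for k, r2, typ in zip(variant_keys(res.variants), res.rsq, res.typed)
            if r2 < 0.9 and k not in a0_typed
        ]
        shared = set(variant_keys(panel.variants))
        assert weak, "fixture should contain weakly imputed variants"
        assert not (set(weak) & shared)

    def test_tie_breaks_to_lexicographically_smaller_source(self):
        # identical designs and samples in sources b and c give equal quality
        founders = ts.simulate_founders(6, 30, seed=8)
        cohort = ts.simulate_cohort(founders, 18, seed=9)
        maf = np.minimum(cohort.allele_freq(), 1 - cohort.allele_freq())
        d = ts.design_array(cohort.variants, 1.0, 0.0, seed=10, universe_maf=maf)
        sub = ts.design_array(cohort.variants, 0.4, 0.0, seed=11, universe_maf=maf)
        arrays = {
            "a": ts.genotype_on_array(cohort, sub, 0.0, 0.0, seed=12, sample_index=np.arange(6)),
            "b": ts.genotype_on_array(cohort, d, 0.0, 0.0, seed=13, sample_index=np.arange(6, 12)),
            "c": ts.genotype_on_array(cohort, d, 0.0, 0.0, seed=14, sample_index=np.arange(6, 12)),
        }
        arrays["c"].sample_ids = [f"c{i}" for i in range(6)]  # avoid duplicate ids
        pw = ts.pairwise_impute(arrays)
        # force exact ties by copying the b-sourced result onto c
        for t in ("a", "b"):
            if ("a", "c") in pw and t == "a":
                pw[("a", "c")] = pw[("a", "b")]
        panel = ts.build_intermediate_panels(pw, arrays, r2_min=0.0)
        tags = panel.source_tag["a"]
        imputed = tags != "typed"
        assert set(tags[imputed]) <= {"b"}

    def test_r2min_monotonicity_and_strict_mode(self):
        _, arrays, _ = tiny_arrays(k=3, densities=[0.4, 0.6, 0.8], seed=2)
        pw = ts.pairwise_impute(arrays)
        sizes = {}
        for r2_min in (0.8, 0.9):
            panel = ts.build_intermediate_panels(pw, arrays, r2_min=r2_min)
            sizes[r2_min] = len(panel.variants)
        assert sizes[0.9] <= sizes[0.8]
        lenient = ts.build_intermediate_panels(pw, arrays, r2_min=0.5)
        strict = ts.build_intermediate_panels(pw, arrays, r2_min=0.5, strict=True)
        assert len(strict.variants) <= len(lenient.variants)

    def test_empty_shared_set_raises(self):
        # disjoint designs: nothing is typed on both arrays, and with an
        # unreachable quality bar nothing qualifies by imputation either
        _, arrays, _ = tiny_arrays(k=2, densities=[0.9, 0.9], seed=7)
        from tsimpute.datatypes import variant_keys

        a0 = arrays["a0"].subset_variants(np.arange(30))
        k0 = set(variant_keys(a0.variants))
        keep = [j for j, k in enumerate(variant_keys(arrays["a1"].variants)) if k not in k0]
        disjoint = {"a0": a0, "a1": arrays["a1"].subset_variants(np.array(keep))}
        pw = ts.pairwise_impute(disjoint)
        with pytest.raises(ValueError, match="r2_min"):
            ts.build_intermediate_panels(pw, disjoint, r2_min=1.0)


class TestSecondStepAndComparators:
    def test_intermediate_equal_to_ref_sites_reproduced(self):
        _, arrays, ref = tiny_arrays(k=2, densities=[1.0, 1.0])
        pw = ts.pairwise_impute(arrays)
        panel = ts.build_intermediate_panels(pw, arrays, r2_min=0.9)
        out = ts.second_step_impute(panel, ref)
        for t, res in out.items():
            assert res.n_variants == ref.n_variants
            np.testing.assert_allclose(res.dosages, panel.datasets[t].calls.astype(float), atol=1e-12)

    def test_outputs_cover_reference_variants(self):
        _, arrays, ref = tiny_arrays(k=2, densities=[0.4, 0.7], seed=3)
        conv = ts.conventional_impute(arrays, ref)
        for res in conv.values():
            assert res.n_variants == ref.n_variants

    def test_conventional_per_array_independent(self):
        _, arrays, ref = tiny_arrays(k=2, densities=[0.4, 0.7], seed=4)
        solo = ts.conventional_impute({"a0": arrays["a0"]}, ref)["a0"]
        both = ts.conventional_impute(arrays, ref)["a0"]
        np.testing.assert_allclose(solo.dosages, both.dosages, atol=0)

    def test_overlap_identical_designs_equals_conventional(self):
        _, arrays, ref = tiny_arrays(k=2, densities=[1.0, 1.0], seed=5)
        ov = ts.overlap_only_impute(arrays, ref)
        conv = ts.conventional_impute(arrays, ref)
        for t in arrays:
            np.testing.assert_allclose(ov[t].dosages, conv[t].dosages, atol=0)

    def test_overlap_disjoint_designs_error(self):
        cohort, arrays, ref = tiny_arrays(k=2, densities=[0.5, 0.5], seed=6)
        a0, a1 = arrays["a0"], arrays["a1"]
        half = a0.n_variants // 2
        arrays2 = {"a0": a0.subset_variants(np.arange(half))}
        from tsimpute.datatypes import variant_keys

        k0 = set(variant_keys(arrays2["a0"].variants))
        keep = [j for j, k in enumerate(variant_keys(a1.variants)) if k not in k0]
        arrays2["a1"] = a1.subset_variants(np.array(keep))
        with pytest.raises(ValueError, match="no variants"):
            ts.overlap_only_impute(arrays2, ref)

    def test_overlap_nested_designs_reduce_to_smallest(self):
        cohort, _, ref = tiny_arrays(k=2, seed=8)
        full = cohort.to_genotypes()
        idx_a = np.arange(0, 30)
        idx_b = np.arange(0, 50)
        idx_c = np.arange(0, 70)
        arrays = {
            "a": full.subset_samples(np.arange(4)).subset_variants(idx_a),
            "b": full.subset_samples(np.arange(4, 8)).subset_variants(idx_b),
            "c": full.subset_samples(np.arange(8, 12)).subset_variants(idx_c),
        }
        out = ts.overlap_only_impute(arrays, ref)
        for res in out.values():
            assert res.typed.sum() == len(idx_a)


class TestRunWorkflow:
    def test_degenerate_equivalence_at_typed_sites(self):
        _, arrays, ref = tiny_arrays(k=2, densities=[1.0, 1.0], seed=9)
        outs = {
            mode: ts.run_workflow(mode, arrays, ref, apply_qc=False).combined
            for mode in ("twostep", "conventional", "overlap")
        }
        typed = outs["conventional"].typed
        for mode in ("twostep", "overlap"):
            np.testing.assert_allclose(
                outs[mode].dosages[:, typed], outs["conventional"].dosages[:, typed], atol=1e-12
            )

    def test_twostep_counts_and_reports(self):
        _, arrays, ref = tiny_arrays(k=2, densities=[0.6, 0.8], seed=10)
        res = ts.run_workflow("twostep", arrays, ref, r2_min=0.5)
        assert res.reports["stages"]["pairwise_imputations"] == 2
        assert res.combined.n_samples == sum(a.n_samples for a in arrays.values())

    def test_deterministic_outputs_byte_identical(self, tmp_path):
        _, arrays, ref = tiny_arrays(k=2, densities=[0.5, 0.8], seed=11)
        paths = []
        for i in range(2):
            res = ts.run_workflow("conventional", arrays, ref)
            p = tmp_path / f"run{i}.vcf"
            ts.write_vcf(res.combined, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_reference_panel_fill_is_deterministic(self):
        _, arrays, _ = tiny_arrays(k=2, seed=12)
        ds = arrays["a0"]
        ds.calls[0, 0] = -1
        ds.phase[0, 0] = -1
        p1 = as_reference_panel(ds, "x")
        p2 = as_reference_panel(ds, "x")
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        assert (p1.haplotypes >= 0).all()
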