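import numpy as np
import pytest

from sparseassoc.collapse import classify_maf
from sparseassoc.simulate import (
    LDBlockSpec,
    SimulationSpec,
    VariantSpec,
    default_panel_spec,
    gen_alt_phenotypes,
    gen_genotypes,
    gen_null_phenotypes,
    spec_partition,
)


class TestVariantSpecValidation:
    def test_maf_range(self):
        with pytest.raises(ValueError):
            VariantSpec(maf=0.0, subregion=1)

    def test_functional_effect_coupling(self):
        with pytest.raises(ValueError):
            VariantSpec(maf=0.01, subregion=1, functional=True, beta=0.0)
        with pytest.raises(ValueError):
            VariantSpec(maf=0.01, subregion=1, functional=False, beta=0.5)


class TestDefaultPanel:
    def setup_method(self):
        self.spec = default_panel_spec(seed=2027)

    def test_layout(self):
        v = self.spec.variants
        assert len(v) == 90
        part = spec_partition(self.spec)
        assert part.sizes() == [16, 22, 15, 24, 9, 4]
        assert sorted(x.position for x in v) == [x.position for x in v]

    def test_functional_counts_by_subregion(self):
        counts = [sum(x.functional for x in self.spec.variants if x.subregion == k) for k in range(1, 7)]
        assert counts == [4, 7, 0, 13, 0, 2]

    def test_maf_class_composition(self):
        cls = classify_maf(np.array([x.maf for x in self.spec.variants]))
        assert (cls == "rare").sum() == 81
        assert (cls == "low-frequency").sum() == 5
        assert (cls == "common").sum() == 4
        fcls = classify_maf(np.array([x.maf for x in self.spec.variants if x.functional]))
        assert (fcls == "rare").sum() == 22
        assert (fcls == "low-frequency").sum() == 2
        assert (fcls == "common").sum() == 2

    def test_effect_sizes_scale_with_rarity_and_alternate_sign(self):
        for k in range(1, 7):
            funcs = [x for x in self.spec.variants if x.subregion == k and x.functional]
            for x in funcs:
                assert abs(x.beta) == pytest.approx(0.75 * abs(np.log10(x.maf)))
            signs = [np.sign(x.beta) for x in funcs]
            assert all(signs[i] != signs[i + 1] for i in range(len(signs) - 1))

    def test_ld_block_is_tightly_clustered_equal_maf(self):
        idx = self.spec.ld_block.indices
        assert len(idx) == 4
        mafs = [self.spec.variants[i].maf for i in idx]
        assert mafs == [0.008] * 4
        pos = [self.spec.variants[i].position for i in idx]
        assert max(pos) - min(pos) <= 27


class TestGenotypes:
    def test_deterministic_given_seed(self):
        spec = default_panel_spec(seed=5)
        g1 = gen_genotypes(spec, seed=11).dosages
        g2 = gen_genotypes(spec, seed=11).dosages
        assert np.array_equal(g1, g2)
        assert not np.array_equal(g1, gen_genotypes(spec, seed=12).dosages)

    def test_marginal_mafs_near_spec(self):
        spec = default_panel_spec(seed=3)
        spec.n = 20000
        gm = gen_genotypes(spec, seed=1)
        emp = gm.dosages.mean(axis=0) / 2
        target = np.array([v.maf for v in spec.variants])
        common = target > 0.03
        np.testing.assert_allclose(emp[common], target[common], rtol=0.15)

    def test_ld_block_high_pairwise_r2(self):
        spec = default_panel_spec(seed=3)
        spec.n = 20000
        gm = gen_genotypes(spec, seed=1)
        idx = list(spec.ld_block.indices)
        R = np.corrcoef(gm.dosages[:, idx].T) ** 2
        off = R[~np.eye(4, dtype=bool)]
        assert np.all(off > 0.7)

    def test_infeasible_block_raises(self):
        variants = [
            VariantSpec(maf=0.001, subregion=1, position=10),
            VariantSpec(maf=0.05, subregion=1, position=20),
        ]
        spec = SimulationSpec(n=100, variants=variants, ld_block=LDBlockSpec((0, 1), 0.9), n_complete=None)
        with pytest.raises(ValueError, match="r\\^2"):
            gen_genotypes(spec, seed=1)


class TestNullPhenotypes:
    def test_exact_case_count_and_missingness(self):
        spec = default_panel_spec(seed=9)
        gm = gen_genotypes(spec)
        pt = gen_null_phenotypes(spec, gm, replicate_seed=4)
        assert int(np.isnan(pt.age).sum()) == spec.n - spec.n_complete
        n_obs = int((~np.isnan(pt.outcome)).sum())
        assert int(np.nansum(pt.outcome)) == round(0.178 * n_obs)

    def test_covariates_fixed_across_replicates(self):
        spec = default_panel_spec(seed=9)
        gm = gen_genotypes(spec)
        p1 = gen_null_phenotypes(spec, gm, replicate_seed=1)
        p2 = gen_null_phenotypes(spec, gm, replicate_seed=2)
        np.testing.assert_array_equal(p1.age, p2.age)
        np.testing.assert_array_equal(p1.sex, p2.sex)
        assert not np.array_equal(p1.outcome, p2.outcome)

    def test_outcome_correlates_with_age(self):
        spec = default_panel_spec(seed=9)
        gm = gen_genotypes(spec)
        pt = gen_null_phenotypes(spec, gm, replicate_seed=1)
        obs = ~np.isnan(pt.outcome) & ~np.isnan(pt.age)
        assert np.corrcoef(pt.age[obs], pt.outcome[obs])[0, 1] > 0.02


class TestAltPhenotypes:
    def test_prevalence_near_target(self):
        spec = default_panel_spec(seed=9)
        gm = gen_genotypes(spec)
        prevs = []
        for r in range(5):
            pt = gen_alt_phenotypes(spec, gm, replicate_seed=r)
            prevs.append(np.nanmean(pt.outcome))
        assert np.mean(prevs) == pytest.approx(0.178, abs=0.02)

    def test_functional_variants_shift_risk(self):
        spec = default_panel_spec(seed=9)
        gm = gen_genotypes(spec)
        pt = gen_alt_phenotypes(spec, gm, replicate_seed=1)
        betas = np.array([v.beta for v in spec.variants])
        burden = gm.dosages @ betas
        obs = ~np.isnan(pt.outcome)
        # carriers of risk burden should be enriched among cases
        assert np.mean(burden[obs][pt.outcome[obs] == 1]) > np.mean(burden[obs][pt.outcome[obs] == 0])

    def test_requires_functional_variants(self):
        variants = [VariantSpec(maf=0.1, subregion=1, position=5)]
        spec = SimulationSpec(n=200, variants=variants, n_complete=None)
        gm = gen_genotypes(spec, seed=1)
        with pytest.raises(ValueError, match="functional"):
            gen_alt_phenotypes(spec, gm, replicate_seed=1)
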