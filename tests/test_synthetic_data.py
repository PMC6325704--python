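"""The generators must realise the statistical structure they promise."""

import numpy as np
import pandas as pd
import pytest

from brachykit.core import MISSING
from brachykit.genotype_core import fixed_divergence, ibs_distance
from brachykit.synthetic_data import (
    ClimateSpec,
    PhenoSimSpec,
    PopulationSpec,
    default_subgenome_setup,
    gen_climate,
    gen_coverage,
    gen_genotypes,
    gen_phenotypes,
)


class TestGenotypes:
    def test_replicates_identical_without_divergence_or_missingness(self):
        spec = PopulationSpec(
            n_subgroups=1,
            n_families_per_subgroup=2,
            n_accessions_per_family=2,
            n_replicates_per_accession=3,
            within_family_divergence=0.0,
            missing_rate=0.0,
            n_snps=500,
            seed=1,
        )
        matrix, truth = gen_genotypes(spec)
        for _, grp in truth.groupby("accession"):
            idx = [matrix.samples.index(s) for s in grp["sample"]]
            assert np.all(matrix.calls[idx] == matrix.calls[idx[0]])

    def test_fixed_divergence_matches_generative_fraction(self):
        # 6.5% between-subgroup divergence, measured on a founder-faithful
        # panel; tolerance is 3 binomial SDs at 10,000 SNPs
        spec = PopulationSpec(
            fixed_divergence_between_subgroups=0.065,
            within_family_divergence=0.0,
            missing_rate=0.0,
            n_snps=10_000,
            seed=2,
        )
        matrix, truth = gen_genotypes(spec)
        groups = dict(zip(truth["sample"], truth["subgroup"]))
        est = fixed_divergence(matrix, groups)
        sd = np.sqrt(0.065 * 0.935 / 10_000)
        assert abs(est - 0.065) <= 3 * sd

    def test_missing_rate_within_binomial_error(self):
        spec = PopulationSpec(
            n_subgroups=1,
            n_families_per_subgroup=20,
            n_accessions_per_family=5,
            n_snps=5000,
            missing_rate=0.185,
            seed=3,
        )
        matrix, _ = gen_genotypes(spec)
        frac = np.mean(matrix.calls == MISSING)
        sd = np.sqrt(0.185 * 0.815 / matrix.calls.size)
        assert abs(frac - 0.185) <= 3 * sd

    def test_clone_kinship_exceeds_cross_subgroup_kinship(self, clonal_panel):
        matrix, truth = clonal_panel
        D = ibs_distance(matrix).values
        acc = truth.set_index("sample")["accession"]
        sub = truth.set_index("sample")["subgroup"]
        clone_d, cross_d = [], []
        for i, si in enumerate(matrix.samples):
            for j in range(i + 1, matrix.n_samples):
                sj = matrix.samples[j]
                if acc[si] == acc[sj]:
                    clone_d.append(D[i, j])
                elif sub[si] != sub[sj]:
                    cross_d.append(D[i, j])
        assert max(clone_d) < min(cross_d)

    def test_bit_reproducible_for_fixed_seed(self):
        a, _ = gen_genotypes(PopulationSpec(n_snps=800, seed=9))
        b, _ = gen_genotypes(PopulationSpec(n_snps=800, seed=9))
        c, _ = gen_genotypes(PopulationSpec(n_snps=800, seed=10))
        assert np.array_equal(a.calls, b.calls)
        assert not np.array_equal(a.calls, c.calls)

    def test_overcommitted_divergence_rejected(self):
        spec = PopulationSpec(n_subgroups=4, fixed_divergence_between_subgroups=0.6)
        with pytest.raises(ValueError, match="sum above 1"):
            spec.validate()


class TestCoverage:
    def test_pure_species_signatures_and_truth_labels(self):
        summaries, truth = gen_coverage(
            [("distachyon", 2), ("stacei", 2)], noise_sd=0.0, seed=0
        )
        submap, _ = default_subgenome_setup()
        d = summaries[0]
        on = [f for c, f in d.covered_fraction.items() if submap[c] == "distachyon"]
        off = [f for c, f in d.covered_fraction.items() if submap[c] == "stacei"]
        assert min(on) > 0.5 and max(off) < 0.01
        assert list(truth["species"]) == ["distachyon"] * 2 + ["stacei"] * 2

    def test_low_coverage_samples_fall_below_read_gate(self):
        summaries, _ = gen_coverage([("low_coverage", 3)], seed=1)
        assert all(s.total_reads < 100_000 for s in summaries)

    def test_unknown_species_label_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            gen_coverage([("sylvaticum", 1)])


class TestClimate:
    def test_constant_series_when_amplitudes_zero(self):
        series = gen_climate(
            ClimateSpec(diurnal_amplitude=0, seasonal_amplitude=0, mean_temp=22, n_days=2)
        )
        assert np.allclose(series["temp_C"], 22.0)
        assert len(series) == 2 * 1440 // 5

    def test_warming_offset_is_additive(self):
        base = gen_climate(ClimateSpec(n_days=3))
        warm = gen_climate(ClimateSpec(n_days=3, warming_offset=2.0))
        assert np.allclose(warm["temp_C"] - base["temp_C"], 2.0)

    def test_photoperiod_fraction_of_records(self):
        series = gen_climate(ClimateSpec(day_length_hours=12, cadence_minutes=5, n_days=4))
        assert np.mean(series["par"] > 0) == pytest.approx(0.5)

    def test_cadence_must_divide_day(self):
        with pytest.raises(ValueError, match="divide"):
            gen_climate(ClimateSpec(cadence_minutes=7))


@pytest.fixture(scope="module")
def panel():
    spec = PopulationSpec(
        n_subgroups=1,
        n_families_per_subgroup=50,
        n_accessions_per_family=1,
        within_family_divergence=0.0,
        n_snps=400,
        ld_block_size_snps=1,
        missing_rate=0.0,
        seed=21,
    )
    return gen_genotypes(spec)[0]


class TestPhenotypes:
    def test_no_genetics_means_no_between_genotype_variance(self, panel):
        spec = PhenoSimSpec(polygenic_h2=0.0, n_replicates=20, seed=1)
        traits, _ = gen_phenotypes(panel, spec, envs=("2015",))
        means = traits.groupby("sample")["value"].mean()
        # genotype means vary only through residual averaging: var ~ 1/20
        assert means.var() < 3 * (1.0 / 20)

    def test_single_qtl_anova_recovers_target_pve(self, panel):
        maf = panel.maf()
        locus = int(np.argmax(maf))
        spec = PhenoSimSpec(
            qtl_loci=[(locus, 0.62)], polygenic_h2=0.0, n_replicates=1, seed=2
        )
        traits, _ = gen_phenotypes(panel, spec, envs=("2015",))
        y = traits.set_index("sample")["value"].loc[panel.samples].to_numpy()
        z = panel.calls[:, locus]
        groups = [y[z == g] for g in (0, 2)]
        grand = y.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_total = ((y - grand) ** 2).sum()
        assert ss_between / ss_total == pytest.approx(0.62, abs=0.12)

    def test_environment_difference_variance_without_gxe(self, panel):
        n_reps = 4
        spec = PhenoSimSpec(polygenic_h2=0.3, n_replicates=n_reps, gxe_shift=0.0, seed=3)
        traits, _ = gen_phenotypes(panel, spec)
        means = traits.pivot_table(index="sample", columns="environment", values="value")
        diff = means["2050"] - means["2015"]
        resid_var = 1.0 - 0.3
        expected = 2 * resid_var / n_reps
        assert abs(diff.mean()) < 3 * np.sqrt(expected / len(diff))
        assert diff.var() == pytest.approx(expected, rel=0.5)

    def test_genotype_means_track_true_genetic_values_with_unit_slope(self, panel):
        maf = panel.maf()
        locus = int(np.argmax(maf))
        spec = PhenoSimSpec(
            qtl_loci=[(locus, 0.3)], polygenic_h2=0.4, n_replicates=10, seed=4
        )
        traits, truth = gen_phenotypes(panel, spec, envs=("2015",))
        means = traits.groupby("sample")["value"].mean()
        g = truth.set_index("sample")["genetic_value"].loc[means.index]
        slope = np.polyfit(g, means, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_monomorphic_qtl_rejected(self):
        from conftest import make_matrix

        tiny = make_matrix([[0, 0], [0, 2], [0, 0]])
        spec = PhenoSimSpec(qtl_loci=[(0, 0.3)], seed=5)
        with pytest.raises(ValueError, match="monomorphic"):
            gen_phenotypes(tiny, spec)

    def test_variance_budget_enforced(self, panel):
        spec = PhenoSimSpec(qtl_loci=[(0, 0.7)], polygenic_h2=0.5)
        with pytest.raises(ValueError, match="sum"):
            spec.validate()
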