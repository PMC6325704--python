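"""Mixed-model scan: kinship, LOD oracle equivalence, permutations, QTL."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from conftest import make_matrix

from brachykit.gwas_scan import (
    LmmScanner,
    call_qtl,
    gxe_response,
    kinship_ibs,
    permutation_threshold,
    pve_from_lod,
    variance_explained,
)
from brachykit.synthetic_data import (
    PhenoSimSpec,
    PopulationSpec,
    gen_genotypes,
    gen_phenotypes,
)


@pytest.fixture(scope="module")
def panel():
    spec = PopulationSpec(
        n_subgroups=1,
        n_families_per_subgroup=74,
        n_accessions_per_family=1,
        within_family_divergence=0.0,
        n_snps=600,
        n_chromosomes=2,
        ld_block_size_snps=1,
        missing_rate=0.0,
        seed=31,
    )
    return gen_genotypes(spec)[0]


class TestKinship:
    def test_clone_pair_is_one_divergent_pair_is_zero(self):
        rng = np.random.default_rng(0)
        proto = rng.integers(0, 2, 100) * 2
        m = make_matrix([list(proto), list(proto), list(2 - proto)])
        K = kinship_ibs(m)
        assert K[0, 1] == pytest.approx(1.0)
        assert K[0, 2] == pytest.approx(0.0)

    def test_loco_kinship_ignores_scanned_chromosome(self, panel):
        K_before = kinship_ibs(panel, exclude_chromosome="Bd1")
        perturbed = panel.copy()
        chr1 = np.flatnonzero(np.asarray(panel.chrom) == "Bd1")
        perturbed.calls[:, chr1] = 2 - perturbed.calls[:, chr1]
        K_after = kinship_ibs(perturbed, exclude_chromosome="Bd1")
        assert np.allclose(K_before, K_after)

    def test_exclusion_must_leave_snps(self):
        m = make_matrix([[0, 2], [2, 0], [0, 0]], chrom=["c1", "c1"])
        with pytest.raises(ValueError, match="leaves no SNPs"):
            kinship_ibs(m, exclude_chromosome="c1")


class TestScan:
    def test_identity_kinship_matches_ols_likelihood_ratio(self, panel):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(panel.n_samples)
        scanner = LmmScanner(panel, kinship_mode="none")
        result = scanner.scan(y)
        X0 = np.ones((panel.n_samples, 1))
        ll0 = sm.OLS(y, X0).fit().llf
        for j in rng.choice(panel.n_snps, 25, replace=False):
            z = panel.calls[:, j].astype(float)
            ll1 = sm.OLS(y, np.column_stack([X0, z])).fit().llf
            oracle_lod = (ll1 - ll0) / np.log(10)
            assert result.table["lod"].iloc[int(j)] == pytest.approx(oracle_lod, abs=1e-6)

    def test_null_lod_upper_tail_is_chi_square_like(self, panel):
        # under the null, 2 ln(10) LOD ~ chi2(1); check the 3.84 upper tail
        rng = np.random.default_rng(6)
        fracs = []
        scanner = LmmScanner(panel, kinship_mode="none")
        for _ in range(8):
            y = rng.standard_normal(panel.n_samples)
            lods = scanner.scan(y).table["lod"].to_numpy()
            fracs.append(np.mean(2 * np.log(10) * lods > 3.841))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.03)

    def test_strong_qtl_peaks_at_causal_snp(self, panel):
        maf = panel.maf()
        locus = int(np.flatnonzero(maf > 0.35)[3])
        spec = PhenoSimSpec(qtl_loci=[(locus, 0.62)], polygenic_h2=0.1, n_replicates=1, seed=7)
        traits, _ = gen_phenotypes(panel, spec, envs=("2015",))
        y = traits.set_index("sample")["value"].loc[panel.samples].to_numpy()
        scanner = LmmScanner(panel, kinship_mode="loco")
        result = scanner.scan(y)
        assert int(result.table["lod"].idxmax()) == locus

    def test_scan_invariant_to_sample_order(self, panel):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(panel.n_samples)
        base = LmmScanner(panel, kinship_mode="loco").scan(y).table["lod"].to_numpy()
        perm = rng.permutation(panel.n_samples)
        shuffled = LmmScanner(panel.take_samples(perm), kinship_mode="loco").scan(y[perm])
        assert np.allclose(shuffled.table["lod"].to_numpy(), base, atol=1e-8)

    def test_missing_phenotype_rejected(self, panel):
        scanner = LmmScanner(panel, kinship_mode="none")
        y = np.full(panel.n_samples, np.nan)
        with pytest.raises(ValueError, match="missing"):
            scanner.scan(y)


class TestPermutationThreshold:
    def test_threshold_is_the_printed_order_statistic(self, panel):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(panel.n_samples)
        scanner = LmmScanner(panel, kinship_mode="none")
        thr, maxima = permutation_threshold(scanner, y, n_perm=40, alpha=0.05, seed=1)
        rank = int(np.ceil(0.95 * 40))  # 38th order statistic
        assert thr == np.sort(maxima)[rank - 1]

    def test_constant_phenotype_gives_zero_threshold(self, panel):
        scanner = LmmScanner(panel, kinship_mode="none")
        thr, _ = permutation_threshold(scanner, np.ones(panel.n_samples), n_perm=20, seed=2)
        assert thr == 0.0


class TestPve:
    def test_uncorrelated_snp_explains_nothing(self):
        assert pve_from_lod(0.0, 74) == 0.0

    def test_deterministic_phenotype_explains_everything(self, panel):
        z = panel.calls[:, 10].astype(float)
        scanner = LmmScanner(panel, kinship_mode="none")
        pve = variance_explained(scanner, z, str(panel.chrom[10]), int(panel.pos[10]))
        assert pve > 99.0


class TestCallQtl:
    def _scan_table(self, rows):
        from brachykit.gwas_scan import ScanResult

        return ScanResult(
            pd.DataFrame(rows, columns=["chrom", "pos", "lod", "effect"]), {}
        )

    def test_nearby_significant_snps_form_one_qtl(self):
        scan = self._scan_table(
            [("c1", 100_000, 8.0, 1.0), ("c1", 130_000, 6.0, 0.9)]
        )
        qtl = call_qtl(scan, threshold=5.0, n_samples=74)
        assert len(qtl) == 1
        assert qtl[0].peak_pos == 100_000
        assert qtl[0].member_positions == [100_000, 130_000]

    def test_distant_significant_snps_form_two_qtl(self):
        scan = self._scan_table(
            [("c1", 100_000, 8.0, 1.0), ("c1", 400_000, 6.0, 0.9)]
        )
        assert len(call_qtl(scan, threshold=5.0, n_samples=74)) == 2

    def test_window_genes_listed_by_interval_intersection(self):
        scan = self._scan_table([("c1", 200_000, 9.0, 1.0)])
        genes = pd.DataFrame(
            {
                "chrom": ["c1"] * 4 + ["c2"],
                "start": [155_000, 190_000, 249_000, 300_000, 200_000],
                "end": [160_000, 195_000, 260_000, 310_000, 210_000],
                "gene_id": ["in1", "in2", "in3", "out_far", "out_chrom"],
            }
        )
        qtl = call_qtl(scan, threshold=5.0, n_samples=74, annotation=genes)
        assert qtl[0].genes == ["in1", "in2", "in3"]


class TestGxe:
    def test_identical_environments_give_flat_scan(self, panel):
        rng = np.random.default_rng(12)
        vals = rng.standard_normal(panel.n_samples)
        means = pd.DataFrame(
            {
                "genotype": panel.samples * 2,
                "environment": ["2015"] * panel.n_samples + ["2050"] * panel.n_samples,
                "value": np.concatenate([vals, vals]),
            }
        )
        y = gxe_response(means, "2015", "2050", panel.samples)
        assert np.allclose(y, 0.0)
        lods = LmmScanner(panel, kinship_mode="loco").scan(y).table["lod"]
        assert np.allclose(lods, 0.0)

    def test_environment_specific_qtl_detected_and_additive_qtl_ignored(self, panel):
        maf = panel.maf()
        common = np.flatnonzero(maf > 0.35)
        gxe_locus, additive_locus = int(common[5]), int(common[40])
        spec = PhenoSimSpec(
            qtl_loci=[(additive_locus, 0.3)],
            qtl_loci_env_specific=[(gxe_locus, 0.4)],
            polygenic_h2=0.1,
            n_replicates=4,
            seed=13,
        )
        traits, _ = gen_phenotypes(panel, spec)
        means = (
            traits.groupby(["sample", "environment"])["value"].mean().reset_index()
        ).rename(columns={"sample": "genotype"})
        y = gxe_response(means, "2015", "2050", panel.samples)
        scanner = LmmScanner(panel, kinship_mode="loco")
        result = scanner.scan(y)
        thr, _ = permutation_threshold(scanner, y, n_perm=100, alpha=0.05, seed=3)
        assert int(result.table["lod"].idxmax()) == gxe_locus
        assert result.table["lod"].iloc[gxe_locus] > thr
        assert result.table["lod"].iloc[additive_locus] < thr

    def test_genotype_missing_in_one_environment_flagged(self, panel):
        means = pd.DataFrame(
            {
                "genotype": panel.samples,
                "environment": ["2015"] * panel.n_samples,
                "value": np.zeros(panel.n_samples),
            }
        )
        with pytest.raises(ValueError, match="missing"):
            gxe_response(means, "2015", "2050", panel.samples)
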