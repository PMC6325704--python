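"""Filtering, IBS distance, lineage clustering and replicate retention."""

import numpy as np
import pytest
from conftest import make_matrix

from brachykit.core import MISSING
from brachykit.genotype_core import (
    DistanceMatrix,
    cluster_lineages,
    filter_variants,
    fixed_divergence,
    ibs_distance,
    retain_replicates,
)


class TestFilterVariants:
    def test_low_maf_snp_dropped(self):
        # SNP 0: one alt homozygote of 25 samples -> MAF 0.04, below the
        # 5% threshold; SNP 1: MAF 0.48, kept
        rows = [[0, 0]] * 12 + [[0, 2]] * 12 + [[2, 2]]
        m = make_matrix(rows)
        out = filter_variants(m, min_quality=0, min_maf=0.05)
        assert out.n_snps == 1 and out.pos[0] == m.pos[1]

    def test_heterozygotes_recoded_missing(self):
        m = make_matrix([[1, 0], [0, 2], [2, 2]])
        out = filter_variants(m, min_quality=0, min_maf=0.0, het_policy="to_missing")
        assert out.calls[0, 0] == MISSING

    def test_identity_thresholds_change_nothing(self):
        m = make_matrix([[0, 2], [2, 0], [0, None]])
        out = filter_variants(m, min_quality=0, min_maf=0.0, het_policy="keep")
        assert np.array_equal(out.calls, m.calls)

    def test_quality_filter_strictly_above(self):
        m = make_matrix([[0, 0], [2, 2]], qual=[20.0, 21.0])
        out = filter_variants(m, min_quality=20, min_maf=0.0)
        assert out.n_snps == 1 and out.qual[0] == 21.0

    def test_empty_result_warns(self):
        m = make_matrix([[0, 0], [0, 0]])
        with pytest.warns(UserWarning, match="all SNPs removed"):
            filter_variants(m, min_quality=0, min_maf=0.4)


class TestIbsDistance:
    def test_identical_and_opposite_samples(self):
        m = make_matrix([[0, 2, 0], [0, 2, 0], [2, 0, 2]])
        D = ibs_distance(m).values
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0

    def test_count_oracle_127_of_1000(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 2, 1000) * 2
        other = base.copy()
        flip = rng.choice(1000, 127, replace=False)
        other[flip] = 2 - other[flip]
        m = make_matrix([list(base), list(other)])
        assert ibs_distance(m).values[0, 1] == pytest.approx(0.127)

    def test_missing_calls_excluded_from_denominator(self):
        m = make_matrix([[0, 2, None, 0], [0, 0, 2, None]])
        # joint SNPs: 0 (agree), 1 (differ) -> d = 1/2
        assert ibs_distance(m).values[0, 1] == pytest.approx(0.5)

    def test_undefined_pair_raises_unless_allowed(self):
        m = make_matrix([[0, None], [None, 2]])
        with pytest.raises(ValueError, match="jointly observed"):
            ibs_distance(m)
        D = ibs_distance(m, allow_undefined=True)
        assert np.isnan(D.values[0, 1])

    def test_matches_brute_force_and_triangle_inequality(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 2, size=(6, 60)) * 2
        m = make_matrix(calls.tolist())
        D = ibs_distance(m).values
        # brute-force oracle
        for i in range(6):
            for j in range(6):
                expected = np.mean(np.abs(calls[i] - calls[j]) / 2)
                assert D[i, j] == pytest.approx(expected)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


def _dist(samples, values):
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(samples=samples, values=v, joint_counts=np.full(v.shape, 100))


class TestClusterLineages:
    def test_two_separated_clouds_give_two_lineages(self):
        # two chains of five samples: within-cloud merge heights spread
        # smoothly over 0.003-0.009; clouds separated by 10x that spread
        n = 10
        D = np.full((n, n), 0.02)
        chain_a = [0.003, 0.0045, 0.006, 0.0075]
        chain_b = [0.00375, 0.00525, 0.00675, 0.009]
        for k, h in enumerate(chain_a):
            D[k, k + 1] = D[k + 1, k] = h
        for k, h in enumerate(chain_b):
            D[5 + k, 5 + k + 1] = D[5 + k + 1, 5 + k] = h
        D[:5, 5:] = 0.06
        D[5:, :5] = 0.06
        np.fill_diagonal(D, 0.0)
        cl = cluster_lineages(_dist([f"s{i}" for i in range(n)], D))
        assert cl.n_lineages == 2
        assert sorted(map(len, cl.members().values())) == [5, 5]

    def test_equal_distances_collapse_to_one_lineage(self):
        n = 6
        D = np.full((n, n), 0.3)
        np.fill_diagonal(D, 0.0)
        cl = cluster_lineages(_dist([f"s{i}" for i in range(n)], D))
        assert cl.n_lineages == 1

    def test_clones_cocluster_against_generator_truth(self, clonal_panel):
        matrix, truth = clonal_panel
        cl = cluster_lineages(ibs_distance(matrix))
        acc_lineages = truth.assign(
            lineage=[cl.assignment[s] for s in truth["sample"]]
        ).groupby("accession")["lineage"].nunique()
        assert (acc_lineages == 1).all()
        assert cl.n_lineages > 1

    def test_invariant_to_sample_order(self, clonal_panel):
        matrix, _ = clonal_panel
        cl1 = cluster_lineages(ibs_distance(matrix))
        perm = np.random.default_rng(0).permutation(matrix.n_samples)
        cl2 = cluster_lineages(ibs_distance(matrix.take_samples(perm)))
        # same partition, identities aside
        part1 = {}
        for s, g in cl1.assignment.items():
            part1.setdefault(g, set()).add(s)
        part2 = {}
        for s, g in cl2.assignment.items():
            part2.setdefault(g, set()).add(s)
        assert sorted(map(sorted, part1.values())) == sorted(map(sorted, part2.values()))


class TestRetainReplicates:
    def _clustering(self, assignment):
        from brachykit.genotype_core import GenotypeClustering

        return GenotypeClustering(assignment=assignment, cut_height=0.01, z=3.5)

    def test_majority_lineage_wins(self):
        cl = self._clustering({"a1": 1, "a2": 1, "a3": 2})
        kept = retain_replicates(
            cl, {"a1": "acc", "a2": "acc", "a3": "acc"}, {"a1": 0.1, "a2": 0.2, "a3": 0.0}
        )
        assert kept == {"a1", "a2"}

    def test_tie_broken_by_lowest_missingness(self):
        cl = self._clustering({"a1": 1, "a2": 2})
        kept = retain_replicates(
            cl, {"a1": "acc", "a2": "acc"}, {"a1": 0.10, "a2": 0.25}
        )
        assert kept == {"a1"}

    def test_unsplit_accession_fully_kept(self):
        cl = self._clustering({"a1": 1, "a2": 1, "b1": 2})
        kept = retain_replicates(
            cl, {"a1": "accA", "a2": "accA", "b1": "accB"}, {"a1": 0.1, "a2": 0.2, "b1": 0.3}
        )
        assert kept == {"a1", "a2", "b1"}


class TestFixedDivergence:
    def test_identical_groups_zero(self):
        m = make_matrix([[0, 2], [0, 2], [0, 2], [0, 2]])
        assert fixed_divergence(m, [1, 1, 2, 2]) == 0.0

    def test_fully_complementary_groups_one(self):
        m = make_matrix([[0, 2], [0, 2], [2, 0], [2, 0]])
        assert fixed_divergence(m, [1, 1, 2, 2]) == 1.0

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(17)
        m = make_matrix((rng.integers(0, 2, size=(6, 50)) * 2).tolist())
        g = [1, 1, 1, 2, 2, 2]
        swapped = [2, 2, 2, 1, 1, 1]
        assert fixed_divergence(m, g) == fixed_divergence(m, swapped)
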