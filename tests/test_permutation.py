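"""The constrained permutation null, empirical p-values, paired-run protocol."""
import math

import numpy as np
import pytest

from modrp import (
    ConstraintConfig,
    ConstraintError,
    ConvergenceConfig,
    ModrpError,
    NullDistribution,
    UNCONSTRAINED,
    assign_maf_bins,
    assign_ranks,
    build_null_distribution,
    draw_null_tuple,
    empirical_pvalue,
    rank_product,
    run_modrp,
)
from _util import enumerate_null_values, make_dataset, pairwise_outside_ld


def dataset_and_ranks(pmat, **kwargs):
    ds = make_dataset(pmat, **kwargs)
    return ds, assign_ranks(ds)


class TestDrawNullTuple:
    def test_k1_values_are_exactly_the_bin_log_ranks(self, rng):
        ds, ranks = dataset_and_ranks(np.linspace(0.1, 0.9, 5).reshape(-1, 1))
        binning = assign_maf_bins(ds.mafs)
        allowed = {math.log(r) for r in range(1, 6)}
        draws = {
            draw_null_tuple(2, ds, ranks, ConstraintConfig(), rng, binning=binning)
            for _ in range(200)
        }
        assert draws <= allowed
        assert len(draws) == 5  # every rank reachable

    def test_all_tuples_invalid_raises_constraint_error(self, rng):
        # two SNPs 500 bp apart on one chromosome: every pair (including a
        # SNP with itself) is within LD range, so no valid K=2 tuple exists
        ds, ranks = dataset_and_ranks(
            [[0.1, 0.2], [0.3, 0.4]], chromosomes=["1", "1"], positions=[1000, 1500]
        )
        binning = assign_maf_bins(ds.mafs)
        constraints = ConstraintConfig(max_rejections_per_draw=500)
        with pytest.raises(ConstraintError, match="2 SNPs"):
            draw_null_tuple(2, ds, ranks, constraints, rng, binning=binning)

    def test_valid_tuples_equiprobable_across_chromosomes(self, rng):
        # 2 SNPs on different chromosomes: the same-SNP tuples are within
        # LD range of themselves (distance 0) and rejected, leaving the two
        # cross-SNP tuples, each drawn with probability 1/2
        ds, ranks = dataset_and_ranks(
            [[0.1, 0.2], [0.3, 0.4]], chromosomes=["1", "2"], positions=[1000, 1500]
        )
        binning = assign_maf_bins(ds.mafs)
        b = 4000
        draws = np.array(
            [
                draw_null_tuple(2, ds, ranks, ConstraintConfig(), rng, binning=binning)
                for _ in range(b)
            ]
        )
        contrib = np.log(ranks.ranks.astype(float))
        valid = lambda t: pairwise_outside_ld(t, ds.chromosomes, ds.positions, 1_000_000)
        exact = enumerate_null_values(contrib, np.arange(2), valid)
        assert exact.size == 2  # only the two cross-SNP tuples survive
        assert set(np.round(draws, 12)) == set(np.round(exact, 12))

    def test_three_isolated_snps_tuple_frequencies(self, rng):
        # 3 SNPs on 3 chromosomes: valid tuples pair distinct SNPs (6 of 9);
        # each must appear with frequency 1/6
        ds, ranks = dataset_and_ranks(
            [[0.1, 0.6], [0.3, 0.2], [0.5, 0.9]],
            chromosomes=["1", "2", "3"],
            positions=[1000, 1000, 1000],
        )
        binning = assign_maf_bins(ds.mafs)
        b = 9000
        draws = np.array(
            [
                draw_null_tuple(2, ds, ranks, ConstraintConfig(), rng, binning=binning)
                for _ in range(b)
            ]
        )
        contrib = np.log(ranks.ranks.astype(float))
        valid = lambda t: pairwise_outside_ld(t, ds.chromosomes, ds.positions, 1_000_000)
        exact = enumerate_null_values(contrib, np.arange(3), valid)
        assert exact.size == 6
        exact_vals, exact_counts = np.unique(np.round(exact, 12), return_counts=True)
        got_vals, got_counts = np.unique(np.round(draws, 12), return_counts=True)
        assert set(got_vals) == set(exact_vals)
        freq = dict(zip(got_vals, got_counts / b))
        for v, c in zip(exact_vals, exact_counts):
            q = c / 6
            assert abs(freq[v] - q) < 3 * math.sqrt(q * (1 - q) / b)


class TestBuildNullDistribution:
    def test_zero_iterations_rejected(self, rng):
        ds, ranks = dataset_and_ranks([[0.1], [0.2]])
        with pytest.raises(ModrpError):
            build_null_distribution(2, ds, ranks, ConstraintConfig(), 0, rng,
                                    binning=assign_maf_bins(ds.mafs))

    def test_same_seed_gives_identical_multisets(self):
        ds, ranks = dataset_and_ranks(np.linspace(0.05, 0.95, 10).reshape(-1, 2))
        binning = assign_maf_bins(ds.mafs)
        a = build_null_distribution(2, ds, ranks, ConstraintConfig(), 5000, 7, binning=binning)
        b = build_null_distribution(2, ds, ranks, ConstraintConfig(), 5000, 7, binning=binning)
        np.testing.assert_array_equal(a.values, b.values)

    def test_values_sorted_and_sized(self):
        ds, ranks = dataset_and_ranks(np.linspace(0.05, 0.95, 10).reshape(-1, 2))
        null = build_null_distribution(2, ds, ranks, ConstraintConfig(), 3000, 11,
                                       binning=assign_maf_bins(ds.mafs))
        assert null.values.size == null.B == 3000
        assert (np.diff(null.values) >= 0).all()

    def test_unconstrained_matches_exhaustive_enumeration(self, rng):
        # brute-force oracle: all 64 tuples of an 8-SNP, 2-study instance
        pmat = rng.uniform(size=(8, 2))
        ds, ranks = dataset_and_ranks(pmat)
        null = build_null_distribution(0, ds, ranks, UNCONSTRAINED, 100_000, 3)
        exact = enumerate_null_values(np.log(ranks.ranks.astype(float)), np.arange(8))
        exact_vals, exact_counts = np.unique(np.round(exact, 12), return_counts=True)
        got_vals, got_counts = np.unique(np.round(null.values, 12), return_counts=True)
        assert set(got_vals) <= set(exact_vals)
        freq = dict(zip(got_vals, got_counts / null.B))
        for v, c in zip(exact_vals, exact_counts):
            q = c / 64
            sd = math.sqrt(q * (1 - q) / null.B)
            assert abs(freq.get(v, 0.0) - q) < 3 * sd

    def test_ld_rejection_excludes_only_in_range_pairs(self):
        # 3 SNPs: rs0-rs1 within LD on chr1, rs2 alone on chr2
        ds, ranks = dataset_and_ranks(
            [[0.1, 0.6], [0.3, 0.2], [0.5, 0.9]],
            chromosomes=["1", "1", "2"],
            positions=[1000, 2000, 1000],
        )
        null = build_null_distribution(
            2, ds, ranks, ConstraintConfig(), 5000, 5, binning=assign_maf_bins(ds.mafs)
        )
        contrib = np.log(ranks.ranks.astype(float))
        valid = lambda t: pairwise_outside_ld(t, ds.chromosomes, ds.positions, 1_000_000)
        exact = np.round(enumerate_null_values(contrib, np.arange(3), valid), 12)
        assert set(np.round(null.values, 12)) <= set(exact)
        assert null.rejection_rate > 0


class TestEmpiricalPvalue:
    def _null(self, values):
        return NullDistribution(
            bin_index=0, values=np.sort(np.asarray(values, float)),
            B=len(values), seed=0, constraints=ConstraintConfig(),
        )

    def test_observed_below_every_null_value(self):
        null = self._null(np.arange(1, 1000, dtype=float))
        assert empirical_pvalue(0.0, null) == pytest.approx(1 / 1000)

    def test_observed_above_every_null_value(self):
        null = self._null(np.arange(1, 1000, dtype=float))
        assert empirical_pvalue(1e6, null) == pytest.approx(1.0)

    def test_observed_at_median_counts_ties_conservatively(self):
        null = self._null(np.arange(1, 1000, dtype=float))  # 999 distinct values
        assert empirical_pvalue(500.0, null) == pytest.approx(501 / 1000)

    def test_monotone_in_observed_statistic(self, rng):
        null = self._null(rng.normal(size=500))
        obs = np.sort(rng.normal(size=50))
        ps = [empirical_pvalue(o, null) for o in obs]
        assert all(a <= b for a, b in zip(ps, ps[1:]))


class TestRunModrp:
    def _setup(self, rng, n=120, k=2):
        pmat = rng.uniform(size=(n, k))
        mafs = rng.uniform(0.01, 0.5, size=n)
        ds = make_dataset(pmat, mafs=mafs)
        ranks = assign_ranks(ds)
        return ds, ranks, rank_product(ranks), assign_maf_bins(ds.mafs)

    def test_identical_seed_pair_converges_immediately(self, rng):
        ds, ranks, rp, binning = self._setup(rng)
        conv = ConvergenceConfig(B_initial=2000, seed_pair=(9, 9))
        res = run_modrp(ds, ranks, rp, binning, convergence=conv)
        assert res.doublings == 0 and not res.not_converged.any()
        np.testing.assert_array_equal(res.p, res.p_run1)
        np.testing.assert_array_equal(res.p_run1, res.p_run2)

    def test_reported_p_is_max_of_pair_and_floor_respected(self, rng):
        ds, ranks, rp, binning = self._setup(rng)
        conv = ConvergenceConfig(B_initial=2000, seed_pair=(3, 17))
        res = run_modrp(ds, ranks, rp, binning, convergence=conv)
        np.testing.assert_array_equal(res.p, np.maximum(res.p_run1, res.p_run2))
        assert (res.p >= 1 / (res.B + 1)).all()
        assert (res.p <= 1).all()

    def test_determinism_bit_identical(self, rng):
        ds, ranks, rp, binning = self._setup(rng)
        conv = ConvergenceConfig(B_initial=2000, seed_pair=(3, 17))
        a = run_modrp(ds, ranks, rp, binning, convergence=conv)
        b = run_modrp(ds, ranks, rp, binning, convergence=conv)
        np.testing.assert_array_equal(a.p, b.p)
        assert a.B == b.B and a.doublings == b.doublings

    def test_unconstrained_equals_global_null(self, rng):
        # with both constraints off the bin structure must not matter
        ds, ranks, rp, binning = self._setup(rng)
        conv = ConvergenceConfig(B_initial=2000, seed_pair=(5, 6))
        res = run_modrp(ds, ranks, rp, binning, constraints=UNCONSTRAINED, convergence=conv)
        res2 = run_modrp(ds, ranks, rp, None, constraints=UNCONSTRAINED, convergence=conv)
        np.testing.assert_array_equal(res.p, res2.p)

    def test_per_bin_monotone_in_statistic(self, rng):
        ds, ranks, rp, binning = self._setup(rng, n=200, k=3)
        conv = ConvergenceConfig(B_initial=2000, seed_pair=(5, 6))
        res = run_modrp(ds, ranks, rp, binning, convergence=conv)
        for b in range(binning.n_bins):
            members = np.flatnonzero(binning.bin_of == b)
            order = members[np.argsort(res.statistic[members])]
            assert (np.diff(res.p_run1[order]) >= 0).all()

    def test_report_carries_bin_rejection_rates(self, rng):
        ds, ranks, rp, binning = self._setup(rng)
        conv = ConvergenceConfig(B_initial=2000, seed_pair=(5, 6))
        res = run_modrp(ds, ranks, rp, binning, convergence=conv)
        for b, pool_stats in res.report["bins"].items():
            assert 0 <= pool_stats["rejection_rate_run1"] < 1
            assert pool_stats["n_snps"] > 0
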