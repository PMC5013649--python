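"""Omega bin profiles, fold contrasts, MWU, and dS sensitivity filtering."""

import numpy as np
import pytest
from scipy import stats

from omegacontrast import contrasts as ct
from omegacontrast.dnds_ng86 import FLAG_DS_ZERO, FLAG_OK, DnDsRecord


def make_record(omega, ds=0.3, gene="g", flag=FLAG_OK):
    return DnDsRecord(
        gene_a=gene, gene_b=gene, n_codons=100, N=230.0, S=70.0,
        Nd=10.0, Sd=10.0, pN=0.04, pS=0.14,
        dN=None if flag != FLAG_OK else omega * ds,
        dS=None if flag != FLAG_OK else ds,
        omega=None if flag != FLAG_OK else omega, flag=flag,
    )


class TestBinOmegas:
    def test_one_gene_per_bin_with_inclusive_lower_bounds(self):
        records = [make_record(w, gene=f"g{i}") for i, w in enumerate([0.1, 0.5, 0.8, 1.2])]
        profile = ct.bin_omegas(records)
        assert profile.counts == (1, 1, 1, 1)
        assert sum(profile.proportions) == pytest.approx(1.0)

    def test_all_below_first_edge(self):
        records = [make_record(0.2, gene=f"g{i}") for i in range(7)]
        assert ct.bin_omegas(records).counts == (7, 0, 0, 0)

    def test_flagged_records_are_excluded_and_empty_input_errors(self):
        with pytest.raises(ValueError):
            ct.bin_omegas([make_record(0.0, flag=FLAG_DS_ZERO)])

    def test_bin_proportions_match_sampling_distribution(self):
        rng = np.random.default_rng(0)
        omegas = rng.gamma(shape=2.0, scale=0.1, size=20000)
        records = [make_record(w, gene=f"g{i}") for i, w in enumerate(omegas)]
        profile = ct.bin_omegas(records)
        expected = [
            np.mean(omegas < 0.5),
            np.mean((omegas >= 0.5) & (omegas < 0.75)),
            np.mean((omegas >= 0.75) & (omegas < 1.0)),
            np.mean(omegas >= 1.0),
        ]
        for got, want in zip(profile.proportions, expected):
            assert got == pytest.approx(want, abs=0.02)


class TestFoldContrast:
    def run(self, pairs, **kw):
        omegas_a = {f"a{i}": wa for i, (wa, _) in enumerate(pairs)}
        omegas_b = {f"b{i}": wb for i, (_, wb) in enumerate(pairs)}
        mapping = [(f"a{i}", f"b{i}") for i in range(len(pairs))]
        return ct.fold_contrast(omegas_a, omegas_b, mapping, **kw)

    def test_boundary_ratio_is_inclusive(self):
        summary = self.run([(0.3, 0.2)])
        assert summary.n_fold_genes == 1
        assert summary.pct_higher_in_first == 100.0

    def test_sub_threshold_ratio_excluded(self):
        assert self.run([(0.2, 0.25)]).n_fold_genes == 0

    def test_zero_omega_attributed_to_nonzero_genus(self):
        summary = self.run([(0.0, 0.3), (0.0, 0.0), (0.4, 0.1)])
        assert summary.n_fold_genes == 2
        assert summary.pct_higher_in_first == 50.0

    def test_antisymmetric_under_genus_swap(self):
        pairs = [(0.5, 0.1), (0.1, 0.4), (0.3, 0.29), (0.2, 0.0)]
        fwd = self.run(pairs)
        rev = self.run([(b, a) for a, b in pairs])
        assert fwd.pct_higher_in_first == rev.pct_higher_in_second
        assert fwd.pct_higher_in_second == rev.pct_higher_in_first
        assert fwd.pct_higher_in_first + fwd.pct_higher_in_second == 100.0

    def test_empty_matched_set_errors(self):
        with pytest.raises(ValueError):
            ct.fold_contrast({}, {}, [("a", "b")])


class TestMannWhitney:
    def test_exact_enumeration_of_disjoint_samples(self):
        u, p = ct.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_degenerate_samples_return_p_one(self):
        with pytest.warns(UserWarning):
            _, p = ct.mann_whitney_u([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_exact_and_asymptotic_branches_agree_for_n8(self):
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(50):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            _, p_exact = ct.mann_whitney_u(list(a), list(b))
            p_asym = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            diffs.append(abs(p_exact - p_asym))
        # the continuity-corrected normal approximation tracks the exact
        # null closely at n=8; worst-case discrepancy stays below 0.015
        assert np.mean(diffs) < 0.01
        assert max(diffs) < 0.015

    def test_null_pvalues_are_roughly_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            pvals.append(ct.mann_whitney_u(rng.normal(size=30), rng.normal(size=30))[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDsFilter:
    def test_highest_decile_gene_removed_at_default_quantile(self):
        records = [make_record(0.2, ds=float(d), gene=f"g{d}") for d in range(1, 11)]
        kept = ct.ds_percentile_filter(records, q=0.90)
        assert {r.dS for r in kept} == set(map(float, range(1, 10)))

    def test_full_quantile_removes_nothing(self):
        records = [make_record(0.2, ds=float(d), gene=f"g{d}") for d in range(1, 11)]
        assert len(ct.ds_percentile_filter(records, q=1.0)) == 10

    def test_removes_about_ten_percent_of_continuous_ds(self):
        rng = np.random.default_rng(5)
        records = [
            make_record(0.2, ds=float(d), gene=f"g{i}")
            for i, d in enumerate(rng.lognormal(-1.2, 0.4, size=2000))
        ]
        kept = ct.ds_percentile_filter(records, q=0.90)
        removed_frac = 1 - len(kept) / len(records)
        assert 0.09 <= removed_frac <= 0.11

    def test_rebinning_shift_bounded_by_removed_count(self):
        rng = np.random.default_rng(6)
        records = [
            make_record(float(w), ds=float(d), gene=f"g{i}")
            for i, (w, d) in enumerate(
                zip(rng.gamma(2.0, 0.15, size=500), rng.lognormal(-1.2, 0.4, size=500))
            )
        ]
        kept = ct.ds_percentile_filter(records, q=0.90)
        removed = len(records) - len(kept)
        before = ct.bin_omegas(records).counts
        after = ct.bin_omegas(kept).counts
        assert all(abs(x - y) <= removed for x, y in zip(before, after))


class TestDsSummary:
    def test_constant_ds_has_equal_quartiles_and_no_outliers(self):
        records = [make_record(0.2, ds=0.3, gene=f"g{i}") for i in range(5)]
        s = ct.ds_distribution_summary(records)
        assert s.q25 == s.median == s.q75 == 0.3
        assert s.n_outliers == 0

    def test_extreme_value_flagged_as_outlier(self):
        records = [
            make_record(0.2, ds=d, gene=f"g{i}")
            for i, d in enumerate([0.1, 0.2, 0.3, 0.4, 10.0])
        ]
        s = ct.ds_distribution_summary(records)
        assert s.n_outliers == 1
        assert s.whisker_high < 10.0
        assert s.maximum == 10.0

    def test_simulated_genome_median_near_target(self):
        from omegacontrast import synthetic_data as syn
        from omegacontrast.pipeline import run_species_pair

        sim = syn.simulate_genome_pair(60, ds_dist=0.3, seed=8, length_dist=300.0)
        res = run_species_pair(sim.cds_a, sim.cds_b, ortho_map=sim.ortho_truth)
        s = ct.ds_distribution_summary(res.records)
        assert 0.25 <= s.median <= 0.35
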