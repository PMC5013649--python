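"""Expression categories, stage profiles and profile comparisons."""

import numpy as np
import pandas as pd
import pytest

from omegacontrast import expression as ex
from omegacontrast import synthetic_data as syn
from omegacontrast.expression import ExpressionCategory as Cat


def table_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=list(ex.DEFAULT_STAGES))
    return ex.ExpressionTable(df)


class TestCategories:
    @pytest.mark.parametrize(
        "rpkm,category",
        [
            (0, Cat.NONE),
            (0.01, Cat.LOW),
            (10, Cat.LOW),
            (10.01, Cat.MODERATE),
            (50, Cat.MODERATE),
            (50.01, Cat.HIGH),
            (1000, Cat.HIGH),
            (2000, Cat.EXTREMELY_HIGH),
        ],
    )
    def test_half_open_boundaries(self, rpkm, category):
        assert ex.categorize_expression(rpkm) is category

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ex.categorize_expression(-1)

    def test_boundaries_partition_the_nonnegative_line(self):
        rng = np.random.default_rng(0)
        for rpkm in np.concatenate([[0, 10, 50, 1000], rng.exponential(100, size=200)]):
            assert isinstance(ex.categorize_expression(float(rpkm)), Cat)


class TestStageProfile:
    def test_all_zero_table_gives_zero_percent(self):
        table = table_from(np.zeros((4, 10)))
        profile = ex.stage_profile([f"g{i}" for i in range(4)], table)
        assert profile.pct_expressed == (0.0,) * 10
        assert profile.pct_high == (0.0,) * 10

    def test_single_gene_high_at_one_stage(self):
        values = np.zeros((1, 10))
        values[0, 2] = 60.0
        profile = ex.stage_profile(["g0"], table_from(values))
        assert profile.pct_expressed[2] == profile.pct_high[2] == 100.0
        assert sum(profile.pct_expressed) == 100.0

    def test_missing_genes_reported_not_fatal(self):
        table = table_from(np.ones((2, 10)))
        profile = ex.stage_profile(["g0", "absent"], table)
        assert profile.n_genes == 1
        assert profile.missing_genes == ("absent",)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            ex.stage_profile([], table_from(np.ones((1, 10))))

    def test_planted_expression_probability_recovered(self):
        genes = [f"g{i}" for i in range(1000)]
        table = syn.simulate_expression(genes, expressed_prob=0.8, seed=1)
        profile = ex.stage_profile(genes, table)
        for pct in profile.pct_expressed:
            assert pct == pytest.approx(80.0, abs=4.0)

    def test_high_never_exceeds_expressed(self):
        genes = [f"g{i}" for i in range(200)]
        table = syn.simulate_expression(genes, seed=2)
        profile = ex.stage_profile(genes, table)
        for hi, expr in zip(profile.pct_high, profile.pct_expressed):
            assert hi <= expr


class TestCompareProfiles:
    def test_identical_profiles_give_p_one_and_perfect_correlation(self):
        genes = [f"g{i}" for i in range(300)]
        table = syn.simulate_expression(genes, expressed_prob=[0.5 + 0.04 * j for j in range(10)], seed=3)
        profile = ex.stage_profile(genes, table)
        cmp = ex.compare_stage_profiles(profile, profile)
        assert all(p == pytest.approx(1.0) for p in cmp.chi2_pvalues_expressed)
        assert cmp.spearman_r_expressed == pytest.approx(1.0)

    def test_reversed_rank_order_gives_negative_one(self):
        up = ex.StageProfile(
            stages=ex.DEFAULT_STAGES, n_genes=100,
            expressed_counts=tuple(range(10, 60, 5)), high_counts=(0,) * 10,
        )
        down = ex.StageProfile(
            stages=ex.DEFAULT_STAGES, n_genes=100,
            expressed_counts=tuple(range(55, 5, -5)), high_counts=(0,) * 10,
        )
        cmp = ex.compare_stage_profiles(up, down)
        assert cmp.spearman_r_expressed == pytest.approx(-1.0)

    def test_symmetry_in_arguments(self):
        genes = [f"g{i}" for i in range(200)]
        t1 = syn.simulate_expression(genes, expressed_prob=0.7, seed=4)
        t2 = syn.simulate_expression(genes, expressed_prob=0.8, seed=5)
        p1, p2 = ex.stage_profile(genes, t1), ex.stage_profile(genes, t2)
        fwd = ex.compare_stage_profiles(p1, p2)
        rev = ex.compare_stage_profiles(p2, p1)
        assert fwd.chi2_pvalues_expressed == rev.chi2_pvalues_expressed
        assert abs(fwd.spearman_r_expressed) == abs(rev.spearman_r_expressed)

    def test_planted_difference_is_detected(self):
        probs_a = [0.7] * 10
        probs_b = [0.7] * 10
        probs_b[0] = 0.5  # 20-point difference at the first stage
        genes = [f"g{i}" for i in range(500)]
        pa = ex.stage_profile(genes, syn.simulate_expression(genes, expressed_prob=probs_a, seed=6))
        pb = ex.stage_profile(genes, syn.simulate_expression(genes, expressed_prob=probs_b, seed=7))
        cmp = ex.compare_stage_profiles(pa, pb)
        assert cmp.chi2_pvalues_expressed[0] < 0.001


class TestTransfer:
    def test_fully_mapped_set_keeps_cardinality(self):
        mapped, unmapped = ex.transfer_gene_set(["a", "b"], {"a": "ra", "b": "rb"})
        assert mapped == ["ra", "rb"] and unmapped == []

    def test_unmapped_genes_are_listed(self):
        mapped, unmapped = ex.transfer_gene_set(
            ["a", "b", "c", "d", "e"], {"a": "ra", "b": "rb"}
        )
        assert len(mapped) == 2 and unmapped == ["c", "d", "e"]

    def test_transfer_then_profile_equals_direct_profiling(self):
        genes = [f"r{i}" for i in range(50)]
        table = syn.simulate_expression(genes, seed=8)
        ortho = {f"x{i}": f"r{i}" for i in range(50)}
        mapped, _ = ex.transfer_gene_set([f"x{i}" for i in range(50)], ortho)
        assert ex.stage_profile(mapped, table) == ex.stage_profile(genes, table)
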