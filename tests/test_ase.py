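"""Exact binomial ASE testing, FDR selection and gene-level aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aselof import (
    BiasModel,
    Thresholds,
    ase_calls,
    binomial_ase,
    exact_binom_p,
    fdr_select,
    gene_ase,
    gene_ase_table,
    proportion_ase,
)

from conftest import make_counts


class TestExactBinomial:
    def test_central_value_is_one(self):
        p, direction = binomial_ase(10, 10, 0.5)
        assert p == pytest.approx(1.0)

    def test_known_tail_value(self):
        # 18/20 vs 0.5: both tails enumerated exactly
        p, direction = binomial_ase(18, 2, 0.5)
        assert p == pytest.approx(4.0245056152343723e-4, rel=1e-12)
        assert direction == "REF"

    def test_observed_at_null_mean(self):
        p, _ = binomial_ase(60, 40, 0.6)
        assert p > 0.9

    def test_direction_follows_ratio(self):
        assert binomial_ase(2, 18, 0.5)[1] == "ALT"
        assert binomial_ase(12, 8, 0.6)[1] == "BAL"  # ratio == p0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            binomial_ase(0, 0, 0.5)

    @given(
        n=st.integers(1, 25),
        p0=st.sampled_from([0.4, 0.5, 0.6]),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_independent_exact_test(self, n, p0, data):
        """scipy's exact binomial test is the independent oracle."""
        k = data.draw(st.integers(0, n))
        mine = exact_binom_p(k, n, p0)
        oracle = stats.binomtest(k, n, p0).pvalue
        assert mine == pytest.approx(oracle, abs=1e-12)


class TestFdrSelect:
    def test_clear_separation_selects_exactly_the_small_pvalues(self):
        p = np.array([0.001] * 10 + [0.9] * 90)
        out = fdr_select(p)
        assert int(out["significant"].sum()) == 10
        assert out.loc[out["p"] == 0.001, "significant"].all()
        # manual BH for the small block: q = p * m / rank = .001*100/10
        assert out.loc[0, "q"] == pytest.approx(0.01)

    def test_single_pvalue(self):
        out = fdr_select([0.004])
        assert out["q"].iloc[0] == pytest.approx(0.004)
        assert bool(out["significant"].iloc[0])

    def test_small_p_among_many_nulls_usually_not_selected(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(50):
            p = np.append(rng.uniform(size=999), 0.004)
            hits += bool(fdr_select(p)["significant"].iloc[-1])
        assert hits <= 5  # q typically far above 0.05

    def test_empty_and_invalid(self):
        assert fdr_select([]).empty
        with pytest.raises(ValueError):
            fdr_select([0.5, 1.5])


class TestGeneAse:
    def test_maf_direct_arithmetic(self):
        df = make_counts([(40, 10), (35, 15)])
        df["gene"] = "G"
        g = gene_ase(df, n_mc=2000, seed=0)
        assert g.maf == pytest.approx(0.75)
        assert g.major_count == 75
        assert g.haplotype == "reference"

    def test_ambiguous_haplotype(self):
        df = make_counts([(40, 10), (10, 40)])
        df["gene"] = "G"
        g = gene_ase(df, n_mc=500, seed=0)
        assert g.haplotype == "ambiguous"

    def test_alternative_haplotype(self):
        df = make_counts([(10, 40), (15, 35)])
        g = gene_ase(df, n_mc=500, seed=0)
        assert g.haplotype == "alternative"

    def test_site_tie_breaks_toward_reference(self):
        df = make_counts([(25, 25)])
        g = gene_ase(df, n_mc=500, seed=0)
        assert g.major_is_ref == [True]
        assert g.maf == pytest.approx(0.5)

    def test_adding_balanced_site_never_increases_maf(self):
        base = make_counts([(40, 10), (35, 15)])
        bigger = make_counts([(40, 10), (35, 15), (25, 25)])
        g0 = gene_ase(base, n_mc=500, seed=0)
        g1 = gene_ase(bigger, n_mc=500, seed=0)
        assert g1.maf <= g0.maf

    def test_mc_p_smoothing_floor(self):
        df = make_counts([(50, 0), (50, 0)])
        g = gene_ase(df, n_mc=1000, seed=0)
        assert g.p_value >= 1 / 1001
        assert g.ase  # extreme MAF, tiny p

    def test_zero_count_sites_excluded(self):
        df = make_counts([(40, 10), (0, 0)])
        g = gene_ase(df, n_mc=500, seed=0)
        assert g.n_sites == 1

    def test_table_determinism_and_fdr_columns(self):
        rng = np.random.default_rng(7)
        rows = []
        for gi in range(6):
            for si in range(3):
                ref = int(rng.binomial(60, 0.5))
                rows.append({"refCount": ref, "altCount": 60 - ref,
                             "gene": f"g{gi}"})
        df = make_counts(rows)
        df["gene"] = [r["gene"] for r in rows]
        t1 = gene_ase_table(df, n_mc=500, seed=5)
        t2 = gene_ase_table(df, n_mc=500, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert {"maf", "p", "q", "ase", "haplotype"} <= set(t1.columns)


class TestAseCallsTable:
    def test_states_and_conjunctive_significance(self):
        rows = [(50, 50)] * 30 + [(95, 5), (5, 95)]
        df = make_counts(rows)
        out = ase_calls(df, BiasModel.flat(0.5))
        extreme = out[out["variantID"].isin(["s31", "s32"])]
        assert list(extreme["state"]) == ["REF", "ALT"]
        balanced = out[~out["variantID"].isin(["s31", "s32"])]
        assert (balanced["state"] == "BAL").all()
        # invariant: significant <=> p < 0.005 and q <= 0.05
        assert (
            out["significant"]
            == ((out["p"] < 0.005) & (out["q"] <= 0.05))
        ).all()

    def test_zero_read_sites_skipped(self):
        df = make_counts([(50, 50), (0, 0)])
        out = ase_calls(df)
        assert len(out) == 1

    def test_proportion(self):
        rows = [(95, 5)] * 3 + [(50, 50)] * 17
        out = ase_calls(make_counts(rows))
        assert proportion_ase(out) == pytest.approx(3 / 20)
        assert np.isnan(proportion_ase(out.iloc[0:0]))
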