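"""Paired normal/tumor pattern classification and its symmetries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aselof import (
    BiasModel,
    ase_calls,
    classify_pairs,
    classify_pattern,
    fisher_diff,
    pattern_table,
)
from aselof.patterns import PATTERN_STATES, STATE_TO_PATTERN

from conftest import make_counts


def fisher_two_sided_oracle(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins
    and sum hypergeometric probabilities <= that of the observed table."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


class TestFisherDiff:
    @pytest.mark.parametrize(
        "table,expect",
        [
            ((10, 10, 10, 10), "eq1"),
            ((50, 50, 20, 80), "lt"),
            ((5, 5, 6, 4), "gt"),
        ],
    )
    def test_against_hypergeometric_enumeration(self, table, expect):
        p = fisher_diff(*table)
        oracle = fisher_two_sided_oracle(*table)
        assert p == pytest.approx(oracle, rel=1e-9)
        if expect == "eq1":
            assert p == pytest.approx(1.0)
        elif expect == "lt":
            assert p < 0.05
        else:
            assert p > 0.05

    def test_zero_margin_returns_one(self):
        assert fisher_diff(10, 0, 20, 0) == 1.0
        assert fisher_diff(0, 0, 10, 10) == 1.0


class TestClassifyPattern:
    @pytest.mark.parametrize("states,expected", list(STATE_TO_PATTERN.items()))
    def test_state_mapping_with_significant_fisher(self, states, expected):
        assert classify_pattern(states[0], states[1], 0.001) == expected

    @pytest.mark.parametrize("states", list(STATE_TO_PATTERN))
    def test_fisher_gate_applies_to_every_pattern(self, states):
        assert classify_pattern(states[0], states[1], 0.2) == "no-change"

    def test_identical_and_concordant_states(self):
        assert classify_pattern("BAL", "BAL", 0.001) == "no-change"
        assert classify_pattern("REF", "REF", 0.001) == "concordant"
        assert classify_pattern("ALT", "ALT", 0.001) == "concordant"

    def test_unknown_state_rejected(self):
        with pytest.raises(Exception):
            classify_pattern("XXX", "BAL", 0.5)


def _paired_calls(normal_rows, tumor_rows, p0=0.5):
    n = ase_calls(make_counts(normal_rows, sample="P1-N"), BiasModel.flat(p0))
    t = ase_calls(make_counts(tumor_rows, sample="P1-T"), BiasModel.flat(p0))
    return classify_pairs(n, t)


class TestClassifyPairs:
    def test_balanced_to_alt_is_p1(self):
        out = _paired_calls([(50, 50)], [(20, 80)])
        assert out["pattern"].iloc[0] == "P1"

    def test_identical_counts_no_change(self):
        out = _paired_calls([(50, 50)], [(50, 50)])
        assert out["pattern"].iloc[0] == "no-change"

    def test_ref_to_alt_flip_is_p3(self):
        out = _paired_calls([(80, 20)], [(20, 80)])
        assert out["pattern"].iloc[0] == "P3"

    def test_exactly_one_label_per_paired_site(self, small_bundle):
        rna = small_bundle.rna_counts
        n = ase_calls(rna[rna["sample"] == "P001-N"], BiasModel.flat(0.52))
        t = ase_calls(rna[rna["sample"] == "P001-T"], BiasModel.flat(0.52))
        out = classify_pairs(n, t)
        assert len(out) == len(out.drop_duplicates("variantID"))
        assert out["pattern"].notna().all()

    def test_label_swap_symmetry(self, small_bundle):
        """Swapping the tissue labels maps P1<->P5, P2<->P4, P3<->P6."""
        swap = {"P1": "P5", "P5": "P1", "P2": "P4", "P4": "P2",
                "P3": "P6", "P6": "P3", "no-change": "no-change",
                "concordant": "concordant"}
        rna = small_bundle.rna_counts
        n = ase_calls(rna[rna["sample"] == "P002-N"], BiasModel.flat(0.52))
        t = ase_calls(rna[rna["sample"] == "P002-T"], BiasModel.flat(0.52))
        fwd = classify_pairs(n, t).set_index("variantID")
        rev = classify_pairs(t, n).set_index("variantID")
        for vid in fwd.index:
            assert rev.loc[vid, "pattern"] == swap[fwd.loc[vid, "pattern"]]

    def test_allele_swap_symmetry(self, small_bundle):
        """Swapping ref/alt (and p0 -> 1-p0) maps P1<->P4, P2<->P5, P3<->P6."""
        swap = {"P1": "P4", "P4": "P1", "P2": "P5", "P5": "P2",
                "P3": "P6", "P6": "P3", "no-change": "no-change",
                "concordant": "concordant"}
        rna = small_bundle.rna_counts.copy()
        flipped = rna.rename(
            columns={"refCount": "altCount", "altCount": "refCount",
                     "refAllele": "altAllele", "altAllele": "refAllele"}
        )
        p0 = 0.52
        n_f = ase_calls(flipped[flipped["sample"] == "P003-N"],
                        BiasModel.flat(1 - p0))
        t_f = ase_calls(flipped[flipped["sample"] == "P003-T"],
                        BiasModel.flat(1 - p0))
        n = ase_calls(rna[rna["sample"] == "P003-N"], BiasModel.flat(p0))
        t = ase_calls(rna[rna["sample"] == "P003-T"], BiasModel.flat(p0))
        fwd = classify_pairs(n, t).set_index("variantID")
        rev = classify_pairs(n_f, t_f).set_index("variantID")
        for vid in fwd.index:
            assert rev.loc[vid, "pattern"] == swap[fwd.loc[vid, "pattern"]]


class TestPatternTable:
    def test_single_patient_percentages(self):
        df = pd.DataFrame({"pattern": ["P1"] + ["no-change"] * 9})
        table = pattern_table(df)
        assert table.loc["P1", "Total SNPs"] == 10.0
        assert table.loc["No ASE", "Total SNPs"] == 90.0

    def test_rows_sum_to_100(self, small_bundle):
        rna = small_bundle.rna_counts
        n = ase_calls(rna[rna["sample"] == "P001-N"], BiasModel.flat(0.52))
        t = ase_calls(rna[rna["sample"] == "P001-T"], BiasModel.flat(0.52))
        table = pattern_table(classify_pairs(n, t))
        assert table["Total SNPs"].sum() == pytest.approx(100.0, abs=0.3)

    def test_concordant_folds_into_no_ase(self):
        df = pd.DataFrame({"pattern": ["concordant"] * 2 + ["P4"] * 2})
        table = pattern_table(df)
        assert table.loc["No ASE", "Total SNPs"] == 50.0
        assert table.loc["P4", "Total SNPs"] == 50.0

    def test_empty_category_omitted(self):
        df = pd.DataFrame({"pattern": ["P1", "no-change"]})
        table = pattern_table(
            df,
            {"A": pd.Series([True, True]), "B": pd.Series([False, False])},
        )
        assert "B" not in table.columns
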