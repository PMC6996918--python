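"""Mechanism attribution flags and the printed-table summaries."""

import numpy as np
import pandas as pd
import pytest

from aselof import (
    cnv_duplication_check,
    dna_concordance,
    eqtl_attribution,
    explained_summary,
    mechanism_summary,
    methylation_change,
    skipping_antisense,
    skipping_summary,
    splice_site_overlap,
)
from aselof.datasets import dna_explained_counts, skipping_antisense_counts
from aselof.mechanisms import splice_dinucleotides


class TestDnaConcordance:
    def test_same_direction_significant(self):
        assert dna_concordance(75, 25, 30, 10) is True

    def test_balanced_dna_not_explained(self):
        assert dna_concordance(80, 20, 50, 50) is False

    def test_opposite_direction_not_explained(self):
        assert dna_concordance(75, 25, 10, 30) is False

    def test_low_dna_depth_undetermined(self):
        assert dna_concordance(75, 25, 3, 2) is None


class TestCnvDuplication:
    SEG = pd.DataFrame(
        [{"sample": "p-T", "contig": "chr1", "start": 100, "end": 200,
          "major_cn": 2, "minor_cn": 1}]
    )

    def test_unbalanced_duplication_true(self):
        assert cnv_duplication_check("chr1", 150, self.SEG) is True

    @pytest.mark.parametrize("major,minor", [(1, 1), (2, 2)])
    def test_balanced_states_false(self, major, minor):
        seg = self.SEG.assign(major_cn=major, minor_cn=minor)
        assert cnv_duplication_check("chr1", 150, seg) is False

    def test_no_overlap_false(self):
        assert cnv_duplication_check("chr1", 999, self.SEG) is False


class TestEqtl:
    EQTLS = pd.DataFrame({"variant": ["rs9"], "slope": [0.8]})

    def test_no_record_means_not_egene(self):
        assert eqtl_attribution("alternative", self.EQTLS.iloc[0:0]) == (False, False)

    def test_in_phase_with_sufficient_ld(self):
        flags = eqtl_attribution(
            "alternative", self.EQTLS, {"rs9": 1}, {"rs9": 0.5}
        )
        assert flags == (True, True)

    def test_ld_below_threshold_blocks_phase(self):
        flags = eqtl_attribution(
            "alternative", self.EQTLS, {"rs9": 1}, {"rs9": 0.3}
        )
        assert flags == (True, False)

    def test_missing_ld_leaves_phase_undetermined(self):
        flags = eqtl_attribution("alternative", self.EQTLS, {"rs9": 1}, {})
        assert flags == (True, None)

    def test_wrong_direction_slope(self):
        neg = pd.DataFrame({"variant": ["rs9"], "slope": [-0.8]})
        flags = eqtl_attribution("alternative", neg, {"rs9": 1}, {"rs9": 0.9})
        assert flags == (True, False)


class TestMethylation:
    @pytest.mark.parametrize(
        "n,t,expected",
        [(0.20, 0.30, True), (0.25, 0.30, False), (0.3, 0.3, False),
         (0.30, 0.20, True)],
    )
    def test_fold_threshold(self, n, t, expected):
        assert methylation_change(n, t) is expected

    def test_missing_undetermined(self):
        assert methylation_change(None, 0.3) is None
        assert methylation_change(0.3, float("nan")) is None


class TestSpliceSites:
    # two-exon gene: exon1 [100,200), exon2 [500,600), intron [200,500)
    def exons(self, strand):
        return pd.DataFrame(
            {
                "gene": ["G", "G"],
                "contig": ["chr1", "chr1"],
                "strand": [strand, strand],
                "exon_index": [0, 1],
                "start": [100, 500],
                "end": [200, 600],
            }
        )

    def test_plus_strand_donor_and_acceptor(self):
        exons = self.exons("+")
        # donor: first two intronic bases (1-based 201, 202)
        assert splice_site_overlap("chr1", 201, exons)
        assert splice_site_overlap("chr1", 202, exons)
        # acceptor: last two intronic bases (499, 500)
        assert splice_site_overlap("chr1", 499, exons)
        assert splice_site_overlap("chr1", 500, exons)
        assert not splice_site_overlap("chr1", 150, exons)  # mid-exon
        assert not splice_site_overlap("chr1", 300, exons)  # deep intron

    def test_minus_strand_roles_mirror(self):
        plus = splice_dinucleotides(self.exons("+")).set_index("position")
        minus = splice_dinucleotides(self.exons("-")).set_index("position")
        assert set(plus.index) == set(minus.index)  # same positions
        for pos in plus.index:
            assert plus.loc[pos, "role"] != minus.loc[pos, "role"]

    def test_single_exon_gene_has_no_sites(self):
        one = self.exons("+").iloc[:1]
        assert splice_dinucleotides(one).empty


class TestSkippingAntisense:
    def test_published_adam15_like_folds(self):
        # library 1e6 so folds are (count+1)/(count+1) exactly
        out = skipping_antisense(999, 3799, 999, 1699, 999, 1799, 1e6, 1e6)
        assert out["exon_skipping"] and out["antisense_supported"]
        assert out["iso1_fold"] == pytest.approx(3.8)
        assert out["antisense_donor_fold"] == pytest.approx(1.7)
        assert out["antisense_acceptor_fold"] == pytest.approx(1.8)

    def test_strong_event(self):
        out = skipping_antisense(99, 989, 99, 869, 99, 919, 1e6, 1e6)
        assert out["exon_skipping"] and out["antisense_supported"]
        assert out["iso1_fold"] == pytest.approx(9.9)

    def test_below_threshold(self):
        out = skipping_antisense(999, 1199, 999, 1699, 999, 1799, 1e6, 1e6)
        assert not out["exon_skipping"]
        assert not out["antisense_supported"]  # antisense needs skipping

    def test_antisense_requires_both_sites(self):
        out = skipping_antisense(999, 3799, 999, 1699, 999, 1099, 1e6, 1e6)
        assert out["exon_skipping"] and not out["antisense_supported"]

    def test_library_size_normalisation(self):
        # same counts, tumor library twice as deep -> folds halve
        out = skipping_antisense(999, 999, 999, 999, 999, 999, 1e6, 2e6)
        assert out["iso1_fold"] == pytest.approx(0.5)


class TestSummaries:
    def test_explained_summary_reproduces_percentages(self):
        out = explained_summary(dna_explained_counts())
        assert out.loc[out["patient"] == "Breast 1", "percentage"].iloc[0] == 39.4
        total = out[out["patient"] == "Total"].iloc[0]
        assert total["explained"] == 2207 and total["total"] == 6266
        assert total["percentage"] == 35.2

    def test_skipping_summary_reproduces_percentages(self):
        out = skipping_summary(skipping_antisense_counts()).set_index("pattern")
        assert out.loc["P1", "iso1_pct"] == 47.0
        assert out.loc["P1", "iso1_antisense_pct"] == 32.3
        assert out.loc["Total", "iso1_pct"] == 46.3
        assert out.loc["Total", "iso1_antisense_pct"] == 33.0

    def test_zero_explained_patient(self):
        out = explained_summary(
            pd.DataFrame([{"patient": "p", "explained": 0, "total": 10}])
        )
        assert out.loc[0, "percentage"] == 0.0

    def test_mechanism_summary_counts_own_columns(self):
        attr = pd.DataFrame(
            {
                "patient": ["p1"] * 4,
                "pattern": ["P1", "P1", "P4", "P4"],
                "dna_explained": [True, False, True, None],
                "cnv_duplication": [True, False, False, False],
                "methylation_changed": [False] * 4,
                "splice_site_overlap": [False] * 4,
                "exon_skipping": [True, True, False, False],
                "antisense_supported": [True, False, False, False],
            }
        )
        tables = mechanism_summary(attr)
        dna = tables["dna_explained"].set_index("patient")
        assert dna.loc["p1", "explained"] == 2
        assert dna.loc["p1", "total"] == 3  # undetermined excluded
        skipping = tables["skipping"].set_index("pattern")
        assert skipping.loc["P1", "iso1"] == 2
        assert skipping.loc["P1", "iso1_antisense"] == 1
        assert tables["proportions"]["exon_skipping"] == pytest.approx(0.5)

    def test_empty_attributions_rejected(self):
        with pytest.raises(ValueError):
            mechanism_summary(pd.DataFrame())
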