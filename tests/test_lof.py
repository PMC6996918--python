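"""Loss-of-function triage rules and population burden counting."""

import numpy as np
import pandas as pd
import pytest

from aselof import classify_lof, classify_lof_table, intersect_population
from aselof.io import write_vcf


class TestClassifyLof:
    @pytest.mark.parametrize(
        "consequence",
        ["stop_gained", "frameshift_variant", "splice_acceptor_variant",
         "splice_donor_variant", "transcript_ablation", "non-sense"],
    )
    def test_truncating_classes(self, consequence):
        v = classify_lof(consequence)
        assert v.is_lof and v.reason == "truncating-class"

    def test_missense_needs_both_predictors(self):
        both = classify_lof("missense_variant", "deleterious", "probably_damaging")
        assert both.is_lof and both.reason == "missense-concordant-damaging"
        assert classify_lof("missense_variant", "deleterious", "benign").is_lof is False
        assert classify_lof("missense_variant", "tolerated",
                            "probably_damaging").is_lof is False

    def test_possibly_damaging_accepted_by_default_but_configurable(self):
        v = classify_lof("missense_variant", "deleterious", "possibly_damaging")
        assert v.is_lof
        strict = classify_lof("missense_variant", "deleterious",
                              "possibly_damaging",
                              accept_possibly_damaging=False)
        assert not strict.is_lof

    def test_clinvar_benign_overrides_everything(self):
        for consequence in ("stop_gained", "missense_variant", "frameshift"):
            for label in ("benign", "likely_benign", "Likely benign"):
                v = classify_lof(consequence, "deleterious",
                                 "probably_damaging", clinvar=label)
                assert not v.is_lof
                assert v.reason == "clinvar-benign-override"

    def test_synonymous_not_lof(self):
        assert classify_lof("synonymous_variant").is_lof is False

    def test_start_stop_lost_only_in_second_hit_mode(self):
        for term in ("start_lost", "stop_lost"):
            assert classify_lof(term, mode="population").is_lof is False
            assert classify_lof(term, mode="second-hit").is_lof is True

    def test_unknown_vocabulary_warned_not_silent(self, caplog):
        with caplog.at_level("WARNING"):
            v = classify_lof("weird_new_term")
        assert not v.is_lof
        assert "unknown consequence" in caplog.text

    def test_pure_function(self):
        a = classify_lof("stop_gained", "deleterious", "benign", None)
        b = classify_lof("stop_gained", "deleterious", "benign", None)
        assert a == b


def _census(rows):
    return pd.DataFrame(
        rows,
        columns=["contig", "position", "refAllele", "altAllele", "gene",
                 "gene_role", "consequence"],
    )


def _write_population_vcf(path, sites, gts_by_sample):
    samples = sorted(gts_by_sample)
    df = pd.DataFrame(
        sites, columns=["contig", "position", "variantID", "refAllele",
                        "altAllele"]
    )
    df = pd.concat(
        [df, pd.DataFrame({s: gts_by_sample[s] for s in samples})], axis=1
    )
    write_vcf(df, path, samples)
    return path


class TestIntersectPopulation:
    def test_toy_genotype_counts_and_carrier_fraction(self, tmp_path):
        census = _census(
            [("chr1", 100, "A", "T", "TSG1", "TSG", "stop_gained")]
        )
        vcf = _write_population_vcf(
            tmp_path / "pop.vcf",
            [("chr1", 100, "rs1", "A", "T")],
            {"I1": ["0/0"], "I2": ["0/1"], "I3": ["1/1"]},
        )
        res = intersect_population(census, vcf)
        burden = res["burden"].set_index("sample")
        assert burden.loc["I1", ["hom_count", "het_count"]].tolist() == [0, 0]
        assert burden.loc["I2", ["hom_count", "het_count"]].tolist() == [0, 1]
        assert burden.loc["I3", ["hom_count", "het_count"]].tolist() == [1, 0]
        carriers = res["gene_carriers"].set_index("gene")
        assert carriers.loc["TSG1", "carrier_fraction"] == pytest.approx(2 / 3)
        assert res["tsg_distribution"].to_dict() == {0: 1, 1: 2}

    def test_no_overlap_gives_zero_burden(self, tmp_path):
        census = _census(
            [("chr1", 999, "A", "T", "TSG1", "TSG", "stop_gained")]
        )
        vcf = _write_population_vcf(
            tmp_path / "pop.vcf",
            [("chr1", 100, "rs1", "A", "T")],
            {"I1": ["0/1"]},
        )
        res = intersect_population(census, vcf)
        assert res["burden"][["hom_count", "het_count"]].to_numpy().sum() == 0

    def test_exact_allele_match_required(self, tmp_path):
        census = _census(
            [("chr1", 100, "A", "G", "TSG1", "TSG", "stop_gained")]
        )
        vcf = _write_population_vcf(
            tmp_path / "pop.vcf",
            [("chr1", 100, "rs1", "A", "T")],  # same position, other alt
            {"I1": ["1/1"]},
        )
        res = intersect_population(census, vcf)
        assert res["burden"][["hom_count", "het_count"]].to_numpy().sum() == 0

    def test_record_order_invariance(self, tmp_path):
        census = _census(
            [("chr1", 100, "A", "T", "TSG1", "TSG", "stop_gained"),
             ("chr1", 200, "C", "G", "TSG2", "TSG", "frameshift_variant")]
        )
        sites = [("chr1", 100, "rs1", "A", "T"), ("chr1", 200, "rs2", "C", "G")]
        gts = {"I1": ["0/1", "1/1"], "I2": ["0/0", "0/1"]}
        v1 = _write_population_vcf(tmp_path / "a.vcf", sites, gts)
        v2 = _write_population_vcf(
            tmp_path / "b.vcf", sites[::-1],
            {s: g[::-1] for s, g in gts.items()},
        )
        r1 = intersect_population(census, v1)
        r2 = intersect_population(census, v2)
        pd.testing.assert_frame_equal(r1["burden"], r2["burden"])

    def test_hardy_weinberg_carrier_fraction(self, tmp_path):
        """Carrier fractions match 1-(1-q)^2 under Hardy-Weinberg draws."""
        rng = np.random.default_rng(33)
        q = 0.3
        n_ind = 400
        samples = {f"I{i:03d}": [] for i in range(n_ind)}
        for s in samples:
            dose = rng.binomial(2, q)
            samples[s].append({0: "0/0", 1: "0/1", 2: "1/1"}[dose])
        census = _census(
            [("chr1", 100, "A", "T", "TSG1", "TSG", "stop_gained")]
        )
        vcf = _write_population_vcf(
            tmp_path / "hw.vcf", [("chr1", 100, "rs1", "A", "T")], samples
        )
        res = intersect_population(census, vcf)
        frac = res["gene_carriers"]["carrier_fraction"].iloc[0]
        expected = 1 - (1 - q) ** 2
        se = np.sqrt(expected * (1 - expected) / n_ind)
        assert abs(frac - expected) < 3 * se

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n')
            fh.write("##contig=<ID=chr1>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\n")
            fh.write("chr1\t100\trs1\tA\tT,G\t.\tPASS\t.\tGT\t1/2\n")
        census = _census(
            [("chr1", 100, "A", "T", "TSG1", "TSG", "stop_gained")]
        )
        with pytest.raises(Exception):
            intersect_population(census, path)


def test_classify_lof_table_vectorises():
    df = pd.DataFrame(
        {
            "consequence": ["stop_gained", "missense_variant", "synonymous_variant"],
            "sift": [None, "deleterious", None],
            "polyphen": [None, "probably_damaging", None],
            "clinvar": [None, None, None],
        }
    )
    out = classify_lof_table(df)
    assert out["is_lof"].tolist() == [True, True, False]
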