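"""Loss-of-function triage of annotated variants and population burden.

A variant is deleterious (LOF) when it is truncating — nonsense /
frameshift / splice acceptor or donor / whole-gene deletion — or when it
is a missense call predicted deleterious by SIFT *and* damaging by
PolyPhen-2. Any variant labelled benign or likely benign by ClinVar is
excluded regardless. The second-hit analysis uses an extended truncating
set that additionally accepts start-lost and stop-lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

#: Sequence-Ontology synonyms -> canonical consequence term
CONSEQUENCE_SYNONYMS = {
    "non-sense": "stop_gained",
    "nonsense": "stop_gained",
    "stop gained": "stop_gained",
    "frameshift": "frameshift_variant",
    "frame-shift": "frameshift_variant",
    "splice_acceptor": "splice_acceptor_variant",
    "splice acceptor": "splice_acceptor_variant",
    "splice_donor": "splice_donor_variant",
    "splice donor": "splice_donor_variant",
    "whole_gene_deletion": "transcript_ablation",
    "whole gene deletion": "transcript_ablation",
    "start lost": "start_lost",
    "stop lost": "stop_lost",
    "missense": "missense_variant",
}

TRUNCATING_BASE = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "transcript_ablation",
    }
)
#: extended set used when screening for somatic second hits
TRUNCATING_SECOND_HIT = TRUNCATING_BASE | {"start_lost", "stop_lost"}

#: consequence terms that are recognised but never LOF on their own
_KNOWN_NON_LOF = frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "stop_retained_variant",
        "intron_variant",
        "splice_region_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "inframe_deletion",
        "inframe_insertion",
        "start_retained_variant",
        "intergenic_variant",
        "non_coding_transcript_exon_variant",
    }
)

SIFT_DELETERIOUS = ("deleterious", "deleterious_low_confidence")
POLYPHEN_DAMAGING = ("probably_damaging", "possibly_damaging")
CLINVAR_BENIGN = ("benign", "likely_benign", "benign/likely_benign")


@dataclass(frozen=True)
class LofVerdict:
    is_lof: bool
    reason: str  # truncating-class | missense-concordant-damaging |
    #              not-lof | clinvar-benign-override


def normalize_consequence(term: str) -> str:
    t = str(term).strip().lower().replace(" ", "_")
    return CONSEQUENCE_SYNONYMS.get(t, CONSEQUENCE_SYNONYMS.get(str(term).strip().lower(), t))


def classify_lof(
    consequence: str,
    sift: str | None = None,
    polyphen: str | None = None,
    clinvar: str | None = None,
    mode: str = "population",
    accept_possibly_damaging: bool = True,
) -> LofVerdict:
    """Classify one annotated variant as loss-of-function or not.

    ``mode`` selects the truncating set: "population" (base) or
    "second-hit" (adds start_lost / stop_lost). The ClinVar benign /
    likely-benign override dominates every other rule. Unknown consequence
    vocabulary is logged and treated as not-lof, never silently accepted.
    """
    if mode not in ("population", "second-hit"):
        raise ValueError(f"unknown mode {mode!r}")
    if clinvar and str(clinvar).strip().lower().replace(" ", "_") in CLINVAR_BENIGN:
        return LofVerdict(False, "clinvar-benign-override")

    term = normalize_consequence(consequence)
    truncating = (
        TRUNCATING_SECOND_HIT if mode == "second-hit" else TRUNCATING_BASE
    )
    if term in truncating:
        return LofVerdict(True, "truncating-class")
    if term == "missense_variant":
        sift_hit = bool(sift) and str(sift).strip().lower() in SIFT_DELETERIOUS
        damaging = POLYPHEN_DAMAGING if accept_possibly_damaging else (
            "probably_damaging",
        )
        poly_hit = bool(polyphen) and str(polyphen).strip().lower() in damaging
        if sift_hit and poly_hit:
            return LofVerdict(True, "missense-concordant-damaging")
        return LofVerdict(False, "not-lof")
    if term not in _KNOWN_NON_LOF and term not in TRUNCATING_SECOND_HIT:
        log.warning("classify_lof: unknown consequence %r -> not-lof", consequence)
    return LofVerdict(False, "not-lof")


def classify_lof_table(variants: pd.DataFrame, mode: str = "population",
                       accept_possibly_damaging: bool = True) -> pd.DataFrame:
    """Vector version over an annotation table with columns
    consequence / sift / polyphen / clinvar (the latter three optional)."""
    out = variants.copy()
    verdicts = [
        classify_lof(
            row.get("consequence"),
            row.get("sift"),
            row.get("polyphen"),
            row.get("clinvar"),
            mode=mode,
            accept_possibly_damaging=accept_possibly_damaging,
        )
        for _, row in variants.iterrows()
    ]
    out["is_lof"] = [v.is_lof for v in verdicts]
    out["lof_reason"] = [v.reason for v in verdicts]
    return out


def intersect_population(
    census_sites: pd.DataFrame,
    population_vcf,
    mode: str = "population",
) -> dict:
    """Burden of census-site variants across a population VCF.

    Sites are matched on exact (contig, position, refAllele, altAllele).
    Returns a dict with:

    * ``burden`` — per individual: hom/het counts over matched census
      sites and over the LOF subset;
    * ``gene_carriers`` — per gene: carrier fraction (individuals with
      >= 1 LOF allele);
    * ``tsg_distribution`` — individuals by number of distinct LOF-mutated
      TSGs;
    * ``top_genes`` — genes ranked by LOF carrier fraction.

    Multi-allelic VCF records must be decomposed upstream and raise.
    Order of VCF records and samples does not affect the counts.
    """
    from .io import read_vcf_genotypes

    census = classify_lof_table(census_sites, mode=mode)
    gts, samples = read_vcf_genotypes(population_vcf)
    keys = ["contig", "position", "refAllele", "altAllele"]
    merged = gts.merge(
        census[keys + ["gene", "gene_role", "is_lof"]], on=keys, how="inner"
    )
    merged = merged[merged["n_alt"] >= 0]  # drop missing genotypes

    if merged.empty:
        burden = pd.DataFrame(
            {
                "sample": samples,
                "hom_count": 0,
                "het_count": 0,
                "lof_hom": 0,
                "lof_het": 0,
            }
        )
        return {
            "burden": burden,
            "gene_carriers": pd.DataFrame(columns=["gene", "carrier_fraction"]),
            "tsg_distribution": pd.Series(dtype=int),
            "top_genes": pd.DataFrame(columns=["gene", "carrier_fraction"]),
        }

    merged["hom"] = merged["n_alt"] == 2
    merged["het"] = merged["n_alt"] == 1
    burden = (
        merged.groupby("sample")
        .agg(
            hom_count=("hom", "sum"),
            het_count=("het", "sum"),
            lof_hom=("hom", lambda s: int((s & merged.loc[s.index, "is_lof"]).sum())),
            lof_het=("het", lambda s: int((s & merged.loc[s.index, "is_lof"]).sum())),
        )
        .reindex(samples, fill_value=0)
        .reset_index()
        .rename(columns={"index": "sample"})
    )

    lof = merged[merged["is_lof"] & (merged["n_alt"] >= 1)]
    n = len(samples)
    gene_carriers = (
        lof.groupby("gene")["sample"]
        .nunique()
        .div(n)
        .rename("carrier_fraction")
        .reset_index()
        .sort_values("carrier_fraction", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    tsg_lof = lof[lof["gene_role"] == "TSG"]
    per_sample_tsgs = tsg_lof.groupby("sample")["gene"].nunique()
    per_sample_tsgs = per_sample_tsgs.reindex(samples, fill_value=0)
    tsg_distribution = per_sample_tsgs.value_counts().sort_index()
    return {
        "burden": burden,
        "gene_carriers": gene_carriers,
        "tsg_distribution": tsg_distribution,
        "top_genes": gene_carriers.head(10),
    }
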