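"""Knudson two-hit classification per patient x tumor-suppressor gene.

A gene qualifies only when the normal tissue carries a heterozygous LOF
variant. The tumor then provides a second hit as either (in priority
order): the same variant turned homozygous (``same_hom``); a new LOF
variant phased to the opposite haplotype (``compound_het``); or an
overlapping DNA segment with minor copy number 0, i.e. loss of the
remaining allele (``loh``). Tumor-novel LOF candidates without phase
information are reported as ``compound_candidate_unphased`` rather than
asserted, since without phase the new hit could sit on the already-lost
haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

VERDICT_PRIORITY = ("same_hom", "compound_het", "loh",
                    "compound_candidate_unphased", "none")


@dataclass
class SecondHitCall:
    patient: str
    gene: str
    verdict: str
    normal_lof_sites: list[str] = field(default_factory=list)
    evidence: str = ""


def _phase_of(gt: str) -> int | None:
    """Haplotype index carrying the alt allele of a phased het GT, else None."""
    if "|" not in gt:
        return None
    alleles = gt.split("|")
    if sorted(alleles) != ["0", "1"]:
        return None
    return alleles.index("1")


def classify_second_hit(
    normal_gts: pd.DataFrame,
    tumor_gts: pd.DataFrame,
    segments: pd.DataFrame | None,
    lof_table: pd.DataFrame,
    patient: str,
) -> list[SecondHitCall]:
    """Two-hit verdicts for one patient over all genes with a normal LOF het.

    ``normal_gts`` / ``tumor_gts``: long genotype tables (one row per site)
    with columns contig, position, variantID, refAllele, altAllele, gt,
    n_alt and phased. ``lof_table`` maps variantID -> gene, is_lof
    (classified in second-hit mode). ``segments``: tumor copy-number
    segments (contig, start, end, major_cn, minor_cn; 1-based inclusive
    start/end). Any qualifying normal het LOF site triggers the gene's
    verdict; multiple sites are all reported as evidence.
    """
    lof = lof_table[lof_table["is_lof"]]
    n = normal_gts.merge(lof[["variantID", "gene"]], on="variantID", how="inner")
    t = tumor_gts.merge(lof[["variantID", "gene"]], on="variantID", how="inner")
    t_by_id = t.set_index("variantID")
    calls = []
    for gene, n_gene in n.groupby("gene", sort=True):
        n_het = n_gene[n_gene["n_alt"] == 1]
        if n_het.empty:
            continue
        site_ids = sorted(n_het["variantID"])
        t_gene = t[t["gene"] == gene]
        verdict, evidence = "none", ""

        # 1) same variant homozygous in tumor
        for sid in site_ids:
            if sid in t_by_id.index and int(t_by_id.loc[sid, "n_alt"]) == 2:
                verdict, evidence = "same_hom", sid
                break

        # 2) tumor-novel LOF on the opposite haplotype
        if verdict == "none":
            known = set(n_gene["variantID"])
            novel = t_gene[(t_gene["n_alt"] == 1) & ~t_gene["variantID"].isin(known)]
            for sid in site_ids:
                n_row = n_het[n_het["variantID"] == sid].iloc[0]
                normal_phase = _phase_of(str(n_row["gt"]))
                for t_row in novel.itertuples(index=False):
                    t_phase = _phase_of(str(t_row.gt))
                    if normal_phase is None or t_phase is None:
                        verdict = "compound_candidate_unphased"
                        evidence = f"{sid}+{t_row.variantID}"
                    elif t_phase != normal_phase:
                        verdict, evidence = "compound_het", f"{sid}+{t_row.variantID}"
                        break
                if verdict == "compound_het":
                    break

        # 3) loss of the remaining allele (minor copy number 0)
        if verdict in ("none", "compound_candidate_unphased") and segments is not None:
            for sid in site_ids:
                n_row = n_het[n_het["variantID"] == sid].iloc[0]
                pos = int(n_row["position"])
                hit = segments[
                    (segments["contig"].astype(str) == str(n_row["contig"]))
                    & (segments["start"] <= pos)
                    & (pos <= segments["end"])
                    & (segments["minor_cn"] == 0)
                ]
                if len(hit):
                    seg = hit.iloc[0]
                    verdict = "loh"
                    evidence = f"{seg['contig']}:{seg['start']}-{seg['end']}"
                    break

        missing_tumor = [
            sid for sid in site_ids if sid not in t_by_id.index
        ]
        if missing_tumor and verdict == "none":
            log.warning(
                "patient %s gene %s: no tumor genotype at normal LOF site(s) %s",
                patient, gene, missing_tumor,
            )
        calls.append(
            SecondHitCall(
                patient=patient,
                gene=gene,
                verdict=verdict,
                normal_lof_sites=site_ids,
                evidence=evidence,
            )
        )
    return calls


def second_hit_table(calls: list[SecondHitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient": c.patient,
                "gene": c.gene,
                "verdict": c.verdict,
                "normal_lof_sites": ";".join(c.normal_lof_sites),
                "evidence": c.evidence,
            }
            for c in calls
        ],
        columns=["patient", "gene", "verdict", "normal_lof_sites", "evidence"],
    )


def two_hit_rate(calls: pd.DataFrame) -> dict:
    """Fraction of patients with >= 1 affirmative two-hit verdict.

    Unphased compound candidates are not affirmative. Returns the count,
    total, fraction and per-verdict breakdown.
    """
    affirmative = {"same_hom", "compound_het", "loh"}
    patients = calls["patient"].unique()
    hit = (
        calls[calls["verdict"].isin(affirmative)]
        .groupby("patient")
        .size()
        .reindex(patients, fill_value=0)
    )
    n_hit = int((hit > 0).sum())
    n = len(patients)
    return {
        "n_patients": n,
        "n_two_hit": n_hit,
        "fraction": n_hit / n if n else 0.0,
        "by_verdict": calls["verdict"].value_counts().to_dict(),
    }
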