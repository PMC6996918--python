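"""Attribution of ASE changes to candidate molecular mechanisms.

For each ASE locus the module asks, independently and order-invariantly:

* does the tumor DNA show a significant allelic imbalance in the same
  direction as the RNA (copy change / clonal heterogeneity)?
* does an overlapping tumor segment carry an unbalanced duplication
  (total copies > 2, unequal alleles)?
* is the gene an eGene, and is a het eQTL's high-expression allele in
  phase with the over-expressed haplotype (LD r >= 0.42)?
* did gene-level methylation change > 1.3-fold between the tissues?
* does the SNP itself sit in a canonical splice donor/acceptor
  dinucleotide?
* is an exon-skipping isoform (ISO1 split reads) up >= 1.5-fold in the
  tumor, and are antisense reads at both the donor and acceptor of the
  skipped exon up >= 1.5-fold as well?

Fold changes use counts-per-million with a pseudocount of 1 so zero
counts stay finite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._util import round_half_up
from .ase import exact_binom_p
from .config import FilterConfig, Thresholds

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Individual mechanism checks

def dna_concordance(
    rna_ref: int,
    rna_alt: int,
    dna_ref: int,
    dna_alt: int,
    alpha: float = 0.05,
    min_dna_depth: int = 8,
) -> bool | None:
    """Is the RNA imbalance explained by the DNA allele counts?

    True when the DNA counts depart from 0.5 significantly (exact two-sided
    binomial, p < alpha) *and* skew toward the same allele as the RNA.
    DNA depth below the genotyping minimum returns None (undetermined,
    excluded from denominators).
    """
    n_dna = dna_ref + dna_alt
    if n_dna < min_dna_depth:
        return None
    n_rna = rna_ref + rna_alt
    if n_rna == 0:
        return None
    p = exact_binom_p(dna_ref, n_dna, 0.5)
    if p >= alpha:
        return False
    dna_dir = 1 if dna_ref / n_dna > 0.5 else -1
    rna_dir = 1 if rna_ref / n_rna > 0.5 else (-1 if rna_ref / n_rna < 0.5 else 0)
    return bool(dna_dir == rna_dir)


def cnv_duplication_check(
    contig: str, position: int, segments: pd.DataFrame
) -> bool:
    """Unbalanced copy-number duplication overlapping the locus?

    True when an overlapping tumor segment has total copy number > 2 with
    unequal major/minor copies. Segments use 1-based inclusive start/end.
    """
    if segments is None or segments.empty:
        return False
    hit = segments[
        (segments["contig"].astype(str) == str(contig))
        & (segments["start"] <= position)
        & (position <= segments["end"])
    ]
    if hit.empty:
        log.info("cnv_duplication_check: no segment overlaps %s:%d",
                 contig, position)
        return False
    total = hit["major_cn"] + hit["minor_cn"]
    return bool(((total > 2) & (hit["major_cn"] != hit["minor_cn"])).any())


def eqtl_attribution(
    overexpressed_haplotype: str,
    eqtls: pd.DataFrame,
    genotypes: dict[str, int] | None = None,
    ld_r: dict[str, float] | None = None,
    r_min: float = 0.42,
) -> tuple[bool, bool | None]:
    """(eGene flag, eQTL-in-phase flag) for one gene.

    ``overexpressed_haplotype`` is the gene's pseudo-phased label
    ("reference" | "alternative" | "ambiguous"). ``eqtls`` holds the
    gene's eQTL records (columns variant, slope); ``genotypes`` maps
    variant -> alt allele count for this patient; ``ld_r`` maps variant ->
    linkage-disequilibrium r with the ASE SNP. In-phase requires a het
    eQTL whose high-expression allele (alt when slope > 0) matches the
    over-expressed haplotype, with r >= r_min; missing LD information
    leaves the phase flag undetermined (None).
    """
    egene = eqtls is not None and len(eqtls) > 0
    if not egene:
        return False, False
    if overexpressed_haplotype not in ("reference", "alternative"):
        return True, False
    over_allele = "alt" if overexpressed_haplotype == "alternative" else "ref"
    genotypes = genotypes or {}
    ld_r = ld_r or {}
    undetermined = False
    for rec in eqtls.itertuples(index=False):
        if genotypes.get(rec.variant) != 1:  # needs a het eQTL
            continue
        high_allele = "alt" if rec.slope > 0 else "ref"
        if high_allele != over_allele:
            continue
        r = ld_r.get(rec.variant)
        if r is None:
            undetermined = True
            continue
        if r >= r_min:
            return True, True
    return True, (None if undetermined else False)


def methylation_change(
    normal_value: float | None,
    tumor_value: float | None,
    fold_min: float = 1.3,
) -> bool | None:
    """Did methylation change more than ``fold_min`` in either direction?"""
    if normal_value is None or tumor_value is None:
        return None
    if not np.isfinite(normal_value) or not np.isfinite(tumor_value):
        return None
    if normal_value <= 0 or tumor_value <= 0:
        return None
    fold = max(tumor_value / normal_value, normal_value / tumor_value)
    return bool(fold > fold_min)


def splice_dinucleotides(exons: pd.DataFrame) -> pd.DataFrame:
    """Canonical splice-site dinucleotide positions for a per-exon table.

    ``exons``: flattened exon intervals (gene, contig, strand, exon_index,
    start, end; 0-based half-open). For each intron the two intronic bases
    at each end are returned with their role: on the + strand the
    genomically left pair is the donor (GT) and the right pair the
    acceptor (AG); on the - strand the roles mirror.
    """
    rows = []
    for (gene, contig, strand), grp in exons.groupby(
        ["gene", "contig", "strand"], sort=False
    ):
        grp = grp.sort_values("start")
        bounds = list(zip(grp["end"].iloc[:-1], grp["start"].iloc[1:]))
        for intron_start0, intron_end0 in bounds:  # 0-based half-open intron
            left = [intron_start0 + 1, intron_start0 + 2]  # 1-based
            right = [intron_end0 - 1, intron_end0]
            left_role = "donor" if strand == "+" else "acceptor"
            right_role = "acceptor" if strand == "+" else "donor"
            for pos in left:
                rows.append({"gene": gene, "contig": contig, "position": pos,
                             "role": left_role})
            for pos in right:
                rows.append({"gene": gene, "contig": contig, "position": pos,
                             "role": right_role})
    return pd.DataFrame(rows, columns=["gene", "contig", "position", "role"])


def splice_site_overlap(
    contig: str, position: int, exons: pd.DataFrame
) -> bool:
    """Does the SNP fall in a canonical donor/acceptor dinucleotide?"""
    dinucs = splice_dinucleotides(exons)
    if dinucs.empty:
        return False
    return bool(
        (
            (dinucs["contig"].astype(str) == str(contig))
            & (dinucs["position"] == position)
        ).any()
    )


def cpm(count: float, library_size: float, pseudocount: float = 1.0) -> float:
    return (count + pseudocount) / library_size * 1e6


def skipping_antisense(
    iso1_normal: float,
    iso1_tumor: float,
    donor_as_normal: float,
    donor_as_tumor: float,
    acceptor_as_normal: float,
    acceptor_as_tumor: float,
    lib_normal: float,
    lib_tumor: float,
    fold_min: float = 1.5,
    antisense_fold_min: float = 1.5,
) -> dict:
    """Exon-skipping and antisense-support flags for one splice event.

    All counts are CPM-normalised with pseudocount 1 before folds are
    taken. ``exon_skipping`` requires tumor/normal ISO1 fold >= 1.5;
    ``antisense_supported`` additionally requires both the donor and the
    acceptor antisense folds >= 1.5 (antisense is only interpreted at
    skipping events).
    """
    iso_fold = cpm(iso1_tumor, lib_tumor) / cpm(iso1_normal, lib_normal)
    donor_fold = cpm(donor_as_tumor, lib_tumor) / cpm(donor_as_normal, lib_normal)
    acceptor_fold = cpm(acceptor_as_tumor, lib_tumor) / cpm(
        acceptor_as_normal, lib_normal
    )
    skipping = bool(iso_fold >= fold_min)
    supported = bool(
        skipping
        and donor_fold >= antisense_fold_min
        and acceptor_fold >= antisense_fold_min
    )
    return {
        "exon_skipping": skipping,
        "antisense_supported": supported,
        "iso1_fold": float(iso_fold),
        "antisense_donor_fold": float(donor_fold),
        "antisense_acceptor_fold": float(acceptor_fold),
    }


# ---------------------------------------------------------------------------
# Cohort driver

def attribute_sites(
    classified: pd.DataFrame,
    dna_counts: pd.DataFrame | None = None,
    segments: pd.DataFrame | None = None,
    isoform_counts: pd.DataFrame | None = None,
    antisense_counts: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
    thresholds: Thresholds | None = None,
    filter_cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Mechanism flags for every site with a P1..P6 pattern call.

    ``classified`` is the per-patient output of
    :func:`aselof.patterns.classify_pairs` with ``patient`` and ``gene``
    columns. DNA concordance compares tumor RNA with tumor DNA counts
    matched on variantID. Flags that cannot be evaluated are left as
    missing rather than False where the check itself was impossible.
    """
    th = thresholds or Thresholds()
    fc = filter_cfg or FilterConfig()
    ase_sites = classified[classified["pattern"].isin(
        ["P1", "P2", "P3", "P4", "P5", "P6"]
    )].copy()
    if ase_sites.empty:
        return ase_sites

    dna_idx = None
    if dna_counts is not None and not dna_counts.empty:
        dna_idx = dna_counts.set_index(["sample", "variantID"])
    iso_idx = None
    if isoform_counts is not None and not isoform_counts.empty:
        iso_idx = isoform_counts.set_index(["gene", "sample"]).sort_index()
    as_idx = None
    if antisense_counts is not None and not antisense_counts.empty:
        as_idx = antisense_counts.set_index(["event_id", "sample"]).sort_index()
    meth_idx = None
    if methylation is not None and not methylation.empty:
        meth_idx = methylation.set_index(["gene", "sample"]).sort_index()
    exon_dinucs = None
    if exons is not None and not exons.empty:
        exon_dinucs = splice_dinucleotides(exons)

    rows = []
    for site in ase_sites.itertuples(index=False):
        patient = site.patient
        tumor_sample, normal_sample = f"{patient}-T", f"{patient}-N"
        rec = {
            "patient": patient,
            "variantID": site.variantID,
            "gene": getattr(site, "gene", ""),
            "pattern": site.pattern,
        }

        explained = None
        if dna_idx is not None and (tumor_sample, site.variantID) in dna_idx.index:
            d = dna_idx.loc[(tumor_sample, site.variantID)]
            explained = dna_concordance(
                site.refCount_tumor,
                site.altCount_tumor,
                int(d["refCount"]),
                int(d["altCount"]),
                alpha=th.dna_p,
                min_dna_depth=fc.gt_min_depth,
            )
        rec["dna_explained"] = explained

        rec["cnv_duplication"] = (
            cnv_duplication_check(
                site.contig, site.position,
                segments[segments["sample"] == tumor_sample]
                if segments is not None else None,
            )
            if segments is not None
            else None
        )

        meth_flag = None
        if meth_idx is not None:
            try:
                mn = float(meth_idx.loc[(rec["gene"], normal_sample), "value"])
                mt = float(meth_idx.loc[(rec["gene"], tumor_sample), "value"])
                meth_flag = methylation_change(mn, mt, th.methylation_fold_min)
            except KeyError:
                pass
        rec["methylation_changed"] = meth_flag

        splice_flag = None
        if exon_dinucs is not None:
            splice_flag = bool(
                (
                    (exon_dinucs["contig"].astype(str) == str(site.contig))
                    & (exon_dinucs["position"] == site.position)
                ).any()
            )
        rec["splice_site_overlap"] = splice_flag

        skip = {
            "exon_skipping": None,
            "antisense_supported": None,
            "iso1_fold": np.nan,
            "antisense_donor_fold": np.nan,
            "antisense_acceptor_fold": np.nan,
        }
        if iso_idx is not None:
            try:
                iso_n = iso_idx.loc[(rec["gene"], normal_sample)]
                iso_t = iso_idx.loc[(rec["gene"], tumor_sample)]
                iso_n = iso_n.iloc[0] if isinstance(iso_n, pd.DataFrame) else iso_n
                iso_t = iso_t.iloc[0] if isinstance(iso_t, pd.DataFrame) else iso_t
                event = iso_n["event_id"]
                as_n = as_idx.loc[(event, normal_sample)] if as_idx is not None else None
                as_t = as_idx.loc[(event, tumor_sample)] if as_idx is not None else None
                if as_n is not None:
                    skip = skipping_antisense(
                        iso_n["iso1_count"], iso_t["iso1_count"],
                        as_n["donor_antisense"], as_t["donor_antisense"],
                        as_n["acceptor_antisense"], as_t["acceptor_antisense"],
                        iso_n["library_size"], iso_t["library_size"],
                        fold_min=th.skip_fold_min,
                        antisense_fold_min=th.antisense_fold_min,
                    )
            except KeyError:
                log.info("no splice event for gene %s patient %s",
                         rec["gene"], patient)
        rec.update(skip)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Printed-table style summaries

def explained_summary(per_patient: pd.DataFrame) -> pd.DataFrame:
    """DNA-explained tally per patient with a Total row.

    ``per_patient`` needs columns patient, explained, total; the
    percentage column is recomputed from the counts, rounded half-up to
    one decimal.
    """
    out = per_patient[["patient", "explained", "total"]].copy()
    total_row = pd.DataFrame(
        [{
            "patient": "Total",
            "explained": out["explained"].sum(),
            "total": out["total"].sum(),
        }]
    )
    out = pd.concat([out, total_row], ignore_index=True)
    out["percentage"] = [
        round_half_up(100.0 * e / t, 1) if t else float("nan")
        for e, t in zip(out["explained"], out["total"])
    ]
    return out


def skipping_summary(per_pattern: pd.DataFrame) -> pd.DataFrame:
    """Exon-skipping / antisense tally per pattern with a Total row.

    ``per_pattern`` needs columns pattern, total, iso1, iso1_antisense.
    Both percentage columns are fractions of the pattern's total ASE
    SNPs, rounded half-up to one decimal.
    """
    out = per_pattern[["pattern", "total", "iso1", "iso1_antisense"]].copy()
    total_row = pd.DataFrame(
        [{
            "pattern": "Total",
            "total": out["total"].sum(),
            "iso1": out["iso1"].sum(),
            "iso1_antisense": out["iso1_antisense"].sum(),
        }]
    )
    out = pd.concat([out, total_row], ignore_index=True)
    out["iso1_pct"] = [
        round_half_up(100.0 * i / t, 1) if t else float("nan")
        for i, t in zip(out["iso1"], out["total"])
    ]
    out["iso1_antisense_pct"] = [
        round_half_up(100.0 * a / t, 1) if t else float("nan")
        for a, t in zip(out["iso1_antisense"], out["total"])
    ]
    return out


def mechanism_summary(attributions: pd.DataFrame) -> dict:
    """Cohort summaries of the mechanism attributions.

    Returns ``dna_explained`` (per-patient tally), ``skipping`` (per-pattern
    tally) and ``proportions`` (fraction of evaluable ASE loci flagged per
    mechanism).
    """
    if attributions is None or attributions.empty:
        raise ValueError("mechanism_summary needs a non-empty attribution table")
    det = attributions[attributions["dna_explained"].notna()]
    per_patient = (
        det.groupby("patient")
        .agg(
            explained=("dna_explained", lambda s: int(s.astype(bool).sum())),
            total=("dna_explained", "size"),
        )
        .reset_index()
    )
    per_pattern_rows = []
    for pattern in ("P1", "P2", "P3", "P4", "P5", "P6"):
        sub = attributions[attributions["pattern"] == pattern]
        if sub.empty:
            continue
        per_pattern_rows.append(
            {
                "pattern": pattern,
                "total": len(sub),
                "iso1": int(sub["exon_skipping"].eq(True).sum()),
                "iso1_antisense": int(sub["antisense_supported"].eq(True).sum()),
            }
        )
    proportions = {}
    for flag in (
        "dna_explained",
        "cnv_duplication",
        "methylation_changed",
        "splice_site_overlap",
        "exon_skipping",
        "antisense_supported",
    ):
        if flag in attributions.columns:
            known = attributions[attributions[flag].notna()]
            proportions[flag] = (
                float(known[flag].astype(bool).mean()) if len(known) else float("nan")
            )
    return {
        "dna_explained": explained_summary(per_patient)
        if len(per_patient)
        else pd.DataFrame(columns=["patient", "explained", "total", "percentage"]),
        "skipping": skipping_summary(pd.DataFrame(per_pattern_rows))
        if per_pattern_rows
        else pd.DataFrame(
            columns=["pattern", "total", "iso1", "iso1_antisense",
                     "iso1_pct", "iso1_antisense_pct"]
        ),
        "proportions": proportions,
    }
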