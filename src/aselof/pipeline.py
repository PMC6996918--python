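"""End-to-end orchestration of the paired-cohort ASE analysis.

Stage order: filter RNA counts -> fit per-sample mapping-bias models ->
SNP-level ASE calls (per-sample FDR) -> paired normal/tumor pattern
classification -> gene-level pseudo-phased ASE -> DNA genotyping and
two-hit classification -> mechanism attribution -> cohort summaries and
the normal-vs-tumor Mann-Whitney comparison of per-sample ASE
proportions. A run manifest records the package version, seed,
thresholds and input checksums; identical config and seed reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .ase import ase_calls, gene_ase_table, proportion_ase
from .config import ConfigError, FilterConfig, Thresholds, thresholds_dict
from .counts import call_genotypes, filter_sites, fit_bias_model
from .io import (
    bed12_exons,
    read_bed12,
    read_counts,
    read_mapability_bed,
    read_tsv,
    read_vcf_genotypes,
    write_tsv,
)
from .lof import classify_lof_table
from .mechanisms import attribute_sites, mechanism_summary
from .patterns import classify_pairs, pattern_table
from .second_hit import classify_second_hit, second_hit_table, two_hit_rate

log = logging.getLogger(__name__)


def compare_groups(
    normal_proportions, tumor_proportions, paired: bool = False
) -> tuple[float, float]:
    """Mann-Whitney U comparison of per-sample ASE proportions.

    Two-sided and unpaired by default (the convention for comparing the
    two distributions); ``paired=True`` switches to the Wilcoxon
    signed-rank test for the matched design. Returns (statistic, p).
    """
    x = np.asarray(normal_proportions, dtype=float)
    y = np.asarray(tumor_proportions, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ConfigError("compare_groups needs >= 2 proportions per group")
    if paired:
        if len(x) != len(y):
            raise ConfigError("paired comparison needs equal-length vectors")
        if np.allclose(x, y):
            return 0.0, 1.0
        res = stats.wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def assign_genes(counts: pd.DataFrame, exons_bed12: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``gene`` column by locating each site inside a gene span."""
    spans = exons_bed12[["contig", "start", "end", "name"]]
    out = counts.copy()
    genes = pd.Series(pd.NA, index=out.index, dtype=object)
    for rec in spans.itertuples(index=False):
        mask = (
            (out["contig"].astype(str) == str(rec.contig))
            & (out["position"] > rec.start)
            & (out["position"] <= rec.end)
        )
        genes[mask] = rec.name
    out["gene"] = genes
    return out


@dataclass
class RunConfig:
    """File-based pipeline configuration (paths + threshold overrides)."""

    rna_counts: str
    dna_counts: str | None = None
    genotype_vcf: str | None = None
    exons_bed12: str | None = None
    mapability_bed: str | None = None
    segments: str | None = None
    isoform_counts: str | None = None
    antisense_counts: str | None = None
    methylation: str | None = None
    annotations: str | None = None
    outdir: str = "aselof_out"
    seed: int = 0
    n_mc: int = 10_000
    log_level: str = "INFO"
    thresholds: Thresholds = field(default_factory=Thresholds)
    filters: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = Thresholds(**raw.pop("thresholds", {}))
        fc = FilterConfig(**raw.pop("filters", {}))
        return cls(thresholds=th, filters=fc, **raw)

    def validate(self) -> None:
        if not Path(self.rna_counts).exists():
            raise ConfigError(f"missing input {self.rna_counts}")
        for name in (
            "dna_counts", "genotype_vcf", "exons_bed12", "mapability_bed",
            "segments", "isoform_counts", "antisense_counts", "methylation",
            "annotations",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"missing input {name}: {p}")
        self.thresholds.validate()
        self.filters.validate()


@dataclass
class PipelineResult:
    ase_calls: pd.DataFrame
    bias_models: dict
    classified: pd.DataFrame
    pattern_summary: pd.DataFrame
    gene_ase: pd.DataFrame
    proportions: pd.DataFrame
    comparison: dict
    second_hits: pd.DataFrame
    two_hit: dict
    attributions: pd.DataFrame
    mechanism_tables: dict
    rejections: pd.DataFrame
    manifest: dict


def _split_patient(sample: str) -> tuple[str, str] | None:
    """'P001-N' -> ('P001', 'N'); None when the suffix is missing."""
    if "-" in sample and sample.rsplit("-", 1)[1] in ("N", "T"):
        patient, tissue = sample.rsplit("-", 1)
        return patient, tissue
    return None


def run_tables(
    rna_counts: pd.DataFrame,
    dna_counts: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
    mapability: pd.DataFrame | None = None,
    segments: pd.DataFrame | None = None,
    isoform_counts: pd.DataFrame | None = None,
    antisense_counts: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    thresholds: Thresholds | None = None,
    filters: FilterConfig | None = None,
    n_mc: int = 10_000,
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on in-memory tables (the library entry point).

    ``genotypes`` is a long genotype table (site x patient rows with gt and
    n_alt), e.g. from :func:`aselof.io.read_vcf_genotypes`.
    """
    th = thresholds or Thresholds()
    fc = filters or FilterConfig()
    th.validate()
    fc.validate()

    filtered, rejections = filter_sites(rna_counts, fc, mapability)
    if exons is not None and "gene" not in filtered.columns:
        filtered = assign_genes(filtered, exons)

    bias_models = fit_bias_model(filtered, pooled=False)
    calls = []
    for sample, grp in filtered.groupby("sample", sort=True):
        calls.append(ase_calls(grp, bias_models[sample], th))
    calls = pd.concat(calls, ignore_index=True)

    # per-sample ASE proportions and the normal/tumor comparison
    prop_rows = []
    for sample, grp in calls.groupby("sample", sort=True):
        split = _split_patient(sample)
        prop_rows.append(
            {
                "sample": sample,
                "patient": split[0] if split else sample,
                "tissue": split[1] if split else "",
                "n_sites": len(grp),
                "proportion_ase": proportion_ase(grp),
            }
        )
    proportions = pd.DataFrame(prop_rows)
    comparison = {}
    normal = proportions.loc[proportions["tissue"] == "N", "proportion_ase"]
    tumor = proportions.loc[proportions["tissue"] == "T", "proportion_ase"]
    if len(normal) >= 2 and len(tumor) >= 2:
        u, p = compare_groups(normal, tumor)
        comparison = {
            "u_statistic": u,
            "p_value": p,
            "normal_mean": float(normal.mean()),
            "tumor_mean": float(tumor.mean()),
        }

    # paired pattern classification
    classified_parts = []
    patients = sorted(
        {r["patient"] for r in prop_rows if r["tissue"] in ("N", "T")}
    )
    for patient in patients:
        n = calls[calls["sample"] == f"{patient}-N"]
        t = calls[calls["sample"] == f"{patient}-T"]
        if n.empty or t.empty:
            continue
        pairs = classify_pairs(n, t, th)
        pairs["patient"] = patient
        classified_parts.append(pairs)
    classified = (
        pd.concat(classified_parts, ignore_index=True)
        if classified_parts
        else pd.DataFrame()
    )
    pattern_summary = (
        pattern_table(classified) if len(classified) else pd.DataFrame()
    )

    if "gene" in filtered.columns:
        gene_table = gene_ase_table(
            filtered.dropna(subset=["gene"]),
            bias=bias_models,
            n_mc=n_mc,
            seed=seed,
            thresholds=th,
        )
    else:
        gene_table = pd.DataFrame()

    # second hits (needs genotypes; annotations restrict to LOF variants)
    second = pd.DataFrame(columns=["patient", "gene", "verdict",
                                   "normal_lof_sites", "evidence"])
    two_hit = {}
    if genotypes is not None and dna_counts is not None and exons is not None:
        if annotations is not None:
            lof_tab = classify_lof_table(annotations, mode="second-hit")
        else:
            log.info("no annotation table: treating every het site as a "
                     "candidate LOF variant for the two-hit screen")
            lof_tab = assign_genes(
                genotypes.drop_duplicates("variantID"), exons
            )[["variantID", "gene"]].assign(is_lof=True)
        tumor_dna = dna_counts[
            dna_counts["sample"].str.endswith("-T")
        ] if "sample" in dna_counts.columns else dna_counts
        gt_calls = call_genotypes(tumor_dna, fc)
        gt_calls = gt_calls[gt_calls["genotype"] != "no-call"].copy()
        gt_calls["n_alt"] = gt_calls["genotype"].map(
            {"hom-ref": 0, "het": 1, "hom-alt": 2}
        )
        gt_calls["gt"] = gt_calls["genotype"].map(
            {"hom-ref": "0/0", "het": "0/1", "hom-alt": "1/1"}
        )
        all_calls = []
        for patient in patients:
            n_gts = genotypes[genotypes["sample"] == patient]
            if n_gts.empty:
                continue
            t_gts = gt_calls[gt_calls["sample"] == f"{patient}-T"]
            segs = (
                segments[segments["sample"] == f"{patient}-T"]
                if segments is not None
                else None
            )
            all_calls.extend(
                classify_second_hit(n_gts, t_gts, segs, lof_tab, patient)
            )
        second = second_hit_table(all_calls)
        if len(second):
            two_hit = two_hit_rate(second)

    attributions = pd.DataFrame()
    mech_tables = {}
    if len(classified):
        attributions = attribute_sites(
            classified,
            dna_counts=dna_counts,
            segments=segments,
            isoform_counts=isoform_counts,
            antisense_counts=antisense_counts,
            methylation=methylation,
            exons=bed12_exons(exons) if exons is not None else None,
            thresholds=th,
            filter_cfg=fc,
        )
        if len(attributions) and attributions["dna_explained"].notna().any():
            mech_tables = mechanism_summary(attributions)

    manifest = {
        "package": "aselof",
        "version": __version__,
        "seed": seed,
        "n_mc": n_mc,
        "thresholds": thresholds_dict(th),
    }
    return PipelineResult(
        ase_calls=calls,
        bias_models=bias_models,
        classified=classified,
        pattern_summary=pattern_summary,
        gene_ase=gene_table,
        proportions=proportions,
        comparison=comparison,
        second_hits=second,
        two_hit=two_hit,
        attributions=attributions,
        mechanism_tables=mech_tables,
        rejections=rejections,
        manifest=manifest,
    )


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based pipeline run; writes result tables and a JSON manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    def opt(path, reader):
        return reader(path) if path else None

    rna = read_counts(config.rna_counts)
    dna = opt(config.dna_counts, read_counts)
    exons = opt(config.exons_bed12, read_bed12)
    mapability = opt(config.mapability_bed, read_mapability_bed)
    segments = opt(config.segments, read_tsv)
    iso = opt(config.isoform_counts, read_tsv)
    anti = opt(config.antisense_counts, read_tsv)
    meth = opt(config.methylation, read_tsv)
    annotations = opt(config.annotations, read_tsv)
    genotypes = None
    if config.genotype_vcf:
        genotypes_df, _ = read_vcf_genotypes(config.genotype_vcf)
        genotypes = genotypes_df
    if dna is None:
        log.info("no DNA counts supplied: DNA-dependent stages are skipped")

    result = run_tables(
        rna, dna, genotypes, exons, mapability, segments, iso, anti, meth,
        annotations, config.thresholds, config.filters,
        n_mc=config.n_mc, seed=config.seed,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(result.ase_calls, outdir / "ase_calls.tsv")
    write_tsv(result.classified, outdir / "patterns.tsv")
    if len(result.pattern_summary):
        result.pattern_summary.to_csv(outdir / "pattern_summary.csv")
    write_tsv(result.gene_ase, outdir / "gene_ase.tsv")
    write_tsv(result.proportions, outdir / "proportions.tsv")
    write_tsv(result.second_hits, outdir / "second_hits.tsv")
    write_tsv(result.attributions, outdir / "mechanisms.tsv")
    for name, table in result.mechanism_tables.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(outdir / f"mechanism_{name}.csv", index=False)
    write_tsv(result.rejections, outdir / "rejected_sites.tsv")

    manifest = dict(result.manifest)
    manifest["inputs"] = {
        name: {"path": str(p), "sha256": _checksum(p)}
        for name, p in (
            ("rna_counts", config.rna_counts),
            ("dna_counts", config.dna_counts),
            ("genotype_vcf", config.genotype_vcf),
            ("exons_bed12", config.exons_bed12),
            ("mapability_bed", config.mapability_bed),
            ("segments", config.segments),
            ("isoform_counts", config.isoform_counts),
            ("antisense_counts", config.antisense_counts),
            ("methylation", config.methylation),
            ("annotations", config.annotations),
        )
        if p
    }
    manifest["comparison"] = result.comparison
    manifest["two_hit"] = result.two_hit
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    result.manifest = manifest
    return result
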