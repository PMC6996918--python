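"""Paired normal/tumor cohort simulator with planted ASE truth.

Emulates the statistical structure the downstream analysis assumes:

* germline het SNP panel shared by all patients, one gene model per gene
  (three exons on alternating strands), SNPs placed mid-exon;
* RNA read counts binomial at the planted allele ratio composed with a
  per-nucleotide-pair reference-mapping bias (odds multiplication, so a
  balanced locus reads out exactly the pair's p0 and the bias-model
  estimator can recover it);
* DNA read counts binomial at 0.5, except tumor DNA of copy-driven loci,
  which follows the planted copy state (major 3 / minor 1, oriented
  toward the over-expressed allele);
* exon-skipping loci get tumor split-read (ISO1) counts scaled by a
  planted fold >= 2 and antisense donor/acceptor counts scaled by
  ``antisense_coupling x fold``;
* every locus carries exactly one truth record (pattern, mechanism,
  planted ratios).

All randomness flows from ``SimConfig.seed`` through a documented
splittable-stream order: root -> [layout, patient_1, ..., patient_N];
each patient stream is split per gene. Adding genes or patients never
perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    ConfigError,
    DepthModel,
    NUCLEOTIDE_PAIRS,
    SimConfig,
)
from .io import COUNT_COLUMNS, write_bed12, write_counts, write_tsv, write_vcf
from .patterns import PATTERN_STATES

STATE_RATIO = {"BAL": 0.5}  # REF/ALT filled per config at run time

#: copy state planted at copy-driven loci (total 4, unequal alleles)
CNV_MAJOR, CNV_MINOR = 3, 1


def compose_bias(ratio, p0):
    """Compose a true allele ratio with a mapping bias by odds multiplication.

    ``odds_obs = odds(ratio) * odds(p0)``; a balanced locus (ratio 0.5)
    therefore reads out exactly ``p0``.
    """
    ratio = np.asarray(ratio, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    num = ratio * p0
    return num / (num + (1.0 - ratio) * (1.0 - p0))


def _state_ratio(state: str, effect_ratio: float) -> float:
    if state == "BAL":
        return 0.5
    if state == "REF":
        return effect_ratio
    if state == "ALT":
        return 1.0 - effect_ratio
    raise ValueError(f"unknown state {state!r}")


@dataclass
class CohortBundle:
    """In-memory result of :func:`simulate_cohort`."""

    config: SimConfig
    rna_counts: pd.DataFrame
    dna_counts: pd.DataFrame
    genotypes: pd.DataFrame
    patients: list[str]
    exons: pd.DataFrame  # BED12 rows
    isoform_counts: pd.DataFrame
    antisense_counts: pd.DataFrame
    segments: pd.DataFrame
    methylation: pd.DataFrame
    truth: pd.DataFrame

    def write_dir(self, outdir, phased: bool = True) -> dict[str, Path]:
        """Write every table in its interchange format; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rna_counts": outdir / "rna_counts.tsv",
            "dna_counts": outdir / "dna_counts.tsv",
            "genotypes": outdir / "genotypes.vcf",
            "exons": outdir / "exons.bed12",
            "isoform_counts": outdir / "isoform_counts.tsv",
            "antisense_counts": outdir / "antisense_counts.tsv",
            "segments": outdir / "segments.tsv",
            "methylation": outdir / "methylation.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_counts(self.rna_counts, paths["rna_counts"])
        write_counts(self.dna_counts, paths["dna_counts"])
        write_vcf(self.genotypes, paths["genotypes"], self.patients, phased=phased)
        write_bed12(self.exons, paths["exons"])
        write_tsv(self.isoform_counts, paths["isoform_counts"])
        write_tsv(self.antisense_counts, paths["antisense_counts"])
        write_tsv(self.segments, paths["segments"])
        write_tsv(self.methylation, paths["methylation"])
        write_tsv(self.truth, paths["truth"])
        return paths


def _build_layout(cfg: SimConfig, layout_ss: np.random.SeedSequence):
    """Gene models and the shared SNP panel (one stream per gene)."""
    gene_ss = layout_ss.spawn(cfg.n_genes)
    pairs = np.array(NUCLEOTIDE_PAIRS)
    genes, snps, bed_rows = [], [], []
    exon_len, intron_len, n_exons = 200, 300, 3
    span = n_exons * exon_len + (n_exons - 1) * intron_len
    for g in range(cfg.n_genes):
        rng = np.random.default_rng(gene_ss[g])
        name = f"g{g + 1:04d}"
        start = 10_000 + g * (span + 2_000)  # 0-based
        strand = "+" if g % 2 == 0 else "-"
        n_snps = int(rng.integers(cfg.snps_per_gene[0], cfg.snps_per_gene[1] + 1))
        exon_starts = [start + i * (exon_len + intron_len) for i in range(n_exons)]
        bed_rows.append(
            {
                "contig": "chr1",
                "start": start,
                "end": start + span,
                "name": name,
                "score": 0,
                "strand": strand,
                "thickStart": start,
                "thickEnd": start + span,
                "itemRgb": "0,0,0",
                "blockCount": n_exons,
                "blockSizes": ",".join([str(exon_len)] * n_exons),
                "blockStarts": ",".join(str(s - start) for s in exon_starts),
            }
        )
        genes.append({"gene": name, "start": start, "end": start + span,
                      "strand": strand})
        # SNPs strictly inside exons, away from splice dinucleotides
        exon_idx = rng.integers(0, n_exons, size=n_snps)
        offsets = rng.integers(10, exon_len - 10, size=n_snps)
        chosen = rng.choice(len(pairs), size=n_snps)
        positions = sorted(
            int(exon_starts[e] + off) + 1  # 1-based
            for e, off in zip(exon_idx, offsets)
        )
        for j, pos in enumerate(positions):
            pair = pairs[chosen[j]]
            ref, alt = pair.split(">")
            snps.append(
                {
                    "contig": "chr1",
                    "position": pos,
                    "variantID": f"snp_{name}_{j + 1}",
                    "refAllele": ref,
                    "altAllele": alt,
                    "gene": name,
                }
            )
    return pd.DataFrame(genes), pd.DataFrame(snps), pd.DataFrame(bed_rows)


def simulate_cohort(cfg: SimConfig) -> CohortBundle:
    """Generate a full paired cohort with truth labels.

    Per patient x gene a pattern is drawn from ``pattern_mix``; loci whose
    tumor state is imbalanced draw a mechanism from {cnv, skipping+antisense,
    pure-regulatory} with weights (cnv_fraction, skip_fraction, remainder);
    tumor-balanced ASE patterns (P2, P5) are pure-regulatory; no-change loci
    have mechanism none.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_patients + 1)
    genes, snps, bed = _build_layout(cfg, children[0])

    labels = sorted(cfg.pattern_mix)
    probs = np.array([cfg.pattern_mix[c] for c in labels])
    probs = probs / probs.sum()
    mech_labels = np.array(["cnv", "skipping+antisense", "pure-regulatory"])
    mech_probs = np.array(
        [cfg.cnv_fraction, cfg.skip_fraction,
         1.0 - cfg.cnv_fraction - cfg.skip_fraction]
    )

    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    count_rows, iso_rows, as_rows, seg_rows, meth_rows, truth_rows = (
        [], [], [], [], [], []
    )
    gt = snps.drop(columns="gene").copy()

    for p_idx, patient in enumerate(patients):
        patient_ss = children[p_idx + 1]
        gene_ss = patient_ss.spawn(cfg.n_genes)
        gt_haps = []
        for g_idx, gene in enumerate(genes.itertuples(index=False)):
            rng = np.random.default_rng(gene_ss[g_idx])
            gsnps = snps[snps["gene"] == gene.gene]
            pattern = labels[rng.choice(len(labels), p=probs)]
            if pattern == "no-change":
                n_state = t_state = "BAL"
                mechanism = "none"
            else:
                n_state, t_state = PATTERN_STATES[pattern]
                if t_state == "BAL":
                    mechanism = "pure-regulatory"
                else:
                    mechanism = mech_labels[rng.choice(3, p=mech_probs)]
            n_ratio = _state_ratio(n_state, cfg.effect_ratio)
            t_ratio = _state_ratio(t_state, cfg.effect_ratio)

            # tumor DNA allele ratio follows the copy state at cnv loci
            t_dna_ratio = 0.5
            major, minor = 1, 1
            if mechanism == "cnv":
                major, minor = CNV_MAJOR, CNV_MINOR
                frac = major / (major + minor)
                t_dna_ratio = frac if t_state == "REF" else 1.0 - frac
            seg_rows.append(
                {
                    "sample": f"{patient}-T",
                    "contig": "chr1",
                    "start": gene.start,
                    "end": gene.end,
                    "major_cn": major,
                    "minor_cn": minor,
                }
            )

            for site in gsnps.itertuples(index=False):
                p0 = cfg.bias_table.get(f"{site.refAllele}>{site.altAllele}", 0.5)
                for tissue, ratio, dna_ratio in (
                    ("N", n_ratio, 0.5),
                    ("T", t_ratio, t_dna_ratio),
                ):
                    rna_depth = int(cfg.rna_depth.sample(rng, 1)[0])
                    dna_depth = int(cfg.dna_depth.sample(rng, 1)[0])
                    rna_ref = int(rng.binomial(rna_depth, compose_bias(ratio, p0)))
                    dna_ref = int(rng.binomial(dna_depth, dna_ratio))
                    base = {
                        "contig": site.contig,
                        "position": site.position,
                        "variantID": site.variantID,
                        "refAllele": site.refAllele,
                        "altAllele": site.altAllele,
                    }
                    count_rows.append(
                        base
                        | {
                            "refCount": rna_ref,
                            "altCount": rna_depth - rna_ref,
                            "totalCount": rna_depth,
                            "sample": f"{patient}-{tissue}",
                            "assay": "RNA",
                        }
                    )
                    count_rows.append(
                        base
                        | {
                            "refCount": dna_ref,
                            "altCount": dna_depth - dna_ref,
                            "totalCount": dna_depth,
                            "sample": f"{patient}-{tissue}",
                            "assay": "DNA",
                        }
                    )
                truth_rows.append(
                    {
                        "variantID": site.variantID,
                        "gene": gene.gene,
                        "patient": patient,
                        "pattern": pattern,
                        "mechanism": mechanism,
                        "normal_ratio": n_ratio,
                        "tumor_ratio": t_ratio,
                    }
                )

            # splicing / antisense event (one per gene, middle exon)
            skip_fold = 1.0
            if mechanism == "skipping+antisense":
                skip_fold = float(rng.uniform(2.0, 6.0))
            as_fold = cfg.antisense_coupling * skip_fold if skip_fold > 1 else 1.0
            event = f"ev_{gene.gene}"
            iso_n = int(rng.poisson(cfg.iso1_base_rate))
            iso_t = int(rng.poisson(cfg.iso1_base_rate * skip_fold))
            for tissue, iso in (("N", iso_n), ("T", iso_t)):
                iso_rows.append(
                    {
                        "gene": gene.gene,
                        "event_id": event,
                        "skipped_exon_index": 1,
                        "sample": f"{patient}-{tissue}",
                        "iso1_count": iso,
                        "library_size": cfg.library_size,
                    }
                )
            for tissue, fold in (("N", 1.0), ("T", as_fold)):
                as_rows.append(
                    {
                        "event_id": event,
                        "sample": f"{patient}-{tissue}",
                        "donor_antisense": int(
                            rng.poisson(cfg.antisense_base_rate * fold)
                        ),
                        "acceptor_antisense": int(
                            rng.poisson(cfg.antisense_base_rate * fold)
                        ),
                        "library_size": cfg.library_size,
                    }
                )

            meth_n = float(rng.beta(6, 14))
            meth_t = float(np.clip(meth_n * rng.lognormal(0.0, 0.08), 0.01, 0.99))
            meth_rows.append(
                {"gene": gene.gene, "sample": f"{patient}-N", "value": meth_n}
            )
            meth_rows.append(
                {"gene": gene.gene, "sample": f"{patient}-T", "value": meth_t}
            )

            # germline phase: which haplotype carries each alt allele
            gt_haps.append(rng.integers(0, 2, size=len(gsnps)))
        hap = np.concatenate(gt_haps)
        gt[patient] = np.where(hap == 0, "0|1", "1|0")

    rna = pd.DataFrame(
        [r for r in count_rows if r["assay"] == "RNA"],
        columns=COUNT_COLUMNS + ["sample", "assay"],
    )
    dna = pd.DataFrame(
        [r for r in count_rows if r["assay"] == "DNA"],
        columns=COUNT_COLUMNS + ["sample", "assay"],
    )
    return CohortBundle(
        config=cfg,
        rna_counts=rna,
        dna_counts=dna,
        genotypes=gt,
        patients=patients,
        exons=bed,
        isoform_counts=pd.DataFrame(iso_rows),
        antisense_counts=pd.DataFrame(as_rows),
        segments=pd.DataFrame(seg_rows),
        methylation=pd.DataFrame(meth_rows),
        truth=pd.DataFrame(truth_rows),
    )


def simulate_null_sites(
    n_sites: int,
    depth_model: DepthModel | int,
    bias_table: dict[str, float] | float,
    seed: int,
) -> pd.DataFrame:
    """Allele-count table with no ASE anywhere (counts binomial at p0).

    ``depth_model`` may be an integer for fixed depth; ``bias_table`` may be
    a scalar p0 applied to every pair. Sites cycle deterministically through
    the 12 nucleotide pairs.
    """
    if n_sites < 1:
        raise ConfigError("n_sites must be >= 1")
    if isinstance(depth_model, (int, np.integer)):
        depth_model = DepthModel(mean=float(depth_model), dispersion=None)
    depth_model.validate()
    if isinstance(bias_table, (int, float)) and not isinstance(bias_table, bool):
        if not 0.0 < bias_table < 1.0:
            raise ConfigError(f"p0 must be in (0,1), got {bias_table}")
        bias_table = {pair: float(bias_table) for pair in NUCLEOTIDE_PAIRS}

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pairs = [p for p in NUCLEOTIDE_PAIRS if p in bias_table]
    if not pairs:
        raise ConfigError("bias_table holds no known nucleotide pair")
    idx = np.arange(n_sites) % len(pairs)
    p0 = np.array([bias_table[pairs[i]] for i in idx])
    depth = depth_model.sample(rng, n_sites)
    ref = rng.binomial(depth, p0)
    refs = np.array([pairs[i][0] for i in idx])
    alts = np.array([pairs[i][2] for i in idx])
    return pd.DataFrame(
        {
            "contig": "chr1",
            "position": np.arange(1, n_sites + 1) * 100,
            "variantID": [f"null_{i + 1}" for i in range(n_sites)],
            "refAllele": refs,
            "altAllele": alts,
            "refCount": ref,
            "altCount": depth - ref,
            "totalCount": depth,
            "sample": "null",
            "assay": "RNA",
        }
    )
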