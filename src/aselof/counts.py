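"""Allele-count filtering, DNA genotype calling, and the mapping-bias model.

The bias model replaces the naive binomial null of 0.5 with the
genome-wide reference-allele ratio observed for each ordered ref->alt
nucleotide pair, the standard correction for residual reference-mapping
bias after discarding low-mapability regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .config import FilterConfig, InputFormatError, NUCLEOTIDE_PAIRS
from .io import validate_counts

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Site filtering

def _mapable_trees(mapability: pd.DataFrame, threshold: float) -> dict:
    """One interval tree per contig holding intervals with score >= threshold."""
    trees: dict[str, IntervalTree] = {}
    ok = mapability[mapability["score"] >= threshold]
    for rec in ok.itertuples(index=False):
        if rec.end > rec.start:
            trees.setdefault(str(rec.contig), IntervalTree()).addi(
                rec.start, rec.end
            )
    return trees


def filter_sites(
    counts: pd.DataFrame,
    cfg: FilterConfig | None = None,
    mapability: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the ASE site filters; returns (retained, rejection log).

    Retains sites with informative depth (ref+alt) >= ``min_site_depth``,
    both alleles >= ``min_allele_depth``, and — when a mapability table is
    given — position inside an interval of mapability >= threshold
    (1-based positions checked against 0-based half-open intervals).
    The rejection log carries one row per dropped site with a reason code
    (``site_depth`` | ``allele_depth`` | ``mapability``).
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    counts = validate_counts(counts)
    informative = counts["refCount"] + counts["altCount"]
    reasons = pd.Series("", index=counts.index, dtype=object)
    reasons[informative < cfg.min_site_depth] = "site_depth"
    low_allele = (
        (counts["refCount"] < cfg.min_allele_depth)
        | (counts["altCount"] < cfg.min_allele_depth)
    ) & (reasons == "")
    reasons[low_allele] = "allele_depth"

    if mapability is not None:
        trees = _mapable_trees(mapability, cfg.mapability_threshold)
        undecided = reasons == ""
        for idx in counts.index[undecided]:
            contig = str(counts.at[idx, "contig"])
            pos0 = int(counts.at[idx, "position"]) - 1
            tree = trees.get(contig)
            if tree is None or not tree.overlaps(pos0):
                reasons[idx] = "mapability"

    keep = reasons == ""
    rejected = counts.loc[~keep].copy()
    rejected["reason"] = reasons[~keep]
    n = len(rejected)
    if n:
        log.info("filter_sites rejected %d of %d sites", n, len(counts))
    return counts.loc[keep].copy(), rejected


# ---------------------------------------------------------------------------
# DNA genotype calling

def call_genotypes(
    dna_counts: pd.DataFrame, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """Threshold-based genotype calls from DNA allele counts.

    A variant is supported when depth >= 8, alt reads >= 2, VAF >= 0.2 and a
    one-sided binomial test of the alt count against the sequencing error
    rate (default 1%) gives p < 0.01. Supported variants are het, or hom-alt
    at VAF >= 0.8; unsupported positions with adequate depth are hom-ref;
    depth < 8 is a no-call. Calls are independent per row, hence invariant
    to row order.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    if "assay" in dna_counts.columns:
        non_dna = dna_counts["assay"] != "DNA"
        if non_dna.any():
            raise InputFormatError("call_genotypes accepts DNA counts only")
    dna_counts = validate_counts(dna_counts)
    depth = (dna_counts["refCount"] + dna_counts["altCount"]).to_numpy()
    alt = dna_counts["altCount"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    # P(X >= alt | depth, error_rate): sf(alt - 1)
    p_support = stats.binom.sf(alt - 1, depth, cfg.gt_error_rate)
    supported = (
        (depth >= cfg.gt_min_depth)
        & (alt >= cfg.gt_min_alt_depth)
        & (vaf >= cfg.gt_min_vaf)
        & (p_support < cfg.gt_p_threshold)
    )
    genotype = np.where(
        depth < cfg.gt_min_depth,
        "no-call",
        np.where(
            supported,
            np.where(vaf >= cfg.gt_hom_alt_vaf, "hom-alt", "het"),
            "hom-ref",
        ),
    )
    out = dna_counts.copy()
    out["vaf"] = vaf
    out["variant_p"] = p_support
    out["genotype"] = genotype
    return out


# ---------------------------------------------------------------------------
# Mapping-bias model

@dataclass
class BiasModel:
    """Expected reference-allele ratio p0 per ordered nucleotide pair.

    Pairs with fewer than the minimum number of contributing sites carry the
    ``fallback`` ratio (0.5).
    """

    p0: dict[str, float] = field(default_factory=dict)
    n_sites: dict[str, int] = field(default_factory=dict)
    n_reads: dict[str, int] = field(default_factory=dict)
    fallback: float = 0.5

    def __post_init__(self) -> None:
        for pair in NUCLEOTIDE_PAIRS:
            self.p0.setdefault(pair, self.fallback)
            self.n_sites.setdefault(pair, 0)
            self.n_reads.setdefault(pair, 0)
        bad = {k: v for k, v in self.p0.items() if not 0.0 < v < 1.0}
        if bad:
            raise InputFormatError(f"bias p0 out of (0,1): {bad}")

    def expected_ratio(self, ref: str, alt: str) -> float:
        return self.p0.get(f"{ref}>{alt}", self.fallback)

    def lookup(self, counts: pd.DataFrame) -> np.ndarray:
        """Vector of p0 for each row of an allele-count table."""
        keys = counts["refAllele"].astype(str) + ">" + counts["altAllele"].astype(str)
        return keys.map(lambda k: self.p0.get(k, self.fallback)).to_numpy()

    @classmethod
    def flat(cls, p0: float = 0.5) -> "BiasModel":
        return cls(p0={pair: p0 for pair in NUCLEOTIDE_PAIRS}, fallback=p0)


def fit_bias_model(
    het_counts: pd.DataFrame,
    min_sites_per_pair: int = 10,
    pooled: bool = True,
) -> BiasModel | dict[str, BiasModel]:
    """Estimate p0 per ordered nucleotide pair from heterozygous counts.

    p0(pair) = total ref reads / total informative reads over that pair's
    sites; pairs with fewer than ``min_sites_per_pair`` sites fall back to
    0.5. With ``pooled=False`` one model is fitted per ``sample`` column
    value (mapping bias is library-specific).
    """
    if not pooled:
        if "sample" not in het_counts.columns:
            raise InputFormatError("per-sample bias fit needs a sample column")
        return {
            sample: fit_bias_model(grp, min_sites_per_pair, pooled=True)
            for sample, grp in het_counts.groupby("sample", sort=True)
        }
    if het_counts.empty:
        log.warning("fit_bias_model: empty input, all pairs fall back to 0.5")
        return BiasModel()
    het_counts = validate_counts(het_counts)
    keys = (
        het_counts["refAllele"].astype(str)
        + ">"
        + het_counts["altAllele"].astype(str)
    )
    p0, n_sites, n_reads = {}, {}, {}
    grouped = het_counts.groupby(keys.values)
    for pair, grp in grouped:
        ref = int(grp["refCount"].sum())
        tot = int((grp["refCount"] + grp["altCount"]).sum())
        n_sites[pair] = len(grp)
        n_reads[pair] = tot
        if len(grp) >= min_sites_per_pair and 0 < ref < tot:
            p0[pair] = ref / tot
    return BiasModel(p0=p0, n_sites=n_sites, n_reads=n_reads)
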