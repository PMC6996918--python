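"""SNP- and gene-level allele-specific expression statistics.

SNP level: exact two-sided binomial test of the reference-allele count
against the pair-specific expected ratio p0 (mapping-bias corrected),
with Benjamini-Hochberg FDR control per sample. A site shows ASE when
its raw p < 0.005 *and* its BH q <= 0.05 (conjunctive, matching the
dual-threshold convention); the directional state is REF (ref > alt) or
ALT (ref < alt) only for significant sites, BAL otherwise.

Gene level: heterozygous SNPs of a gene are pseudo-phased onto a major
haplotype (per site, the allele with the higher RNA count; ties break
toward reference). The aggregated major-allele frequency (MAF, >= 0.5 by
construction) is calibrated by Monte Carlo: each null replicate resamples
every site binomially at its p0 and re-derives the major haplotype, so
the post-hoc selection bias of taking the maximum is priced into the
null. A gene shows ASE at MAF > 0.7 and Monte-Carlo p < 0.05 (FDR 5%
across the sample's genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Thresholds
from .counts import BiasModel

log = logging.getLogger(__name__)

#: relative tolerance when comparing outcome probabilities in the
#: two-sided exact test (the R binom.test convention)
_REL_TOL = 1.0 + 1e-7


def exact_binom_p(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value by enumeration.

    Sums the probabilities of all outcomes whose likelihood does not
    exceed that of the observed count (within relative tolerance 1e-7).
    """
    if n == 0:
        raise ValueError("undefined for n = 0")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * _REL_TOL].sum()))


def binomial_ase(
    ref_count: int, alt_count: int, p0: float = 0.5
) -> tuple[float, str]:
    """Exact two-sided binomial p and direction for one het site.

    Direction is REF when the observed ref ratio exceeds p0, ALT when it
    falls below, BAL at exact equality. Raises on zero informative reads.
    """
    n = ref_count + alt_count
    if n == 0:
        raise ValueError("zero informative reads: site must be skipped")
    p = exact_binom_p(ref_count, n, p0)
    ratio = ref_count / n
    direction = "REF" if ratio > p0 else ("ALT" if ratio < p0 else "BAL")
    return p, direction


def _binom_p_vector(ref: np.ndarray, total: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Vectorised exact two-sided p-values, grouped by unique (n, p0)."""
    out = np.empty(len(ref), dtype=float)
    key = pd.DataFrame({"n": total, "p0": np.round(p0, 12)})
    for (n, q), idx in key.groupby(["n", "p0"], sort=False).groups.items():
        rows = np.asarray(idx, dtype=int)  # key has a positional RangeIndex
        pmf = stats.binom.pmf(np.arange(int(n) + 1), int(n), q)
        pmf_sorted = np.sort(pmf)
        csum = np.cumsum(pmf_sorted)
        # p-value for count k = sum of pmf <= pmf[k]*(1+1e-7)
        j = np.searchsorted(pmf_sorted, pmf[ref[rows]] * _REL_TOL, side="right")
        out[rows] = np.minimum(1.0, csum[j - 1])
    return out


def fdr_select(
    pvalues, alpha: float = 0.05, p_raw_max: float = 0.005
) -> pd.DataFrame:
    """Benjamini-Hochberg q-values plus the conjunctive significance flag.

    significant <=> raw p < ``p_raw_max`` AND q <= ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return pd.DataFrame({"p": [], "q": [], "significant": []})
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"p": p, "q": q, "significant": (p < p_raw_max) & (q <= alpha)}
    )


def ase_calls(
    counts: pd.DataFrame,
    bias: BiasModel | None = None,
    thresholds: Thresholds | None = None,
    per_sample_fdr: bool = True,
) -> pd.DataFrame:
    """Per-site ASE calls for an allele-count table.

    Adds ref_ratio, p0, p, q, state (REF/BAL/ALT) and ``significant``.
    FDR is controlled within each sample (the analysis unit for reported
    per-sample ASE proportions). Sites without informative reads are
    dropped with a log entry.
    """
    bias = bias or BiasModel.flat(0.5)
    th = thresholds or Thresholds()
    th.validate()
    counts = counts.copy()
    informative = counts["refCount"] + counts["altCount"]
    empty = informative == 0
    if empty.any():
        log.info("ase_calls: skipping %d sites with no informative reads",
                 int(empty.sum()))
        counts = counts.loc[~empty].copy()
        informative = informative[~empty]
    if counts.empty:
        return counts.assign(ref_ratio=[], p0=[], p=[], q=[],
                             significant=[], state=[])
    p0 = bias.lookup(counts)
    ref = counts["refCount"].to_numpy()
    total = informative.to_numpy()
    counts["ref_ratio"] = ref / total
    counts["p0"] = p0
    counts["p"] = _binom_p_vector(ref, total, p0)

    if per_sample_fdr and "sample" in counts.columns:
        qs = np.empty(len(counts))
        sig = np.empty(len(counts), dtype=bool)
        pos = {idx: i for i, idx in enumerate(counts.index)}
        for _, grp in counts.groupby("sample", sort=False):
            sel = fdr_select(grp["p"].to_numpy(), th.fdr, th.ase_p)
            rows = [pos[idx] for idx in grp.index]
            qs[rows] = sel["q"].to_numpy()
            sig[rows] = sel["significant"].to_numpy()
        counts["q"] = qs
        counts["significant"] = sig
    else:
        sel = fdr_select(counts["p"].to_numpy(), th.fdr, th.ase_p)
        counts["q"] = sel["q"].to_numpy()
        counts["significant"] = sel["significant"].to_numpy()

    direction = np.where(counts["ref_ratio"] > counts["p0"], "REF", "ALT")
    counts["state"] = np.where(counts["significant"], direction, "BAL")
    return counts


def proportion_ase(calls: pd.DataFrame, universe: pd.Series | None = None) -> float:
    """Fraction of significant calls within a universe of sites.

    ``universe`` is a boolean mask over ``calls``; None means all sites.
    Returns NaN (with a log entry) for an empty universe.
    """
    sub = calls if universe is None else calls.loc[universe]
    if len(sub) == 0:
        log.warning("proportion_ase: empty universe")
        return float("nan")
    return float(sub["significant"].sum() / len(sub))


# ---------------------------------------------------------------------------
# Gene-level aggregation

@dataclass
class GeneAse:
    """Pseudo-phased gene-level ASE summary for one gene in one sample."""

    gene: str
    sample: str
    n_sites: int
    major_is_ref: list[bool]
    major_count: int
    total_count: int
    maf: float
    p_value: float
    haplotype: str  # reference | alternative | ambiguous
    ase: bool


def gene_ase(
    sites: pd.DataFrame,
    bias: BiasModel | None = None,
    n_mc: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    thresholds: Thresholds | None = None,
) -> GeneAse:
    """Aggregate the het sites of one gene into a gene-level ASE call.

    The Monte-Carlo p-value is the smoothed fraction of null replicates
    whose re-derived MAF reaches the observed MAF:
    ``p = (1 + #{MAF_null >= MAF_obs}) / (n_mc + 1)``.
    Zero-count sites are excluded. The returned ``ase`` flag applies the
    MAF > 0.7 and p < 0.05 thresholds; cohort-level FDR is layered on by
    :func:`gene_ase_table`.
    """
    bias = bias or BiasModel.flat(0.5)
    th = thresholds or Thresholds()
    if n_mc < 100:
        log.warning("gene_ase: n_mc=%d is very low; p-values will be coarse", n_mc)
    sites = sites.loc[(sites["refCount"] + sites["altCount"]) > 0]
    if sites.empty:
        raise ValueError("gene_ase needs at least one site with reads")
    gene = str(sites["gene"].iloc[0]) if "gene" in sites.columns else ""
    sample = str(sites["sample"].iloc[0]) if "sample" in sites.columns else ""
    ref = sites["refCount"].to_numpy()
    alt = sites["altCount"].to_numpy()
    total = ref + alt
    p0 = bias.lookup(sites)

    major_is_ref = ref >= alt  # tie breaks toward the reference allele
    major = np.where(major_is_ref, ref, alt)
    maf = major.sum() / total.sum()

    rng = np.random.default_rng(seed)
    null_ref = rng.binomial(total, p0, size=(int(n_mc), len(total)))
    null_major = np.maximum(null_ref, total - null_ref)
    null_maf = null_major.sum(axis=1) / total.sum()
    p = (1 + int((null_maf >= maf - 1e-12).sum())) / (n_mc + 1)

    n_ref = int(major_is_ref.sum())
    n_alt = len(sites) - n_ref
    if n_ref > n_alt:
        haplotype = "reference"
    elif n_alt > n_ref:
        haplotype = "alternative"
    else:
        haplotype = "ambiguous"
    return GeneAse(
        gene=gene,
        sample=sample,
        n_sites=len(sites),
        major_is_ref=list(map(bool, major_is_ref)),
        major_count=int(major.sum()),
        total_count=int(total.sum()),
        maf=float(maf),
        p_value=float(p),
        haplotype=haplotype,
        ase=bool(maf > th.maf_min and p < th.gene_p),
    )


def gene_ase_table(
    counts: pd.DataFrame,
    bias: BiasModel | dict | None = None,
    n_mc: int = 10_000,
    seed: int = 0,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Gene-level ASE for every (sample, gene) group, FDR per sample.

    ``bias`` may be a single model or a dict of per-sample models. The
    final ``ase`` flag requires MAF > 0.7, Monte-Carlo p < 0.05 and
    BH q <= 0.05 within the sample.
    """
    th = thresholds or Thresholds()
    root = np.random.SeedSequence(seed)
    groups = list(counts.groupby(["sample", "gene"], sort=True))
    streams = root.spawn(max(len(groups), 1))
    rows = []
    for ((sample, gene), grp), ss in zip(groups, streams):
        model = bias.get(sample) if isinstance(bias, dict) else bias
        g = gene_ase(grp, bias=model, n_mc=n_mc, seed=ss, thresholds=th)
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "n_sites": g.n_sites,
                "maf": g.maf,
                "p": g.p_value,
                "haplotype": g.haplotype,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=[], ase=[])
    out["q"] = np.nan
    for _, grp in out.groupby("sample", sort=False):
        sel = fdr_select(grp["p"].to_numpy(), th.fdr, p_raw_max=th.gene_p)
        out.loc[grp.index, "q"] = sel["q"].to_numpy()
    out["ase"] = (out["maf"] > th.maf_min) & (out["p"] < th.gene_p) & (
        out["q"] <= th.fdr
    )
    return out
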