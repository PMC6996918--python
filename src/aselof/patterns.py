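"""Six-pattern classification of paired normal/tumor ASE changes.

Each paired het site carries a directional ASE state per sample
(REF: ref > alt significantly; ALT: ref < alt significantly; BAL:
balanced). The state pair maps onto six patterns of change — e.g. P1 is
no ASE in normal but alt-allele over-expression in tumor — and every
pattern call additionally requires a two-sided Fisher exact test of the
two count tables at p < 0.05, so that only sites whose allelic ratios
actually differ between the tissues are labelled (the combined
binomial-Fisher procedure). Same-direction significant ASE in both
tissues has no pattern of its own; it is labelled ``concordant`` and
folded into "No ASE" in cohort summary tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import InputFormatError, PATTERNS, Thresholds

log = logging.getLogger(__name__)

#: (normal state, tumor state) -> pattern
STATE_TO_PATTERN = {
    ("BAL", "ALT"): "P1",
    ("REF", "BAL"): "P2",
    ("REF", "ALT"): "P3",
    ("BAL", "REF"): "P4",
    ("ALT", "BAL"): "P5",
    ("ALT", "REF"): "P6",
}

#: pattern -> (normal state, tumor state); the simulator's planting table
PATTERN_STATES = {v: k for k, v in STATE_TO_PATTERN.items()}


def fisher_diff(
    ref_normal: int, alt_normal: int, ref_tumor: int, alt_tumor: int
) -> float:
    """Two-sided Fisher exact p on [[refN, altN], [refT, altT]].

    A zero margin (no reads for one allele in both samples, or an empty
    sample) carries no information about a ratio difference; p = 1 is
    returned with a log entry.
    """
    table = np.array([[ref_normal, alt_normal], [ref_tumor, alt_tumor]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.info("fisher_diff: zero margin in %s, returning p=1", table.tolist())
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classify_pattern(
    normal_state: str, tumor_state: str, fisher_p: float, fisher_alpha: float = 0.05
) -> str:
    """Pattern label from the two directional states and the Fisher p.

    Returns one of P1..P6, ``concordant`` (same-direction ASE in both) or
    ``no-change``. The six patterns all require fisher_p < alpha.
    """
    for s in (normal_state, tumor_state):
        if s not in ("REF", "BAL", "ALT"):
            raise InputFormatError(f"unknown ASE state {s!r}")
    if normal_state == tumor_state:
        return "concordant" if normal_state != "BAL" else "no-change"
    pattern = STATE_TO_PATTERN[(normal_state, tumor_state)]
    return pattern if fisher_p < fisher_alpha else "no-change"


def classify_pairs(
    normal_calls: pd.DataFrame,
    tumor_calls: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Pair per-site ASE calls of a normal and a tumor sample and classify.

    Sites are matched on (contig, position, variantID, refAllele,
    altAllele); only sites present and filtered in both samples are paired.
    Returns one row per paired site with both states, the Fisher p and the
    pattern label.
    """
    th = thresholds or Thresholds()
    keys = ["contig", "position", "variantID", "refAllele", "altAllele"]
    carry = ["refCount", "altCount", "ref_ratio", "p", "q", "state"]
    extra = [c for c in ("gene",) if c in normal_calls.columns]
    n = normal_calls[keys + extra + carry].rename(
        columns={c: f"{c}_normal" for c in carry}
    )
    t = tumor_calls[keys + carry].rename(columns={c: f"{c}_tumor" for c in carry})
    merged = n.merge(t, on=keys, how="inner")
    if merged.empty:
        return merged.assign(fisher_p=[], pattern=[])
    merged["fisher_p"] = [
        fisher_diff(r.refCount_normal, r.altCount_normal,
                    r.refCount_tumor, r.altCount_tumor)
        for r in merged.itertuples(index=False)
    ]
    merged["pattern"] = [
        classify_pattern(r.state_normal, r.state_tumor, r.fisher_p, th.fisher_p)
        for r in merged.itertuples(index=False)
    ]
    return merged


def pattern_table(
    classified: pd.DataFrame,
    categories: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Cohort summary: percentage of sites per pattern and category.

    ``categories`` maps a column label (e.g. "TSG", "All COSMIC") to a
    boolean mask over ``classified``; None gives a single "Total SNPs"
    column. ``concordant`` sites are folded into the "No ASE" row so the
    rows of each column are exhaustive and sum to 100 up to rounding.
    Percentages are rounded half-up to one decimal.
    """
    from ._util import round_half_up

    if categories is None:
        categories = {"Total SNPs": pd.Series(True, index=classified.index)}
    rows = list(PATTERNS) + ["No ASE"]
    out = {}
    for name, mask in categories.items():
        sub = classified.loc[mask]
        if len(sub) == 0:
            log.info("pattern_table: empty category %r omitted", name)
            continue
        col = []
        for pattern in PATTERNS:
            col.append(100.0 * (sub["pattern"] == pattern).sum() / len(sub))
        col.append(
            100.0 * sub["pattern"].isin(["no-change", "concordant"]).sum() / len(sub)
        )
        out[name] = [round_half_up(v, 1) for v in col]
    return pd.DataFrame(out, index=pd.Index(rows, name="Pattern"))
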