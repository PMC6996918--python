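"""Calibration and recovery studies on synthetic cohorts.

Each study generates its inputs with the simulator, runs the relevant
analysis stage, and measures how well the planted truth is recovered (or
how well a null is calibrated). The studies are deliberately sized for a
single CPU: depths and cohort sizes are chosen so the statistical checks
have adequate power while a full run stays in the minutes range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ase import _binom_p_vector, ase_calls, fdr_select, gene_ase_table
from .config import DepthModel, SimConfig, Thresholds, default_bias_table
from .counts import BiasModel, filter_sites, fit_bias_model
from .mechanisms import dna_concordance, skipping_antisense
from .patterns import classify_pairs
from .second_hit import classify_second_hit, second_hit_table
from .simulate import simulate_cohort, simulate_null_sites


def type_i_error_study(
    seed: int, n_sites: int = 10_000, depth: int = 100, p0: float = 0.55,
    alpha: float = 0.005,
) -> dict:
    """Raw rejection rate of the exact binomial test on pure-null sites.

    The true p0 is supplied to the test, so the measured rate estimates
    the attained size at the 0.005 cut.
    """
    null = simulate_null_sites(n_sites, depth, p0, seed=seed)
    ref = null["refCount"].to_numpy()
    total = (null["refCount"] + null["altCount"]).to_numpy()
    p = _binom_p_vector(ref, total, np.full(n_sites, p0))
    rate = float((p < alpha).mean())
    se = float(np.sqrt(alpha * (1 - alpha) / n_sites))
    return {"rate": rate, "nominal": alpha, "se": se, "n": n_sites}


def bh_null_zero_probability(
    m: int = 1000, depth: int = 100, p0: float = 0.55, alpha: float = 0.05,
    n_levels: int = 120,
) -> float:
    """Exact probability that BH at level alpha selects nothing on m
    independent null sites of fixed depth.

    The two-sided exact p-value at fixed depth has a known discrete
    distribution, so the no-selection event — the order statistics never
    crossing the step-up boundary ``alpha * k / m`` — has a probability
    that can be computed by a boundary-crossing recursion over the first
    ``n_levels`` boundary levels (crossings beyond that require hundreds
    of sub-0.01 p-values and carry negligible probability).
    """
    pmf = stats.binom.pmf(np.arange(depth + 1), depth, p0)
    pv = _binom_p_vector(
        np.arange(depth + 1), np.full(depth + 1, depth), np.full(depth + 1, p0)
    )
    levels = np.sort(np.unique(pv))
    mass = np.array([pmf[pv == lv].sum() for lv in levels])
    cum = np.cumsum(mass)

    def cdf(c):
        i = np.searchsorted(levels, c, side="right") - 1
        return 0.0 if i < 0 else float(cum[i])

    crit = alpha * np.arange(1, m + 1) / m
    q = np.array([cdf(c) for c in crit[:n_levels]])
    dp = {0: 1.0}  # dp[j] = P(N_k = j and no crossing up to level k)
    prev = 0.0
    for k in range(n_levels):
        s = (q[k] - prev) / (1.0 - prev) if prev < 1.0 else 0.0
        new: dict[int, float] = {}
        for i, p_i in dp.items():
            pr_add = stats.binom.pmf(np.arange(0, k + 2 - i), m - i, s)
            for add, pr in enumerate(pr_add):
                new[i + add] = new.get(i + add, 0.0) + p_i * float(pr)
        dp = {j: v for j, v in new.items() if j <= k}  # N_{k+1} < k+1
        prev = q[k]
    return float(sum(dp.values()))


def bh_null_study(
    seed: int, m: int = 1000, n_replicates: int = 200,
    depth: int = 100, p0: float = 0.55,
) -> dict:
    """Zero-selection behaviour of BH at 5% FDR on pure-null batches.

    Reports both the exact no-selection probability (deterministic, see
    :func:`bh_null_zero_probability`) and its simulated estimate over
    ``n_replicates`` batches of m sites.
    """
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    zero = 0
    p0_vec = np.full(m, p0)
    for child in ss:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        null = simulate_null_sites(m, depth, p0, seed=rep_seed)
        p = _binom_p_vector(
            null["refCount"].to_numpy(),
            (null["refCount"] + null["altCount"]).to_numpy(),
            p0_vec,
        )
        sel = fdr_select(p)
        if int(sel["significant"].sum()) == 0:
            zero += 1
    exact = bh_null_zero_probability(m=m, depth=depth, p0=p0)
    return {
        "zero_selection_fraction": zero / n_replicates,
        "zero_selection_probability_exact": exact,
        "n_replicates": n_replicates,
        "m": m,
    }


def recovery_sim_config(seed: int) -> SimConfig:
    """Study conditions of the pattern-recovery experiment: 20 patients,
    fixed depth 100, effect ratio 0.75, even planted mix over P1-P6."""
    mix = {p: 0.12 for p in ("P1", "P2", "P3", "P4", "P5", "P6")}
    mix["no-change"] = 1.0 - sum(mix.values())
    return SimConfig(
        n_patients=20,
        n_genes=150,
        snps_per_gene=(2, 5),
        rna_depth=DepthModel(100, None),
        dna_depth=DepthModel(100, None),
        effect_ratio=0.75,
        pattern_mix=mix,
        seed=seed,
    )


def classify_cohort(bundle, thresholds: Thresholds | None = None):
    """Filter, fit bias, call ASE and classify patterns for a bundle.

    Returns (classified table with patient column, per-sample calls).
    """
    th = thresholds or Thresholds()
    filtered, _ = filter_sites(bundle.rna_counts)
    bias = fit_bias_model(filtered, pooled=False)
    calls = {
        sample: ase_calls(grp, bias[sample], th)
        for sample, grp in filtered.groupby("sample", sort=True)
    }
    parts = []
    for patient in bundle.patients:
        n = calls.get(f"{patient}-N")
        t = calls.get(f"{patient}-T")
        if n is None or t is None or n.empty or t.empty:
            continue
        pairs = classify_pairs(n, t, th)
        pairs["patient"] = patient
        parts.append(pairs)
    classified = pd.concat(parts, ignore_index=True)
    return classified, calls


def pattern_metrics(classified: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-pattern precision and recall of pattern calls against truth.

    Sites dropped by the filters are not scored; ``concordant`` predictions
    count as non-pattern calls.
    """
    merged = truth.merge(
        classified[["patient", "variantID", "pattern"]],
        on=["patient", "variantID"],
        suffixes=("_true", "_pred"),
    )
    rows = []
    for pattern in ("P1", "P2", "P3", "P4", "P5", "P6"):
        tp = int(
            ((merged["pattern_true"] == pattern)
             & (merged["pattern_pred"] == pattern)).sum()
        )
        n_pred = int((merged["pattern_pred"] == pattern).sum())
        n_true = int((merged["pattern_true"] == pattern).sum())
        rows.append(
            {
                "pattern": pattern,
                "n_true": n_true,
                "n_pred": n_pred,
                "precision": tp / n_pred if n_pred else float("nan"),
                "recall": tp / n_true if n_true else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def pattern_recovery_study(seed: int) -> dict:
    """Plant an even six-pattern mix and measure per-pattern recovery."""
    bundle = simulate_cohort(recovery_sim_config(seed))
    classified, _ = classify_cohort(bundle)
    metrics = pattern_metrics(classified, bundle.truth)
    return {
        "metrics": metrics,
        "min_precision": float(metrics["precision"].min()),
        "min_recall": float(metrics["recall"].min()),
        "n_sites": int(len(classified)),
    }


def gene_mc_calibration_study(
    seed: int, n_genes: int = 500, n_mc: int = 10_000
) -> dict:
    """Monte-Carlo gene-level p-values under the null vs uniformity.

    Null genes of 2-5 het sites at overdispersed depth, counts binomial at
    the pair-specific p0 that the test is also given. Reports the one-sided
    Kolmogorov-Smirnov test of the anti-conservative direction (empirical
    CDF above uniform): a large KS p-value means no inflation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bias_table = default_bias_table()
    pairs = sorted(bias_table)
    depth = DepthModel(60, 5)
    rows = []
    for g in range(n_genes):
        n_sites = int(rng.integers(2, 6))
        for s in range(n_sites):
            pair = pairs[(g + s) % len(pairs)]
            p0 = bias_table[pair]
            d = int(depth.sample(rng, 1)[0])
            d = max(d, 1)
            ref = int(rng.binomial(d, p0))
            rows.append(
                {
                    "contig": "chr1",
                    "position": g * 1000 + s,
                    "variantID": f"g{g}_s{s}",
                    "refAllele": pair[0],
                    "altAllele": pair[2],
                    "refCount": ref,
                    "altCount": d - ref,
                    "totalCount": d,
                    "sample": "S1",
                    "gene": f"gene{g:04d}",
                }
            )
    counts = pd.DataFrame(rows)
    model = BiasModel(p0=dict(bias_table))
    table = gene_ase_table(counts, bias=model, n_mc=n_mc, seed=seed)
    ks = stats.kstest(table["p"].to_numpy(), "uniform", alternative="greater")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_genes": int(len(table)),
        "mean_p": float(table["p"].mean()),
    }


# ---------------------------------------------------------------------------
# Two-hit fixtures

def _gt_rows(variant_id, position, gt, n_alt):
    return {
        "contig": "chr17",
        "position": position,
        "variantID": variant_id,
        "refAllele": "C",
        "altAllele": "T",
        "gt": gt,
        "n_ref": 2 - n_alt,
        "n_alt": n_alt,
        "phased": "|" in gt,
    }


def second_hit_fixture_study() -> dict:
    """Four single-patient fixtures, one per two-hit verdict class."""
    lof = pd.DataFrame(
        {
            "variantID": ["siteA", "siteB"],
            "gene": ["TSG1", "TSG1"],
            "is_lof": [True, True],
        }
    )
    segments_loh = pd.DataFrame(
        [{"sample": "loh-T", "contig": "chr17", "start": 1,
          "end": 10_000, "major_cn": 1, "minor_cn": 0}]
    )
    segments_flat = segments_loh.assign(minor_cn=1, sample="none-T")
    fixtures = {
        "same_hom": (
            pd.DataFrame([_gt_rows("siteA", 500, "0|1", 1)]),
            pd.DataFrame([_gt_rows("siteA", 500, "1/1", 2)]),
            None,
        ),
        "compound_het": (
            pd.DataFrame([_gt_rows("siteA", 500, "0|1", 1)]),
            pd.DataFrame(
                [_gt_rows("siteA", 500, "0|1", 1),
                 _gt_rows("siteB", 700, "1|0", 1)]
            ),
            None,
        ),
        "loh": (
            pd.DataFrame([_gt_rows("siteA", 500, "0|1", 1)]),
            pd.DataFrame([_gt_rows("siteA", 500, "0/1", 1)]),
            segments_loh,
        ),
        "none": (
            pd.DataFrame([_gt_rows("siteA", 500, "0|1", 1)]),
            pd.DataFrame([_gt_rows("siteA", 500, "0/1", 1)]),
            segments_flat,
        ),
    }
    verdicts = {}
    for expected, (normal, tumor, segments) in fixtures.items():
        calls = classify_second_hit(normal, tumor, segments, lof, expected)
        table = second_hit_table(calls)
        verdicts[expected] = table["verdict"].iloc[0] if len(table) else "missing"
    correct = sum(v == k for k, v in verdicts.items())
    return {"verdicts": verdicts, "n_correct": correct, "n_classes": len(fixtures)}


# ---------------------------------------------------------------------------
# Mechanism recovery

def mechanism_sim_config(seed: int) -> SimConfig:
    """Study conditions of the mechanism-recovery experiment: gain-of-ASE
    patterns only, fixed RNA depth 100 and DNA depth 60."""
    return SimConfig(
        n_patients=12,
        n_genes=120,
        snps_per_gene=(2, 4),
        rna_depth=DepthModel(100, None),
        dna_depth=DepthModel(60, None),
        effect_ratio=0.75,
        pattern_mix={"P1": 0.2, "P4": 0.2, "no-change": 0.6},
        seed=seed,
    )


def mechanism_recovery_study(seed: int) -> dict:
    """Sensitivity/false-positive rate of the DNA-concordance flag on
    planted copy-driven vs pure-regulatory loci, and precision/recall of
    the exon-skipping flag on planted splice events."""
    bundle = simulate_cohort(mechanism_sim_config(seed))
    truth = bundle.truth
    rna = bundle.rna_counts.set_index(["sample", "variantID"])
    dna = bundle.dna_counts.set_index(["sample", "variantID"])

    def dna_flag(patient, variant):
        r = rna.loc[(f"{patient}-T", variant)]
        d = dna.loc[(f"{patient}-T", variant)]
        return dna_concordance(
            int(r["refCount"]), int(r["altCount"]),
            int(d["refCount"]), int(d["altCount"]),
        )

    cnv = truth[truth["mechanism"] == "cnv"]
    reg = truth[truth["mechanism"] == "pure-regulatory"]
    cnv_flags = [dna_flag(t.patient, t.variantID) for t in cnv.itertuples()]
    reg_flags = [dna_flag(t.patient, t.variantID) for t in reg.itertuples()]
    cnv_flags = [f for f in cnv_flags if f is not None]
    reg_flags = [f for f in reg_flags if f is not None]
    sensitivity = float(np.mean(cnv_flags)) if cnv_flags else float("nan")
    fpr = float(np.mean(reg_flags)) if reg_flags else float("nan")

    # exon-skipping flags per patient x gene event vs planted mechanism
    iso = bundle.isoform_counts.set_index(["gene", "sample"]).sort_index()
    anti = bundle.antisense_counts.set_index(["event_id", "sample"]).sort_index()
    gene_truth = truth.drop_duplicates(["patient", "gene"])
    tp = fp = fn = tn = 0
    as_tp = as_fp = 0
    for rec in gene_truth.itertuples():
        ns, ts = f"{rec.patient}-N", f"{rec.patient}-T"
        iso_n, iso_t = iso.loc[(rec.gene, ns)], iso.loc[(rec.gene, ts)]
        event = iso_n["event_id"]
        as_n, as_t = anti.loc[(event, ns)], anti.loc[(event, ts)]
        flags = skipping_antisense(
            iso_n["iso1_count"], iso_t["iso1_count"],
            as_n["donor_antisense"], as_t["donor_antisense"],
            as_n["acceptor_antisense"], as_t["acceptor_antisense"],
            iso_n["library_size"], iso_t["library_size"],
        )
        planted = rec.mechanism == "skipping+antisense"
        if flags["exon_skipping"]:
            tp += planted
            fp += not planted
            as_tp += planted and flags["antisense_supported"]
            as_fp += (not planted) and flags["antisense_supported"]
        else:
            fn += planted
            tn += not planted
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {
        "cnv_sensitivity": sensitivity,
        "cnv_n": len(cnv_flags),
        "regulatory_false_positive_rate": fpr,
        "regulatory_n": len(reg_flags),
        "skip_precision": float(precision),
        "skip_recall": float(recall),
        "skip_n_true": int(tp + fn),
        "antisense_precision": float(as_tp / (as_tp + as_fp))
        if as_tp + as_fp else float("nan"),
    }
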