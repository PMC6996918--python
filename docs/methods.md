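# Methods

This note documents the statistical model, the simulator that stands in
for controlled-access cohort data, the numerical choices, and the known
limits of what the tests demonstrate.

## SNP-level model

Read counts at a heterozygous site are modelled as
`ref ~ Binomial(ref + alt, p0)` under no ASE. The null ratio `p0` is not
0.5: reads carrying the alternative allele mismatch the reference genome
and map slightly less often, inflating the reference ratio. Two
corrections are applied in sequence:

1. sites inside regions of 50 bp mapability below 1 are removed before
   any testing (mapability intervals are consumed as BED);
2. the residual bias is estimated per ordered `ref→alt` nucleotide pair
   (12 pairs) as the pooled reference-read fraction over that pair's
   het sites, and used as `p0` in place of 0.5. Pairs with fewer than
   `min_sites_per_pair` (default 10) sites fall back to 0.5. Estimation
   is pooled across the cohort by default (`pooled=True`, the
   "genome-wide" reading) with a per-sample mode available, since
   mapping bias is in principle library-specific; per-sample fits need
   several hundred sites per pair to beat the fallback.

The two-sided exact p-value is the sum of the probabilities of all
outcomes no more likely than the observed one, with the conventional
relative tolerance `1 + 1e-7` on the comparison (the same definition as
R's `binom.test`; agreement with `scipy.stats.binomtest` is verified to
1e-12 in the tests). Significance is conjunctive: raw `p < 0.005` *and*
BH `q ≤ 0.05`, with BH applied within sample, because downstream
comparisons are of per-sample ASE proportions. Sites with zero
informative reads are skipped and logged.

Filtering thresholds (site depth ≥ 20, each allele ≥ 4, genotype
calling at depth ≥ 8, allelic depth ≥ 2, VAF ≥ 0.2, variant-support
`p < 0.01`) are inclusive at the boundary, reading "minimum" literally.
The variant-support test is a one-sided binomial of the alt count
against a 1% sequencing error rate — a stand-in for VarScan's internal
test with the same thresholds; the error rate is configurable. Hom-alt
calls use the VAF ≥ 0.8 convention, which no published threshold fixes;
it only affects the boundary between het and hom-alt at extreme VAF.

## Gene-level model

Sites of a gene are pseudo-phased: each site's higher-count allele is
assigned to a shared "major haplotype" (ties break toward reference,
which only matters at MAF = 0.5). The gene statistic is
`MAF = Σ major counts / Σ total counts ∈ [0.5, 1]`. Because the major
haplotype is chosen post hoc, MAF is upward-biased under the null; the
p-value therefore comes from Monte Carlo rather than a closed form: each
of `n_mc` replicates redraws every site at its `p0`, re-derives the
major haplotype, and the p-value is the smoothed exceedance
`(1 + #{MAF_null ≥ MAF_obs}) / (n_mc + 1)`. The +1 smoothing makes the
p-value slightly conservative (floor `1/(n_mc+1)`), which the
calibration test confirms (null p-values are super-uniform). A gene is
an ASE gene at `MAF > 0.7`, `p < 0.05`, BH `q ≤ 0.05` per sample. The
haplotype label (reference / alternative / ambiguous) counts which
allele class dominates the major haplotype.

`n_mc` defaults to 10,000; at the 0.05 threshold the Monte-Carlo
standard error is then ~0.002, negligible against the effect sizes of
interest.

## Paired patterns

With per-tissue states REF/BAL/ALT, the mapping is
`(BAL,ALT)→P1, (REF,BAL)→P2, (REF,ALT)→P3, (BAL,REF)→P4, (ALT,BAL)→P5,
(ALT,REF)→P6`, each contingent on a two-sided Fisher exact `p < 0.05`
between the normal and tumor count tables; otherwise the site is
no-change. `(BAL,BAL)` is no-change. Same-direction significant ASE in
both tissues has no pattern of its own; it is labelled `concordant` and
folded into the "No ASE" row of summary tables so that rows are
exhaustive and sum to 100 up to rounding. The Fisher gate applies to
all six patterns uniformly, including P3/P6 where the two binomial
calls alone would already imply a difference. A Fisher table with a
zero margin carries no information about a ratio difference and returns
p = 1 with a log entry. Standard (not mid-p) exact p-values are used.

Two exact symmetries follow from the definitions and are enforced by
test: swapping the tissue labels maps P1↔P5, P2↔P4, P3↔P6; swapping the
allele labels (with `p0 → 1−p0`) maps P1↔P4, P2↔P5, P3↔P6.

## Two-hit classification

A patient × gene qualifies only with a heterozygous LOF variant in the
normal tissue (LOF in "second-hit" mode: stop gained, frameshift,
splice acceptor/donor, start/stop lost, whole-gene deletion, or
missense called deleterious by SIFT *and* damaging by PolyPhen-2;
ClinVar benign/likely-benign overrides everything). Verdicts, in
priority order same_hom > compound_het > loh (co-occurrence is not
otherwise ranked by any published rule): the same variant homozygous in
tumor; a tumor-novel LOF variant phased opposite the normal LOF site; a
tumor segment with minor copy number 0 overlapping the locus. Without
phase information a tumor-novel candidate is reported as
`compound_candidate_unphased` and never counted as an affirmative
verdict — asserting it would fabricate phase the data does not contain.
Any qualifying normal het site triggers the verdict; multiple sites are
all listed as evidence. PolyPhen-2 "damaging" accepts both
probably_damaging and possibly_damaging by default (configurable), the
inclusive reading of a predictor-concordance rule stated without a
severity qualifier.

## Mechanism attribution

Flags are computed independently per ASE locus and are order-invariant:

* **DNA concordance** — "the RNA imbalance is already in the DNA":
  exact binomial of tumor DNA counts vs 0.5 at `p < 0.05` *and* the DNA
  skew direction matches the RNA. DNA depth below the genotyping
  minimum (8) leaves the flag undetermined and out of denominators.
  "Correlated" has no published operational definition; significant
  same-direction imbalance is this package's, with the alpha
  configurable.
* **CNV duplication** — overlapping tumor segment with total copies > 2
  and unequal major/minor.
* **eQTL phase** — gene is an eGene (≥ 1 eQTL record) and some het
  eQTL's high-expression allele (sign of the slope) lies on the gene's
  over-expressed pseudo-haplotype with LD `r ≥ 0.42`; LD is consumed
  from an input table, not computed from a panel.
* **Methylation** — gene-level change > 1.3-fold in either direction
  (array methylation is not allele-specific, so this is a gene-level
  proxy).
* **Splice-site overlap** — the SNP falls in a canonical donor or
  acceptor dinucleotide (the two intronic bases flanking an exon),
  strand-aware.
* **Exon skipping / antisense** — tumor/normal fold of ISO1 split reads
  (spanning the exons flanking a skipped exon) ≥ 1.5, with counts
  CPM-normalised with pseudocount 1 so zeros stay finite; antisense
  support additionally requires both the donor and acceptor antisense
  folds ≥ 1.5. Antisense is only interpreted at skipping events.

Summary tables recompute every percentage from their own count columns,
rounded half-up to one decimal (printed-table convention; banker's
rounding would differ at x.x5).

## The simulator

`simulate_cohort` emulates what the analysis assumes about real paired
cohorts, not the cohorts themselves:

* a shared germline het SNP panel over synthetic genes (three 200 bp
  exons, 300 bp introns, alternating strands), SNPs mid-exon;
* per patient × gene, a pattern drawn from `pattern_mix`; the default
  mix (P1 8%, P4 5%, P2 1%, P5 2%, P3/P6 0.5%, rest no-change) mirrors
  the empirical predominance of tumor ASE gains, and the default
  imbalanced ratio is 0.75 vs 0.25;
* RNA depth ~ NegBin(mean 60, dispersion 5) — overdispersed coverage;
  nothing is published about the real depth distribution, so these are
  plausible defaults, not estimates;
* the planted ratio is composed with the pair's mapping bias by odds
  multiplication (`odds_obs = odds(ratio) · odds(p0)`), so a balanced
  locus reads out exactly `p0` and the bias estimator can recover the
  injected table; the default table puts transitions at 0.53–0.55 and
  transversions at 0.50–0.52;
* mechanisms are mutually exclusive per locus for clean truth labels
  (real loci can mix them): tumor-imbalanced loci are copy-driven with
  probability 0.35 (copy state 3:1 oriented toward the loud allele,
  which also skews tumor DNA to 0.75), splice-driven with probability
  0.46 (ISO1 fold ~ U(2,6), antisense folds coupled multiplicatively,
  default coupling 1), else pure-regulatory; the 0.35/0.46 defaults
  match the attribution rates the analysis is designed around;
* DNA counts are binomial at 0.5 (no DNA mapping bias is simulated);
  methylation values are Beta-distributed with only small multiplicative
  normal/tumor noise (no planted methylation mechanism); eQTL and LD
  tables are not simulated — those attributions are tested on
  constructed fixtures.

All randomness flows from one seed through `numpy` SeedSequence
spawning in a documented order (layout, then one stream per patient,
split per gene), so enlarging a cohort never perturbs earlier draws and
identical configs are byte-identical.

What passing tests on this simulator do **not** show: robustness to
overdispersed (beta-binomial) allelic noise, clonal mixtures, co-occurring
mechanisms, phasing errors, or annotation noise — all explicitly out of
scope.

## Study sizes and numerical choices

The calibration/recovery studies (in `aselof.evaluation`) use sizes
chosen for adequate statistical power on one CPU: 10,000 null sites at
fixed depth 100 for the type-I check (3-SE band around 0.005); 200
batches of m = 1000 for the BH null check, compared against the exact
no-selection probability (0.953) computed by a boundary-crossing
recursion over the discrete p-value distribution, because a
200-replicate estimate of a quantity this close to its 0.95 bound is
dominated by its own sampling noise; a 20-patient, 150-gene cohort at
fixed depth 100 with an even 12%-per-pattern mix for pattern recovery
(~10,000 scored sites, so per-pattern precision/recall estimates carry
~0.01 standard error); 500 null genes × 10,000 Monte-Carlo replicates
for gene-level calibration; a 12-patient, 120-gene cohort (RNA depth
100, DNA depth 60) for mechanism recovery.

Degenerate inputs are defined behaviour, not crashes: empty FDR input
returns empty output; an empty bias fit warns and falls back to 0.5
everywhere; empty pattern categories are omitted with a log entry;
zero-read sites are skipped and logged; missing mechanism inputs leave
flags undetermined rather than false where the check itself was
impossible.

## Limitations

Beta-binomial overdispersion is not modelled (a known cause of
anti-conservative ASE calls in real data); the binomial null is exactly
what the simulator generates, so calibration results transfer to real
data only to the extent the binomial assumption holds. Gene-level
aggregation assumes pseudo-phasing is adequate — true phase is used
only in the two-hit compound-het rule. The Mann-Whitney comparison of
per-sample ASE proportions is unpaired two-sided by convention despite
the matched design; a paired Wilcoxon variant is available behind a
flag.
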