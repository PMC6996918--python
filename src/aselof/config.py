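"""Configuration objects shared across the pipeline.

All statistical thresholds live here with their field-standard defaults:
per-SNP ASE requires a two-sided exact binomial p < 0.005 together with
Benjamini-Hochberg FDR control at 5%; paired normal/tumor pattern calls
additionally require a Fisher exact p < 0.05; gene-level ASE requires a
pseudo-phased major-allele frequency (MAF) > 0.7 at Monte-Carlo p < 0.05;
mechanism fold thresholds are 1.5x for exon skipping / antisense and 1.3x
for methylation; the eQTL phase call requires linkage-disequilibrium
r >= 0.42.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

NUCLEOTIDES = ("A", "C", "G", "T")

#: The 12 ordered ref->alt nucleotide substitution pairs used by the
#: mapping-bias model.
NUCLEOTIDE_PAIRS = tuple(
    f"{r}>{a}" for r in NUCLEOTIDES for a in NUCLEOTIDES if r != a
)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


class InputFormatError(ValueError):
    """Raised when an input table or file is malformed."""


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial read-depth model (mean/dispersion parametrisation).

    ``var = mean + mean**2 / dispersion``; ``dispersion=None`` degenerates to
    a fixed depth equal to ``mean``.
    """

    mean: float = 60.0
    dispersion: Optional[float] = 5.0

    def validate(self) -> None:
        if self.mean < 0:
            raise ConfigError(f"depth mean must be >= 0, got {self.mean}")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigError(
                f"depth dispersion must be > 0 or None, got {self.dispersion}"
            )

    def sample(self, rng, size):
        if self.dispersion is None:
            import numpy as np

            return np.full(size, int(round(self.mean)), dtype=int)
        k = self.dispersion
        return rng.negative_binomial(k, k / (k + self.mean), size=size)


def default_bias_table() -> dict[str, float]:
    """Mild reference-mapping bias: genome-wide ref ratios slightly above 0.5.

    Transition pairs (A>G, G>A, C>T, T>C) get the strongest bias, mirroring
    the empirical tendency of reference-biased alignment at transitions.
    """
    table = {pair: 0.52 for pair in NUCLEOTIDE_PAIRS}
    table.update({"A>G": 0.54, "G>A": 0.53, "C>T": 0.55, "T>C": 0.54})
    table.update({"C>A": 0.50, "G>T": 0.50, "A>T": 0.51, "T>A": 0.51})
    return table


def default_pattern_mix() -> dict[str, float]:
    """Cohort-realistic mix: gain-of-ASE patterns (P1, P4) predominate and
    discordant double-ASE patterns (P3, P6) are rare."""
    return {
        "P1": 0.08,
        "P2": 0.01,
        "P3": 0.005,
        "P4": 0.05,
        "P5": 0.02,
        "P6": 0.005,
        "no-change": 0.83,
    }


PATTERNS = ("P1", "P2", "P3", "P4", "P5", "P6")
PATTERN_LABELS = PATTERNS + ("no-change",)


@dataclass
class SimConfig:
    """Parameters of the paired normal/tumor cohort simulator."""

    n_patients: int = 20
    n_genes: int = 50
    snps_per_gene: tuple[int, int] = (2, 4)
    rna_depth: DepthModel = field(default_factory=DepthModel)
    dna_depth: DepthModel = field(default_factory=DepthModel)
    bias_table: dict[str, float] = field(default_factory=default_bias_table)
    pattern_mix: dict[str, float] = field(default_factory=default_pattern_mix)
    effect_ratio: float = 0.75
    cnv_fraction: float = 0.35
    skip_fraction: float = 0.46
    antisense_coupling: float = 1.0
    iso1_base_rate: float = 80.0
    antisense_base_rate: float = 40.0
    library_size: int = 200_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1:
            raise ConfigError("n_patients and n_genes must be positive")
        lo, hi = self.snps_per_gene
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid snps_per_gene range {self.snps_per_gene}")
        self.rna_depth.validate()
        self.dna_depth.validate()
        for pair, p0 in self.bias_table.items():
            if pair not in NUCLEOTIDE_PAIRS:
                raise ConfigError(f"unknown nucleotide pair {pair!r}")
            if not 0.0 < p0 < 1.0:
                raise ConfigError(f"bias p0 for {pair} must be in (0,1), got {p0}")
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"pattern_mix proportions sum to {total}, not 1")
        for label in self.pattern_mix:
            if label not in PATTERN_LABELS:
                raise ConfigError(f"unknown pattern label {label!r}")
        if any(p < 0 for p in self.pattern_mix.values()):
            raise ConfigError("pattern_mix proportions must be non-negative")
        if not 0.5 < self.effect_ratio < 1.0:
            raise ConfigError(
                f"effect_ratio must be in (0.5, 1), got {self.effect_ratio}"
            )
        for name in ("cnv_fraction", "skip_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.cnv_fraction + self.skip_fraction > 1.0 + 1e-12:
            raise ConfigError("cnv_fraction + skip_fraction must not exceed 1")
        if self.antisense_coupling < 0:
            raise ConfigError("antisense_coupling must be >= 0")
        if self.library_size < 1:
            raise ConfigError("library_size must be positive")


@dataclass(frozen=True)
class FilterConfig:
    """Site-filtering and DNA genotype-calling thresholds.

    All thresholds are inclusive ("minimum depth 20" keeps depth == 20).
    Mapping/base-quality minima are metadata when counts are precomputed.
    """

    min_site_depth: int = 20
    min_allele_depth: int = 4
    min_mapping_quality: int = 20
    min_base_quality: int = 30
    mapability_threshold: float = 1.0
    # DNA genotype calling (VarScan-style thresholds)
    gt_min_depth: int = 8
    gt_min_alt_depth: int = 2
    gt_min_vaf: float = 0.2
    gt_p_threshold: float = 0.01
    gt_min_mapping_quality: int = 14
    gt_error_rate: float = 0.01
    gt_hom_alt_vaf: float = 0.8

    def validate(self) -> None:
        for name in (
            "min_site_depth",
            "min_allele_depth",
            "min_mapping_quality",
            "min_base_quality",
            "gt_min_depth",
            "gt_min_alt_depth",
            "gt_min_mapping_quality",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.gt_min_vaf < 1.0:
            raise ConfigError("gt_min_vaf must be in (0,1)")
        if not 0.0 < self.gt_hom_alt_vaf < 1.0:
            raise ConfigError("gt_hom_alt_vaf must be in (0,1)")
        if not 0.0 < self.gt_p_threshold < 1.0:
            raise ConfigError("gt_p_threshold must be in (0,1)")
        if not 0.0 < self.gt_error_rate < 1.0:
            raise ConfigError("gt_error_rate must be in (0,1)")


@dataclass(frozen=True)
class Thresholds:
    """Statistical thresholds of the ASE analysis proper."""

    ase_p: float = 0.005
    fdr: float = 0.05
    fisher_p: float = 0.05
    maf_min: float = 0.7
    gene_p: float = 0.05
    dna_p: float = 0.05
    skip_fold_min: float = 1.5
    antisense_fold_min: float = 1.5
    methylation_fold_min: float = 1.3
    ld_r_min: float = 0.42

    def validate(self) -> None:
        for name in ("ase_p", "fdr", "fisher_p", "gene_p", "dna_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if not 0.5 <= self.maf_min < 1.0:
            raise ConfigError("maf_min must be in [0.5, 1)")
        for name in ("skip_fold_min", "antisense_fold_min", "methylation_fold_min"):
            if getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must be >= 1")


def thresholds_dict(th: Thresholds) -> dict:
    return asdict(th)
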