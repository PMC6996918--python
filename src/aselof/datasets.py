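"""Small bundled example datasets.

Count tallies from a published pan-cancer matched normal/tumor cohort
(233 patients; breast, head & neck, lung and thyroid carcinoma), used by
the examples and the acceptance script to exercise the summary
arithmetic on realistic numbers. Only raw counts are stored; every
percentage is recomputed at run time.
"""

from __future__ import annotations

import pandas as pd


def dna_explained_counts() -> pd.DataFrame:
    """Per-patient tally of ASE SNPs whose tumor DNA allele counts
    corroborate the RNA imbalance, for nine deeply-profiled patients."""
    return pd.DataFrame(
        [
            ("Breast 1", 526, 1336),
            ("Breast 2", 719, 1411),
            ("Breast 3", 177, 367),
            ("Head & Neck 1", 275, 930),
            ("Head & Neck 2", 179, 674),
            ("Head & Neck 3", 217, 993),
            ("Lung 1", 56, 233),
            ("Lung 2", 47, 155),
            ("Lung 3", 11, 167),
        ],
        columns=["patient", "explained", "total"],
    )


def skipping_antisense_counts() -> pd.DataFrame:
    """Per-pattern tally of ASE SNPs with a >= 1.5x exon-skipping isoform
    (ISO1 split reads), and the subset also showing >= 1.5x antisense
    reads at both splice sites of the skipped exon."""
    return pd.DataFrame(
        [
            ("P1", 591, 278, 191),
            ("P2", 13, 5, 1),
            ("P3", 4, 4, 4),
            ("P4", 500, 217, 155),
            ("P5", 59, 18, 7),
            ("P6", 71, 51, 51),
        ],
        columns=["pattern", "total", "iso1", "iso1_antisense"],
    )
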