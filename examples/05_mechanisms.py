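"""Attribute ASE changes to candidate mechanisms and summarise a cohort.

Shows the per-locus checks (DNA concordance, copy-number duplication,
exon skipping with antisense support) and the cohort summary tables
recomputed from the bundled example tallies.
"""

from aselof import dna_concordance, cnv_duplication_check, skipping_antisense
from aselof.datasets import dna_explained_counts, skipping_antisense_counts
from aselof.mechanisms import explained_summary, skipping_summary
import pandas as pd

# RNA 75/25 with DNA 30/10 in the same direction: the imbalance is
# already present in the DNA, so ASE is "explained" structurally.
print("DNA concordance (RNA 75/25, DNA 30/10):",
      dna_concordance(75, 25, 30, 10))
print("DNA concordance (RNA 80/20, DNA 50/50):",
      dna_concordance(80, 20, 50, 50))

seg = pd.DataFrame([{"sample": "p-T", "contig": "chr1", "start": 100,
                     "end": 200, "major_cn": 2, "minor_cn": 1}])
print("unbalanced duplication overlapping locus:",
      cnv_duplication_check("chr1", 150, seg))

# an exon-19-skipping event: ISO1 split reads up 3.8x in the tumor with
# antisense reads at the donor (1.8x) and acceptor (1.7x) splice sites
flags = skipping_antisense(999, 3799, 999, 1799, 999, 1699, 1e6, 1e6)
print(f"\nexon skipping: {flags['exon_skipping']} "
      f"(ISO1 fold {flags['iso1_fold']:.1f}), antisense supported: "
      f"{flags['antisense_supported']} "
      f"(donor {flags['antisense_donor_fold']:.1f}x, "
      f"acceptor {flags['antisense_acceptor_fold']:.1f}x)")

print("\nper-patient DNA-explained summary (percentages recomputed):")
print(explained_summary(dna_explained_counts()).to_string(index=False))

print("\nper-pattern exon-skipping / antisense summary:")
print(skipping_summary(skipping_antisense_counts()).to_string(index=False))
# The Total rows say: ~35% of ASE SNPs are explained by DNA allele
# counts, ~46% coincide with an exon-skipping isoform gain, and ~33%
# additionally show antisense enrichment at both splice sites.
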