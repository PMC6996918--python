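"""Loss-of-function triage and population burden from a small VCF.

Classifies annotated variants with the LOF rules (truncating classes,
concordantly damaging missense, ClinVar benign override) and intersects
them with a population VCF to count per-individual LOF burden and
per-gene carrier fractions.
"""

import tempfile
from pathlib import Path

import pandas as pd

from aselof import classify_lof, intersect_population
from aselof.io import write_vcf

for args in [("stop_gained",), ("missense_variant", "deleterious",
              "probably_damaging"),
             ("missense_variant", "deleterious", "probably_damaging", "benign"),
             ("synonymous_variant",)]:
    v = classify_lof(*args)
    print(f"{args!r:<70} -> LOF={v.is_lof} ({v.reason})")

census = pd.DataFrame(
    [("chr1", 100, "A", "T", "TSG1", "TSG", "stop_gained"),
     ("chr1", 200, "C", "G", "TSG2", "TSG", "missense_variant")],
    columns=["contig", "position", "refAllele", "altAllele", "gene",
             "gene_role", "consequence"],
).assign(sift=["deleterious"] * 2, polyphen=["probably_damaging"] * 2)

sites = pd.DataFrame(
    [("chr1", 100, "rs1", "A", "T"), ("chr1", 200, "rs2", "C", "G")],
    columns=["contig", "position", "variantID", "refAllele", "altAllele"],
)
gts = {"I1": ["0/1", "0/0"], "I2": ["1/1", "0/1"], "I3": ["0/0", "0/0"]}
for s, g in gts.items():
    sites[s] = g
vcf = Path(tempfile.mkdtemp()) / "pop.vcf"
write_vcf(sites, vcf, sorted(gts))

res = intersect_population(census, vcf)
print("\nper-individual burden over census LOF sites:")
print(res["burden"].to_string(index=False))
print("\nper-gene carrier fractions (individuals with >=1 LOF allele):")
print(res["gene_carriers"].to_string(index=False))
print("\nindividuals by number of LOF-mutated TSGs:")
print(res["tsg_distribution"].to_string())
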