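"""Simulate a paired normal/tumor cohort with planted ASE truth.

Every downstream stage of the library can be exercised on this bundle:
allele counts carry a planted allele ratio composed with a per-pair
mapping bias, and each locus has exactly one truth record.
"""

from aselof import SimConfig, simulate_cohort

cfg = SimConfig(n_patients=4, n_genes=25, seed=42)
bundle = simulate_cohort(cfg)

print("patients:", bundle.patients)
print("RNA count rows:", len(bundle.rna_counts))
print("\nfirst sites:")
print(bundle.rna_counts.head(4).to_string(index=False))

print("\nplanted pattern mix (per patient x gene locus):")
print(bundle.truth["pattern"].value_counts().to_string())
print("\nplanted mechanisms at imbalanced loci:")
print(bundle.truth["mechanism"].value_counts().to_string())

# The pattern labels describe how ASE changes from normal to tumor:
# P1/P4 gain ASE in the tumor (alt- or ref-skewed), P2/P5 lose it,
# P3/P6 flip direction. Mechanism 'cnv' loci also skew the tumor DNA.
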