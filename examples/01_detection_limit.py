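"""Detection-limit arithmetic and VAF-to-prevalence conversion.

How rare a clone can a duplex assay see? The ceiling is set by the number of
genome copies in the input DNA, not by sequencing depth: 250 ng of human DNA
holds ~38,000 diploid genome equivalents, so a mutation needs to be present
in roughly 1 in 40,000 cells before even a perfect assay can find two
supporting molecules.
"""
from dupliseq import detection_limit, vaf_to_prevalence

for mass in (250.0, 100.0):
    d = detection_limit(mass)
    print(f"{mass:.0f} ng input: {d.cell_equivalents:,.0f} cell equivalents "
          f"(~{d.cell_equivalents_1sf:,.0f}); limiting prevalence "
          f"{d.limiting_prevalence_pct:.4f}% (~{d.limiting_prevalence_pct_1sf:.3f}%) "
          f"at {d.min_supporting_molecules} supporting molecules")

print()
print("Heterozygous-diploid VAF -> percent of cells carrying the mutation:")
for vaf in (0.01, 0.0003, 0.0017, 0.5):
    print(f"  VAF {vaf:<7} -> {vaf_to_prevalence(vaf):g}% of cells")
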