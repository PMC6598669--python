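"""Deriving reference driver sets from overlapping published-style driver lists.

Given several curated driver-gene lists, the strict intersection forms the
primary reference set and the genes supported by at least two lists form an
extended reference set for evaluation.
"""

from pathreach import derive_reference_sets

vogelstein_style = {"TP53", "KRAS", "BRAF", "PTEN", "APC", "EGFR"}
census_style = {"TP53", "KRAS", "BRAF", "PTEN", "NRAS", "MYC", "ALK"}
cohort_style = {"TP53", "KRAS", "PTEN", "NRAS", "SMAD4"}

part = derive_reference_sets([vogelstein_style, census_style, cohort_style])

n = len(part.union)
print(f"union of the three lists: {n} genes")
for k in (3, 2, 1):
    c = part.overlap_counts[k]
    print(f"  in exactly {k} list(s): {c} ({100 * c / n:.1f}%)")
print(f"strict reference set (all lists): {sorted(part.in_all)}")
print(f"extended reference set (>= 2 lists): {sorted(part.in_at_least_two)}")
# The strict set is the resemblance template for prioritization; the
# extended set is the larger gold standard used when scoring predictions.
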