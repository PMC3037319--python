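"""Classify the bundled published candidate miRNAs through the full funnel.

Loads the 20-locus prostate candidate table shipped with the package
(regional t-statistics for RNA / DNA methylation / H3K9Ac plus mature-miRNA
fold changes for LNCaP-vs-PrEC and the two 5-Aza-CdR contrasts), runs the
concordance classifier and prints the nested funnel counts and the final
candidates.
"""

from epimir import classify_all, venn_summary
from epimir.datasets import candidate_fixture

region_stats, contrasts = candidate_fixture()
calls = classify_all(region_stats, contrasts)

print("Funnel counts (cumulative per tier):")
print(venn_summary(calls))
print()
for direction in ("up", "down"):
    finals = sorted(
        c.mirna_id for c in calls
        if c.tier == "final" and c.expr_direction == direction
    )
    print(f"final {direction}-regulated candidates: {finals}")
print()
print(
    "Reading: of the expression-concordant candidates, the all_assays column\n"
    "counts loci whose DNA methylation AND H3K9Ac both changed concordantly\n"
    "(|t| >= 2), and 'final' additionally requires 5-Aza-CdR reactivation\n"
    "(p < 0.05, fold change > 1) in the cell line predicted to be methylated."
)
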