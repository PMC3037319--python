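"""Fit the regional probe-level linear model on a tiny two-probe design.

The model log2(intensity) ~ probe + condition estimates the average
LNCaP-minus-PrEC change across a miRNA's +/-500 bp window after absorbing
probe-specific affinity. Here two probes are measured in duplicate in both
cells with a planted 1.0 log2 shift.
"""

import pandas as pd

from epimir import fit_region_model

values = pd.DataFrame(
    {
        "PrEC_1": [1.0, 3.0], "PrEC_2": [1.2, 3.2],
        "LNCaP_1": [2.0, 4.0], "LNCaP_2": [2.2, 4.2],
    },
    index=["probe1", "probe2"],
)
stat = fit_region_model(values, condition=[0, 0, 1, 1],
                        locus_id="MIRX", assay="RNA")
print(f"effect (log2 LNCaP - PrEC): {stat.effect:.3f}")
print(f"standard error:             {stat.se:.4f}")
print(f"t-statistic:                {stat.t_statistic:.2f}  (df={stat.df})")
print()
print(
    "Reading: the probe baselines (1 vs 3) are absorbed by the probe terms;\n"
    "the condition coefficient recovers the planted 1.0 log2 shift, and\n"
    "|t| >= 2 would call this region significantly changed."
)
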