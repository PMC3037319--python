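"""Bundled reference data.

``load_candidate_table`` ships the published candidate statistics from a
prostate cell-line study (PrEC vs LNCaP, ± 5-Aza-CdR): regional t-statistics
for RNA, DNA methylation and H3K9Ac at 20 candidate miRNA loci, and mature
miRNA fold changes for the three contrasts with their significance stars.
The table serves as a worked reference input for the concordance classifier.
"""

from __future__ import annotations

from importlib import resources

import math

import pandas as pd

from .qpcr import ContrastResult, call_mature_differential
from .tiling import RegionStat, call_regions

#: p-values encoding the published significance stars (the source prints
#: stars, not p-values): starred -> clearly below 0.05, unstarred -> above
STAR_P = 0.01
NO_STAR_P = 0.5


def load_candidate_table() -> pd.DataFrame:
    """The published candidate table as a DataFrame."""
    ref = resources.files("epimir").joinpath("data/prostate_candidates.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in [c for c in df.columns if c.startswith("star_")]:
        df[col] = df[col].fillna("").astype(str).str.strip()
    return df


def candidate_fixture() -> tuple[list[RegionStat], list[ContrastResult]]:
    """Classifier inputs built from the published candidate table.

    Region statistics carry the printed t-statistics (the effect is taken as
    the sign-matching t value; only sign and magnitude enter the classifier);
    contrast results carry the printed fold changes with stars encoded as
    p = 0.01 (starred) / 0.5 (unstarred).
    """
    df = load_candidate_table()
    region_stats: list[RegionStat] = []
    contrasts: list[ContrastResult] = []
    for row in df.itertuples():
        for assay, t in (
            ("RNA", row.rna_t), ("MeDIP", row.meth_t), ("H3K9Ac", row.ac_t)
        ):
            region_stats.append(
                RegionStat(
                    locus_id=row.mirna_id, assay=assay, n_probes=50,
                    effect=float(t), se=1.0, t_statistic=float(t), df=100,
                )
            )
        for name in ("LvP", "Lv5Aza", "Pv5Aza"):
            fc = float(getattr(row, f"fc_{name}"))
            starred = getattr(row, f"star_{name}") == "*"
            contrasts.append(
                ContrastResult(
                    target_id=row.mirna_id, contrast=name,
                    fold_change=fc, log2fc=math.log2(fc),
                    p_value=STAR_P if starred else NO_STAR_P,
                )
            )
    region_stats = call_regions(region_stats)
    lvp = [c for c in contrasts if c.contrast == "LvP"]
    aza = [c for c in contrasts if c.contrast != "LvP"]
    call_mature_differential(lvp, fc_cut=1.5)
    call_mature_differential(aza, fc_cut=1.0)
    return region_stats, lvp + aza
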