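"""Multi-omic concordance classification of epigenetically deregulated miRNAs.

The discovery funnel intersects three evidence layers per miRNA, all
articulated as LNCaP (prostate cancer) with respect to PrEC (normal prostate
epithelium):

1. expression concordance — the tiling-array primary-transcript region call
   and the mature-miRNA qPCR call must both be significant in the same
   direction;
2. epigenetic marks — DNA methylation (MeDIP) and H3K9Ac regional t-statistics
   are classified as canonical (methylation loss + H3K9Ac gain for activated
   loci; methylation gain + H3K9Ac loss for repressed loci), non-canonical
   (significant but discordant with the expression change) or not significant;
3. pharmacologic reactivation — a 5-Aza-CdR induced increase in the mature
   miRNA (p < 0.05, fold change > 1) in PrEC for activated candidates
   (hypomethylated-in-cancer loci reactivate in the normal line) and in LNCaP
   for repressed candidates.

Tiers nest: expression_only ⊇ one_mark ⊇ all_assays ⊇ final. A locus whose
significant marks all oppose its expression change is flagged non-canonical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .qpcr import ContrastResult
from .tiling import RegionStat, T_CUTOFF

logger = logging.getLogger(__name__)

TIER_ORDER = ("not_candidate", "expression_only", "one_mark", "all_assays", "final")


@dataclass
class EpigeneticCall:
    """Tiered verdict for one miRNA."""

    mirna_id: str
    expr_direction: str = "none"        # up / down / none
    meth_status: str = "not_significant"   # canonical / non_canonical / not_significant
    ac_status: str = "not_significant"
    tier: str = "not_candidate"
    non_canonical: bool = False
    aza_reactivated: bool = False
    aza_cell_used: str = "none"         # PrEC / LNCaP / none

    def tier_at_least(self, tier: str) -> bool:
        return TIER_ORDER.index(self.tier) >= TIER_ORDER.index(tier)


def expression_concordance(
    rna: RegionStat, mature_lvp: ContrastResult
) -> str:
    """Direction shared by primary-transcript and mature expression calls.

    'up'/'down' only when both calls are significant with the same sign;
    'none' otherwise, including discordant significance.
    """
    if not (rna.significant and mature_lvp.significant):
        return "none"
    if rna.direction == mature_lvp.direction and rna.direction in ("up", "down"):
        return rna.direction
    return "none"


def mark_status(
    expr_direction: str,
    meth: RegionStat,
    ac: RegionStat,
    cutoff: float = T_CUTOFF,
) -> tuple[str, str]:
    """Classify each epigenetic mark relative to the expression change.

    For an activated locus, canonical methylation is loss (t <= -cutoff) and
    canonical H3K9Ac is gain (t >= cutoff); for a repressed locus the signs
    mirror. A significant mark in the opposite direction is non-canonical.
    """
    if expr_direction not in ("up", "down"):
        raise ValueError("mark_status requires a concordant expression direction")
    sign = 1.0 if expr_direction == "up" else -1.0

    def status(t: float, canonical_sign: float) -> str:
        if abs(t) < cutoff:
            return "not_significant"
        return "canonical" if t * canonical_sign > 0 else "non_canonical"

    # methylation opposes expression (repressive mark), H3K9Ac tracks it
    meth_status = status(meth.t_statistic, -sign)
    ac_status = status(ac.t_statistic, sign)
    return meth_status, ac_status


def classify(
    mirna_id: str,
    rna: RegionStat,
    meth: RegionStat,
    ac: RegionStat,
    mature: Mapping[str, ContrastResult],
    cutoff: float = T_CUTOFF,
    aza_fc_cut: float = 1.0,
) -> EpigeneticCall:
    """Run the full funnel for one miRNA.

    ``mature`` maps contrast name -> ContrastResult and must contain 'LvP';
    'Pv5Aza' / 'Lv5Aza' feed the reactivation filter. A missing reactivation
    contrast caps the tier at all_assays with a warning.
    """
    call = EpigeneticCall(mirna_id=mirna_id)
    if "LvP" not in mature:
        raise ValueError(f"{mirna_id}: LvP mature contrast is required")
    call.expr_direction = expression_concordance(rna, mature["LvP"])
    if call.expr_direction == "none":
        return call
    call.tier = "expression_only"

    call.meth_status, call.ac_status = mark_status(
        call.expr_direction, meth, ac, cutoff
    )
    statuses = (call.meth_status, call.ac_status)
    if "canonical" in statuses:
        call.tier = "one_mark"
    elif "non_canonical" in statuses:
        call.non_canonical = True
    if statuses == ("canonical", "canonical"):
        call.tier = "all_assays"

    # 5-Aza-CdR reactivation: the cell line where the locus is methylated
    aza_contrast = "Pv5Aza" if call.expr_direction == "up" else "Lv5Aza"
    aza = mature.get(aza_contrast)
    if aza is None:
        logger.warning(
            "%s: missing %s contrast; tier capped at all_assays",
            mirna_id, aza_contrast,
        )
        return call
    call.aza_cell_used = "PrEC" if aza_contrast == "Pv5Aza" else "LNCaP"
    call.aza_reactivated = bool(
        aza.p_value < 0.05 and aza.fold_change > aza_fc_cut
    )
    if call.tier == "all_assays" and call.aza_reactivated:
        call.tier = "final"
    return call


def classify_all(
    region_stats: Iterable[RegionStat],
    contrasts: Iterable[ContrastResult],
    universe: Sequence[str] | None = None,
    cutoff: float = T_CUTOFF,
    aza_fc_cut: float = 1.0,
) -> list[EpigeneticCall]:
    """Classify every miRNA in the platform-intersection universe.

    ``universe`` restricts calls to miRNAs assayed on both platforms; by
    default it is the intersection of locus ids seen in region stats and
    mature contrasts. miRNAs missing an assay are skipped with a warning.
    """
    by_assay: dict[str, dict[str, RegionStat]] = {}
    for rs in region_stats:
        by_assay.setdefault(rs.locus_id, {})[rs.assay] = rs
    by_contrast: dict[str, dict[str, ContrastResult]] = {}
    for cr in contrasts:
        by_contrast.setdefault(cr.target_id, {})[cr.contrast] = cr

    if universe is None:
        universe = sorted(set(by_assay) & set(by_contrast))
    calls = []
    for mid in universe:
        stats = by_assay.get(mid, {})
        mature = by_contrast.get(mid, {})
        missing = {"RNA", "MeDIP", "H3K9Ac"} - set(stats)
        if missing or "LvP" not in mature:
            logger.warning("%s: incomplete data (%s); skipped", mid, missing)
            continue
        calls.append(
            classify(
                mid, stats["RNA"], stats["MeDIP"], stats["H3K9Ac"],
                mature, cutoff=cutoff, aza_fc_cut=aza_fc_cut,
            )
        )
    return calls


def venn_summary(calls: Iterable[EpigeneticCall]) -> pd.DataFrame:
    """Nested funnel counts per tier and direction.

    Counts are cumulative ('tier or better'), so they are non-increasing
    along expression_only -> one_mark -> all_assays -> final by construction
    of the tier ordering. Non-canonical loci are counted separately.
    """
    calls = list(calls)
    rows = []
    for direction in ("up", "down"):
        sub = [c for c in calls if c.expr_direction == direction]
        row = {"direction": direction}
        for tier in ("expression_only", "one_mark", "all_assays", "final"):
            row[tier] = sum(c.tier_at_least(tier) for c in sub)
        row["non_canonical"] = sum(c.non_canonical for c in sub)
        rows.append(row)
    return pd.DataFrame(rows).set_index("direction")


def candidate_report(
    calls: Iterable[EpigeneticCall],
    region_stats: Iterable[RegionStat],
    contrasts: Iterable[ContrastResult],
) -> pd.DataFrame:
    """Publication-style candidate table: one row per one_mark-or-better miRNA.

    Columns carry the three regional t-statistics and the three mature
    fold changes with a significance star (p < 0.05).
    """
    by_assay: dict[str, dict[str, RegionStat]] = {}
    for rs in region_stats:
        by_assay.setdefault(rs.locus_id, {})[rs.assay] = rs
    by_contrast: dict[str, dict[str, ContrastResult]] = {}
    for cr in contrasts:
        by_contrast.setdefault(cr.target_id, {})[cr.contrast] = cr

    rows = []
    for call in calls:
        if not call.tier_at_least("one_mark"):
            continue
        stats = by_assay[call.mirna_id]
        mature = by_contrast[call.mirna_id]
        row = {
            "mirna_id": call.mirna_id,
            "direction": call.expr_direction,
            "rna_t": stats["RNA"].t_statistic,
            "meth_t": stats["MeDIP"].t_statistic,
            "ac_t": stats["H3K9Ac"].t_statistic,
            "tier": call.tier,
        }
        for name in ("LvP", "Lv5Aza", "Pv5Aza"):
            cr = mature.get(name)
            if cr is None:
                row[f"fc_{name}"] = float("nan")
                row[f"star_{name}"] = ""
            else:
                row[f"fc_{name}"] = cr.fold_change
                row[f"star_{name}"] = "*" if cr.p_value < 0.05 else ""
        rows.append(row)
    columns = [
        "mirna_id", "direction", "rna_t", "meth_t", "ac_t",
        "fc_LvP", "star_LvP", "fc_Lv5Aza", "star_Lv5Aza",
        "fc_Pv5Aza", "star_Pv5Aza", "tier",
    ]
    return pd.DataFrame(rows, columns=columns)


def calls_frame(calls: Iterable[EpigeneticCall]) -> pd.DataFrame:
    """Flatten EpigeneticCalls to the tabular output layout."""
    return pd.DataFrame(
        [
            {
                "mirna_id": c.mirna_id, "expr_direction": c.expr_direction,
                "meth_status": c.meth_status, "ac_status": c.ac_status,
                "tier": c.tier, "non_canonical": c.non_canonical,
                "aza_reactivated": c.aza_reactivated,
                "aza_cell_used": c.aza_cell_used,
            }
            for c in calls
        ]
    )
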