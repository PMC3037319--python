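"""End-to-end pipeline driver over synthetic or pre-loaded inputs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from . import simulate as sim
from .classify import (
    EpigeneticCall, calls_frame, candidate_report, classify_all, venn_summary,
)
from .io import write_bed_reads, write_ct_table, write_intensity_table, write_probe_panel
from .loci import MirnaLocus, write_loci_bed
from .mbdcap import enrichment_table
from .qpcr import ContrastResult, contrasts_frame, mature_contrasts, pri_quantification
from .simulate import SimulationParams
from .tiling import RegionStat, analyze_assay, region_stats_frame


@dataclass
class PipelineResult:
    loci: list[MirnaLocus]
    truth: list[sim.TruthRecord]
    region_stats: list[RegionStat]
    contrasts: list[ContrastResult]
    calls: list[EpigeneticCall]
    venn: pd.DataFrame
    report: pd.DataFrame
    mbdcap: pd.DataFrame
    pri: pd.DataFrame


def run_synthetic_pipeline(
    params: SimulationParams,
    outdir: str | Path | None = None,
    with_mbdcap: bool = True,
    with_pri: bool = True,
) -> PipelineResult:
    """Simulate a full study and run every analysis stage on it.

    When ``outdir`` is given, all intermediate tables are written in the
    package's TSV/BED formats alongside the truth table for scoring.
    """
    loci = sim.simulate_loci(params)
    truth = sim.simulate_truth(params)
    panel = sim.simulate_panel(params, loci)
    tiling = sim.simulate_tiling(truth, loci, panel, params)

    region_stats: list[RegionStat] = []
    for assay, matrix in tiling.items():
        region_stats.extend(analyze_assay(matrix, loci, assay))

    tlda = sim.simulate_tlda(truth, params)
    contrasts = mature_contrasts(tlda)
    calls = classify_all(region_stats, contrasts)
    venn = venn_summary(calls)
    report = candidate_report(calls, region_stats, contrasts)

    final_ids = [c.mirna_id for c in calls if c.tier == "final"]
    pri = pd.DataFrame()
    if with_pri and final_ids:
        pri_ct = sim.simulate_pri_qpcr(truth, params, targets=final_ids)
        pri = pri_quantification(pri_ct)

    mbd = pd.DataFrame()
    if with_mbdcap:
        ip_reads, input_reads = sim.simulate_mbdcap(truth, loci, params)
        mbd = enrichment_table(ip_reads, input_reads, loci)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_loci_bed(loci, outdir / "loci.bed")
        write_probe_panel(panel, outdir / "probe_panel.tsv")
        sim.write_truth_table(truth, outdir / "truth.tsv")
        for assay, matrix in tiling.items():
            write_intensity_table(matrix, outdir / f"intensity_{assay}.tsv")
        write_ct_table(tlda, outdir / "tlda_ct.tsv")
        region_stats_frame(region_stats).to_csv(
            outdir / "region_stats.tsv", sep="\t", index=False
        )
        contrasts_frame(contrasts).to_csv(
            outdir / "mature_contrasts.tsv", sep="\t", index=False
        )
        calls_frame(calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
        venn.to_csv(outdir / "venn_summary.tsv", sep="\t")
        report.to_csv(outdir / "candidate_report.tsv", sep="\t", index=False)
        if not pri.empty:
            pri.to_csv(outdir / "pri_quant.tsv", sep="\t", index=False)
        if not mbd.empty:
            mbd.to_csv(outdir / "mbdcap_counts.tsv", sep="\t", index=False)
        if with_mbdcap:
            for cell, reads in ip_reads.items():
                write_bed_reads(reads, outdir / f"mbdcap_ip_{cell}.bed")
            for cell, reads in input_reads.items():
                write_bed_reads(reads, outdir / f"mbdcap_input_{cell}.bed")

    return PipelineResult(
        loci=loci, truth=truth, region_stats=region_stats,
        contrasts=contrasts, calls=calls, venn=venn, report=report,
        mbdcap=mbd, pri=pri,
    )


def recovery_rates(result: PipelineResult) -> pd.DataFrame:
    """Class-conditional recovery of planted loci by the classifier.

    For each planted regulation class, the fraction of loci reaching the
    one_mark, all_assays and final tiers (canonical classes) or flagged
    non-canonical, plus the false-positive rate of planted-none loci.
    """
    call_by_id = {c.mirna_id: c for c in result.calls}
    rows = []
    classes = ["none", *sim.REGULATION_CLASSES]
    for cls in classes:
        ids = [t.locus_id for t in result.truth if t.regulation_class == cls]
        if not ids:
            continue
        calls = [call_by_id[i] for i in ids if i in call_by_id]
        n = len(ids)
        rows.append(
            {
                "regulation_class": cls,
                "n": n,
                "expression_only": sum(
                    c.tier_at_least("expression_only") for c in calls
                ) / n,
                "one_mark": sum(c.tier_at_least("one_mark") for c in calls) / n,
                "all_assays": sum(c.tier_at_least("all_assays") for c in calls) / n,
                "final": sum(c.tier_at_least("final") for c in calls) / n,
                "non_canonical": sum(c.non_canonical for c in calls) / n,
            }
        )
    return pd.DataFrame(rows)
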