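"""Synthetic multi-omic data with planted ground truth.

Emulates the study design the pipeline analyzes: a custom tiling array of
60-nt positive-strand probes over ±2000 bp of each miRNA locus, assayed for
total RNA, MeDIP and H3K9Ac in PrEC and LNCaP biological duplicates; TLDA
mature-miRNA Ct tables over four conditions (both cells ± 5-Aza-CdR) with a
stable RNU48 reference; pri-miRNA qPCR with six replicates per group and an
18S reference; and 36-bp MBD-capture reads piled up at methylated loci.

The tiling model is additive on the log2 scale — baseline + probe affinity +
condition effect + replicate noise — matching the multiplicative affinity
behavior of hybridization arrays and, by construction, the downstream
probe+condition regional linear model, so parameter recovery is a fair test.
Planted epigenetic effects are confined to ±500 bp of the locus center, the
window the regional model reads. One planted log2 unit of expression moves
Ct by -1 cycle (amplification efficiency 2).

All generators are pure functions of (params, seed): a single master seed is
split into per-stage substreams so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CtTable, IntensityMatrix, ReadInterval, SampleMeta, MAX_CYCLES
from .loci import MirnaLocus, ProbeFeature, design_probe_panel
from .tiling import REGION_HALF_WIDTH

REGULATION_CLASSES = (
    "canonical_up", "canonical_down",
    "noncanonical_up", "noncanonical_down",
    "expression_only_up", "expression_only_down",
)

#: per-stage substream labels carved from the master seed
_STAGES = ("truth", "tiling", "tlda", "pri", "mbdcap")


@dataclass(frozen=True)
class TruthRecord:
    """Planted regulation state of one simulated locus."""

    locus_id: str
    regulation_class: str
    rna_log2fc: float
    medip_log2fc: float
    h3k9ac_log2fc: float
    mature_log2fc: Mapping[str, float]  # per contrast: LvP, Lv5Aza, Pv5Aza


@dataclass
class SimulationParams:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the analyzed study conditions: 341 loci assayed on both
    platforms, biological duplicates, and planted 4-fold (2 log2) effects.
    """

    n_loci: int = 341
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {c: 0.05 for c in REGULATION_CLASSES}
    )
    effect_size_log2: float = 2.0
    baseline_log2: float = 10.0
    probe_affinity_sd: float = 1.0
    noise_sd: float = 0.3
    replicates: int = 2
    ct_noise_sd: float = 0.25
    base_ct_range: tuple[float, float] = (22.0, 30.0)
    reference_ct: float = 20.0
    pri_replicates: int = 6
    read_depth: float = 50.0
    read_length: int = 36
    probe_len: int = 60
    probe_step: int = 20
    tile_half_width: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_fractions) - set(REGULATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown regulation classes: {sorted(unknown)}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be >= 0")
        if sum(self.class_fractions.values()) > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("probe_affinity_sd", "noise_sd", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _stage_rng(params: SimulationParams, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(params.seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES.index(stage)])


# ---------------------------------------------------------------------------
# loci and truth

def simulate_loci(params: SimulationParams) -> list[MirnaLocus]:
    """Synthetic pre-miRNA loci spaced far beyond the tiled windows.

    Loci are 80 bp hairpin-scale intervals placed every 100 kb along
    synthetic chromosomes of 600 loci each, so tiled windows never collide.
    """
    loci = []
    per_chrom = 600
    for i in range(params.n_loci):
        chrom = f"chr{i // per_chrom + 1}"
        start = 100_000 * (i % per_chrom) + 50_000
        loci.append(
            MirnaLocus(
                id=f"MIRS{i:04d}", chrom=chrom, start=start, end=start + 80,
                strand="+",
            )
        )
    return loci


def simulate_truth(params: SimulationParams) -> list[TruthRecord]:
    """Assign planted regulation classes and effect sizes to the loci.

    Exactly floor(fraction * n_loci) loci receive each class, placed by a
    seeded permutation; the remainder is class 'none' with zero effects.
    """
    rng = _stage_rng(params, "truth")
    n = params.n_loci
    order = rng.permutation(n)
    labels = ["none"] * n
    pos = 0
    for cls in REGULATION_CLASSES:
        count = int(np.floor(params.class_fractions.get(cls, 0.0) * n))
        for j in range(count):
            labels[order[pos + j]] = cls
        pos += count

    e = params.effect_size_log2
    records = []
    for i in range(n):
        cls = labels[i]
        rna = medip = ac = 0.0
        mature = {"LvP": 0.0, "Lv5Aza": 0.0, "Pv5Aza": 0.0}
        if cls.endswith("_up"):
            rna, mature["LvP"] = e, e
        elif cls.endswith("_down"):
            rna, mature["LvP"] = -e, -e
        if cls == "canonical_up":
            medip, ac = -e, e
            mature["Pv5Aza"] = e     # hypomethylated in cancer: PrEC reactivates
        elif cls == "canonical_down":
            medip, ac = e, -e
            mature["Lv5Aza"] = e     # hypermethylated in cancer: LNCaP reactivates
        elif cls == "noncanonical_up":
            medip, ac = e, -e
        elif cls == "noncanonical_down":
            medip, ac = -e, e
        records.append(
            TruthRecord(
                locus_id=f"MIRS{i:04d}", regulation_class=cls,
                rna_log2fc=rna, medip_log2fc=medip, h3k9ac_log2fc=ac,
                mature_log2fc=mature,
            )
        )
    return records


def write_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "locus_id": t.locus_id, "regulation_class": t.regulation_class,
                "rna_log2fc": t.rna_log2fc, "medip_log2fc": t.medip_log2fc,
                "h3k9ac_log2fc": t.h3k9ac_log2fc,
                **{f"mature_{k}": v for k, v in t.mature_log2fc.items()},
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tiling arrays

def simulate_tiling(
    truth: Sequence[TruthRecord],
    loci: Sequence[MirnaLocus],
    panel: Sequence[ProbeFeature],
    params: SimulationParams,
) -> dict[str, IntensityMatrix]:
    """Raw tiling-array intensity matrices for RNA, MeDIP and H3K9Ac.

    log2 intensity = baseline + probe affinity + planted effect (LNCaP, probes
    overlapping ±500 bp of the locus center only) + N(0, noise_sd); raw
    output is 2^log2. PrEC carries no condition effect.
    """
    rng = _stage_rng(params, "tiling")
    truth_by_id = {t.locus_id: t for t in truth}
    centers = {l.id: l.center for l in loci}
    missing = {p.locus_id for p in panel} - set(centers)
    if missing:
        raise ValueError(f"panel references unknown loci: {sorted(missing)[:3]}")

    in_window = np.array(
        [
            p.start < centers[p.locus_id] + REGION_HALF_WIDTH
            and p.end > centers[p.locus_id] - REGION_HALF_WIDTH
            for p in panel
        ]
    )
    effect_of = {
        "RNA": lambda t: t.rna_log2fc,
        "MeDIP": lambda t: t.medip_log2fc,
        "H3K9Ac": lambda t: t.h3k9ac_log2fc,
    }
    out: dict[str, IntensityMatrix] = {}
    for assay, getter in effect_of.items():
        affinity = rng.normal(0.0, params.probe_affinity_sd, size=len(panel))
        planted = np.array(
            [getter(truth_by_id[p.locus_id]) for p in panel]
        ) * in_window
        samples = [
            SampleMeta(assay=assay, cell=cell, treatment="none", replicate=r)
            for cell in ("PrEC", "LNCaP")
            for r in range(1, params.replicates + 1)
        ]
        cols = {}
        for s in samples:
            mu = params.baseline_log2 + affinity
            if s.cell == "LNCaP":
                mu = mu + planted
            noise = rng.normal(0.0, params.noise_sd, size=len(panel))
            cols[s.sample_id] = 2.0 ** (mu + noise)
        values = pd.DataFrame(cols, index=[p.probe_id for p in panel])
        out[assay] = IntensityMatrix(
            probes=list(panel), samples=samples, values=values, log2=False
        )
    return out


# ---------------------------------------------------------------------------
# qPCR Ct tables

def _expression_rel_baseline(t: TruthRecord, cell: str, treatment: str) -> float:
    """Planted log2 expression relative to untreated PrEC."""
    lvp = t.mature_log2fc["LvP"]
    if cell == "PrEC":
        return 0.0 if treatment == "none" else t.mature_log2fc["Pv5Aza"]
    return lvp if treatment == "none" else lvp + t.mature_log2fc["Lv5Aza"]


def _ct_table(
    truth: Sequence[TruthRecord],
    params: SimulationParams,
    rng: np.random.Generator,
    reference: str,
    replicates: int,
    targets: Sequence[str] | None = None,
) -> CtTable:
    truth_by_id = {t.locus_id: t for t in truth}
    ids = list(targets) if targets is not None else [t.locus_id for t in truth]
    samples = [
        SampleMeta(assay="RNA", cell=cell, treatment=trt, replicate=r)
        for cell in ("PrEC", "LNCaP")
        for trt in ("none", "aza")
        for r in range(1, replicates + 1)
    ]
    base_ct = {
        tid: rng.uniform(*params.base_ct_range) for tid in ids
    }
    rows = {}
    for tid in ids:
        t = truth_by_id[tid]
        row = []
        for s in samples:
            expr = _expression_rel_baseline(t, s.cell, s.treatment)
            ct = base_ct[tid] - expr + rng.normal(0.0, params.ct_noise_sd)
            if ct <= 0:
                raise ValueError(
                    f"planted fold change drives Ct <= 0 for {tid}"
                )
            row.append(min(ct, MAX_CYCLES))
        rows[tid] = row
    rows[reference] = [
        params.reference_ct + rng.normal(0.0, params.ct_noise_sd)
        for _ in samples
    ]
    ct = pd.DataFrame.from_dict(
        rows, orient="index", columns=[s.sample_id for s in samples]
    )
    censored = pd.DataFrame(
        False, index=ct.index, columns=ct.columns
    )
    return CtTable(ct=ct, censored=censored, samples=samples)


def simulate_tlda(
    truth: Sequence[TruthRecord], params: SimulationParams
) -> CtTable:
    """Mature-miRNA TLDA Ct table: four conditions x biological duplicates."""
    rng = _stage_rng(params, "tlda")
    return _ct_table(truth, params, rng, reference="RNU48",
                     replicates=params.replicates)


def simulate_pri_qpcr(
    truth: Sequence[TruthRecord],
    params: SimulationParams,
    targets: Sequence[str] | None = None,
) -> CtTable:
    """pri-miRNA qPCR Ct table (n = 6 per group by default, 18S reference)."""
    rng = _stage_rng(params, "pri")
    return _ct_table(truth, params, rng, reference="18S",
                     replicates=params.pri_replicates, targets=targets)


# ---------------------------------------------------------------------------
# MBD-capture reads

def simulate_mbdcap(
    truth: Sequence[TruthRecord],
    loci: Sequence[MirnaLocus],
    params: SimulationParams,
    half_width: int = 300,
) -> tuple[dict[str, list[ReadInterval]], dict[str, list[ReadInterval]]]:
    """Capture-sequencing reads around each locus for both cells.

    IP read counts per locus are Poisson(depth · 2^(medip_log2fc · cell_sign))
    with cell_sign 1 in LNCaP and 0 in PrEC; input controls are
    Poisson(depth). Reads are ``read_length`` bp, placed uniformly inside the
    ±``half_width`` window. Returns (ip_reads, input_reads) keyed by cell.
    """
    rng = _stage_rng(params, "mbdcap")
    truth_by_id = {t.locus_id: t for t in truth}
    ip: dict[str, list[ReadInterval]] = {}
    inp: dict[str, list[ReadInterval]] = {}
    for cell in ("PrEC", "LNCaP"):
        cell_sign = 1.0 if cell == "LNCaP" else 0.0
        ip_reads: list[ReadInterval] = []
        input_reads: list[ReadInterval] = []
        for locus in loci:
            t = truth_by_id[locus.id]
            lam_ip = params.read_depth * 2.0 ** (t.medip_log2fc * cell_sign)
            for dest, lam, label in (
                (ip_reads, lam_ip, "IP"),
                (input_reads, params.read_depth, "input"),
            ):
                n = int(rng.poisson(lam)) if lam > 0 else 0
                if n == 0:
                    continue
                lo = locus.center - half_width
                hi = locus.center + half_width - params.read_length
                starts = rng.integers(lo, max(hi, lo + 1), size=n)
                dest.extend(
                    ReadInterval(
                        chrom=locus.chrom, start=int(s),
                        end=int(s) + params.read_length,
                        sample_id=f"{label}:{cell}",
                    )
                    for s in starts
                )
        ip[cell] = ip_reads
        inp[cell] = input_reads
    return ip, inp


def simulate_panel(params: SimulationParams, loci: Sequence[MirnaLocus]) -> list[ProbeFeature]:
    """Probe panel tiling every locus at the simulated array's geometry."""
    return design_probe_panel(
        loci, probe_len=params.probe_len, step=params.probe_step,
        half_width=params.tile_half_width,
    )
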