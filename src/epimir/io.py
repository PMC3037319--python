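"""Tabular I/O: intensity matrices, Ct tables, probe panels and read intervals.

All tables are plain TSV (tab-separated, '.' decimal, mandatory header,
UTF-8); sequencing reads are BED. Sample metadata is encoded in the sample id
as ``assay:cell:treatment:rep`` (e.g. ``RNA:LNCaP:none:1``) so that a single
header row round-trips the full design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .loci import ParseError, ProbeFeature

ASSAYS = ("RNA", "MeDIP", "H3K9Ac", "input")
CELLS = ("PrEC", "LNCaP")
TREATMENTS = ("none", "aza")

#: censoring bound for "Undetermined" qPCR wells (cycles of amplification)
MAX_CYCLES = 40.0


@dataclass(frozen=True)
class SampleMeta:
    """One array/qPCR sample: assay, cell line, 5-Aza treatment, replicate."""

    assay: str
    cell: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.cell not in CELLS:
            raise ValueError(f"unknown cell {self.cell!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def sample_id(self) -> str:
        return f"{self.assay}:{self.cell}:{self.treatment}:{self.replicate}"

    @classmethod
    def from_id(cls, sample_id: str) -> "SampleMeta":
        try:
            assay, cell, treatment, rep = sample_id.split(":")
            return cls(assay=assay, cell=cell, treatment=treatment, replicate=int(rep))
        except Exception as exc:
            raise ParseError(f"malformed sample id {sample_id!r}") from exc


@dataclass
class IntensityMatrix:
    """Probes x samples tiling-array intensities with sample metadata.

    ``values`` is indexed by probe_id with one column per sample_id;
    ``log2`` records whether values are on the log2 scale.
    """

    probes: list[ProbeFeature]
    samples: list[SampleMeta]
    values: pd.DataFrame
    log2: bool = False

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample metadata")
        if list(self.values.columns) != ids:
            raise ValueError("values columns must match sample ids in order")
        if list(self.values.index) != [p.probe_id for p in self.probes]:
            raise ValueError("values index must match probe ids in order")
        if self.values.isna().any().any():
            raise ValueError("intensity matrix contains missing values")
        if not self.log2 and (self.values.values <= 0).any():
            raise ValueError("raw intensities must be positive")

    def copy_with(self, values: pd.DataFrame, log2: bool) -> "IntensityMatrix":
        return IntensityMatrix(
            probes=self.probes, samples=self.samples, values=values, log2=log2
        )


@dataclass
class CtTable:
    """Targets x samples qPCR Ct values with a censoring mask.

    Censored wells ("Undetermined") carry ct = MAX_CYCLES and censored=True.
    """

    ct: pd.DataFrame            # targets x sample_id, cycles
    censored: pd.DataFrame      # same shape, boolean
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if self.ct.shape != self.censored.shape:
            raise ValueError("ct and censored shapes differ")
        vals = self.ct.values
        if np.isnan(vals).any():
            raise ValueError("Ct table contains missing values")
        if (vals <= 0).any() or (vals > MAX_CYCLES).any():
            raise ValueError(f"Ct values must lie in (0, {MAX_CYCLES}]")

    @property
    def targets(self) -> list[str]:
        return list(self.ct.index)


@dataclass(frozen=True)
class ReadInterval:
    """One aligned capture-sequencing read (0-based half-open)."""

    chrom: str
    start: int
    end: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read start must be < end")


# ---------------------------------------------------------------------------
# probe panels

def write_probe_panel(probes: Iterable[ProbeFeature], path: str | Path) -> None:
    rows = [
        (p.probe_id, p.locus_id, p.chrom, p.start, p.end) for p in probes
    ]
    pd.DataFrame(
        rows, columns=["probe_id", "locus_id", "chrom", "start", "end"]
    ).to_csv(path, sep="\t", index=False)


def read_probe_panel(path: str | Path) -> list[ProbeFeature]:
    df = pd.read_csv(path, sep="\t")
    return [
        ProbeFeature(
            probe_id=str(r.probe_id), locus_id=str(r.locus_id),
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# intensity matrices

def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "probe_id", out.index)
    # shortest-repr floats + correctly rounded parsing: bit-exact round trip
    out.to_csv(path, sep="\t", index=False)


def read_intensity_table(
    path: str | Path, probes: Sequence[ProbeFeature], log2: bool = False
) -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "probe_id" not in df.columns:
        raise ParseError(f"{path}: missing probe_id column")
    df = df.set_index("probe_id")
    if df.isna().any().any():
        row, col = _first_missing(df)
        raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
    samples = [SampleMeta.from_id(c) for c in df.columns]
    by_id = {p.probe_id: p for p in probes}
    try:
        ordered = [by_id[pid] for pid in df.index]
    except KeyError as exc:
        raise ParseError(f"{path}: probe {exc.args[0]!r} not in panel") from exc
    return IntensityMatrix(probes=ordered, samples=samples, values=df, log2=log2)


def _first_missing(df: pd.DataFrame) -> tuple[str, str]:
    mask = df.isna()
    for col in df.columns:
        if mask[col].any():
            return str(mask.index[mask[col]][0]), str(col)
    raise AssertionError("no missing value found")


# ---------------------------------------------------------------------------
# Ct tables

def write_ct_table(table: CtTable, path: str | Path) -> None:
    out = table.ct.copy().astype(object)
    out[table.censored] = "Undetermined"
    out.insert(0, "target", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "target" not in df.columns:
        raise ParseError(f"{path}: missing target column")
    df = df.set_index("target")
    censored = df.apply(lambda c: c.str.lower() == "undetermined")
    ct = df.mask(censored, str(MAX_CYCLES)).astype(float)
    if ct.isna().any().any():
        row, col = _first_missing(ct)
        raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
    if (ct.values > MAX_CYCLES).any():
        raise ParseError(f"{path}: Ct value exceeds {MAX_CYCLES} cycles")
    samples = [SampleMeta.from_id(c) for c in ct.columns]
    return CtTable(ct=ct, censored=censored, samples=samples)


# ---------------------------------------------------------------------------
# BED reads

def write_bed_reads(reads: Iterable[ReadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.sample_id}\n")


def read_bed_reads(path: str | Path) -> list[ReadInterval]:
    reads: list[ReadInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED read needs 4 fields")
            try:
                reads.append(
                    ReadInterval(
                        chrom=fields[0], start=int(fields[1]),
                        end=int(fields[2]), sample_id=fields[3],
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return reads
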