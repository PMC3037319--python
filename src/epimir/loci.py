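"""miRNA locus annotations and tiling-probe panel design.

Coordinates are 0-based half-open throughout the package. BED input is taken
as-is; GFF3 (1-based inclusive) is converted on load. Each locus carries a
derived ``center`` — the floor of the midpoint of the annotated pre-miRNA
interval — which anchors every analysis window downstream (the tiled region,
the regional-model window and the capture-sequencing count window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed annotation or table input."""


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA gene: coordinates, strand and the derived center point."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"locus {self.id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"locus {self.id}: strand must be '+' or '-'")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ProbeFeature:
    """A tiling-array oligo probe, positive strand, assigned to one locus."""

    probe_id: str
    locus_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def load_loci(path: str | Path) -> list[MirnaLocus]:
    """Load miRNA loci from a BED6 or GFF3 file.

    Format is chosen by extension (``.gff``, ``.gff3`` -> GFF3, otherwise BED).
    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Duplicate locus ids are rejected.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    loci: list[MirnaLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if is_gff:
                    locus = _parse_gff3_record(fields)
                else:
                    locus = _parse_bed6_record(fields)
            except ParseError:
                raise
            except Exception as exc:  # malformed field types etc.
                raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if locus.id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate locus id {locus.id!r}")
            seen.add(locus.id)
            loci.append(locus)
    return loci


def _parse_bed6_record(fields: Sequence[str]) -> MirnaLocus:
    if len(fields) < 4:
        raise ParseError(f"BED record needs >= 4 fields, got {len(fields)}")
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5] if len(fields) >= 6 else "+"
    return MirnaLocus(id=name, chrom=chrom, start=start, end=end, strand=strand)


def _parse_gff3_record(fields: Sequence[str]) -> MirnaLocus:
    if len(fields) < 9:
        raise ParseError(f"GFF3 record needs 9 fields, got {len(fields)}")
    chrom = fields[0]
    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
    end = int(fields[4])
    strand = fields[6]
    attrs = dict(
        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
    )
    name = attrs.get("ID") or attrs.get("Name")
    if name is None:
        raise ParseError("GFF3 record lacks ID/Name attribute")
    return MirnaLocus(id=name, chrom=chrom, start=start, end=end, strand=strand)


def write_loci_bed(loci: Iterable[MirnaLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.id}\t0\t{loc.strand}\n")


def design_probe_panel(
    loci: Sequence[MirnaLocus],
    probe_len: int = 60,
    step: int = 20,
    half_width: int = 2000,
) -> list[ProbeFeature]:
    """Tile each locus's window [center - half_width, center + half_width).

    Probes of ``probe_len`` nt are laid on the positive strand at the given
    step, keeping only fully contained probes. Each probe is assigned to the
    locus whose center is nearest (ties broken by lexicographic locus id); a
    warning is logged when two tiled windows overlap.
    """
    if probe_len > 2 * half_width:
        raise ValueError("probe_len must be <= 2 * half_width")
    ordered = sorted(loci, key=lambda l: l.id)
    # warn about windows that collide on the same chromosome
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for loc in ordered:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    # loci whose tiled windows collide with a neighbour need per-probe
    # nearest-center arbitration; isolated loci own all their probes
    contested: dict[str, list[MirnaLocus]] = {}
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda l: l.center)
        for a, b in zip(group, group[1:]):
            if b.center - a.center < 2 * half_width:
                logger.warning(
                    "tiled windows of %s and %s overlap on %s; probes assigned "
                    "by nearest center", a.id, b.id, chrom,
                )
                for loc in (a, b):
                    contested.setdefault(loc.id, []).extend(
                        x for x in (a, b) if x.id != loc.id
                    )

    probes: list[ProbeFeature] = []
    for loc in ordered:
        win_start = loc.center - half_width
        win_end = loc.center + half_width
        rivals = contested.get(loc.id, [])
        idx = 0
        pos = win_start
        while pos + probe_len <= win_end:
            mid = pos + probe_len // 2
            owner = min(
                [loc, *rivals], key=lambda l: (abs(l.center - mid), l.id)
            )
            if owner.id == loc.id:
                probes.append(
                    ProbeFeature(
                        probe_id=f"{loc.id}_p{idx:04d}",
                        locus_id=loc.id,
                        chrom=loc.chrom,
                        start=pos,
                        end=pos + probe_len,
                    )
                )
            idx += 1
            pos += step
    return probes
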