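"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: 0-based half-open everywhere internally (BED-native).
GTF coordinates (1-based inclusive) are converted on read.  Chromosome names
must match exactly across all inputs; no aliasing (``chr1`` vs ``1``) is
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "DataError",
    "GenomicInterval",
    "GeneModel",
    "BinnedTrack",
    "GeneSetCollection",
    "read_bed",
    "read_gene_annotation",
    "read_chrom_sizes",
    "read_bedgraph_as_track",
    "read_gmt",
    "write_bed",
    "write_table",
]


class ParseError(ValueError):
    """A malformed record in an input file; message names the line number."""


class DataError(ValueError):
    """Inputs are well-formed but inconsistent (e.g. unknown chromosome)."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional strand.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with mandatory strand; the unit of gene-based pattern calling."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must have strand + or -")


@dataclass
class BinnedTrack:
    """Fixed-width-bin coverage for one library (one condition x channel).

    ``bins`` maps chromosome name to a float vector; bin ``i`` covers
    ``[i*bin_size, (i+1)*bin_size)``.  Values are raw read mass after
    :func:`read_bedgraph_as_track` and CPM after ``normalize_cpm``.
    """

    bin_size: int
    bins: dict[str, np.ndarray]
    library_size: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.library_size > 0:
            raise ValueError("library_size must be > 0")
        for chrom, vec in self.bins.items():
            vec = np.asarray(vec, dtype=float)
            if vec.ndim != 1:
                raise ValueError(f"{chrom}: bin vector must be 1-D")
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValueError(f"{chrom}: bin values must be finite and >= 0")
            self.bins[chrom] = vec

    @property
    def chroms(self) -> list[str]:
        return list(self.bins)

    def chrom_length(self, chrom: str) -> int:
        return len(self.bins[chrom]) * self.bin_size


@dataclass
class GeneSetCollection:
    """Named gene sets (stand-in for pathway databases supplied as GMT)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6/BED12 intervals (e.g. peak caller output).

    Unnamed records (BED3) get synthesized names ``peak_1``, ``peak_2``, ...
    """
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else ""
            if not name:
                name = f"peak_{len(intervals) + 1}"
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate name {name!r}")
            seen.add(name)
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return intervals


def read_gene_annotation(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read gene models from BED6/BED12 or a minimal GTF ("gene" features).

    GTF coordinates are 1-based inclusive and are converted to 0-based
    half-open.  A duplicate ``gene_id`` or a missing strand is an error.
    """
    if format not in ("bed", "gtf"):
        raise ValueError(f"format must be 'bed' or 'gtf', got {format!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if format == "bed":
                fields = line.split()
                if len(fields) < 6:
                    raise ParseError(
                        f"{path}:{lineno}: BED6 requires 6 columns (strand)"
                    )
                gene_id = fields[3]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                strand = fields[5]
            else:
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ParseError(f"{path}:{lineno}: GTF requires 9 columns")
                if fields[2] != "gene":
                    continue
                try:
                    # GTF is 1-based inclusive
                    start, end = int(fields[3]) - 1, int(fields[4])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                strand = fields[6]
                gene_id = _gtf_attribute(fields[8], "gene_id")
                if gene_id is None:
                    raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: missing or invalid strand")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            genes.append(
                GeneModel(gene_id, GenomicInterval(fields[0], start, end, strand, gene_id))
            )
    return genes


def _gtf_attribute(attr_field: str, key: str) -> str | None:
    for part in attr_field.split(";"):
        part = part.strip()
        if part.startswith(key):
            value = part[len(key):].strip()
            return value.strip('"')
    return None


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV (name, length-in-bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                size = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer size") from exc
            if size <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive size")
            sizes[fields[0]] = size
    if not sizes:
        raise ParseError(f"{path}: empty chrom.sizes file")
    return sizes


def read_bedgraph_as_track(
    path: str | Path,
    bin_size: int,
    chrom_sizes: Mapping[str, int],
    label: str = "",
) -> BinnedTrack:
    """Bin a bedGraph into fixed-width raw-mass bins.

    bedGraph values are interpreted as per-bp depth: a record over
    ``[start, end)`` with value ``v`` contributes ``v * overlap_width`` mass
    to each bin it overlaps, so total read mass is conserved regardless of
    how records are fragmented.  Every chromosome in ``chrom_sizes`` gets a
    (possibly all-zero) bin vector; the resulting ``library_size`` is the
    total mass.
    """
    bins = {
        chrom: np.zeros(math.ceil(size / bin_size))
        for chrom, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
            chrom = fields[0]
            if chrom not in chrom_sizes:
                raise DataError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed record") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if end > chrom_sizes[chrom]:
                raise DataError(
                    f"{path}:{lineno}: interval extends past end of {chrom}"
                )
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            if value == 0:
                continue
            vec = bins[chrom]
            first = start // bin_size
            last = (end - 1) // bin_size
            for b in range(first, last + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                vec[b] += value * (hi - lo)
    library_size = float(sum(v.sum() for v in bins.values()))
    if library_size <= 0:
        raise DataError(f"{path}: track has zero total mass")
    return BinnedTrack(bin_size=bin_size, bins=bins, library_size=library_size, label=label)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read tab-separated GMT gene sets (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT requires >= 3 tab-separated columns"
                )
            name, desc = fields[0], fields[1]
            members = {m for m in fields[2:] if m}
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} is empty")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# writers


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def write_table(records, path: str | Path, columns: list[str] | None = None) -> None:
    """Write records (a DataFrame or an iterable of dicts sharing a schema)
    as a UTF-8 TSV with a header row, floats at 6 significant digits.

    An empty record list yields a header-only file; ``columns`` supplies the
    header in that case (and fixes column order otherwise).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame.from_records(list(records), columns=columns)
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")
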