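"""Track normalization, gene-proximal windows, bin extraction and
peak-to-gene assignment.

The quantification unit for gene-based calling is the gene-proximal window:
by default the gene body plus 5 kb of 5' flank and 1 kb of 3' flank
(strand-aware).  For marks that concentrate upstream of the TSS
(e.g. promoter/enhancer acetylation) an ``upstream_only`` mode restricts the
window to the 5 kb immediately 5' of the gene start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import BinnedTrack, DataError, GeneModel, GenomicInterval

__all__ = [
    "WindowSpec",
    "RegionIntensity",
    "normalize_cpm",
    "gene_window",
    "extract_bins",
    "region_fold_change",
    "assign_peaks_to_genes",
]

DEFAULT_PSEUDOCOUNT = 0.25  # CPM; avoids division by zero in sparse bins


@dataclass(frozen=True)
class WindowSpec:
    """Gene-proximal window definition.

    ``gene_body_flanked``: [5' end - upstream_bp, 3' end + downstream_bp],
    strand-aware (the default, 5 kb/1 kb).  ``upstream_only``: only the
    ``upstream_bp`` bp immediately 5' of the gene start.
    """

    upstream_bp: int = 5000
    downstream_bp: int = 1000
    mode: str = "gene_body_flanked"

    def __post_init__(self) -> None:
        if self.mode not in ("gene_body_flanked", "upstream_only"):
            raise ValueError(f"invalid window mode {self.mode!r}")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("flank sizes must be >= 0")
        if self.mode == "upstream_only" and self.downstream_bp != 0:
            object.__setattr__(self, "downstream_bp", 0)


@dataclass
class RegionIntensity:
    """Per-bin CPM vectors for one unit across libraries (label -> vector)."""

    unit_id: str
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.vectors.values()}
        if len(lengths) != 1 or lengths == {0}:
            raise ValueError(
                f"{self.unit_id}: library vectors must share a length >= 1"
            )

    @property
    def n_bins(self) -> int:
        return len(next(iter(self.vectors.values())))


def normalize_cpm(raw_track: BinnedTrack) -> BinnedTrack:
    """Scale raw bin mass to counts-per-million of the library size."""
    if raw_track.library_size <= 0:
        raise DataError("cannot CPM-normalize a track with library_size <= 0")
    factor = 1e6 / raw_track.library_size
    return replace(
        raw_track,
        bins={c: v * factor for c, v in raw_track.bins.items()},
    )


def gene_window(
    gene: GeneModel,
    spec: WindowSpec,
    chrom_sizes: Mapping[str, int],
) -> GenomicInterval:
    """The gene-proximal quantification window, clipped to the chromosome."""
    iv = gene.interval
    if iv.chrom not in chrom_sizes:
        raise DataError(f"gene {gene.gene_id}: unknown chromosome {iv.chrom!r}")
    chrom_len = chrom_sizes[iv.chrom]
    if spec.mode == "gene_body_flanked":
        if iv.strand == "+":
            start, end = iv.start - spec.upstream_bp, iv.end + spec.downstream_bp
        else:
            start, end = iv.start - spec.downstream_bp, iv.end + spec.upstream_bp
    else:  # upstream_only
        if iv.strand == "+":
            start, end = iv.start - spec.upstream_bp, iv.start
        else:
            start, end = iv.end, iv.end + spec.upstream_bp
    start, end = max(0, start), min(chrom_len, end)
    if start >= end:
        raise DataError(
            f"gene {gene.gene_id}: window empty after clipping to {iv.chrom}"
        )
    return GenomicInterval(iv.chrom, start, end, iv.strand, gene.gene_id)


def extract_bins(track: BinnedTrack, interval: GenomicInterval) -> np.ndarray:
    """Bin values overlapping ``interval``, in genomic order.

    Partial boundary bins are included whole (no fractional weighting).
    """
    if interval.chrom not in track.bins:
        raise DataError(f"unknown chromosome {interval.chrom!r} in track")
    vec = track.bins[interval.chrom]
    first = interval.start // track.bin_size
    last = min(math.ceil(interval.end / track.bin_size), len(vec))
    if first >= last:
        raise DataError(
            f"interval {interval.chrom}:[{interval.start},{interval.end}) "
            "is beyond the chromosome's binned extent"
        )
    return vec[first:last].copy()


def region_fold_change(
    chip_bins: Sequence[float],
    input_bins: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, np.ndarray]:
    """Region fold-change (ChIP vs Input) and per-bin log2 fold-changes.

    Returns ``(mean(chip)+c) / (mean(input)+c)`` and the vector
    ``log2((chip_b+c) / (input_b+c))``, with pseudocount ``c`` applied
    symmetrically.
    """
    chip = np.asarray(chip_bins, dtype=float)
    inp = np.asarray(input_bins, dtype=float)
    if chip.shape != inp.shape:
        raise ValueError(f"length mismatch: {chip.shape} vs {inp.shape}")
    if chip.size == 0:
        raise ValueError("empty region")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    fc = (chip.mean() + pseudocount) / (inp.mean() + pseudocount)
    per_bin = np.log2((chip + pseudocount) / (inp + pseudocount))
    return float(fc), per_bin


def assign_peaks_to_genes(
    peaks: Iterable[GenomicInterval],
    genes: Iterable[GeneModel],
    spec: WindowSpec,
    chrom_sizes: Mapping[str, int],
    enhancer_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Associate peaks with genes whose proximal window they overlap.

    A (peak, gene) pair is emitted iff the peak overlaps the gene's window by
    at least 1 bp; duplicate pairs are merged.  ``enhancer_map`` (columns
    chrom, start, end, gene_id) contributes extra pairs for peaks overlapping
    an annotated enhancer.  Peaks hitting no gene appear once with an empty
    ``gene_id``.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        w = gene_window(gene, spec, chrom_sizes)
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, gene.gene_id)
    if enhancer_map is not None:
        required = {"chrom", "start", "end", "gene_id"}
        if not required.issubset(enhancer_map.columns):
            raise ValueError(f"enhancer map must have columns {sorted(required)}")
        for row in enhancer_map.itertuples(index=False):
            if row.start >= row.end:
                raise ValueError(
                    f"enhancer record [{row.start}, {row.end}) is empty"
                )
            trees.setdefault(row.chrom, IntervalTree()).addi(
                int(row.start), int(row.end), str(row.gene_id)
            )
    rows: list[tuple[str, str]] = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        hits = sorted({h.data for h in tree.overlap(peak.start, peak.end)}) if tree else []
        if hits:
            rows.extend((peak.name, g) for g in hits)
        else:
            rows.append((peak.name, ""))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id"]).drop_duplicates(
        ignore_index=True
    )
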