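"""Increased/Unchanged calling and cross-condition pattern classification.

A region is called Increased (I) in one condition when its ChIP intensity is
significantly higher than the matched Input (one-sided Mann-Whitney U,
p < alpha) AND the region fold-change exceeds ``fc_min``; otherwise it is
Unchanged (U).  The per-condition letters, in the configured order
(reference, disease, rescue), form a 3-letter code; the four codes that flip
between reference and disease and test the rescue -- IUI, IUU, UII, UIU --
are the dynamic classes GP1-GP4 (genes) or PP1-PP4 (peaks), and the other
four codes are static.

Peak-mode calling additionally applies a consistency filter: the per-bin
log2 fold-change of every I-condition must stochastically exceed that of
every U-condition (one-sided Mann-Whitney p < consistency_alpha), otherwise
the peak is demoted to static.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import BinnedTrack, DataError, GeneModel, GenomicInterval
from .quantify import (
    DEFAULT_PSEUDOCOUNT,
    WindowSpec,
    extract_bins,
    gene_window,
    region_fold_change,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CallParameters",
    "IUCall",
    "PatternAssignment",
    "DYNAMIC_CODES",
    "mann_whitney_one_sided",
    "mann_whitney_two_sided",
    "iu_call",
    "classify_code",
    "consistency_filter",
    "call_gene_patterns",
    "call_peak_patterns",
    "summarize_patterns",
    "genomewide_fc_table",
    "compare_fc_distributions",
]

#: dynamic code -> class index (GP<i>/PP<i>); order fixed by the
#: (reference, disease, rescue) condition order.
DYNAMIC_CODES = {"IUI": 1, "IUU": 2, "UII": 3, "UIU": 4}

MIN_BINS = 4  # below this the rank test is uninformative; unit is called U


@dataclass(frozen=True)
class CallParameters:
    """Thresholds for I/U designation and the peak consistency filter."""

    alpha: float = 0.05
    fc_min: float = 1.5
    consistency_alpha: float = 0.05
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.consistency_alpha < 1):
            raise ValueError("alpha values must lie in (0, 1)")
        if self.fc_min <= 0:
            raise ValueError("fc_min must be > 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(frozen=True)
class IUCall:
    """I/U designation for one unit in one condition."""

    unit_id: str
    condition: str
    designation: str  # "I" or "U"
    p_value: float
    fold_change: float
    low_coverage: bool = False


@dataclass(frozen=True)
class PatternAssignment:
    """Cross-condition pattern code and class for one unit."""

    unit_id: str
    code: str
    class_label: str  # GP1..GP4 / PP1..PP4 / static
    consistency_pass: bool | None = None  # None = not applicable (gene mode)
    calls: tuple[IUCall, ...] = field(default=(), compare=False)


# ---------------------------------------------------------------------------
# rank tests


def _mwu(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Mann-Whitney U p-value: exact enumeration when both tie-free and
    min(n1, n2) <= 8, tie-corrected normal approximation with continuity
    correction otherwise."""
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # every observation identical: no evidence either way
        return 1.0
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if tie_free and min(x.size, y.size) <= 8 else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    p = float(res.pvalue)
    if math.isnan(p):
        return 1.0
    return min(max(p, np.finfo(float).tiny), 1.0)


def mann_whitney_one_sided(
    x: Sequence[float], y: Sequence[float]
) -> float:
    """P-value for the alternative "x stochastically greater than y"."""
    return _mwu(np.asarray(x, float), np.asarray(y, float), "greater")


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p-value (symmetric in its arguments)."""
    return _mwu(np.asarray(x, float), np.asarray(y, float), "two-sided")


def compare_fc_distributions(
    fc_a: Sequence[float], fc_b: Sequence[float]
) -> float:
    """Two-sided Mann-Whitney comparison of two per-gene fold-change
    distributions (e.g. genotype vs genotype, genome-wide)."""
    return mann_whitney_two_sided(fc_a, fc_b)


# ---------------------------------------------------------------------------
# per-condition calling


def iu_call(
    unit_id: str,
    condition: str,
    chip_bins: Sequence[float],
    input_bins: Sequence[float],
    params: CallParameters = CallParameters(),
) -> IUCall:
    """Designate one unit I or U in one condition (ChIP vs Input).

    I requires BOTH p < alpha and fold-change > fc_min.  Units with fewer
    than 4 bins are called U with a low-coverage flag.
    """
    chip = np.asarray(chip_bins, float)
    inp = np.asarray(input_bins, float)
    fc, _ = region_fold_change(chip, inp, params.pseudocount)
    if chip.size < MIN_BINS:
        return IUCall(unit_id, condition, "U", 1.0, fc, low_coverage=True)
    p = mann_whitney_one_sided(chip, inp)
    designation = "I" if (p < params.alpha and fc > params.fc_min) else "U"
    return IUCall(unit_id, condition, designation, p, fc)


def classify_code(code: str, unit_kind: str = "gene") -> str:
    """Map a 3-letter I/U code to its class label.

    IUI/IUU/UII/UIU -> GP1-GP4 (genes) or PP1-PP4 (peaks); the other four
    codes are ``static``.
    """
    if unit_kind not in ("gene", "peak"):
        raise ValueError(f"unit_kind must be 'gene' or 'peak', got {unit_kind!r}")
    if len(code) != 3 or any(c not in "IU" for c in code):
        raise ValueError(f"invalid pattern code {code!r}")
    idx = DYNAMIC_CODES.get(code)
    if idx is None:
        return "static"
    prefix = "GP" if unit_kind == "gene" else "PP"
    return f"{prefix}{idx}"


def consistency_filter(
    log2fc_by_condition: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    code: str,
    consistency_alpha: float = 0.05,
) -> bool:
    """Require every I-condition's per-bin log2 fold-change to stochastically
    exceed every U-condition's (one-sided Mann-Whitney p < alpha).

    All-I and all-U codes pass vacuously.
    """
    if isinstance(log2fc_by_condition, Mapping):
        vectors = [np.asarray(v, float) for v in log2fc_by_condition.values()]
    else:
        vectors = [np.asarray(v, float) for v in log2fc_by_condition]
    if len(vectors) != len(code):
        raise ValueError("one fold-change vector per code letter required")
    if len({v.size for v in vectors}) != 1:
        raise ValueError("fold-change vectors must share a length")
    i_vecs = [v for v, c in zip(vectors, code) if c == "I"]
    u_vecs = [v for v, c in zip(vectors, code) if c == "U"]
    return all(
        mann_whitney_one_sided(vi, vu) < consistency_alpha
        for vi in i_vecs
        for vu in u_vecs
    )


# ---------------------------------------------------------------------------
# whole-annotation calling

Tracks = Mapping[str, Mapping[str, BinnedTrack]]  # condition -> channel -> track


def _condition_order(tracks: Tracks, conditions: Sequence[str] | None) -> list[str]:
    order = list(conditions) if conditions is not None else list(tracks)
    for cond in order:
        for channel in ("chip", "input"):
            if channel not in tracks[cond]:
                raise DataError(f"condition {cond!r} lacks a {channel!r} track")
    return order


def _call_units(
    tracks: Tracks,
    units: Sequence[tuple[str, GenomicInterval]],
    params: CallParameters,
    conditions: Sequence[str] | None,
    unit_kind: str,
    apply_consistency: bool,
) -> pd.DataFrame:
    order = _condition_order(tracks, conditions)
    rows = []
    for unit_id, region in units:
        calls: list[IUCall] = []
        log2fcs: list[np.ndarray] = []
        try:
            for cond in order:
                chip = extract_bins(tracks[cond]["chip"], region)
                inp = extract_bins(tracks[cond]["input"], region)
                calls.append(iu_call(unit_id, cond, chip, inp, params))
                _, per_bin = region_fold_change(chip, inp, params.pseudocount)
                log2fcs.append(per_bin)
        except DataError as exc:
            logger.warning("skipping %s %s: %s", unit_kind, unit_id, exc)
            continue
        code = "".join(c.designation for c in calls)
        label = classify_code(code, unit_kind)
        cons: bool | None = None
        if apply_consistency:
            cons = True
            if label != "static":
                cons = consistency_filter(log2fcs, code, params.consistency_alpha)
                if not cons:
                    label = "static"
        row: dict = {
            "unit_id": unit_id,
            "code": code,
            "class_label": label,
            "consistency_pass": cons,
        }
        for cond, call in zip(order, calls):
            row[f"p_{cond}"] = call.p_value
            row[f"fc_{cond}"] = call.fold_change
            row[f"call_{cond}"] = call.designation
            row[f"low_coverage_{cond}"] = call.low_coverage
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        raise DataError(f"no {unit_kind} could be called")
    # BH-adjusted q per condition, reported for transparency only: the I/U
    # designation uses the raw p < alpha rule.
    for cond in order:
        df[f"q_{cond}"] = multipletests(df[f"p_{cond}"], method="fdr_bh")[1]
    return df


def call_gene_patterns(
    tracks: Tracks,
    genes: Sequence[GeneModel],
    spec: WindowSpec,
    params: CallParameters,
    chrom_sizes: Mapping[str, int],
    conditions: Sequence[str] | None = None,
    apply_consistency: bool = False,
) -> pd.DataFrame:
    """Gene-based pattern calling over gene-proximal windows.

    The peak consistency filter is not applied in gene mode (override with
    ``apply_consistency=True``); ``consistency_pass`` is left null.
    """
    units = []
    for gene in genes:
        try:
            units.append((gene.gene_id, gene_window(gene, spec, chrom_sizes)))
        except DataError as exc:
            logger.warning("skipping gene %s: %s", gene.gene_id, exc)
    return _call_units(tracks, units, params, conditions, "gene", apply_consistency)


def call_peak_patterns(
    tracks: Tracks,
    peaks: Sequence[GenomicInterval],
    params: CallParameters,
    conditions: Sequence[str] | None = None,
    apply_consistency: bool = True,
) -> pd.DataFrame:
    """Peak-based pattern calling; dynamic codes must also pass the
    consistency filter, otherwise the peak is demoted to static with
    ``consistency_pass = False``."""
    units = [(p.name, p) for p in peaks]
    return _call_units(tracks, units, params, conditions, "peak", apply_consistency)


# ---------------------------------------------------------------------------
# summaries


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_patterns(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and integer percentages per dynamic class (static excluded
    from the denominator).  Percentages round half away from zero; a total
    row closes the table."""
    dynamic = assignments[assignments["class_label"] != "static"]
    if dynamic.empty:
        logger.warning("no dynamic units to summarize")
        return pd.DataFrame(columns=["class_label", "count", "percent"])
    counts = dynamic["class_label"].value_counts().sort_index()
    total = int(counts.sum())
    rows = [
        {
            "class_label": label,
            "count": int(n),
            "percent": _round_half_away(100.0 * n / total),
        }
        for label, n in counts.items()
    ]
    rows.append({"class_label": "total", "count": total, "percent": 100})
    return pd.DataFrame(rows)


def genomewide_fc_table(
    tracks: Tracks,
    genes: Sequence[GeneModel],
    spec: WindowSpec,
    chrom_sizes: Mapping[str, int],
    conditions: Sequence[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene ChIP-vs-Input fold-change for every condition (the
    genome-wide distribution compared between genotypes)."""
    order = _condition_order(tracks, conditions)
    rows = []
    for gene in genes:
        try:
            region = gene_window(gene, spec, chrom_sizes)
            row: dict = {"gene_id": gene.gene_id}
            for cond in order:
                chip = extract_bins(tracks[cond]["chip"], region)
                inp = extract_bins(tracks[cond]["input"], region)
                fc, _ = region_fold_change(chip, inp, pseudocount)
                row[f"fc_{cond}"] = fc
        except DataError as exc:
            logger.warning("skipping gene %s: %s", gene.gene_id, exc)
            continue
        rows.append(row)
    return pd.DataFrame(rows)
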