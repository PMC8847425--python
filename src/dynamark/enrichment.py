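"""Binomial gene-set enrichment of pattern classes.

For a pattern pt, the background probability p_b is learned genome-wide as
the fraction of assessed genes carrying pt.  For a gene list of size n with
k members carrying pt, the enrichment p-value is the binomial survival
probability

    P = P(X > k),  X ~ Binomial(n, p_b)
      = 1 - sum_{i=0..k} C(n, i) p_b^i (1 - p_b)^(n-i),

computed in the numerically stable survival form.  Results are sorted by
raw p; a Benjamini-Hochberg q is attached per pattern for reference.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "background_probability",
    "binomial_enrichment_p",
    "enrich_gene_sets",
]

DYNAMIC_CLASSES = ("GP1", "GP2", "GP3", "GP4")


def background_probability(assignments: pd.DataFrame, pattern: str) -> float:
    """Fraction of all assessed genes whose class is ``pattern``."""
    total = len(assignments)
    if total == 0:
        raise ValueError("no genome-wide assignments to learn background from")
    k = int((assignments["class_label"] == pattern).sum())
    return k / total


def binomial_enrichment_p(n: int, k: int, p_b: float) -> float:
    """P(X > k) for X ~ Binomial(n, p_b); strict inequality."""
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p_b <= 1.0):
        raise ValueError(f"p_b must lie in [0, 1], got {p_b}")
    p = float(scipy.stats.binom.sf(k, n, p_b))
    return min(max(p, 0.0), 1.0)


def enrich_gene_sets(
    assignments: pd.DataFrame,
    gene_sets: GeneSetCollection,
    patterns: Sequence[str] = DYNAMIC_CLASSES,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every (pattern, gene set) pair for pattern enrichment.

    The universe defaults to the genes with an assignment; sets are
    intersected with it and empty intersections are skipped with a warning.
    Output columns: set, pattern, n, k, p_b, p, q — sorted ascending by p,
    with BH q computed within each pattern.
    """
    if universe is None:
        universe = set(assignments["unit_id"])
    else:
        universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    by_gene = assignments.set_index("unit_id")["class_label"]
    rows = []
    for pattern in patterns:
        p_b = background_probability(assignments, pattern)
        for set_name, members in gene_sets.items():
            hit = members & universe
            n = len(hit)
            if n == 0:
                logger.warning(
                    "set %s shares no genes with the universe; skipped", set_name
                )
                continue
            k = int((by_gene.loc[sorted(hit)] == pattern).sum())
            rows.append(
                {
                    "set": set_name,
                    "pattern": pattern,
                    "n": n,
                    "k": k,
                    "p_b": p_b,
                    "p": binomial_enrichment_p(n, k, p_b),
                }
            )
    result = pd.DataFrame(
        rows, columns=["set", "pattern", "n", "k", "p_b", "p"]
    )
    if result.empty:
        result["q"] = []
        return result
    result["q"] = float("nan")
    for pattern in result["pattern"].unique():
        mask = result["pattern"] == pattern
        result.loc[mask, "q"] = multipletests(
            result.loc[mask, "p"], method="fdr_bh"
        )[1]
    return result.sort_values("p", kind="mergesort", ignore_index=True)
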