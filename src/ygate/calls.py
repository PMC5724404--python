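"""Expressed/non-expressed calls, level bins, top-expressed gene lists and
call-set concordance.

A probe is expressed in a sample when its fluorescence Fi is at or above the
absolute threshold T. Level bins partition the real line:

    below  = [-inf, T)      non-expressed
    low    = [T, 6)
    medium = [6, 10]
    high   = (10, inf)

The boundary convention (6 belongs to medium, 10 to medium, values exactly
at T to low) gives a clean partition and is recorded in output headers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "classify",
    "bin_levels",
    "gene_calls",
    "shared_top_fraction",
    "concordance",
    "ConcordanceCounts",
    "BIN_LABELS",
]

BIN_LABELS = ("below", "low", "medium", "high")

# upper bin edges shared with the level definitions above
_LOW_UPPER = 6.0
_MEDIUM_UPPER = 10.0


def classify(matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Boolean expressed-call table, same shape as ``matrix``.

    ``True`` wherever Fi >= threshold (a value exactly at the threshold is
    expressed).
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return matrix >= threshold


def bin_levels(matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Categorical level-bin table, same shape as ``matrix``.

    Requires ``threshold <= 6`` so the below/low/medium/high edges are
    ordered; a higher threshold would make the low bin empty or inverted.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if threshold > _LOW_UPPER:
        raise ValueError(
            f"threshold {threshold} exceeds the low/medium edge {_LOW_UPPER}; "
            "level bins are undefined"
        )
    values = matrix.to_numpy(dtype=float)
    bins = np.full(values.shape, "below", dtype=object)
    bins[(values >= threshold) & (values < _LOW_UPPER)] = "low"
    bins[(values >= _LOW_UPPER) & (values <= _MEDIUM_UPPER)] = "medium"
    bins[values > _MEDIUM_UPPER] = "high"
    return pd.DataFrame(bins, index=matrix.index, columns=matrix.columns)


def gene_calls(
    calls: pd.DataFrame, annot: pd.DataFrame, rule: str = "any_probe"
) -> pd.DataFrame:
    """Summarize probe-level expressed calls to genes.

    A gene is expressed in a sample when any of its probes is
    (``rule="any_probe"``, default) or when all are (``"all_probes"``).
    """
    if rule not in ("any_probe", "all_probes"):
        raise ValueError("rule must be 'any_probe' or 'all_probes'")
    symbols = annot.loc[calls.index.intersection(annot.index), "gene_symbol"]
    grouped = calls.loc[symbols.index].groupby(symbols)
    return grouped.any() if rule == "any_probe" else grouped.all()


def shared_top_fraction(
    matrix: pd.DataFrame,
    fraction: float = 0.05,
    annot: pd.DataFrame | None = None,
) -> list[str]:
    """Genes among the top ``fraction`` most-fluorescent probes of *every*
    sample.

    Per sample, probes are ranked by fluorescence descending and the top
    ``ceil(fraction * n_probes)`` kept (ties broken by probe id so the list
    is deterministic across platforms); the per-sample sets are intersected
    and mapped to distinct gene symbols via ``annot`` (sorted). Without an
    annotation the shared probe ids themselves are returned.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_top = math.ceil(fraction * len(matrix))
    shared: set[str] | None = None
    for sample in matrix.columns:
        order = sorted(
            matrix.index, key=lambda p: (-matrix.at[p, sample], str(p))
        )
        top = set(order[:n_top])
        shared = top if shared is None else shared & top
    if shared is None:
        raise ValueError("matrix has no samples")
    if not shared:
        warnings.warn("no probe is in the top fraction of every sample")
        return []
    if annot is None:
        return sorted(shared)
    present = [p for p in shared if p in annot.index]
    return sorted(set(annot.loc[present, "gene_symbol"]))


@dataclass(frozen=True)
class ConcordanceCounts:
    """Two-set Venn counts over a probe universe, with universe percentages."""

    only_a: int
    only_b: int
    shared: int
    universe_size: int
    label_a: str = "a"
    label_b: str = "b"

    @property
    def pct_only_a(self) -> float:
        return 100.0 * self.only_a / self.universe_size

    @property
    def pct_only_b(self) -> float:
        return 100.0 * self.only_b / self.universe_size

    @property
    def pct_shared(self) -> float:
        return 100.0 * self.shared / self.universe_size


def concordance(
    calls_a: Iterable[str],
    calls_b: Iterable[str],
    universe: Iterable[str],
    label_a: str = "a",
    label_b: str = "b",
) -> ConcordanceCounts:
    """Venn counts between two probe call sets over a shared universe.

    Typical use: comparing the non-expressed probe sets of two absolute
    callers on the same array.
    """
    a, b, uni = set(calls_a), set(calls_b), set(universe)
    stray = (a | b) - uni
    if stray:
        raise ValueError(
            f"elements outside the universe: {', '.join(sorted(map(str, stray))[:5])}"
        )
    return ConcordanceCounts(
        only_a=len(a - b),
        only_b=len(b - a),
        shared=len(a & b),
        universe_size=len(uni),
        label_a=label_a,
        label_b=label_b,
    )
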