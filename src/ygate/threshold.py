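"""Absolute gene expression threshold from female Y-chromosome fluorescence.

Females carry no Y chromosome, so whatever fluorescence a Y probe shows in a
female sample is cross-hybridization background. The procedure:

1. For every probe annotated to chromosome Y, test male vs female
   fluorescence with a two-sided Mann–Whitney U test (exact p for small
   tie-free inputs, normal approximation with tie correction otherwise).
2. Keep probes significant at ``alpha`` and whose male/female ranges do not
   overlap (male-high orientation: min male > max female — only truly
   male-specific Y transcripts qualify; many Y genes have X homologues or
   sit in the pseudoautosomal region and fluoresce equally in both sexes).
3. Pool the female fluorescence of the surviving probes and take the
   one-sided upper confidence limit ``mean + z(confidence) * sd`` as the
   absolute gene expression threshold T: Fi >= T means expressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mann_whitney",
    "ranges_overlap",
    "select_threshold_probes",
    "count_significant_genes",
    "compute_threshold",
    "ThresholdModel",
]

#: exact Mann-Whitney enumeration is used up to this pooled sample size
_EXACT_LIMIT = 12

_ALTERNATIVES = {"two_sided": "two-sided", "a_greater": "greater"}


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Mann–Whitney U test between two fluorescence groups.

    Returns ``(U, p)`` where U is the statistic for group ``a``. The exact
    permutation null is used for tie-free inputs with ``n_a + n_b <= 12``;
    larger or tied inputs use the normal approximation with tie correction.
    Two identical constant groups give p = 1 (no separation), not an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("fluorescence values must be finite")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")

    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if np.unique(pooled).size == 1:
        # all values identical across both groups: no evidence of separation
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (tie_free and pooled.size <= _EXACT_LIMIT) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=_ALTERNATIVES[alternative], method=method
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def ranges_overlap(
    values_m: Sequence[float],
    values_f: Sequence[float],
    sign_agnostic: bool = False,
) -> bool:
    """True when the male and female fluorescence ranges overlap.

    Default orientation is male-high: the ranges count as non-overlapping
    only when ``min(male) > max(female)``, because a genuinely Y-specific
    transcript can only be high in males. With ``sign_agnostic=True`` any
    disjoint arrangement counts as non-overlapping.
    """
    m = np.asarray(values_m, dtype=float)
    f = np.asarray(values_f, dtype=float)
    if m.size == 0 or f.size == 0:
        raise ValueError("both groups must be non-empty")
    male_high = m.min() > f.max()
    if sign_agnostic:
        return not (male_high or f.min() > m.max())
    return not male_high


def _split_by_sex(
    matrix: pd.DataFrame, meta: pd.Series
) -> tuple[list[str], list[str]]:
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without sex label: {', '.join(missing)}")
    males = [s for s in matrix.columns if meta[s] == "male"]
    females = [s for s in matrix.columns if meta[s] == "female"]
    return males, females


def select_threshold_probes(
    matrix: pd.DataFrame,
    meta: pd.Series,
    annot: pd.DataFrame,
    alpha: float = 0.05,
    sign_agnostic_overlap: bool = False,
) -> pd.DataFrame:
    """Per-Y-probe sex test and overlap filter.

    Returns one row per Y-chromosome probe, ordered by probe id, with
    columns ``gene_symbol``, ``U``, ``p_value``, ``male_min``, ``male_max``,
    ``female_min``, ``female_max``, ``significant`` (p <= alpha) and
    ``nonoverlapping``. The threshold probes are the rows with
    ``significant & nonoverlapping``.

    Testing is at probe level; genes are reported as the distinct symbols of
    selected probes (one gene may contribute several probes).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    males, females = _split_by_sex(matrix, meta)
    if len(males) < 2 or len(females) < 2:
        raise ValueError(
            f"need at least 2 samples of each sex (got {len(males)} male, "
            f"{len(females)} female)"
        )
    y_probes = [
        p
        for p in matrix.index
        if p in annot.index and str(annot.loc[p, "chromosome"]).upper() == "Y"
    ]
    if not y_probes:
        raise ValueError("no probes annotated to chromosome Y in the matrix")

    rows = []
    for probe in sorted(y_probes):
        m = matrix.loc[probe, males].to_numpy(dtype=float)
        f = matrix.loc[probe, females].to_numpy(dtype=float)
        u, p = mann_whitney(m, f, "two_sided")
        rows.append(
            {
                "probe_id": probe,
                "gene_symbol": annot.loc[probe, "gene_symbol"],
                "U": u,
                "p_value": p,
                "male_min": m.min(),
                "male_max": m.max(),
                "female_min": f.min(),
                "female_max": f.max(),
                "significant": p <= alpha,
                "nonoverlapping": not ranges_overlap(
                    m, f, sign_agnostic=sign_agnostic_overlap
                ),
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")


def count_significant_genes(
    results: pd.DataFrame, rule: str = "any_probe"
) -> int:
    """Number of genes passing the significance stage (before overlap filter).

    ``rule="any_probe"`` (default) counts a gene when any of its probes is
    significant; ``"all_probes"`` requires every probe of the gene to be.
    """
    if rule == "any_probe":
        return int(results.groupby("gene_symbol")["significant"].any().sum())
    if rule == "all_probes":
        return int(results.groupby("gene_symbol")["significant"].all().sum())
    raise ValueError("rule must be 'any_probe' or 'all_probes'")


@dataclass
class ThresholdModel:
    """The absolute gene expression threshold T and its provenance.

    ``threshold = female_mean + z * female_sd`` over the pooled female
    fluorescence of the selected probes; ``z`` is the one-sided standard
    normal quantile at ``confidence`` (1.6449 at 95%) and sd uses the n-1
    denominator (small-n upper-limit estimation).
    """

    threshold: float
    confidence: float
    z: float
    female_mean: float
    female_sd: float
    n_female_values: int
    selected_probes: list[str] = field(default_factory=list)
    selected_genes: list[str] = field(default_factory=list)
    sided: str = "one"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        return cls(**json.loads(Path(path).read_text()))


def compute_threshold(
    selected: pd.DataFrame,
    matrix: pd.DataFrame,
    meta: pd.Series,
    confidence: float = 0.95,
    sided: str = "one",
) -> ThresholdModel:
    """Pool female fluorescence of the selected probes into one vector and
    return the upper confidence limit as the threshold.

    ``selected`` is the (possibly pre-filtered) output of
    :func:`select_threshold_probes`; only rows with
    ``significant & nonoverlapping`` are pooled. ``sided="one"`` uses
    z = Phi^-1(confidence) (default, 1.6449 at 95%); ``sided="two"`` uses
    z = Phi^-1((1+confidence)/2) (1.96 at 95%).
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    keep = selected[selected["significant"] & selected["nonoverlapping"]]
    if keep.empty:
        raise ValueError("no selected probes: cannot compute a threshold")
    _, females = _split_by_sex(matrix, meta)
    if len(females) < 2:
        raise ValueError("need at least 2 female samples (sd undefined otherwise)")
    pooled = matrix.loc[list(keep.index), females].to_numpy(dtype=float).ravel()
    if pooled.size < 2:
        raise ValueError("need at least 2 pooled female values")
    z = float(
        stats.norm.ppf(confidence if sided == "one" else (1 + confidence) / 2)
    )
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    return ThresholdModel(
        threshold=mean + z * sd,
        confidence=confidence,
        z=z,
        female_mean=mean,
        female_sd=sd,
        n_female_values=int(pooled.size),
        selected_probes=list(keep.index),
        selected_genes=sorted(set(keep["gene_symbol"])),
        sided=sided,
    )
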