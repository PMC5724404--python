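"""Gene-set over-representation of an expressed-gene list.

For a query of n genes drawn from a background of N, a set containing K
background genes and k query genes is scored by the hypergeometric upper
tail P(X >= k), computed in log space for stability, then adjusted across
sets by Benjamini-Hochberg. This mirrors the standard over-representation
setup (hypergeometric test, all genes as background, BH correction) used by
web enrichment tools.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from ygate.io import GeneSet

__all__ = ["hypergeom_upper_tail", "bh_adjust", "enrich"]

#: sets with fewer background members than this are skipped as degenerate
MIN_SET_SIZE = 2


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n, k = np.asarray(n, float), np.asarray(k, float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the set size within the background, n the
    query size and k the observed overlap. Computed as a log-space sum of
    pmf terms so tails of order 1e-60 keep full relative accuracy.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k > K:
        return 0.0
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    log_pmf = (
        _log_comb(K, support) + _log_comb(N - K, n - support) - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Sequence[str],
    sets: Mapping[str, GeneSet],
    background: Sequence[str],
    cutoff: float = 1e-9,
) -> pd.DataFrame:
    """Over-representation of ``query`` genes in each gene set.

    Genes are uppercased; query genes outside the background are dropped
    with a warning, and each set is intersected with the background before
    testing (sets left with < 2 members are skipped). Returns one row per
    tested set, sorted by ascending raw p, with columns ``set_name``,
    ``description``, ``k``, ``K``, ``n``, ``N``, ``p_raw``, ``p_adjusted``
    and ``enriched`` (adjusted p <= cutoff).
    """
    bg = {str(g).upper() for g in background}
    if not bg:
        raise ValueError("background is empty")
    q = {str(g).upper() for g in query}
    dropped = q - bg
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) absent from the background were dropped"
        )
    q &= bg
    if not q:
        raise ValueError("no query genes remain after background filtering")

    N, n = len(bg), len(q)
    rows = []
    for name, gene_set in sets.items():
        members = set(gene_set.genes) & bg
        if len(members) < MIN_SET_SIZE:
            continue
        k = len(q & members)
        rows.append(
            {
                "set_name": name,
                "description": gene_set.description,
                "k": k,
                "K": len(members),
                "n": n,
                "N": N,
                "p_raw": hypergeom_upper_tail(k, len(members), n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name", "description", "k", "K", "n", "N",
                "p_raw", "p_adjusted", "enriched",
            ]
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_raw"].to_numpy())
    table["enriched"] = table["p_adjusted"] <= cutoff
    return (
        table.sort_values(["p_raw", "set_name"], kind="mergesort")
        .reset_index(drop=True)
    )
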