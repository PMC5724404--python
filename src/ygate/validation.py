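"""Agreement between microarray fluorescence and qPCR expression.

qPCR crossing-point cycles (Ct/Cp) fall as transcript abundance rises, so a
well-behaved array should show a strongly *negative* Spearman correlation
between fluorescence and Ct. Both the signed coefficient and its magnitude
are reported, since either sign convention appears in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["spearman", "correlate_with_qpcr", "CorrelationReport"]


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Requires equal lengths >= 3; a constant vector has no rank ordering and
    is reported as an error rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class CorrelationReport:
    """Spearman agreement between fluorescence and qPCR Ct values."""

    rho: float
    abs_rho: float
    n_pairs: int
    pairs: pd.DataFrame  # columns: gene_symbol, sample_id, probe_id, fi, ct
    method: str = (
        "Spearman rank correlation of probe fluorescence vs qPCR Ct; "
        "Ct is inversely related to expression, so rho < 0 indicates agreement"
    )


def correlate_with_qpcr(
    matrix: pd.DataFrame,
    qpcr: pd.DataFrame,
    genes: Sequence[str],
    annot: pd.DataFrame,
    collapse: str = "none",
) -> CorrelationReport:
    """Pair fluorescence with Ct for the requested genes and correlate.

    Each gene contributes one (Fi, Ct) pair per probe per sample present in
    both tables (``collapse="mean"`` averages a gene's probes per sample
    first). Genes with no probe in the matrix or no Ct entry raise an error
    naming them.
    """
    if collapse not in ("none", "mean"):
        raise ValueError("collapse must be 'none' or 'mean'")
    genes = [str(g).upper() for g in genes]
    probe_map = {
        g: list(annot.index[annot["gene_symbol"] == g].intersection(matrix.index))
        for g in genes
    }
    no_probe = [g for g, probes in probe_map.items() if not probes]
    qpcr_genes = set(qpcr["gene_symbol"])
    no_ct = [g for g in genes if g not in qpcr_genes]
    if no_probe or no_ct:
        parts = []
        if no_probe:
            parts.append(f"no probe in matrix: {', '.join(no_probe)}")
        if no_ct:
            parts.append(f"no qPCR entry: {', '.join(no_ct)}")
        raise ValueError("; ".join(parts))

    rows = []
    for gene in genes:
        ct_by_sample = (
            qpcr.loc[qpcr["gene_symbol"] == gene]
            .groupby("sample_id")["ct"]
            .mean()
        )
        probes = probe_map[gene]
        fi = matrix.loc[probes]
        if collapse == "mean":
            fi = fi.mean(axis=0).to_frame().T
            fi.index = [f"{gene}:mean"]
        for probe_id, sample_fi in fi.iterrows():
            for sample, ct in ct_by_sample.items():
                if sample in sample_fi.index:
                    rows.append(
                        {
                            "gene_symbol": gene,
                            "sample_id": sample,
                            "probe_id": probe_id,
                            "fi": float(sample_fi[sample]),
                            "ct": float(ct),
                        }
                    )
    if not rows:
        raise ValueError("no overlapping (gene, sample) pairs between tables")
    pairs = pd.DataFrame(rows).sort_values(
        ["gene_symbol", "probe_id", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)
    rho = spearman(pairs["fi"], pairs["ct"])
    return CorrelationReport(
        rho=rho, abs_rho=abs(rho), n_pairs=len(pairs), pairs=pairs
    )
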