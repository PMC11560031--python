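"""BestKeeper consensus-correlation ranking.

BestKeeper condenses the candidate panel into a single per-sample consensus
profile — the geometric mean of the candidates' Cq values, a proxy for the
cDNA content of each sample — and ranks each gene by the Pearson correlation
of its Cq profile with that consensus.  Genes that faithfully track overall
sample behaviour (r near 1) are strong references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_qpcr import CqMatrix, CompletenessError

__all__ = ["BestkeeperResult", "bestkeeper_index", "gene_correlations", "bestkeeper"]


class InsufficientDataError(ValueError):
    pass


def _values(matrix, genes=None) -> pd.DataFrame:
    v = matrix.values if isinstance(matrix, CqMatrix) else matrix
    if genes is not None:
        v = v.loc[list(genes)]
    if v.isna().any().any():
        raise CompletenessError("BestKeeper requires a complete matrix")
    return v


@dataclass
class BestkeeperResult:
    index: pd.Series             # per-sample consensus Cq
    correlations: pd.Series      # per-gene Pearson r vs index (NaN if undefined)
    descriptives: pd.DataFrame   # per-gene Cq SD and CV, reported but not ranked on

    @property
    def ranking(self) -> list[str]:
        """Genes by descending r; undefined correlations rank last."""
        r = self.correlations
        return list(r.sort_values(ascending=False, na_position="last").index)

    def to_frame(self, subset_label: str = "") -> pd.DataFrame:
        rows = []
        for rank, g in enumerate(self.ranking, start=1):
            rows.append(
                {"subset_label": subset_label, "gene": g,
                 "pearson_r": self.correlations[g], "rank": rank}
            )
        return pd.DataFrame(rows)


def bestkeeper_index(matrix, genes=None, method: str = "geometric") -> pd.Series:
    """Per-sample consensus profile: the (geometric) mean Cq of the panel.

    The geometric mean follows the original BestKeeper definition; the
    arithmetic mean is available as a sensitivity option.  Cq must be
    strictly positive for the geometric mean to exist.
    """
    v = _values(matrix, genes)
    if (v <= 0).any().any():
        raise ValueError("geometric mean undefined for non-positive Cq")
    if method == "geometric":
        idx = np.exp(np.log(v).mean(axis=0))
    elif method == "arithmetic":
        idx = v.mean(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    idx.name = "bestkeeper_index"
    return idx


def gene_correlations(matrix, index: pd.Series, genes=None) -> BestkeeperResult:
    """Pearson r of each gene's Cq profile against the consensus index.

    A zero-variance gene (or index) leaves r undefined: it is reported as
    NaN with a warning and ranked last.
    """
    v = _values(matrix, genes)
    if v.shape[1] < 3:
        raise InsufficientDataError("correlations need >= 3 samples")
    if list(index.index) != list(v.columns):
        index = index.loc[v.columns]
    r = {}
    idx_const = np.isclose(index.std(ddof=1), 0.0)
    for g in v.index:
        x = v.loc[g]
        if np.isclose(x.std(ddof=1), 0.0) or idx_const:
            warnings.warn(f"Pearson r undefined for zero-variance profile ({g})",
                          stacklevel=2)
            r[g] = np.nan
        else:
            r[g] = float(stats.pearsonr(x, index).statistic)
    correlations = pd.Series(r, name="pearson_r")
    desc = pd.DataFrame(
        {
            "cq_mean": v.mean(axis=1),
            "cq_sd": v.std(axis=1, ddof=1),
            "cq_cv_pct": 100 * v.std(axis=1, ddof=1) / v.mean(axis=1),
        }
    )
    return BestkeeperResult(index=index, correlations=correlations, descriptives=desc)


def bestkeeper(matrix, genes=None, method: str = "geometric") -> BestkeeperResult:
    """Full BestKeeper analysis: consensus index plus per-gene correlations."""
    idx = bestkeeper_index(matrix, genes, method=method)
    return gene_correlations(matrix, idx, genes)
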