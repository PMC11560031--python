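"""Comparative deltaCt stability scoring.

For every gene pair the difference of Cq values within each sample (the
deltaCt) is taken; a pair of genes that co-vary consistently keeps a constant
deltaCt across samples.  Each gene is scored by the mean standard deviation
of its deltaCt against every other candidate — genes least variable with
respect to all others make strong references.  On raw Cq with 100%
efficiency this is the same statistic as the geNorm first-round M value,
reached through a different computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qpcr import CqMatrix, CompletenessError

__all__ = ["DeltaCtResult", "pair_sd_matrix", "deltact_scores", "deltact"]


class InsufficientDataError(ValueError):
    pass


def _values(matrix, genes=None) -> pd.DataFrame:
    v = matrix.values if isinstance(matrix, CqMatrix) else matrix
    if genes is not None:
        v = v.loc[list(genes)]
    if v.isna().any().any():
        raise CompletenessError("deltaCt requires a complete matrix")
    return v


@dataclass
class DeltaCtResult:
    pair_sd: pd.DataFrame   # SD over samples of per-sample Cq differences
    scores: pd.Series       # mean pair SD vs all other genes (low = stable)

    @property
    def ranking(self) -> list[str]:
        return list(self.scores.sort_values(kind="stable").index)

    def to_frame(self, subset_label: str = "") -> pd.DataFrame:
        rows = []
        for rank, g in enumerate(self.ranking, start=1):
            rows.append(
                {"subset_label": subset_label, "gene": g,
                 "mean_pair_sd": self.scores[g], "rank": rank}
            )
        return pd.DataFrame(rows)


def pair_sd_matrix(matrix, genes=None) -> pd.DataFrame:
    """Symmetric matrix of SD over samples of (Cq_j - Cq_k), zero diagonal."""
    v = _values(matrix, genes)
    if v.shape[1] < 3:
        raise InsufficientDataError("pair SDs need >= 3 samples")
    arr = v.to_numpy()
    G = arr.shape[0]
    out = np.zeros((G, G))
    for j in range(G):
        out[j] = (arr[j] - arr).std(axis=1, ddof=1)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=v.index, columns=v.index)


def deltact_scores(pair_sd: pd.DataFrame) -> DeltaCtResult:
    """Per-gene mean of pair SDs against all other genes, ranked ascending."""
    G = pair_sd.shape[0]
    if G < 2:
        raise InsufficientDataError("deltaCt scores need >= 2 genes")
    scores = pair_sd.sum(axis=1) / (G - 1)
    scores.name = "mean_pair_sd"
    return DeltaCtResult(pair_sd=pair_sd, scores=scores)


def deltact(matrix, genes=None) -> DeltaCtResult:
    """Full deltaCt analysis on a complete Cq matrix."""
    return deltact_scores(pair_sd_matrix(matrix, genes))
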