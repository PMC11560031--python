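"""geNorm expression-stability analysis.

geNorm scores each candidate reference gene by M, the average standard
deviation of its pairwise log2 expression ratios against every other
candidate.  A constant ratio between two genes across samples means both
track the common factor (cDNA input), so low M marks a stable reference.
The least stable gene (highest M) is discarded and M recomputed until two
genes remain — the "best pair", reported at equal rank.  The pairwise
variation V(n/n+1) between normalisation factors built from the n and n+1
most stable genes guides how many references to use (< 0.2 is the customary
adequacy guideline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qpcr import CqMatrix, CompletenessError

__all__ = ["GenormResult", "pairwise_stability", "m_values", "rank_iterative", "v_curve", "genorm"]

#: Customary upper bound on V(n/n+1) for an adequate reference panel.
V_GUIDELINE = 0.2


class InsufficientDataError(ValueError):
    pass


def _values(matrix, genes=None) -> pd.DataFrame:
    v = matrix.values if isinstance(matrix, CqMatrix) else matrix
    if genes is not None:
        v = v.loc[list(genes)]
    if v.isna().any().any():
        raise CompletenessError("geNorm requires a complete matrix; impute or drop first")
    return v


def _log2_rq(v: pd.DataFrame) -> pd.DataFrame:
    # relative quantity at 100% efficiency, per-gene min-Cq calibrator;
    # all geNorm statistics are invariant to the calibrator choice
    return v.rsub(v.min(axis=1), axis=0)


@dataclass
class GenormResult:
    """geNorm ranking: elimination trace, best pair and V curve.

    ``elimination_order`` lists genes least to most stable, excluding the
    best pair; ``m_trace`` holds each gene's M at its elimination round (best
    pair members share the final two-gene M); ``initial_m`` is the
    full-panel M of every gene before any elimination.
    """

    elimination_order: list[str]
    m_trace: pd.Series
    best_pair: tuple[str, str]
    initial_m: pd.Series
    v_curve: list[tuple[int, float]] = field(default_factory=list)

    @property
    def ranking(self) -> list[str]:
        """Genes most to least stable (best pair first, tied)."""
        return list(self.best_pair) + self.elimination_order[::-1]

    def to_frame(self, subset_label: str = "") -> pd.DataFrame:
        rows = []
        rank_of = {}
        for i, g in enumerate(self.ranking):
            rank_of[g] = 1 if g in self.best_pair else i + 1
        for g in self.ranking:
            rows.append(
                {
                    "subset_label": subset_label,
                    "gene": g,
                    "rank": rank_of[g],
                    "M_at_elimination": self.m_trace[g],
                    "initial_M": self.initial_m[g],
                    "is_best_pair": g in self.best_pair,
                }
            )
        return pd.DataFrame(rows)

    def v_frame(self, subset_label: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [{"subset_label": subset_label, "n": n, "V": v} for n, v in self.v_curve]
        )


def pairwise_stability(matrix, genes=None) -> pd.DataFrame:
    """Pairwise variation matrix V_jk = SD over samples of log2(RQ_j/RQ_k).

    At 100% amplification efficiency the log2 expression ratio of gene j to
    gene k in a sample is (Cq_k - Cq_j) up to a per-pair constant, so V_jk is
    the sample SD (n-1) of that difference.  Symmetric with zero diagonal.
    """
    v = _values(matrix, genes)
    if v.shape[1] < 3:
        raise InsufficientDataError("pairwise stability needs >= 3 samples")
    lq = _log2_rq(v).to_numpy()
    G = lq.shape[0]
    out = np.zeros((G, G))
    for j in range(G):
        diff = lq[j] - lq  # log2 ratio of gene j vs every gene, per sample
        out[j] = diff.std(axis=1, ddof=1)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=v.index, columns=v.index)


def m_values(V: pd.DataFrame) -> pd.Series:
    """Gene-stability measure M_j: mean of V_jk over all k != j (low = stable)."""
    G = V.shape[0]
    if G < 3:
        raise InsufficientDataError("M values need >= 3 genes")
    return (V.sum(axis=1)) / (G - 1)


def rank_iterative(matrix, genes=None) -> GenormResult:
    """Iteratively exclude the highest-M gene down to the best pair.

    On a tie at the maximum M the gene occurring later in input order is
    eliminated (deterministic; a warning is emitted).
    """
    v = _values(matrix, genes)
    if v.shape[0] < 3:
        raise InsufficientDataError("geNorm ranking needs >= 3 genes")
    current = list(v.index)
    initial_m = m_values(pairwise_stability(v))
    elimination: list[str] = []
    m_trace: dict[str, float] = {}
    while len(current) > 2:
        m = m_values(pairwise_stability(v.loc[current]))
        mmax = m.max()
        ties = [g for g in current if np.isclose(m[g], mmax, rtol=0, atol=1e-12)]
        if len(ties) > 1:
            warnings.warn(f"geNorm tie at max M among {ties}; eliminating {ties[-1]}",
                          stacklevel=2)
        worst = ties[-1]
        m_trace[worst] = float(m[worst])
        elimination.append(worst)
        current.remove(worst)
    pair = tuple(current)
    # final-pair M: with only two genes left, M_a = M_b = V_ab
    final_v = float(
        (_log2_rq(v.loc[list(pair)]).iloc[0] - _log2_rq(v.loc[list(pair)]).iloc[1]).std(ddof=1)
    )
    for g in pair:
        m_trace[g] = final_v
    return GenormResult(
        elimination_order=elimination,
        m_trace=pd.Series(m_trace).reindex(list(v.index)).dropna().reindex(elimination + list(pair)),
        best_pair=pair,
        initial_m=initial_m,
    )


def v_curve(matrix, ranking: GenormResult, genes=None) -> list[tuple[int, float]]:
    """Pairwise variation V(n/n+1) between n- and (n+1)-gene normalisation factors.

    NF_n(sample) is the geometric mean of the relative quantities of the n
    most stable genes (best pair first, then ascending elimination M);
    V(n/n+1) = SD over samples of log2(NF_n / NF_{n+1}), for n = 2..G-1.
    """
    v = _values(matrix, genes)
    order = ranking.ranking
    lq = _log2_rq(v.loc[order]).to_numpy()
    out = []
    for n in range(2, len(order)):
        log_nf_n = lq[:n].mean(axis=0)        # log2 of geometric-mean NF
        log_nf_n1 = lq[: n + 1].mean(axis=0)
        out.append((n, float((log_nf_n - log_nf_n1).std(ddof=1))))
    return out


def genorm(matrix, genes=None) -> GenormResult:
    """Full geNorm analysis: iterative ranking plus the V(n/n+1) curve."""
    res = rank_iterative(matrix, genes)
    res.v_curve = v_curve(matrix, res, genes)
    return res
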