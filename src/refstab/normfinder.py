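"""NormFinder model-based expression-stability estimation.

NormFinder treats measured log2 expression (y = -Cq at 100% efficiency) as

    y_gs = gene effect + sample loading + noise,

and in grouped mode additionally a systematic gene-by-group deviation d.
The per-sample loading is removed by centering each sample over genes; that
averaging leaks a little of every gene's noise into the residuals, so the
per-gene variance estimates carry a correction factor k/(k-2) (k genes) and
negative estimates are truncated to zero.

Ungrouped stability is the corrected residual SD of a gene.  Grouped
stability combines the magnitude of the gene's intergroup deviation —
shrunk toward zero by an empirical-Bayes normal-normal factor, so noisy
deviations from small groups are damped — with its intragroup sampling
uncertainty.  A candidate pair is scored by averaging the two genes'
shrunken deviations and pooling their uncertainties; the best pair minimises
that combined value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io_qpcr import CqMatrix, CompletenessError

__all__ = [
    "NormfinderResult",
    "center_samples",
    "ungrouped_stability",
    "grouped_stability",
]


class InsufficientDataError(ValueError):
    pass


def _values(matrix, genes=None) -> pd.DataFrame:
    v = matrix.values if isinstance(matrix, CqMatrix) else matrix
    if genes is not None:
        v = v.loc[list(genes)]
    if v.isna().any().any():
        raise CompletenessError("NormFinder requires a complete matrix")
    return v


@dataclass
class NormfinderResult:
    mode: str                                # "ungrouped" | "grouped"
    grouping: str | None
    stabilities: pd.Series                   # per-gene, >= 0, low = stable
    intergroup: pd.DataFrame | None = None   # shrunken d*, genes x groups
    intergroup_raw: pd.DataFrame | None = None
    intragroup_var: pd.DataFrame | None = None  # genes x groups, truncated >= 0
    best_pair: tuple[str, str] | None = None
    best_pair_stability: float | None = None

    @property
    def ranking(self) -> list[str]:
        return list(self.stabilities.sort_values(kind="stable").index)

    def to_frame(self, subset_label: str = "") -> pd.DataFrame:
        rows = []
        for rank, g in enumerate(self.ranking, start=1):
            rows.append(
                {"subset_label": subset_label, "grouping": self.grouping or "",
                 "gene": g, "stability": self.stabilities[g], "rank": rank}
            )
        return pd.DataFrame(rows)


def center_samples(matrix, genes=None) -> pd.DataFrame:
    """Residuals after removing the per-sample loading.

    Works on y = -Cq (log2 expression up to sign) and subtracts each sample's
    gene average, so every output column sums to zero.
    """
    v = _values(matrix, genes)
    y = -v
    return y.sub(y.mean(axis=0), axis=1)


def _corrected_variances(y: pd.DataFrame) -> pd.Series:
    """Per-gene residual variance with the gene-averaging correction.

    Two-way centered residuals r = y - row means - column means + grand mean
    give naive variances s2_g with E[s2_g] = sigma2_g (1 - 2/k) + mean(sigma2)/k.
    Solving the bias equations yields
        sigma2_g = k/(k-2) * (s2_g - sum(s2)/(k(k-1))),
    truncated at zero.  Requires k >= 3 genes and n >= 2 samples.
    """
    k, n = y.shape
    if k < 3:
        raise InsufficientDataError("variance correction degenerate for < 3 genes")
    if n < 2:
        raise InsufficientDataError("need >= 2 samples per (sub)group")
    r = y.sub(y.mean(axis=1), axis=0).sub(y.mean(axis=0), axis=1) + y.to_numpy().mean()
    s2 = (r ** 2).sum(axis=1) / (n - 1)
    sigma2 = (k / (k - 2)) * (s2 - s2.sum() / (k * (k - 1)))
    return sigma2.clip(lower=0.0)


def ungrouped_stability(matrix, genes=None) -> NormfinderResult:
    """Overall stability: corrected residual SD of each gene across samples."""
    v = _values(matrix, genes)
    if v.shape[1] < 3:
        raise InsufficientDataError("ungrouped stability needs >= 3 samples")
    sigma2 = _corrected_variances(-v)
    stab = np.sqrt(sigma2)
    stab.name = "stability"
    return NormfinderResult(mode="ungrouped", grouping=None, stabilities=stab)


def grouped_stability(matrix, genes=None, grouping=None) -> NormfinderResult:
    """Within- and between-group stability with best-pair selection.

    ``grouping`` is either a per-sample label Series/array aligned to the
    matrix columns or, for a :class:`CqMatrix`, the name of an annotation
    column (``age_weeks``, ``genotype``, ``muscle``, ``strain``).
    """
    v = _values(matrix, genes)
    if grouping is None:
        raise ValueError("grouped analysis requires a grouping factor")
    if isinstance(grouping, str):
        if not isinstance(matrix, CqMatrix):
            raise ValueError("grouping by name requires a CqMatrix with annotation")
        labels = matrix.annotation.loc[v.columns, grouping]
        factor_name = grouping
    else:
        labels = pd.Series(np.asarray(grouping), index=v.columns)
        factor_name = getattr(grouping, "name", None) or "group"

    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise InsufficientDataError("grouped analysis needs >= 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise InsufficientDataError(f"group {g} has fewer than 2 samples")

    z = center_samples(v)  # per-sample loading removed
    gene_mean = z.mean(axis=1)

    d_raw = pd.DataFrame(index=v.index, columns=groups, dtype=float)
    sigma2 = pd.DataFrame(index=v.index, columns=groups, dtype=float)
    n_g = {}
    for g in groups:
        cols = labels.index[labels == g]
        n_g[g] = len(cols)
        d_raw[g] = z[cols].mean(axis=1) - gene_mean
        sigma2[g] = _corrected_variances((-v[cols]))

    samp_var = sigma2.div(pd.Series(n_g))  # sampling variance of each d estimate
    k = v.shape[0]
    G = len(groups)
    # empirical-Bayes prior variance of the true intergroup deviations
    dof = max((k - 1) * (G - 1), 1)
    gamma2 = max(0.0, float((d_raw ** 2).to_numpy().sum()) / dof
                 - float(samp_var.to_numpy().mean()))
    shrink = gamma2 / (gamma2 + samp_var) if gamma2 > 0 else samp_var * 0.0
    d_star = d_raw * shrink

    per_group = d_star.abs() + np.sqrt(samp_var)
    stab = per_group.mean(axis=1)
    stab.name = "stability"

    def set_stability(members: tuple[str, ...]) -> float:
        m = list(members)
        d_bar = d_star.loc[m].mean(axis=0)
        var_bar = samp_var.loc[m].sum(axis=0) / len(m) ** 2
        return float((d_bar.abs() + np.sqrt(var_bar)).mean())

    best_pair, best_val = None, np.inf
    for pair in combinations(v.index, 2):
        val = set_stability(pair)
        if val < best_val:
            best_pair, best_val = pair, val

    return NormfinderResult(
        mode="grouped",
        grouping=str(factor_name),
        stabilities=stab,
        intergroup=d_star,
        intergroup_raw=d_raw,
        intragroup_var=sigma2,
        best_pair=best_pair,
        best_pair_stability=best_val,
    )
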