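"""Consensus ranking across the four stability methods.

The four methods score on different scales and orientations: BestKeeper's
Pearson r is high-is-good and clamped to [-1, 1], while geNorm M, deltaCt
mean pair SD and NormFinder stability are low-is-good and unbounded.  To
aggregate, BestKeeper scores are first inverted (1 - r) and every method's
scores are then divided by their maximum, placing all on a (0, 1] scale with
low = stable; the per-gene geometric mean of the four transformed scores is
the consensus, ranked ascending.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bestkeeper import BestkeeperResult
from .deltact import DeltaCtResult
from .genorm import GenormResult
from .normfinder import NormfinderResult

__all__ = ["transform_scores", "aggregate", "consensus_table", "ZERO_FLOOR_FRACTION"]

#: Fraction of a method's maximum used to floor exact-zero transformed scores
#: so the geometric mean stays defined.
ZERO_FLOOR_FRACTION = 1e-6

METHODS = ("genorm", "bestkeeper", "deltact", "normfinder")


def transform_scores(method: str, raw: pd.Series) -> pd.Series:
    """Place one method's raw per-gene scores on the common (0, 1] scale.

    BestKeeper r is inverted to 1 - r first; all methods are then rescaled
    by their maximum so the least stable gene scores exactly 1.  If every
    gene is perfectly stable (max 0) all scores are set to 1 with a warning:
    the method carries no ranking information.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if raw.isna().any():
        missing = list(raw.index[raw.isna()])
        raise ValueError(f"{method} scores missing for genes: {missing}")
    s = (1.0 - raw) if method == "bestkeeper" else raw.astype(float)
    smax = s.max()
    if smax <= 0:
        warnings.warn(
            f"{method}: all genes perfectly stable; transformed scores degenerate to 1",
            stacklevel=2,
        )
        return pd.Series(1.0, index=raw.index)
    return s / smax


def aggregate(transformed: pd.DataFrame) -> pd.DataFrame:
    """Per-gene geometric mean of transformed method scores, ranked ascending.

    ``transformed`` holds one column per method on the common scale.  Exact
    zeros are floored at :data:`ZERO_FLOOR_FRACTION` of the column maximum
    (logged) so the geometric mean is defined.
    """
    t = transformed.copy().astype(float)
    for col in t.columns:
        zero = t[col] <= 0
        if zero.any():
            floor = ZERO_FLOOR_FRACTION * t[col].max()
            warnings.warn(
                f"{col}: flooring zero transformed score(s) for "
                f"{list(t.index[zero])} at {floor:g}",
                stacklevel=2,
            )
            t.loc[zero, col] = floor
    agg = np.exp(np.log(t).mean(axis=1))
    out = t.copy()
    out["aggregate"] = agg
    out["rank"] = agg.rank(method="min").astype(int)
    return out.sort_values("aggregate", kind="stable")


def consensus_table(
    genorm_result: GenormResult,
    bestkeeper_result: BestkeeperResult,
    deltact_result: DeltaCtResult,
    normfinder_result: NormfinderResult,
) -> pd.DataFrame:
    """Build the consensus table from the four method results.

    geNorm contributes each gene's M at elimination (best-pair members share
    the final pair M, honouring their equal rank); BestKeeper its Pearson r;
    deltaCt its mean pair SD; NormFinder its ungrouped stability.
    """
    genes = list(deltact_result.scores.index)
    raw = {
        "genorm": genorm_result.m_trace.reindex(genes),
        "bestkeeper": bestkeeper_result.correlations.reindex(genes),
        "deltact": deltact_result.scores.reindex(genes),
        "normfinder": normfinder_result.stabilities.reindex(genes),
    }
    transformed = pd.DataFrame(
        {m: transform_scores(m, s) for m, s in raw.items()}, index=genes
    )
    return aggregate(transformed)
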