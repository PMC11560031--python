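"""Model/Results interface over the four stability methods.

`ReferenceStabilityModel` is built from a collapsed Cq matrix (or straight
from a long table / CSV); `fit()` runs geNorm, BestKeeper, deltaCt and
NormFinder and returns a `ReferenceStabilityResults` carrying every method's
scores, the consensus ranking, the geNorm V curve and, when a grouping
factor is given, the grouped NormFinder decomposition with its best pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bestkeeper import BestkeeperResult, bestkeeper
from .consensus import consensus_table
from .deltact import DeltaCtResult, deltact
from .genorm import GenormResult, genorm
from .normfinder import NormfinderResult, grouped_stability, ungrouped_stability
from .io_qpcr import (
    CqMatrix,
    CqTable,
    collapse_technical_replicates,
    impute_or_drop,
    read_cq_table,
)

__all__ = ["ReferenceStabilityModel", "ReferenceStabilityResults"]


class ReferenceStabilityModel:
    """Candidate reference-gene stability model for one analysis subset.

    Parameters
    ----------
    matrix : CqMatrix
        Complete collapsed Cq matrix (genes x samples with annotation).
    genes : list of str, optional
        Panel restriction; defaults to every gene in the matrix.
    label : str
        Subset label carried into all tidy outputs.
    """

    def __init__(self, matrix: CqMatrix, genes=None, label: str = "entire"):
        self.matrix = matrix if genes is None else matrix.select(genes=genes)
        self.label = label
        if not self.matrix.is_complete():
            raise ValueError(
                "matrix has missing cells; run impute_or_drop or restrict the panel"
            )

    @classmethod
    def from_table(cls, table: CqTable, sd_threshold: float = 0.8,
                   policy: str = "drop_sample", genes=None, label: str = "entire"):
        """Collapse technical replicates and complete the matrix, then build."""
        matrix = collapse_technical_replicates(table, sd_threshold)
        if genes is not None:
            matrix = matrix.select(genes=genes)
        matrix = impute_or_drop(matrix, policy)
        return cls(matrix, label=label)

    @classmethod
    def from_csv(cls, path, column_map=None, **kwargs):
        """Read a long-format Cq CSV/XLSX and build the model."""
        return cls.from_table(read_cq_table(path, column_map=column_map), **kwargs)

    @property
    def genes(self) -> list[str]:
        return self.matrix.genes

    @property
    def nobs(self) -> int:
        return self.matrix.n_samples

    def fit(self, grouping: str | None = None) -> "ReferenceStabilityResults":
        """Run all four stability methods and the consensus aggregation."""
        gn = genorm(self.matrix)
        bk = bestkeeper(self.matrix)
        dct = deltact(self.matrix)
        nf = ungrouped_stability(self.matrix)
        nf_grouped = (
            grouped_stability(self.matrix, grouping=grouping)
            if grouping is not None
            else None
        )
        cons = consensus_table(gn, bk, dct, nf)
        return ReferenceStabilityResults(
            model=self, genorm=gn, bestkeeper=bk, deltact=dct,
            normfinder=nf, normfinder_grouped=nf_grouped, consensus=cons,
        )


@dataclass
class ReferenceStabilityResults:
    """Fitted stability estimates for one subset of the dataset."""

    model: ReferenceStabilityModel
    genorm: GenormResult
    bestkeeper: BestkeeperResult
    deltact: DeltaCtResult
    normfinder: NormfinderResult
    normfinder_grouped: NormfinderResult | None
    consensus: pd.DataFrame

    @property
    def ranking(self) -> list[str]:
        """Genes most to least stable by consensus aggregate."""
        return list(self.consensus.index)

    @property
    def best_pair(self) -> tuple[str, str]:
        """geNorm's terminal best pair."""
        return self.genorm.best_pair

    def scores(self) -> pd.DataFrame:
        """Raw per-gene scores of all four methods, one column per method."""
        genes = self.model.genes
        return pd.DataFrame(
            {
                "genorm_m": self.genorm.m_trace.reindex(genes),
                "bestkeeper_r": self.bestkeeper.correlations.reindex(genes),
                "deltact_sd": self.deltact.scores.reindex(genes),
                "normfinder_stability": self.normfinder.stabilities.reindex(genes),
            }
        )

    def summary(self) -> str:
        """Human-readable report: raw scores, consensus and the V curve."""
        lines = []
        label = self.model.label
        lines.append(f"Reference-gene stability summary — subset '{label}'")
        lines.append(
            f"{self.model.nobs} samples, {len(self.model.genes)} candidate genes"
        )
        lines.append("")
        table = self.scores().join(self.consensus[["aggregate", "rank"]])
        table = table.sort_values("rank")
        lines.append(table.to_string(float_format=lambda x: f"{x:.4f}"))
        lines.append("")
        bp = ", ".join(self.best_pair)
        lines.append(f"geNorm best pair (equal rank): {bp}")
        if self.normfinder_grouped is not None and self.normfinder_grouped.best_pair:
            a, b = self.normfinder_grouped.best_pair
            lines.append(
                f"NormFinder best pair (grouped by {self.normfinder_grouped.grouping}): "
                f"{a}, {b} (combined stability "
                f"{self.normfinder_grouped.best_pair_stability:.4f})"
            )
        if self.genorm.v_curve:
            vtxt = "  ".join(f"V{n}/{n+1}={v:.3f}" for n, v in self.genorm.v_curve)
            lines.append(f"geNorm pairwise variation: {vtxt}  (guideline < 0.2)")
        return "\n".join(lines)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Tidy CSV-ready frames keyed by result kind."""
        label = self.model.label
        frames = {
            "genorm": self.genorm.to_frame(label),
            "genorm_v": self.genorm.v_frame(label),
            "bestkeeper": self.bestkeeper.to_frame(label),
            "deltact": self.deltact.to_frame(label),
            "normfinder": self.normfinder.to_frame(label),
            "consensus": self.consensus.reset_index(names="gene").assign(
                subset_label=label
            ),
        }
        if self.normfinder_grouped is not None:
            frames["normfinder_grouped"] = self.normfinder_grouped.to_frame(label)
        return frames

    def plot_consensus(self, ax=None):
        from .plotting import plot_consensus

        return plot_consensus(self.consensus, self.model.label, ax=ax)

    def plot_v_curve(self, ax=None):
        from .plotting import plot_v_curve

        return plot_v_curve(self.genorm.v_curve, self.model.label, ax=ax)
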