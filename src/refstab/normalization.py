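"""Validation by normalisation: relative quantities, normalisation factors
and replicate-group coefficients of variation.

A chosen reference panel is validated by normalising poorly-ranked genes to
the panel's per-sample geometric mean and checking that the coefficient of
variation (CoV = SD/mean, linear scale) within replicate groups — samples
sharing strain, age and muscle, i.e. the three animals of one experimental
cell — drops after normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qpcr import CqMatrix, CompletenessError

__all__ = [
    "RQMatrix",
    "CovReport",
    "relative_quantities",
    "normalization_factor",
    "normalize_target",
    "cov_report",
    "validate_panel",
]

REPLICATE_KEYS = ["strain", "age_weeks", "muscle"]


@dataclass
class RQMatrix:
    """Linear-scale relative quantities with the per-gene calibrator Cq.

    RQ = efficiency^(calibrator - Cq) with the per-gene minimum Cq as
    calibrator, so each gene's maximum RQ is exactly 1.  Downstream CoV and
    normalised ratios are invariant to the calibrator choice (it cancels in
    SD/mean and in ratios).
    """

    values: pd.DataFrame       # genes x samples, all > 0
    calibrator: pd.Series      # per-gene reference Cq
    efficiency: float
    annotation: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CovReport:
    """Per-replicate-group CoV of a target, raw and normalised."""

    target: str
    panel: list[str]
    groups: pd.DataFrame       # index = (strain, age_weeks, muscle); cov_raw, cov_norm
    mean_cov_raw: float
    mean_cov_norm: float

    def to_frame(self) -> pd.DataFrame:
        out = self.groups.reset_index()
        out.insert(0, "target", self.target)
        out.insert(1, "panel", "+".join(self.panel))
        summary = pd.DataFrame(
            [{
                "target": self.target, "panel": "+".join(self.panel),
                "strain": "ALL", "age_weeks": -1, "muscle": "ALL",
                "cov_raw": self.mean_cov_raw, "cov_norm": self.mean_cov_norm,
            }]
        )
        return pd.concat([out, summary], ignore_index=True)


def relative_quantities(matrix: CqMatrix, efficiency: float = 2.0, genes=None) -> RQMatrix:
    """Convert Cq to linear relative quantities, RQ = E^(Cq_min - Cq)."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must lie in (1, 2]")
    v = matrix.values if genes is None else matrix.values.loc[list(genes)]
    if v.isna().any().any():
        raise CompletenessError("relative quantities require a complete matrix")
    calibrator = v.min(axis=1)
    rq = np.power(efficiency, v.rsub(calibrator, axis=0))
    return RQMatrix(rq, calibrator, efficiency, matrix.annotation.loc[v.columns])


def normalization_factor(rq: RQMatrix, panel: list[str]) -> pd.Series:
    """Per-sample normalisation factor: geometric mean of the panel's RQs."""
    panel = list(panel)
    if not panel:
        raise ValueError("reference panel is empty")
    missing = [g for g in panel if g not in rq.genes]
    if missing:
        raise KeyError(f"panel gene(s) not in matrix: {missing}")
    nf = np.exp(np.log(rq.values.loc[panel]).mean(axis=0))
    nf.name = "nf"
    return nf


def normalize_target(rq: RQMatrix, target: str, panel: list[str]) -> pd.Series:
    """Target RQ divided by the panel normalisation factor, per sample.

    The target may itself sit in the panel (self-normalisation is a valid,
    if conservative, check).
    """
    out = rq.values.loc[target] / normalization_factor(rq, panel)
    out.name = target
    return out


def _group_cov(values: pd.Series, annotation: pd.DataFrame) -> pd.Series:
    ann = annotation.loc[values.index, REPLICATE_KEYS]
    grouped = values.groupby([ann[k] for k in REPLICATE_KEYS])
    n = grouped.count()
    if (n < 2).any():
        small = list(n.index[n < 2])
        raise ValueError(f"replicate group(s) with < 2 members: {small}")
    mean = grouped.mean()
    if (mean <= 0).any():
        raise ValueError("replicate group with non-positive mean")
    return grouped.std(ddof=1) / mean


def cov_report(
    raw: pd.Series,
    normalised: pd.Series,
    annotation: pd.DataFrame,
    target: str = "",
    panel: list[str] | None = None,
) -> CovReport:
    """Per-replicate-group CoV (SD/mean, linear scale) raw vs normalised.

    Replicate groups are the (strain, age_weeks, muscle) cells of the
    design; the summary is the arithmetic mean of per-group CoVs.
    """
    cov_raw = _group_cov(raw, annotation)
    cov_norm = _group_cov(normalised, annotation)
    groups = pd.DataFrame({"cov_raw": cov_raw, "cov_norm": cov_norm})
    groups.index.names = REPLICATE_KEYS
    return CovReport(
        target=target,
        panel=list(panel or []),
        groups=groups,
        mean_cov_raw=float(cov_raw.mean()),
        mean_cov_norm=float(cov_norm.mean()),
    )


def validate_panel(
    matrix: CqMatrix,
    targets: list[str],
    panel: list[str],
    efficiency: float = 2.0,
) -> dict[str, CovReport]:
    """Normalise each target to the panel and report CoV before/after."""
    rq = relative_quantities(matrix, efficiency)
    out = {}
    for target in targets:
        raw = rq.values.loc[target]
        norm = normalize_target(rq, target, panel)
        out[target] = cov_report(raw, norm, rq.annotation, target=target, panel=panel)
    return out
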