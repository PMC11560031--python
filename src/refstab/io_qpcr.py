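"""Reading, validating, filtering and reshaping raw qPCR Cq data.

Raw data arrives as a long table with one row per well: a biological sample
(one muscle from one animal), a candidate reference gene, a technical
replicate number and the quantification cycle (Cq).  Analysis operates on a
collapsed genes x samples matrix, produced by averaging acceptable technical
duplicates and discarding noisy ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CORE_GENES",
    "HEART_GENES",
    "STRAINS",
    "MUSCLES",
    "AGES",
    "DEFAULT_COLUMNS",
    "SchemaError",
    "ParseError",
    "CompletenessError",
    "CqTable",
    "CqMatrix",
    "read_cq_table",
    "collapse_technical_replicates",
    "impute_or_drop",
    "genotype_of",
]

#: Candidate reference genes assayed in every muscle.
CORE_GENES = ["ACTB", "AP3D1", "CSNK2A2", "GAPDH", "HPRT1", "PAK1IP1", "RPL13A", "SDHA"]
#: Additional candidates assayed in heart only.
HEART_GENES = ["HTATSF1", "HMBS"]

STRAINS = ["BL10-wt", "BL10-mdx", "D2-wt", "D2-mdx"]
MUSCLES = ["GC", "DIA", "heart"]
AGES = [4, 8, 12, 28, 52]

#: Canonical long-format column names; a ``column_map`` may rename source headers.
DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "strain": "strain",
    "age_weeks": "age_weeks",
    "muscle": "muscle",
    "animal": "animal",
    "gene": "gene",
    "tech_rep": "tech_rep",
    "cq": "cq",
}

MANDATORY_FIELDS = list(DEFAULT_COLUMNS)


class SchemaError(ValueError):
    """A mandatory column is absent or an annotation value is not recognised."""


class ParseError(ValueError):
    """A cell could not be parsed (carries the offending row index)."""


class CompletenessError(ValueError):
    """An operation requiring a complete matrix met missing cells."""


def genotype_of(strain: str) -> str:
    """Derive genotype from strain: ``*-wt`` is healthy, ``*-mdx`` dystrophic."""
    if strain.endswith("-wt"):
        return "healthy"
    if strain.endswith("-mdx"):
        return "dystrophic"
    raise SchemaError(f"cannot derive genotype from strain {strain!r}")


@dataclass
class CqTable:
    """Long-format raw Cq measurements, one row per well.

    ``data`` columns: sample_id, strain, genotype, age_weeks, muscle, animal,
    gene, tech_rep, cq.  Missing wells carry NaN in ``cq`` — they are kept as
    rows, never silently dropped.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup = df.duplicated(subset=["sample_id", "gene", "tech_rep"])
        if dup.any():
            bad = df.loc[dup, ["sample_id", "gene", "tech_rep"]].iloc[0]
            raise SchemaError(
                f"(sample_id, gene, tech_replicate) not unique: {tuple(bad)}"
            )
        cq = df["cq"]
        if ((cq <= 0) & cq.notna()).any():
            raise ParseError("non-positive Cq present; missing wells must be NaN")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"]))

    def to_csv(self, path) -> None:
        """Write the canonical long CSV dialect (NaN rendered empty)."""
        self.data.drop(columns=["genotype"]).to_csv(path, index=False)


@dataclass
class CqMatrix:
    """Collapsed genes x samples Cq matrix with aligned sample annotation.

    values: DataFrame indexed by gene, columns = sample_id, NaN = missing.
    annotation: DataFrame indexed by sample_id with strain, genotype,
        age_weeks, muscle, animal columns, exactly one row per sample.
    dropped: log of removed cells, columns (sample_id, gene, reason).
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "gene", "reason"])
    )

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.annotation.index):
            self.annotation = self.annotation.loc[list(self.values.columns)]
        if self.annotation.index.has_duplicates:
            raise SchemaError("annotation has duplicated sample ids")
        v = self.values
        if len(v) and v.isna().all(axis=1).any():
            empty = v.index[v.isna().all(axis=1)].tolist()
            raise CompletenessError(f"gene rows entirely missing: {empty}")
        if len(v.columns) and len(v) and v.isna().all(axis=0).any():
            empty = v.columns[v.isna().all(axis=0)].tolist()
            raise CompletenessError(f"sample columns entirely missing: {empty}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def is_complete(self, genes=None) -> bool:
        v = self.values if genes is None else self.values.loc[list(genes)]
        return not v.isna().any().any()

    def missing_cells(self, genes=None) -> list[tuple[str, str]]:
        v = self.values if genes is None else self.values.loc[list(genes)]
        mask = v.isna()
        return [(g, s) for g in v.index for s in v.columns if mask.at[g, s]]

    def select(self, samples=None, genes=None) -> "CqMatrix":
        """Restrict to the given samples and/or genes (order preserved)."""
        v = self.values
        if genes is not None:
            v = v.loc[[g for g in genes if g in v.index]]
        if samples is not None:
            v = v[[s for s in samples if s in v.columns]]
        ann = self.annotation.loc[list(v.columns)]
        return CqMatrix(v.copy(), ann.copy(), self.dropped.copy())

    def to_wide_csv(self, path) -> None:
        self.values.to_csv(path, index_label="gene")

    def drop_log_csv(self, path) -> None:
        self.dropped.to_csv(path, index=False)


def _normalise_format(path, format: str | None) -> str:
    if format is not None:
        return format
    p = str(path).lower()
    if p.endswith((".xlsx", ".xlsm")):
        return "xlsx"
    return "csv"


def read_cq_table(path, format: str | None = None, column_map: dict | None = None) -> CqTable:
    """Read a long-format Cq table from CSV or XLSX into a :class:`CqTable`.

    ``column_map`` maps canonical field names (keys of :data:`DEFAULT_COLUMNS`)
    to the source file's headers.  Unknown strain/muscle/age values are
    rejected rather than coerced; a non-numeric Cq other than the recognised
    missing markers raises :class:`ParseError` with the row index.
    """
    fmt = _normalise_format(path, format)
    if fmt == "xlsx":
        raw = pd.read_excel(path)
    elif fmt == "csv":
        raw = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    missing = [f for f in MANDATORY_FIELDS if cmap[f] not in raw.columns]
    if missing:
        raise SchemaError(
            "missing mandatory column(s): "
            + ", ".join(f"{f} (expected header {cmap[f]!r})" for f in missing)
        )

    df = pd.DataFrame(
        {field: raw[cmap[field]] for field in MANDATORY_FIELDS}
    ).rename(columns={"animal": "animal", "tech_rep": "tech_rep"})

    missing_markers = {"", "n/a", "na", "nan", "none", "undetermined", "-"}

    def parse_cq(value, idx):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        if isinstance(value, str):
            if value.strip().lower() in missing_markers:
                return np.nan
            try:
                return float(value)
            except ValueError:
                raise ParseError(f"non-numeric cq {value!r} at row {idx}") from None
        return float(value)

    df["cq"] = [parse_cq(v, i) for i, v in zip(raw.index, df["cq"])]

    for col, allowed in (("strain", STRAINS), ("muscle", MUSCLES)):
        df[col] = df[col].astype(str)
        bad = sorted(set(df[col]) - set(allowed))
        if bad:
            raise SchemaError(f"unknown {col} value(s): {bad}")
    df["age_weeks"] = df["age_weeks"].astype(int)
    bad_age = sorted(set(df["age_weeks"]) - set(AGES))
    if bad_age:
        raise SchemaError(f"unknown age_weeks value(s): {bad_age}")
    df["animal"] = df["animal"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    df["sample_id"] = df["sample_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    df["genotype"] = df["strain"].map(genotype_of)

    order = ["sample_id", "strain", "genotype", "age_weeks", "muscle", "animal",
             "gene", "tech_rep", "cq"]
    return CqTable(df[order].reset_index(drop=True))


def collapse_technical_replicates(table: CqTable, sd_threshold: float = 0.8) -> CqMatrix:
    """Collapse technical replicates into a genes x samples Cq matrix.

    The collapsed value is the arithmetic mean of the replicate Cq values
    (the geometric mean of the linear quantities).  A (sample, gene) cell
    whose replicate sample standard deviation (n-1 denominator) is >= the
    threshold is set missing and logged with reason ``duplicate_sd``; the
    comparison is strict, so SD exactly at the threshold is rejected.
    Singleton replicates pass unconditionally; wells missing in the raw data
    are logged with reason ``missing_well``.
    """
    df = table.data
    ann = (
        df.drop_duplicates("sample_id")
        .set_index("sample_id")[["strain", "genotype", "age_weeks", "muscle", "animal"]]
    )
    grouped = df.groupby(["sample_id", "gene"], sort=False)["cq"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)  # NaN for singletons -> passes
    n_present = grouped.count()

    dropped_rows = []
    collapsed = mean.copy()
    fail_sd = (sd >= sd_threshold).fillna(False)
    for (sid, gene) in collapsed.index[fail_sd]:
        dropped_rows.append((sid, gene, "duplicate_sd"))
    collapsed[fail_sd] = np.nan
    for (sid, gene) in collapsed.index[(n_present == 0)]:
        dropped_rows.append((sid, gene, "missing_well"))

    sample_order = list(pd.unique(df["sample_id"]))
    gene_order = list(pd.unique(df["gene"]))
    values = collapsed.unstack("gene").T.reindex(index=gene_order, columns=sample_order)

    # a gene or sample whose every cell failed QC is pruned (cells already logged)
    empty_genes = values.index[values.isna().all(axis=1)].tolist()
    if empty_genes:
        warnings.warn(f"pruning gene(s) with no retained cells: {empty_genes}",
                      stacklevel=2)
        values = values.drop(index=empty_genes)
    empty_samples = values.columns[values.isna().all(axis=0)].tolist()
    if empty_samples:
        warnings.warn(f"pruning sample(s) with no retained cells: {empty_samples}",
                      stacklevel=2)
        values = values.drop(columns=empty_samples)
        sample_order = [s for s in sample_order if s not in empty_samples]

    dropped = pd.DataFrame(dropped_rows, columns=["sample_id", "gene", "reason"])
    return CqMatrix(values, ann.loc[sample_order], dropped)


def impute_or_drop(matrix: CqMatrix, policy: str = "drop_sample") -> CqMatrix:
    """Return a complete matrix under the given missing-cell policy.

    drop_sample removes any sample column with a missing cell, drop_gene any
    gene row, and ``none`` demands completeness and raises
    :class:`CompletenessError` listing the offending cells otherwise.  Every
    removal is appended to the drop log.
    """
    v = matrix.values
    missing = matrix.missing_cells()
    if not missing:
        return matrix
    extra = []
    if policy == "none":
        raise CompletenessError(f"matrix has missing cells: {missing}")
    if policy == "drop_sample":
        bad_samples = sorted({s for _, s in missing}, key=matrix.samples.index)
        keep = [s for s in matrix.samples if s not in bad_samples]
        for s in bad_samples:
            for g in matrix.genes:
                extra.append((s, g, "policy_drop_sample"))
        out = v[keep]
        ann = matrix.annotation.loc[keep]
    elif policy == "drop_gene":
        bad_genes = sorted({g for g, _ in missing}, key=matrix.genes.index)
        keep = [g for g in matrix.genes if g not in bad_genes]
        for g in bad_genes:
            for s in matrix.samples:
                extra.append((s, g, "policy_drop_gene"))
        out = v.loc[keep]
        ann = matrix.annotation
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if out.empty:
        warnings.warn("impute_or_drop removed everything", stacklevel=2)
    dropped = pd.concat(
        [matrix.dropped, pd.DataFrame(extra, columns=["sample_id", "gene", "reason"])],
        ignore_index=True,
    )
    return CqMatrix(out.copy(), ann.copy(), dropped)
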