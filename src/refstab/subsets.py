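"""Standard analysis subsets of the natural-history design.

The full design (4 strains x 5 ages x 3 muscles x 3 animals = 180 samples)
is analysed whole and in fixed subsets: by genotype (N=90), by muscle
(N=60, the heart additionally with its two extra candidate genes), by strain
(N=45) and by age (N=36).  Subset labels are fixed strings reused across all
result files so the four methods' outputs join cleanly.  Because ranking
validity degrades with shrinking N, subsets below 36 samples are refused
unless explicitly forced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io_qpcr import AGES, CORE_GENES, HEART_GENES, MUSCLES, STRAINS, CqMatrix

__all__ = ["SubsetSpec", "standard_subsets", "apply_subset", "MIN_SUBSET_N"]

#: Smallest subset size the engine will materialise without ``force``.
MIN_SUBSET_N = 36

PANELS = {"core8": CORE_GENES, "heart10": CORE_GENES + HEART_GENES}


@dataclass
class SubsetSpec:
    """A labelled sample filter plus the gene panel to analyse it with.

    ``filter`` maps annotation columns to required values; an empty filter
    selects every sample.  ``expected_n`` is checked when set (a mismatch is
    a warning naming the realised N, not an error, so partial designs can
    still be analysed).
    """

    label: str
    filter: dict = field(default_factory=dict)
    expected_n: int | None = None
    gene_panel: str = "core8"

    def matches(self, annotation) -> "pd.Series":
        mask = annotation.index == annotation.index  # all True
        for col, value in self.filter.items():
            mask = mask & (annotation[col] == value)
        return mask


def standard_subsets(matrix: CqMatrix) -> list[SubsetSpec]:
    """The study's full subset plan, with design-arithmetic expectations.

    Returns: entire (180), healthy/dystrophic (90 each), GC/DIA (60),
    heart with the core panel and again with the 10-gene heart panel (60),
    one subset per strain (45) and per age (36).  Each spec whose realised N
    differs from the design expectation triggers a warning.
    """
    specs = [SubsetSpec("entire", {}, 180, "core8")]
    for geno in ("healthy", "dystrophic"):
        specs.append(SubsetSpec(geno, {"genotype": geno}, 90, "core8"))
    for muscle in MUSCLES:
        specs.append(SubsetSpec(muscle, {"muscle": muscle}, 60, "core8"))
    specs.append(SubsetSpec("heart-extended", {"muscle": "heart"}, 60, "heart10"))
    for strain in STRAINS:
        specs.append(SubsetSpec(strain, {"strain": strain}, 45, "core8"))
    for age in AGES:
        specs.append(SubsetSpec(f"age-{age}", {"age_weeks": age}, 36, "core8"))

    ann = matrix.annotation
    for spec in specs:
        realised = int(spec.matches(ann).sum())
        if spec.expected_n is not None and realised != spec.expected_n:
            warnings.warn(
                f"subset {spec.label!r}: design expects N={spec.expected_n}, "
                f"matrix yields N={realised}",
                stacklevel=2,
            )
    return specs


def apply_subset(matrix: CqMatrix, spec: SubsetSpec, force: bool = False) -> CqMatrix:
    """Materialise a subset: filter samples, restrict to the gene panel.

    Refuses subsets smaller than :data:`MIN_SUBSET_N` samples unless
    ``force`` is given; raises on an empty selection.  Completeness of the
    result is re-checked for the chosen panel (heart-only genes are absent
    from skeletal-muscle columns by design, so completeness is only
    meaningful per subset).
    """
    mask = spec.matches(matrix.annotation)
    samples = list(matrix.annotation.index[mask])
    if not samples:
        raise ValueError(f"subset {spec.label!r} selects no samples")
    if len(samples) < MIN_SUBSET_N and not force:
        raise ValueError(
            f"subset {spec.label!r} has N={len(samples)} < {MIN_SUBSET_N}; "
            "ranking validity degrades with small N (pass force=True to override)"
        )
    panel = PANELS[spec.gene_panel]
    genes = [g for g in panel if g in matrix.genes]
    sub = matrix.select(samples=samples, genes=genes)
    if not sub.is_complete():
        warnings.warn(
            f"subset {spec.label!r} has missing cells after panel restriction; "
            "apply impute_or_drop before stability analysis",
            stacklevel=2,
        )
    return sub
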