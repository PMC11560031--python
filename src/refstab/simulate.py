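"""Synthetic Cq data with the natural-history study design and known truth.

The generator emits a full design — 4 strains (two dystrophic mdx lines and
their wild-type backgrounds) x 5 ages (4..52 weeks) x 3 muscles (GC, DIA,
heart) x 3 animals = 180 samples — for 8 core candidate genes plus 2
heart-only candidates, in technical duplicate.  Each well's Cq is

    baseline + muscle shift + age slope * log2(age/4) + disease shift
    + per-sample loading + per-well gene residual + duplicate noise,

with the per-sample loading shared by all genes of a sample (the cDNA
content every stability algorithm tries to see through).  The planted
shifts/slopes are the ground truth against which ranking recovery is
checked.  All draws come from one seeded generator, so a seed fully
determines the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io_qpcr import AGES, MUSCLES, STRAINS, CqTable, genotype_of

__all__ = [
    "GeneSpec",
    "SimulationTruth",
    "default_design",
    "default_truth",
    "simulate_cq",
    "truth_report",
]


@dataclass
class GeneSpec:
    """Ground-truth expression behaviour of one synthetic gene.

    Shifts are in Cq units (negative = more abundant); ``age_slope`` is Cq
    per doubling of age relative to 4 weeks; ``disease_shift`` applies to
    dystrophic samples, keyed by strain background ("BL10", "D2").  A stable
    gene has no shifts or slope and a small ``residual_sd``.
    """

    name: str
    baseline_cq: float
    residual_sd: float = 0.2
    muscle_shift: dict = field(default_factory=dict)
    age_slope: float = 0.0
    disease_shift: dict = field(default_factory=dict)
    heart_only: bool = False

    def expected_cq(self, strain: str, age_weeks: int, muscle: str) -> float:
        """Deterministic Cq for a design cell (no noise, no loading)."""
        cq = self.baseline_cq
        cq += self.muscle_shift.get(muscle, 0.0)
        cq += self.age_slope * np.log2(age_weeks / 4.0)
        if genotype_of(strain) == "dystrophic":
            background = strain.split("-")[0]
            cq += self.disease_shift.get(background, 0.0)
        return cq

    @property
    def is_stable(self) -> bool:
        return (
            not any(self.muscle_shift.values())
            and self.age_slope == 0.0
            and not any(self.disease_shift.values())
        )


@dataclass
class SimulationTruth:
    """Complete generator configuration: gene specs plus global noise terms.

    ``loading_sd`` is the SD (Cq) of the per-sample cDNA-loading offset
    shared by all genes of a sample; ``duplicate_sd`` the SD of technical
    replicate noise.  Serialisable to YAML so every generated dataset can
    carry its truth alongside.
    """

    genes: list[GeneSpec]
    loading_sd: float = 0.8
    duplicate_sd: float = 0.15
    seed: int = 0

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def planted_instability(self, design: pd.DataFrame | None = None) -> pd.Series:
        """Extra per-sample SD each gene carries beyond the shared loading.

        The SD of the deterministic effects over the design cells the gene is
        measured in, pooled with its residual SD: the quantity the stability
        methods should rank by.
        """
        if design is None:
            design = default_design()
        out = {}
        for g in self.genes:
            d = design if not g.heart_only else design[design["muscle"] == "heart"]
            det = np.array(
                [g.expected_cq(r.strain, r.age_weeks, r.muscle) for r in d.itertuples()]
            )
            out[g.name] = float(np.sqrt(det.var() + g.residual_sd ** 2))
        return pd.Series(out, name="planted_instability")

    def to_yaml(self, path) -> None:
        payload = {
            "loading_sd": self.loading_sd,
            "duplicate_sd": self.duplicate_sd,
            "seed": self.seed,
            "genes": [asdict(g) for g in self.genes],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        genes = [GeneSpec(**g) for g in payload.pop("genes")]
        return cls(genes=genes, **payload)


def default_design() -> pd.DataFrame:
    """The full natural-history sampling plan: one row per biological sample."""
    rows = []
    for strain in STRAINS:
        for age in AGES:
            for animal in (1, 2, 3):
                for muscle in MUSCLES:
                    rows.append(
                        {
                            "sample_id": f"{strain}_w{age}_{muscle}_a{animal}",
                            "strain": strain,
                            "genotype": genotype_of(strain),
                            "age_weeks": age,
                            "muscle": muscle,
                            "animal": animal,
                        }
                    )
    return pd.DataFrame(rows)


def default_truth(seed: int = 0) -> SimulationTruth:
    """Truth emulating the study's reported expression behaviour.

    Stable references (no planted effects): CSNK2A2 and AP3D1 (modest
    abundance, Cq ~25-26), ACTB (abundant), SDHA and PAK1IP1.  Planted
    instabilities: GAPDH more abundant in GC with a modest dystrophic
    reduction in expression; HPRT1 muscle-specific (abundant in GC, weak in
    heart); RPL13A expression rising steadily with age.  The two heart-only
    candidates HTATSF1 (stable) and HMBS (middling) appear in heart samples
    only.  Abundances keep the dataset inside the ~14-30 Cq span.
    """
    genes = [
        GeneSpec("ACTB", 15.8, residual_sd=0.25),
        GeneSpec("AP3D1", 25.0, residual_sd=0.2),
        GeneSpec("CSNK2A2", 25.5, residual_sd=0.2),
        GeneSpec(
            "GAPDH", 16.5, residual_sd=0.45,
            muscle_shift={"GC": -1.5},
            disease_shift={"BL10": 0.3, "D2": 0.5},
        ),
        GeneSpec(
            "HPRT1", 24.0, residual_sd=0.5,
            muscle_shift={"GC": -1.0, "heart": 1.0},
        ),
        GeneSpec("PAK1IP1", 26.5, residual_sd=0.3),
        GeneSpec("RPL13A", 18.0, residual_sd=0.4, age_slope=-0.4),
        GeneSpec("SDHA", 19.5, residual_sd=0.3),
        GeneSpec("HTATSF1", 26.0, residual_sd=0.2, heart_only=True),
        GeneSpec("HMBS", 27.5, residual_sd=0.35, heart_only=True),
    ]
    return SimulationTruth(genes=genes, seed=seed)


def simulate_cq(truth: SimulationTruth, design: pd.DataFrame | None = None,
                n_tech_reps: int = 2) -> CqTable:
    """Draw a long-format Cq table from the truth on the given design."""
    if design is None:
        design = default_design()
    rng = np.random.default_rng(truth.seed)
    loading = rng.normal(0.0, truth.loading_sd, size=len(design))
    rows = []
    for (i, sample), load in zip(design.iterrows(), loading):
        for g in truth.genes:
            if g.heart_only and sample["muscle"] != "heart":
                continue
            det = g.expected_cq(sample["strain"], sample["age_weeks"], sample["muscle"])
            well = det + load + rng.normal(0.0, g.residual_sd)
            for rep in range(1, n_tech_reps + 1):
                rows.append(
                    {
                        "sample_id": sample["sample_id"],
                        "strain": sample["strain"],
                        "genotype": sample["genotype"],
                        "age_weeks": sample["age_weeks"],
                        "muscle": sample["muscle"],
                        "animal": sample["animal"],
                        "gene": g.name,
                        "tech_rep": rep,
                        "cq": well + rng.normal(0.0, truth.duplicate_sd),
                    }
                )
    return CqTable(pd.DataFrame(rows))


def truth_report(truth: SimulationTruth, consensus: pd.DataFrame) -> dict:
    """Ranking-recovery metrics of a consensus table against the truth.

    Reports the Spearman correlation between planted instability and the
    aggregate consensus score over the genes analysed, and flags every
    stable gene that ranked below (worse than) any unstable gene.
    """
    genes = list(consensus.index)
    known = {g.name for g in truth.genes}
    unknown = sorted(set(genes) - known)
    if unknown:
        raise ValueError(f"consensus contains genes absent from truth: {unknown}")
    instability = truth.planted_instability().loc[genes]
    aggregate = consensus["aggregate"]
    if instability.nunique() > 1 and aggregate.nunique() > 1:
        rho = float(stats.spearmanr(instability, aggregate).statistic)
    else:
        rho = np.nan  # degenerate: no ranking information to correlate
    stable = [g for g in genes if truth.gene(g).is_stable]
    unstable = [g for g in genes if not truth.gene(g).is_stable]
    flags = []
    if unstable:
        best_unstable_rank = min(consensus.loc[g, "rank"] for g in unstable)
        flags = [g for g in stable if consensus.loc[g, "rank"] > best_unstable_rank]
    return {
        "spearman_instability_vs_aggregate": rho,
        "stable_genes": stable,
        "unstable_genes": unstable,
        "misranked_stable_genes": flags,
    }
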