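"""Synthetic-data generator: design arithmetic, determinism, planted truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from refstab.bestkeeper import bestkeeper
from refstab.deltact import deltact
from refstab.genorm import rank_iterative
from refstab.io_qpcr import collapse_technical_replicates, CORE_GENES
from refstab.model import ReferenceStabilityModel
from refstab.normfinder import ungrouped_stability
from refstab.simulate import (
    GeneSpec,
    SimulationTruth,
    default_design,
    default_truth,
    simulate_cq,
    truth_report,
)


class TestDesign:
    def test_sample_counts(self):
        d = default_design()
        assert len(d) == 180
        assert d.groupby("strain").size().eq(45).all()
        assert d.groupby("age_weeks").size().eq(36).all()
        assert d.groupby("muscle").size().eq(60).all()
        assert d["sample_id"].is_unique

    def test_heart_only_genes_restricted_to_heart(self, cq_table):
        heart_rows = cq_table.data[cq_table.data["gene"].isin(["HTATSF1", "HMBS"])]
        assert set(heart_rows["muscle"]) == {"heart"}

    def test_two_technical_replicates_per_well(self, cq_table):
        reps = cq_table.data.groupby(["sample_id", "gene"])["tech_rep"].count()
        assert (reps == 2).all()


class TestDeterminism:
    def test_same_seed_identical_bytes(self, tmp_path):
        t = default_truth(seed=12)
        a, b = simulate_cq(t), simulate_cq(t)
        pd.testing.assert_frame_equal(a.data, b.data)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa)
        b.to_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ_same_schema(self):
        a = simulate_cq(default_truth(seed=1))
        b = simulate_cq(default_truth(seed=2))
        assert list(a.data.columns) == list(b.data.columns)
        assert not np.allclose(a.data["cq"], b.data["cq"])

    def test_truth_yaml_roundtrip(self, tmp_path, truth):
        path = tmp_path / "truth.yaml"
        truth.to_yaml(path)
        again = SimulationTruth.from_yaml(path)
        assert again == truth


class TestDefaultTruth:
    def test_cq_span_matches_study_range(self, cq_table):
        cq = cq_table.data["cq"]
        assert cq.min() > 12.5 and cq.max() < 31.5
        within = cq.between(14, 30).mean()
        assert within > 0.97  # ~14-30 span, Gaussian tails allowed
        assert cq.min() < 17 and cq.max() > 25  # spans several orders of magnitude

    def test_degenerate_noiseless_truth_is_perfectly_stable(self):
        genes = [GeneSpec(f"G{i}", 20.0 + i, residual_sd=0.0) for i in range(4)]
        truth = SimulationTruth(genes=genes, loading_sd=0.0, duplicate_sd=0.0, seed=0)
        table = simulate_cq(truth)
        m = collapse_technical_replicates(table)
        for g, spec in zip(m.genes, genes):
            assert np.allclose(m.values.loc[g], spec.baseline_cq)
        assert np.allclose(rank_iterative(m).m_trace, 0.0, atol=1e-9)
        assert np.allclose(deltact(m).scores, 0.0, atol=1e-9)
        assert np.allclose(ungrouped_stability(m).stabilities, 0.0, atol=1e-9)
        with pytest.warns(UserWarning, match="zero-variance"):
            bk = bestkeeper(m)
        assert bk.correlations.isna().all()  # r undefined for constant profiles

    def test_planted_age_slope_rises_monotonically_after_normalisation(self, truth):
        """RPL13A-like expression, normalised to stable genes, increases in
        expectation from 4 to 52 weeks (negative Cq slope = rising RQ)."""
        from refstab.normalization import normalize_target, relative_quantities

        table = simulate_cq(truth)
        m = collapse_technical_replicates(table).select(
            genes=["RPL13A", "ACTB", "AP3D1", "CSNK2A2"]
        )
        rq = relative_quantities(m)
        norm = normalize_target(rq, "RPL13A", ["ACTB", "AP3D1", "CSNK2A2"])
        by_age = np.log2(norm).groupby(m.annotation["age_weeks"]).mean()
        assert by_age.loc[52] > by_age.loc[4]
        assert by_age.is_monotonic_increasing

    def test_loading_sd_inflates_bestkeeper_correlations(self):
        """Sample-to-sample loading produces high consensus correlations for
        every gene simultaneously: mean r rises with loading SD."""
        mean_r = []
        for loading in (0.0, 0.5, 1.0):
            truth = default_truth(seed=5)
            truth.loading_sd = loading
            m = collapse_technical_replicates(simulate_cq(truth)).select(
                genes=CORE_GENES
            )
            mean_r.append(bestkeeper(m).correlations.mean())
        assert mean_r[0] < mean_r[1] < mean_r[2]


class TestTruthReport:
    def test_all_stable_truth_has_no_flags(self):
        genes = [GeneSpec(f"G{i}", 20.0 + i, residual_sd=0.2) for i in range(4)]
        truth = SimulationTruth(genes=genes, loading_sd=0.5, seed=6)
        m = collapse_technical_replicates(simulate_cq(truth))
        res = ReferenceStabilityModel(m).fit()
        rep = truth_report(truth, res.consensus)
        assert rep["misranked_stable_genes"] == []
        assert rep["unstable_genes"] == []

    def test_large_effects_fully_recovered_at_large_n(self):
        """3 stable + 3 strongly perturbed genes: consensus separates them
        perfectly on a design replicated to ~1000 samples."""
        genes = [
            GeneSpec("S1", 20.0, residual_sd=0.1),
            GeneSpec("S2", 22.0, residual_sd=0.15),
            GeneSpec("S3", 24.0, residual_sd=0.2),
            GeneSpec("U1", 19.0, residual_sd=0.3, muscle_shift={"GC": -2.0}),
            GeneSpec("U2", 21.0, residual_sd=0.3, age_slope=-0.8),
            GeneSpec("U3", 23.0, residual_sd=0.3,
                     disease_shift={"BL10": 1.5, "D2": 1.5}),
        ]
        truth = SimulationTruth(genes=genes, loading_sd=0.8, seed=8)
        design = pd.concat(
            [default_design().assign(sample_id=lambda d, r=r: d.sample_id + f"_r{r}")
             for r in range(6)],
            ignore_index=True,
        )  # 1080 samples
        m = collapse_technical_replicates(simulate_cq(truth, design=design))
        res = ReferenceStabilityModel(m).fit()
        rep = truth_report(truth, res.consensus)
        assert rep["misranked_stable_genes"] == []
        assert set(res.ranking[:3]) == {"S1", "S2", "S3"}

    def test_paper_like_truth_tops_stable_trio(self, truth, entire_matrix):
        """Under the default truth the stable, abundant trio (CSNK2A2-like,
        AP3D1-like, ACTB-like) should occupy leading consensus ranks."""
        res = ReferenceStabilityModel(entire_matrix).fit()
        rep = truth_report(truth, res.consensus)
        assert rep["misranked_stable_genes"] == []
        assert {"CSNK2A2", "AP3D1"} <= set(res.ranking[:3])
        assert rep["spearman_instability_vs_aggregate"] > 0.7

    def test_gene_mismatch_rejected(self, truth, entire_matrix):
        res = ReferenceStabilityModel(entire_matrix).fit()
        cons = res.consensus.rename(index={"ACTB": "MYSTERY"})
        with pytest.raises(ValueError, match="MYSTERY"):
            truth_report(truth, cons)
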