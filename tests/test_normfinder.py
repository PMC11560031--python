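"""NormFinder: centering, variance estimation, grouped decomposition."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from refstab.normfinder import (
    center_samples,
    grouped_stability,
    ungrouped_stability,
)

from conftest import toy_frame


def simulate_model(rng, sigmas, n, loading_sd=1.0, group_shift=None, labels=None):
    """Draw Cq from the additive model: gene effect + loading + N(0, sigma_g)."""
    G = len(sigmas)
    base = np.linspace(18, 27, G)[:, None]
    loading = rng.normal(0, loading_sd, size=(1, n))
    eps = rng.normal(0, np.asarray(sigmas)[:, None], size=(G, n))
    cq = base + loading + eps
    if group_shift is not None:
        gene, shift = group_shift
        cq[gene, np.asarray(labels) == 1] += shift
    return toy_frame(cq)


class TestCentering:
    def test_identical_gene_columns_center_to_zero(self):
        col = np.array([20.0, 22.0, 24.0])
        v = toy_frame([col, col, col])
        assert np.allclose(center_samples(v), 0.0)

    def test_two_gene_closed_form(self):
        v = toy_frame([[20.0], [24.0]], genes=["A", "B"])
        z = center_samples(v)
        assert z.loc["A"].iloc[0] == pytest.approx(2.0)
        assert z.loc["B"].iloc[0] == pytest.approx(-2.0)

    def test_columns_sum_to_zero(self):
        rng = np.random.default_rng(31)
        z = center_samples(toy_frame(rng.normal(22, 2, size=(5, 8))))
        assert np.allclose(z.sum(axis=0), 0.0, atol=1e-12)


class TestUngrouped:
    def test_constant_offset_genes_perfectly_stable(self):
        base = np.array([20.0, 21.5, 19.0, 22.0])
        v = toy_frame([base, base + 2, base + 5])
        res = ungrouped_stability(v)
        assert np.allclose(res.stabilities, 0.0, atol=1e-9)

    def test_fewer_than_three_genes_rejected(self):
        v = toy_frame(np.random.default_rng(0).normal(20, 1, size=(2, 10)))
        with pytest.raises(Exception, match="3 genes|< 3 genes|degenerate"):
            ungrouped_stability(v)

    def test_parameter_recovery_at_large_n(self):
        """Residual SDs planted in the generative model are recovered."""
        rng = np.random.default_rng(42)
        sigmas = [0.1, 0.2, 0.4, 0.8, 0.3, 0.5]
        v = simulate_model(rng, sigmas, n=500)
        est = ungrouped_stability(v).stabilities
        # MC tolerance: SD of a variance estimate at n=500 is ~sigma*5%
        assert np.allclose(est, sigmas, rtol=0.2, atol=0.03)
        assert list(est.sort_values().index) == list(
            pd.Series(sigmas, index=v.index).sort_values().index
        )

    def test_loading_invariance(self):
        rng = np.random.default_rng(13)
        v = toy_frame(rng.normal(22, 0.5, size=(4, 30)))
        shifted = v + rng.normal(0, 2, size=(1, 30))  # per-sample constant
        a = ungrouped_stability(v).stabilities
        b = ungrouped_stability(shifted).stabilities
        assert np.allclose(a, b, atol=1e-9)


class TestGrouped:
    def labels(self, n_per_group, groups=2):
        return np.repeat(np.arange(groups), n_per_group)

    def test_identical_group_means_zero_intergroup(self):
        rng = np.random.default_rng(55)
        block = rng.normal(22, 0.3, size=(4, 10))
        v = toy_frame(np.hstack([block, block]))  # group 2 duplicates group 1
        v.columns = [f"s{j}" for j in range(20)]
        res = grouped_stability(v, grouping=self.labels(10))
        assert np.allclose(res.intergroup_raw, 0.0, atol=1e-12)
        # stability reduces to the intragroup uncertainty term only
        expected = np.sqrt(res.intragroup_var / 10).mean(axis=1)
        assert np.allclose(res.stabilities, expected, atol=1e-12)

    def test_planted_shift_recovered_and_ranked_last(self):
        """A 1-Cq between-group shift is estimable up to the per-sample
        centering: with k genes the identifiable deviation is shift*(k-1)/k."""
        rng = np.random.default_rng(101)
        k, shift = 6, 1.0
        labels = self.labels(50)
        v = simulate_model(rng, [0.2] * k, n=100, group_shift=(2, shift),
                           labels=labels)
        res = grouped_stability(v, grouping=labels)
        target = shift * (k - 1) / k
        d = res.intergroup.loc["G2"].abs()
        assert d.max() == pytest.approx(target / 2, abs=0.1)  # +/- split around mean
        assert res.ranking[-1] == "G2"

    def test_best_pair_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(77)
        labels = self.labels(8, groups=3)
        v = simulate_model(rng, [0.2, 0.3, 0.5, 0.25, 0.4], n=24,
                           group_shift=(2, 0.8), labels=(labels == 1).astype(int))
        res = grouped_stability(v, grouping=labels)
        n_g = pd.Series(labels).value_counts().sort_index()
        samp_var = res.intragroup_var.div(n_g.to_numpy(), axis=1)

        def pair_value(pair):
            d = res.intergroup.loc[list(pair)].mean(axis=0)
            var = samp_var.loc[list(pair)].sum(axis=0) / 4
            return float((d.abs() + np.sqrt(var)).mean())

        best = min(combinations(v.index, 2), key=pair_value)
        assert set(res.best_pair) == set(best)
        assert res.best_pair_stability == pytest.approx(pair_value(best))

    def test_monotone_in_residual_sd(self):
        """Expected stability rises strictly with a gene's residual SD."""
        means = []
        for sd in (0.2, 0.5, 1.0):
            vals = []
            for rep in range(10):
                rng = np.random.default_rng(1000 + rep)
                v = simulate_model(rng, [0.3, 0.3, sd, 0.3, 0.3], n=60)
                vals.append(ungrouped_stability(v).stabilities["G2"])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_singleton_group_rejected_by_name(self):
        rng = np.random.default_rng(3)
        v = simulate_model(rng, [0.2] * 4, n=5)
        with pytest.raises(Exception, match="group 1"):
            grouped_stability(v, grouping=np.array([0, 0, 0, 0, 1]))

    def test_grouping_by_annotation_column(self, entire_matrix):
        res = grouped_stability(entire_matrix, grouping="genotype")
        assert res.grouping == "genotype"
        assert set(res.intergroup.columns) == {"healthy", "dystrophic"}
        assert (res.stabilities >= 0).all()
        assert res.best_pair is not None
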