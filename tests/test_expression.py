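"""Candidate screening, z-scores, K-means clustering and the DE filter."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from refstab import (
    differential_expression_filter,
    kmeans_cluster,
    pairwise_comparisons,
    screen_candidate_references,
    simulate_expression_matrix,
    zscore_standardize,
)
from refstab.ct_io import ExpressionMatrix


def _expr(values, columns=None, groups=None):
    frame = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"t{i}" for i in range(len(values))],
        columns=columns or [f"X{j + 1}" for j in range(len(values[0]))],
    )
    return ExpressionMatrix(frame, groups)


class TestScreening:
    def _q(self, e, value=0.9):
        comps = [f"{a}_vs_{b}" for a, b in pairwise_comparisons(e.samples)]
        return pd.DataFrame(value, index=e.genes, columns=comps)

    def test_flat_expressed_gene_retained(self):
        e = _expr([[50, 52, 49, 51]])
        assert screen_candidate_references(e, self._q(e)) == ["t0"]

    def test_low_fpkm_excluded_at_threshold_edge(self):
        e = _expr([[3, 50, 50, 50], [5, 5, 5, 5]])
        assert screen_candidate_references(e, self._q(e)) == ["t1"]

    def test_fold_change_and_q_rules(self):
        e = _expr([[10, 25, 10, 10], [10, 12, 11, 10], [10, 12, 11, 10]])
        q = self._q(e)
        q.loc["t2", "X1_vs_X2"] = 0.01  # significant somewhere -> excluded
        assert screen_candidate_references(e, q) == ["t1"]

    def test_matches_brute_force_triple_filter(self, rng):
        vals = rng.uniform(0, 100, size=(30, 4))
        e = _expr(vals)
        q = pd.DataFrame(rng.uniform(0, 1, size=(30, 6)), index=e.genes,
                         columns=[f"{a}_vs_{b}" for a, b in pairwise_comparisons(e.samples)])
        kept = screen_candidate_references(e, q)
        expected = []
        for i, g in enumerate(e.genes):
            row = vals[i]
            ok = row.min() >= 5
            ok = ok and row.max() / row.min() < 2
            ok = ok and (q.loc[g] >= 0.05).all()
            if ok:
                expected.append(g)
        assert kept == expected

    def test_missing_q_values_rejected(self):
        e = _expr([[10, 10]], columns=["X1", "X2"])
        with pytest.raises(ValueError, match="without q values"):
            screen_candidate_references(e, pd.DataFrame(index=["other"]))


class TestZscore:
    def test_row_formula_sample_sd(self):
        z, flags = zscore_standardize(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.values[0], [-1.0, 0.0, 1.0])
        assert not flags.iloc[0]

    def test_population_sd_convention(self):
        z, _ = zscore_standardize(pd.DataFrame([[1.0, 2.0, 3.0]]), ddof=0)
        np.testing.assert_allclose(z.values[0], np.array([-1, 0, 1]) * np.sqrt(1.5),
                                   rtol=1e-12)

    def test_constant_row_flagged_zero(self):
        z, flags = zscore_standardize(pd.DataFrame([[4.0, 4.0, 4.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(z.values[0], 0.0)
        assert flags.iloc[0] and not flags.iloc[1]

    def test_rows_have_zero_mean_unit_sd(self, rng):
        z, _ = zscore_standardize(pd.DataFrame(rng.uniform(0, 50, size=(10, 6))))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, rtol=1e-12)


class TestKmeans:
    def test_planted_two_group_partition_recovered(self, rng):
        up = np.tile([1.0, 1.0, -1.0, -1.0], (10, 1)) + rng.normal(0, 0.05, (10, 4))
        down = -np.tile([1.0, 1.0, -1.0, -1.0], (10, 1)) + rng.normal(0, 0.05, (10, 4))
        frame = pd.DataFrame(np.vstack([up, down]),
                             index=[f"t{i}" for i in range(20)])
        z, _ = zscore_standardize(frame)
        res = kmeans_cluster(z, k=2, seed=0)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, res.labels.values) == 1.0

    def test_k_equals_n_genes_gives_zero_inertia(self, rng):
        frame = pd.DataFrame(rng.uniform(0, 1, size=(5, 4)))
        res = kmeans_cluster(frame, k=5, seed=1)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        assert sorted(res.labels) == [1, 2, 3, 4, 5]

    def test_seed_determinism_and_k_validation(self, rng):
        frame = pd.DataFrame(rng.uniform(0, 1, size=(12, 4)))
        a = kmeans_cluster(frame, k=3, seed=7)
        b = kmeans_cluster(frame, k=3, seed=7)
        assert a.labels.equals(b.labels) and a.inertia == b.inertia
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(frame, k=13, seed=0)

    def test_invariant_to_per_gene_affine_rescaling(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 100, size=(15, 5)))
        scale = rng.uniform(0.5, 20, size=15)[:, None]
        offset = rng.uniform(-5, 5, size=15)[:, None]
        z1, _ = zscore_standardize(raw)
        z2, _ = zscore_standardize(raw * scale + offset)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)
        a = kmeans_cluster(z1, k=3, seed=5)
        b = kmeans_cluster(z2, k=3, seed=5)
        assert adjusted_rand_score(a.labels.values, b.labels.values) == 1.0


class TestDEFilter:
    def test_four_groups_emit_six_comparisons(self):
        e, _ = simulate_expression_matrix(5, samples_per_group=3, seed=0)
        res = differential_expression_filter(e)
        comps = res.table["comparison"].unique().tolist()
        assert comps == ["X1_vs_X2", "X1_vs_X3", "X1_vs_X4",
                         "X2_vs_X3", "X2_vs_X4", "X3_vs_X4"]
        assert len(res.table) == 5 * 6

    def test_identical_group_means_pass_nothing(self):
        e, _ = simulate_expression_matrix(10, samples_per_group=3, dispersion=0.0,
                                          seed=1)
        res = differential_expression_filter(e)
        assert not res.table["passes"].any()

    def test_planted_extreme_fold_passes(self):
        """A 6525-fold effect with tight replicates is called in its comparison."""
        fc = np.array([[1.0, 6525.0, 1.0, 1.0]])
        e, _ = simulate_expression_matrix(1, samples_per_group=3, fold_changes=fc,
                                          dispersion=0.05, seed=2)
        res = differential_expression_filter(e)
        row = res.table[(res.table["comparison"] == "X1_vs_X2")].iloc[0]
        assert row["passes"]
        assert row["fold_change"] == pytest.approx(6525.0, rel=0.2)
        assert res.anova_p.iloc[0] < 0.05

    def test_matches_brute_force_rule_evaluation(self, rng):
        fc = np.exp(rng.normal(0, 1.0, size=(20, 4)))
        fc[:, 0] = 1.0
        e, _ = simulate_expression_matrix(20, samples_per_group=3, fold_changes=fc,
                                          dispersion=0.3, seed=3)
        res = differential_expression_filter(e)
        for _, row in res.table.iterrows():
            assert row["passes"] == (
                (row["fold_change"] > 2.0) and (row["p_value"] < 0.05)
            )

    def test_pass_set_monotone_in_fold_threshold(self, rng):
        fc = np.exp(rng.normal(0, 1.0, size=(15, 4)))
        fc[:, 0] = 1.0
        e, _ = simulate_expression_matrix(15, samples_per_group=3, fold_changes=fc,
                                          dispersion=0.3, seed=4)
        loose = differential_expression_filter(e, fold_threshold=2.0)
        tight = differential_expression_filter(e, fold_threshold=4.0)
        loose_set = set(map(tuple, loose.table[loose.table["passes"]][["gene", "comparison"]].values))
        tight_set = set(map(tuple, tight.table[tight.table["passes"]][["gene", "comparison"]].values))
        assert tight_set <= loose_set

    def test_unreplicated_group_strictness(self):
        frame = pd.DataFrame([[1.0, 2.0, 2.1]], index=["t0"],
                             columns=["a1", "b1", "b2"])
        e = ExpressionMatrix(frame, {"a1": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError, match="without replication"):
            differential_expression_filter(e)
        res = differential_expression_filter(e, strict=False)
        assert res.table["p_value"].isna().all()
        assert not res.table["passes"].any()
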