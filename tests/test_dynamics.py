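import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from helpers import bh_adjust, classify_brute, fcm_objective
from methylflux import (
    classify_deg,
    default_patterns,
    differential_expression,
    filter_low_expression,
    fuzzy_cmeans,
    median_of_ratios_normalize,
    overlap_sets,
    pca_trajectory,
    simulate_timecourse_counts,
    standardize_profiles,
)

TP = [72.0, 120.0, 168.0]


class TestFilter:
    def test_keeps_exactly_row_sums_above_one(self):
        counts = pd.DataFrame(
            {"a": [0, 1, 1], "b": [0, 0, 1]}, index=["zero", "one", "two"]
        )
        kept = filter_low_expression(counts)
        assert list(kept.index) == ["two"]

    def test_all_zero_matrix_empty_with_warning(self, caplog):
        counts = pd.DataFrame({"a": [0, 0], "b": [0, 0]}, index=["g0", "g1"])
        with caplog.at_level("WARNING"):
            kept = filter_low_expression(counts)
        assert kept.empty and "filter" in caplog.text

    def test_equivalence_with_integer_rule(self, rng):
        counts = pd.DataFrame(rng.integers(0, 3, size=(50, 4)))
        counts.index = counts.index.astype(str)
        kept = filter_low_expression(counts)
        assert len(kept) == int((counts.sum(axis=1) >= 2).sum())
        assert list(kept.index) == list(counts.index[counts.sum(axis=1) >= 2])


class TestMedianOfRatios:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]}, index=list("xyz"))
        _, f = median_of_ratios_normalize(counts)
        np.testing.assert_allclose(f, [1.0, 1.0])

    def test_scaled_sample_closed_form(self):
        counts = pd.DataFrame({"a": [10, 20, 40], "b": [30, 60, 120]}, index=list("xyz"))
        norm, f = median_of_ratios_normalize(counts)
        assert f["b"] / f["a"] == pytest.approx(3.0)
        np.testing.assert_allclose(norm["a"], norm["b"])

    def test_gene_with_a_zero_is_excluded_from_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 40], "b": [30, 60, 120]}, index=list("xyz"))
        _, f0 = median_of_ratios_normalize(counts)
        plus = pd.concat([counts, pd.DataFrame({"a": [500], "b": [0]}, index=["w"])])
        _, f1 = median_of_ratios_normalize(plus)
        np.testing.assert_allclose(f0, f1)

    def test_no_all_nonzero_gene_rejected(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="nonzero"):
            median_of_ratios_normalize(counts)


class TestDifferentialExpression:
    def test_identical_groups_zero_lfc(self, rng):
        X = pd.DataFrame(rng.poisson(50, size=(20, 4)).astype(float),
                         columns=list("abcd"))
        X.index = X.index.astype(str)
        X[["c", "d"]] = X[["a", "b"]].to_numpy()
        table = differential_expression(X, ["a", "b"], ["c", "d"])
        np.testing.assert_allclose(table["log2fc"], 0.0)

    def test_hand_arithmetic_lfc(self):
        X = pd.DataFrame({"a1": [100.0], "a2": [100.0], "b1": [900.0], "b2": [900.0]},
                         index=["g0"])
        table = differential_expression(X, ["a1", "a2"], ["b1", "b2"])
        assert table.loc["g0", "log2fc"] == pytest.approx(np.log2(901 / 101))

    def test_bh_closed_form_small_table(self):
        """BH over p = (0.01, 0.02, 0.03) gives padj = 0.03 everywhere."""
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        from scipy.stats import false_discovery_control

        np.testing.assert_allclose(
            false_discovery_control([0.01, 0.02, 0.03], method="bh"),
            [0.03, 0.03, 0.03],
        )

    def test_bh_matches_closed_form_on_random_pvalues(self, rng):
        p = rng.random(40)
        from scipy.stats import false_discovery_control

        np.testing.assert_allclose(
            false_discovery_control(p, method="bh"), bh_adjust(p), atol=1e-12
        )

    def test_overlapping_groups_rejected(self):
        X = pd.DataFrame({"a": [1.0], "b": [1.0]}, index=["g0"])
        with pytest.raises(ValueError, match="share"):
            differential_expression(X, ["a"], ["a", "b"])

    def test_single_replicate_gives_missing_pvalues(self):
        X = pd.DataFrame({"a": [10.0], "b": [90.0]}, index=["g0"])
        table = differential_expression(X, ["a"], ["b"])
        assert np.isnan(table.loc["g0", "p"])


class TestClassifyDeg:
    def table(self, log2fc, p=None):
        return pd.DataFrame(
            {"log2fc": log2fc, "p": p if p is not None else [np.nan] * len(log2fc)},
            index=[f"g{i}" for i in range(len(log2fc))],
        )

    def test_log2fc_boundary_is_inclusive(self):
        t = classify_deg(self.table([1.0, 0.999, -1.0, 0.0]), "log2fc")
        assert list(t["klass"]) == ["up", "ns", "down", "ns"]

    def test_fc_boundary_is_strict(self):
        """fold exactly 1.5 with p = 0.01 stays ns under the fold>1.5 rule."""
        lfc = [np.log2(1.5), np.log2(1.51), np.log2(1 / 1.51)]
        t = classify_deg(self.table(lfc, [0.01, 0.01, 0.01]), "fc_p")
        assert list(t["klass"]) == ["ns", "up", "down"]

    def test_fc_mode_requires_significance(self):
        t = classify_deg(self.table([2.0], [0.2]), "fc_p")
        assert list(t["klass"]) == ["ns"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            classify_deg(self.table([0.0]), "banana")

    def test_fc_mode_without_pvalues_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            classify_deg(self.table([0.0]), "fc_p")

    @pytest.mark.parametrize("mode", ["log2fc", "fc_p"])
    def test_matches_brute_force_scan(self, mode, rng):
        lfc = rng.normal(0, 1.5, size=200)
        lfc[:10] = [1.0, -1.0, 0.0, np.log2(1.5), -np.log2(1.5), 2.0, -2.0,
                    0.584, 0.999, 1.001]
        p = rng.random(200)
        p[:4] = [0.05, 0.049, 0.01, 0.9]
        t = classify_deg(self.table(list(lfc), list(p)), mode)
        assert list(t["klass"]) == classify_brute(lfc, p, mode)


class TestOverlapSets:
    def test_identical_sets_all_in_full_intersection(self):
        s = {"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x", "y"}}
        table, common = overlap_sets(s)
        full = table.loc[table["region"] == "A&B&C", "count"].item()
        assert full == 2 and common == {"x", "y"}
        assert table.loc[table["n_sets"] < 3, "count"].sum() == 0

    def test_three_set_enumeration(self):
        s = {"A": {"a", "b", "c"}, "B": {"b", "c", "d"}, "C": {"c"}}
        table, common = overlap_sets(s)
        assert common == {"c"}
        by_region = table.set_index("region")["count"]
        assert by_region["A&B&C"] == 1   # c
        assert by_region["A&B"] == 1     # b
        assert by_region["A"] == 1       # a
        assert by_region["B"] == 1       # d
        assert by_region["C"] == 0

    def test_disjoint_sets_have_empty_multiset_regions(self):
        s = {"A": {"a"}, "B": {"b"}}
        table, common = overlap_sets(s)
        assert common == set()
        assert table.loc[table["n_sets"] > 1, "count"].sum() == 0

    def test_set_count_limits(self):
        with pytest.raises(ValueError):
            overlap_sets({"A": set()})
        with pytest.raises(ValueError):
            overlap_sets({k: set() for k in "ABCDE"})


class TestPcaTrajectory:
    def planted(self, rng, sep=8.0):
        g1 = rng.normal(50, 2, size=(100, 3))
        g2 = g1 + sep
        X = np.vstack([np.hstack([g1, g2])])
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        return pd.DataFrame(X, columns=cols, index=[f"g{i}" for i in range(100)])

    def test_duplicated_sample_identical_coordinates(self, rng):
        X = self.planted(rng)
        X["b3"] = X["b2"]
        coords, _ = pca_trajectory(X)
        np.testing.assert_allclose(coords.loc["b2"], coords.loc["b3"], atol=1e-8)

    def test_planted_groups_separate_on_pc1(self, rng):
        coords, frac = pca_trajectory(self.planted(rng))
        a = coords.loc[["a1", "a2", "a3"], "PC1"]
        b = coords.loc[["b1", "b2", "b3"], "PC1"]
        # the groups separate with a clear margin on PC1
        assert a.max() < b.min() or b.max() < a.min()
        assert abs(a.mean() - b.mean()) > 4 * max(a.std(), b.std())

    def test_variance_fractions_non_increasing_and_bounded(self, rng):
        _, frac = pca_trajectory(self.planted(rng))
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.sum() <= 1.0 + 1e-9

    def test_invariant_to_gene_order(self, rng):
        X = self.planted(rng)
        shuffled = X.sample(frac=1.0, random_state=0)
        c1, f1 = pca_trajectory(X)
        c2, f2 = pca_trajectory(shuffled)
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="samples"):
            pca_trajectory(X)


class TestFuzzyCMeans:
    def planted_profiles(self, genes_per_pattern=50, seed=1):
        pats = default_patterns(TP, 2)  # up_linear vs down_linear
        cm, truth = simulate_timecourse_counts(
            pats, genes_per_pattern, TP, conditions=("NC",), replicates=2,
            depth=2e6, dispersion=0.05, seed=seed,
        )
        tp = cm.metadata["timepoint_h"]
        prof = np.log2(cm.counts + 1).T.groupby(tp.to_numpy()).mean().T
        return standardize_profiles(prof), truth

    def test_single_cluster_degenerate_case(self):
        Z, _ = self.planted_profiles(10)
        model = fuzzy_cmeans(Z, c=1, seed=0)
        np.testing.assert_allclose(model.memberships.to_numpy(), 1.0)
        np.testing.assert_allclose(model.centroids[0], Z.mean(axis=0), atol=1e-9)

    def test_memberships_sum_to_one(self):
        Z, _ = self.planted_profiles()
        model = fuzzy_cmeans(Z, c=3, seed=2)
        np.testing.assert_allclose(
            model.memberships.sum(axis=1), 1.0, atol=1e-9
        )

    def test_objective_non_increasing(self):
        Z, _ = self.planted_profiles()
        model = fuzzy_cmeans(Z, c=4, seed=3)
        hist = np.array(model.objective_history)
        assert (np.diff(hist) <= 1e-9).all()

    def test_recovers_planted_two_pattern_labels(self):
        """Two well-separated planted patterns are recovered exactly
        (ARI = 1.0 against the generator's truth labels)."""
        Z, truth = self.planted_profiles(genes_per_pattern=50, seed=1)
        model = fuzzy_cmeans(Z, c=2, seed=1)
        labels = model.hard_labels.loc[Z.index]
        true = truth.loc[Z.index, "pattern_id"]
        assert adjusted_rand_score(true, labels) == 1.0

    def test_same_seed_same_model(self):
        Z, _ = self.planted_profiles()
        m1 = fuzzy_cmeans(Z, c=3, seed=5)
        m2 = fuzzy_cmeans(Z, c=3, seed=5)
        np.testing.assert_array_equal(
            m1.memberships.to_numpy(), m2.memberships.to_numpy()
        )
        assert m1.objective == m2.objective

    def test_matches_multi_restart_oracle_on_small_input(self):
        """On <=30 genes the converged objective matches the best of many
        random restarts to 1e-6."""
        Z, _ = self.planted_profiles(genes_per_pattern=15, seed=4)
        assert len(Z) <= 30
        model = fuzzy_cmeans(Z, c=2, seed=0, tol=1e-12, max_iter=2000)
        best = min(
            fuzzy_cmeans(Z, c=2, seed=s, tol=1e-12, max_iter=2000).objective
            for s in range(20)
        )
        assert model.objective == pytest.approx(best, abs=1e-6)

    def test_gene_on_centroid_gets_full_membership(self):
        Z = pd.DataFrame(
            [[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]],
            index=["g0", "g1", "g2"], columns=TP,
        )
        model = fuzzy_cmeans(Z, c=2, seed=0)
        np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert model.memberships.to_numpy().max() > 0.99

    def test_errors(self):
        Z, _ = self.planted_profiles(5)
        with pytest.raises(ValueError, match="exceeds"):
            fuzzy_cmeans(Z, c=len(Z) + 1, seed=0)
        flat = pd.DataFrame([[1.0, 1.0, 1.0]], index=["g0"], columns=TP)
        with pytest.raises(ValueError, match="zero-variance"):
            fuzzy_cmeans(flat, c=1, seed=0)
        with pytest.raises(ValueError, match="fuzzifier"):
            fuzzy_cmeans(Z, c=2, fuzzifier=1.0, seed=0)

    def test_standardize_drops_zero_variance(self, caplog):
        prof = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["ok", "flat"], columns=TP
        )
        with caplog.at_level("WARNING"):
            Z = standardize_profiles(prof)
        assert list(Z.index) == ["ok"]
        np.testing.assert_allclose(Z.mean(axis=1), 0.0, atol=1e-12)
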