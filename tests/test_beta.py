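"""Beta-diversity statistics against brute-force and exhaustive oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from luniche.beta import (
    bray_curtis,
    dispersion_test,
    permanova,
    simper,
    top_discriminant_genera,
)

from conftest import make_metadata, make_table


class TestBrayCurtis:
    def test_identical_samples_have_zero_distance(self):
        dm = bray_curtis(make_table([[3, 3], [1, 1]]))
        assert dm.iloc[0, 1] == 0.0

    def test_disjoint_supports_have_distance_one(self):
        dm = bray_curtis(make_table([[3, 0], [0, 5]]))
        assert dm.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        dm = bray_curtis(make_table([[1, 2], [2, 1]]))
        assert dm.iloc[0, 1] == pytest.approx(1.0 / 3.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(make_table([[1, 0], [2, 0]]))

    def test_invariant_to_joint_rescaling_of_both_samples(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 20, size=(10, 2))
        x[0] += 1
        a = bray_curtis(make_table(x)).iloc[0, 1]
        b = bray_curtis(make_table(x * 7)).iloc[0, 1]
        assert a == pytest.approx(b, abs=1e-12)

    def test_matrix_is_symmetric_with_zero_diagonal_in_unit_interval(self, sim_dataset):
        table, _ = sim_dataset
        dm = bray_curtis(table).to_numpy()
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0)
        assert dm.min() >= 0 and dm.max() <= 1


def permanova_oracle_f(dist, labels):
    """Single-factor pseudo-F from explicit centering/projection matrices."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    x = np.column_stack([np.ones(n)] + [
        (np.asarray(labels) == lv).astype(float)
        for lv in sorted(set(labels))[1:]
    ])
    h = x @ np.linalg.inv(x.T @ x) @ x.T
    h0 = np.ones((n, n)) / n
    ss_term = np.trace(h @ g) - np.trace(h0 @ g)
    ss_res = np.trace(g) - np.trace(h @ g)
    df_term = len(set(labels)) - 1
    df_res = n - len(set(labels))
    return (ss_term / df_term) / (ss_res / df_res)


class TestPermanova:
    def _dataset(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(1, 40, size=(6, 8))
        counts[0, 4:] += 60  # group signal
        labels = ["a"] * 4 + ["b"] * 4
        meta = make_metadata([f"s{j}" for j in range(8)], plant_types=labels)
        table = make_table(counts, metadata=meta)
        return bray_curtis(table), meta, labels

    def test_pseudo_f_matches_bruteforce_projection_oracle(self):
        dist, meta, labels = self._dataset()
        result = permanova(dist, meta, ["plant_type"], n_perm=10, seed=0)
        f_oracle = permanova_oracle_f(dist.to_numpy(), labels)
        assert result.table.loc["plant_type", "F"] == pytest.approx(f_oracle, abs=1e-10)

    def test_p_value_matches_exhaustive_relabeling(self):
        dist, meta, labels = self._dataset()
        d = dist.to_numpy()
        f_obs = permanova_oracle_f(d, labels)
        # distinct relabelings = choices of which 4 samples form group "a"
        f_all = []
        for combo in itertools.combinations(range(8), 4):
            lab = np.array(["b"] * 8)
            lab[list(combo)] = "a"
            f_all.append(permanova_oracle_f(d, lab))
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_all])
        result = permanova(dist, meta, ["plant_type"], n_perm=4000, seed=1)
        p_mc = result.table.loc["plant_type", "p"]
        se = math.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc - p_exact) < 3 * se + 2 / 4001

    def test_agrees_with_scikit_bio_single_factor(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        dist, meta, labels = self._dataset()
        dm = skbio_dist.DistanceMatrix(dist.to_numpy(), ids=list(dist.index))
        ref = skbio_dist.permanova(dm, grouping=labels, permutations=99)
        result = permanova(dist, meta, ["plant_type"], n_perm=10, seed=0)
        assert result.table.loc["plant_type", "F"] == pytest.approx(
            ref["test statistic"], abs=1e-10
        )

    def test_constant_factor_reports_missing_f(self):
        dist, meta, _ = self._dataset()
        meta = meta.copy()
        meta["species"] = "Dactylis_glomerata"
        result = permanova(dist, meta, ["species"], n_perm=10, seed=0)
        row = result.table.loc["species"]
        assert row["df"] == 0 and np.isnan(row["F"]) and np.isnan(row["p"])

    def test_duplicated_groups_capture_all_variance(self):
        base = np.array([[5, 1, 0], [0, 2, 9]], dtype=float).T
        counts = np.column_stack([base[:, 0]] * 3 + [base[:, 1]] * 3)
        labels = ["a"] * 3 + ["b"] * 3
        meta = make_metadata([f"s{j}" for j in range(6)], plant_types=labels)
        dist = bray_curtis(make_table(counts, metadata=meta))
        result = permanova(dist, meta, ["plant_type"], n_perm=10, seed=0)
        assert result.table.loc["plant_type", "R2"] == pytest.approx(1.0, abs=1e-10)

    def test_r2_sums_to_one_with_sequential_terms(self, sim_dataset, sim_lui):
        table, _ = sim_dataset
        sub = table.subset_samples(table.samples[:16])
        dist = bray_curtis(sub)
        meta = sub.metadata.copy()
        meta["LUI"] = sim_lui.loc[meta["plot_id"]].to_numpy()
        result = permanova(dist, meta, ["LUI", "species", "plant_type"], n_perm=30, seed=2)
        assert result.table["R2"].sum() == pytest.approx(1.0, abs=1e-10)
        assert result.table.loc["LUI", "df"] == 1

    def test_confounded_term_rejected(self):
        dist, meta, _ = self._dataset()
        meta = meta.copy()
        meta["copy"] = meta["plant_type"]
        with pytest.raises(ValueError, match="confounded"):
            permanova(dist, meta, ["plant_type", "copy"], n_perm=10, seed=0)

    def test_type_i_error_calibrated_under_null(self):
        """Empirical rejection rate at alpha=0.05 on label-shuffled null data."""
        rng = np.random.default_rng(77)
        n, reps, n_perm = 10, 200, 199
        rejections = 0
        meta_labels = ["a"] * 5 + ["b"] * 5
        for r in range(reps):
            counts = rng.integers(1, 50, size=(8, n))
            meta = make_metadata([f"s{j}" for j in range(n)], plant_types=meta_labels)
            dist = bray_curtis(make_table(counts, metadata=meta))
            res = permanova(dist, meta, ["plant_type"], n_perm=n_perm, seed=int(rng.integers(2**31)))
            rejections += res.table.loc["plant_type", "p"] <= 0.05
        rate = rejections / reps
        assert 0.02 <= rate <= 0.09


def pcoa_distances_oracle(dist, codes):
    """Brute-force betadisper distances via explicit eigen-embedding."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    out = np.zeros(n)
    for k in set(codes):
        members = np.flatnonzero(np.asarray(codes) == k)
        sq = np.zeros(len(members))
        for ax in range(n):
            if abs(vals[ax]) < 1e-10:
                continue
            coord = vecs[:, ax] * math.sqrt(abs(vals[ax]))
            c = coord[members].mean()
            contrib = (coord[members] - c) ** 2
            sq += contrib if vals[ax] > 0 else -contrib
        out[members] = np.sqrt(np.maximum(sq, 0))
    return out


class TestDispersion:
    def test_mirror_image_groups_have_equal_dispersion(self):
        a = np.array([[10, 0, 5], [0, 10, 5], [5, 5, 0], [5, 5, 10]]).T
        counts = np.column_stack([a, a])  # duplicate point set as second group
        labels = ["g1"] * 4 + ["g2"] * 4
        meta = make_metadata([f"s{j}" for j in range(8)], plant_types=labels)
        dist = bray_curtis(make_table(counts, metadata=meta))
        res = dispersion_test(dist, meta["plant_type"], n_perm=199, seed=0)
        assert res["F"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] > 0.5

    def test_tight_versus_spread_group_is_detected(self):
        rng = np.random.default_rng(4)
        tight = np.tile(np.array([[5], [1], [9]]), (1, 8))
        spread = rng.integers(0, 40, size=(3, 8)) + 1
        counts = np.column_stack([tight, spread])
        labels = ["tight"] * 8 + ["spread"] * 8
        meta = make_metadata([f"s{j}" for j in range(16)], plant_types=labels)
        dist = bray_curtis(make_table(counts, metadata=meta))
        res = dispersion_test(dist, meta["plant_type"], n_perm=999, seed=0)
        assert res["group_means"]["tight"] < res["group_means"]["spread"]
        assert res["p"] < 0.05

    def test_distances_match_bruteforce_pcoa_oracle(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 25, size=(7, 10)) + 1
        labels = ["a"] * 5 + ["b"] * 5
        meta = make_metadata([f"s{j}" for j in range(10)], plant_types=labels)
        dist = bray_curtis(make_table(counts, metadata=meta))
        res = dispersion_test(dist, meta["plant_type"], n_perm=9, seed=0)
        codes = [0] * 5 + [1] * 5
        oracle = pcoa_distances_oracle(dist.to_numpy(), codes)
        assert np.allclose(res["distances"].to_numpy(), oracle, atol=1e-8)

    def test_singleton_group_rejected(self):
        counts = np.array([[1, 2, 3], [4, 5, 6]])
        labels = ["a", "a", "b"]
        meta = make_metadata(["s0", "s1", "s2"], plant_types=labels)
        dist = bray_curtis(make_table(counts, metadata=meta))
        with pytest.raises(ValueError, match="fewer than 2"):
            dispersion_test(dist, meta["plant_type"])


def simper_oracle(counts, idx_a, idx_b):
    contrib = np.zeros(counts.shape[0])
    n_pairs = 0
    for a in idx_a:
        for b in idx_b:
            denom = counts[:, a].sum() + counts[:, b].sum()
            contrib += np.abs(counts[:, a] - counts[:, b]) / denom
            n_pairs += 1
    return contrib / n_pairs


class TestSimper:
    def _grouping(self, samples, labels):
        return pd.Series(labels, index=samples)

    def test_contributions_sum_to_mean_between_group_dissimilarity(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(12, 8)) + 1
        table = make_table(counts)
        grouping = self._grouping(table.samples, ["x"] * 4 + ["y"] * 4)
        out = simper(table, grouping)
        dm = bray_curtis(table).to_numpy()
        mean_bc = dm[np.ix_(range(4), range(4, 8))].mean()
        assert out["mean_contribution"].sum() == pytest.approx(mean_bc, abs=1e-10)
        assert out["cumulative_percent"].iloc[-1] == pytest.approx(100.0, abs=1e-9)
        assert out["cumulative_percent"].is_monotonic_increasing

    def test_constant_taxon_contributes_nothing(self):
        counts = np.array([[5, 5, 5, 5], [1, 2, 8, 9]])
        table = make_table(counts)
        out = simper(table, self._grouping(table.samples, ["x", "x", "y", "y"]))
        assert out.set_index("taxon").loc["t0", "mean_contribution"] == 0.0

    def test_matches_bruteforce_pair_enumeration(self):
        counts = np.array([[3, 0, 7, 2], [1, 9, 4, 4], [6, 2, 0, 5]])
        table = make_table(counts)
        out = simper(table, self._grouping(table.samples, ["x", "x", "y", "y"]))
        oracle = simper_oracle(counts.astype(float), [0, 1], [2, 3])
        got = out.set_index("taxon")["mean_contribution"]
        for i in range(3):
            assert got[f"t{i}"] == pytest.approx(oracle[i], abs=1e-12)

    def test_three_level_grouping_rejected(self):
        table = make_table(np.ones((2, 3), dtype=int))
        with pytest.raises(ValueError, match="2 group levels"):
            simper(table, self._grouping(table.samples, ["x", "y", "z"]))


class TestTopDiscriminantGenera:
    def _simper_table(self):
        return pd.DataFrame(
            {
                "taxon": ["Mycena", "unclassified_genus", "Gibberella", "Conocybe"],
                "mean_contribution": [0.4, 0.3, 0.2, 0.1],
                "cumulative_percent": [40.0, 70.0, 90.0, 100.0],
                "rank": [1, 2, 3, 4],
            }
        )

    def test_k_equal_all_returns_everything_classified(self):
        genera, cum = top_discriminant_genera(self._simper_table(), k=3)
        assert genera == ["Mycena", "Gibberella", "Conocybe"]
        assert cum == pytest.approx(70.0)

    def test_k_one_returns_largest_contributor(self):
        genera, _ = top_discriminant_genera(self._simper_table(), k=1)
        assert genera == ["Mycena"]

    def test_extreme_shift_genus_ranks_first(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(5, 15, size=(10, 6))
        counts[4, 3:] += 500  # huge between-group shift for taxon t4
        table = make_table(counts)
        grouping = pd.Series(["x"] * 3 + ["y"] * 3, index=table.samples)
        out = simper(table, grouping)
        genera, _ = top_discriminant_genera(out, k=1)
        assert genera == ["t4"]

    def test_requesting_too_many_genera_rejected(self):
        with pytest.raises(ValueError, match="only 3"):
            top_discriminant_genera(self._simper_table(), k=4)
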