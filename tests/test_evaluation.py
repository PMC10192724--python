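import itertools

import numpy as np
import pandas as pd
import pytest

import demuxbench as db


def brute_force_match(table: pd.DataFrame) -> tuple[dict, float]:
    """Exhaustive search over all assignments of clusters to identities."""
    rows, cols = list(table.index), list(table.columns)
    best, best_score = None, -1
    r = min(len(rows), len(cols))
    for col_subset in itertools.permutations(cols, r):
        for row_subset in itertools.permutations(rows, r):
            score = sum(table.loc[i, j] for i, j in zip(row_subset, col_subset))
            if score > best_score:
                best_score = score
                best = dict(zip(col_subset, row_subset))
    return best, best_score


class TestMatchClusters:
    def test_diagonal_dominant_identity_mapping(self):
        table = pd.DataFrame(
            [[90, 2, 1], [3, 85, 2], [1, 0, 95]],
            index=["a", "b", "c"], columns=[0, 1, 2])
        assert db.match_clusters(table)["mapping"] == {0: "a", 1: "b", 2: "c"}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.integers(0, 100, (4, 4)),
                             index=list("abcd"), columns=[0, 1, 2, 3])
        base = db.match_clusters(table)
        score_base = sum(table.loc[v, k] for k, v in base["mapping"].items() if v)
        perm = [2, 0, 3, 1]
        shuffled = table[perm]
        res = db.match_clusters(shuffled)
        score_perm = sum(shuffled.loc[v, k] for k, v in res["mapping"].items() if v)
        assert score_base == score_perm

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_up_to_k5(self, k, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            rng.integers(0, 50, (k, k)),
            index=[f"ind{i}" for i in range(k)], columns=list(range(k)))
        result = db.match_clusters(table)
        _, oracle_score = brute_force_match(table)
        score = sum(table.loc[v, c] for c, v in result["mapping"].items() if v is not None)
        assert score == oracle_score

    def test_surplus_clusters_flagged_unmatched(self):
        table = pd.DataFrame([[10, 0, 5]], index=["a"], columns=[0, 1, 2])
        mapping = db.match_clusters(table)["mapping"]
        assert mapping[0] == "a"
        assert mapping[1] is None and mapping[2] is None

    def test_reserved_labels_excluded(self):
        table = pd.DataFrame(
            [[50, 1, 9], [2, 40, 1], [5, 5, 30]],
            index=["a", "b", "doublet"], columns=[0, 1, "doublet"])
        mapping = db.match_clusters(table)["mapping"]
        assert mapping == {0: "a", 1: "b"}

    def test_correlation_mode_agrees_on_separated_table(self):
        table = pd.DataFrame(
            [[90, 2, 1], [3, 85, 2], [1, 0, 95]],
            index=["a", "b", "c"], columns=[0, 1, 2])
        assert (db.match_clusters(table, method="correlation")["mapping"]
                == db.match_clusters(table, method="counts")["mapping"])


class TestAccuracyReport:
    @staticmethod
    def _series(pairs):
        return pd.Series({bc: v for bc, v in pairs})

    def test_perfect_predictions(self):
        truth = self._series([(f"c{i}", "a" if i < 5 else "b") for i in range(10)])
        report, overall = db.accuracy_report(truth, truth.copy())
        assert overall == 100.0
        assert (report.set_index("identity").loc["a", "pct_a"]) == 100.0

    def test_arithmetic_example(self):
        truth = self._series([(f"c{i}", "A") for i in range(100)])
        preds = ["A"] * 95 + ["doublet"] * 3 + ["unassigned"] * 2
        pred = self._series(list(zip(truth.index, preds)))
        report, overall = db.accuracy_report(truth, pred)
        row = report.set_index("identity").loc["A"]
        assert (row.pct_A, row.pct_doublet, row.pct_unassigned) == (95.0, 3.0, 2.0)
        assert overall == 95.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(5)
        truth = self._series([(f"c{i}", rng.choice(["a", "b"])) for i in range(50)])
        pred = self._series([
            (f"c{i}", rng.choice(["a", "b", "doublet", "unassigned"]))
            for i in range(50)])
        report, _ = db.accuracy_report(truth, pred)
        pct = report[[c for c in report.columns if c.startswith("pct_")]].sum(axis=1)
        assert np.allclose(pct, 100.0, atol=1e-6)

    def test_empty_identity_reported_not_dropped(self):
        truth = self._series([("c0", "a"), ("c1", "a")])
        pred = self._series([("c0", "a"), ("c1", "a")])
        report, _ = db.accuracy_report(truth, pred, identities=["a", "absent"])
        row = report.set_index("identity").loc["absent"]
        assert row.n_cells == 0


class TestDoubletMetrics:
    @staticmethod
    def _manifest(n_het, n_homo, n_singlet):
        rows = []
        for i in range(n_het):
            rows.append((f"het{i}", "doublet", "a", "b", "heterotypic", "a"))
        for i in range(n_homo):
            rows.append((f"homo{i}", "doublet", "a", "a", "homotypic", "a"))
        for i in range(n_singlet):
            rows.append((f"s{i}", "singlet", "a", None, "not-applicable", "a"))
        return db.TruthManifest(table=pd.DataFrame(
            rows, columns=["barcode", "droplet_type", "origin1", "origin2",
                           "doublet_class", "source_sample"]))

    @staticmethod
    def _predictions(manifest, doublet_barcodes):
        return pd.DataFrame({
            "barcode": manifest.table.barcode,
            "status": ["doublet" if b in doublet_barcodes else "singlet"
                       for b in manifest.table.barcode],
        })

    def test_full_recall(self):
        m = self._manifest(5, 0, 10)
        preds = self._predictions(m, {f"het{i}" for i in range(5)})
        dm = db.doublet_metrics(m, preds)
        assert dm.heterotypic_recall == 1.0
        assert dm.confirmed == 5

    def test_partial_recall_arithmetic(self):
        m = self._manifest(20, 0, 50)
        preds = self._predictions(m, {f"het{i}" for i in range(11)})
        dm = db.doublet_metrics(m, preds)
        assert dm.heterotypic_recall == pytest.approx(0.55)
        assert dm.contested_truth_only == 9

    def test_prediction_only_contested(self):
        m = self._manifest(2, 0, 10)
        preds = self._predictions(m, {"het0", "het1", "s0"})
        dm = db.doublet_metrics(m, preds)
        assert dm.contested_prediction_only == 1
        assert dm.confirmed + dm.contested_truth_only == 2  # total true doublets

    def test_recall_undefined_without_heterotypic_truth(self):
        m = self._manifest(0, 3, 10)
        dm = db.doublet_metrics(m, self._predictions(m, set()))
        assert dm.heterotypic_recall is None


class TestBinnedSeries:
    @staticmethod
    def _cells(n, seed=0):
        rng = np.random.default_rng(seed)
        barcodes = [f"BC{i:05d}-1" for i in range(n)]
        depths = pd.Series(rng.integers(1_000, 50_000, n), index=barcodes)
        calls = pd.Series(
            rng.choice(["a", "b", "doublet", "unassigned"], n, p=[0.4, 0.3, 0.2, 0.1]),
            index=barcodes)
        return depths, calls

    def test_all_assigned_gives_100_everywhere(self):
        depths, _ = self._cells(200)
        calls = pd.Series("a", index=depths.index)
        series = db.binned_id_rate(depths, calls, n_bins=40)
        assert (series.metric_pct == 100.0).all()

    def test_even_bin_sizes(self):
        depths, calls = self._cells(4_000)
        series = db.binned_id_rate(depths, calls, n_bins=40)
        assert (series.n_cells == 100).all()

    def test_bin_sizes_differ_by_at_most_one(self):
        depths, calls = self._cells(403)
        series = db.binned_id_rate(depths, calls, n_bins=40)
        assert series.n_cells.max() - series.n_cells.min() <= 1

    def test_weighted_bin_mean_equals_overall_rate(self):
        depths, calls = self._cells(1234, seed=3)
        series = db.binned_id_rate(depths, calls, n_bins=40)
        weighted = np.average(series.metric_pct, weights=series.n_cells)
        overall = 100.0 * calls.isin(["a", "b"]).mean()
        assert weighted == pytest.approx(overall)

    def test_more_bins_than_cells_rejected(self):
        depths, calls = self._cells(10)
        with pytest.raises(ValueError, match="bins"):
            db.binned_id_rate(depths, calls, n_bins=40)

    def test_agreement_identical_and_disjoint(self):
        depths, calls = self._cells(400, seed=4)
        same = db.agreement_curve(calls, calls.copy(), depths, n_bins=20)
        assert (same.metric_pct == 100.0).all()
        other = pd.Series("zzz", index=calls.index)
        none = db.agreement_curve(calls, other, depths, n_bins=20)
        assert (none.metric_pct == 0.0).all()

    def test_uniform_half_agreement_within_binomial_noise(self):
        rng = np.random.default_rng(6)
        n = 4_000
        barcodes = [f"BC{i:05d}-1" for i in range(n)]
        depths = pd.Series(rng.integers(1_000, 50_000, n), index=barcodes)
        a = pd.Series("x", index=barcodes)
        b = pd.Series(np.where(rng.random(n) < 0.5, "x", "y"), index=barcodes)
        series = db.agreement_curve(a, b, depths, n_bins=40)
        se = 100 * np.sqrt(0.25 / 100)
        assert (np.abs(series.metric_pct - 50.0) <= 3 * se).mean() >= 0.95


class TestSnpDensity:
    def test_single_full_window(self):
        table, mean = db.snp_density({"chr1": np.arange(1, 1_001, 100)})
        assert len(table) == 1
        assert table.snps_per_kb.iloc[0] == 10.0
        assert mean == 10.0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_window_counting(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(1_000, 20_000))
        n = int(rng.integers(0, 30))
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False)) + 1
        table, mean = db.snp_density({"chrA": pos}, {"chrA": length})
        n_windows = -(-length // 1000)
        brute = np.zeros(n_windows)
        for p in pos:
            brute[(p - 1) // 1000] += 1
        assert np.array_equal(table.n_variants.to_numpy(), brute)
        assert mean == pytest.approx(brute.mean())

    def test_tiling_stops_at_last_variant_without_lengths(self):
        table, _ = db.snp_density({"chr1": np.array([500, 2_500])})
        assert len(table) == 3  # windows 1-1000, 1001-2000, 2001-3000

    def test_empty_variant_set_warns_density_zero(self):
        with pytest.warns(UserWarning, match="no variants"):
            _, mean = db.snp_density({})
        assert mean == 0.0

    def test_viability_band_flagging(self):
        low, _ = db.snp_density({"c": np.array([1])}, {"c": 100_000})
        assert low.attrs["below_viability_band"]
        ok, _ = db.snp_density({"c": np.arange(1, 100_000, 300)}, {"c": 100_000})
        assert not ok.attrs["below_viability_band"]


class TestClusterComposition:
    def test_even_cluster_contains_all_animals(self):
        idx = [f"c{i}" for i in range(90)]
        clusters = pd.Series(["k0"] * 90, index=idx)
        identities = pd.Series(["a", "b", "c"] * 30, index=idx)
        table = db.cluster_composition(clusters, identities, pool_size=3)
        assert table.n_animals.iloc[0] == 3
        assert not table.missing_animals.iloc[0]

    def test_doublet_percentage_arithmetic(self):
        idx = [f"c{i}" for i in range(100)]
        clusters = pd.Series(["k0"] * 100, index=idx)
        identities = pd.Series(["a"] * 88 + ["doublet"] * 12, index=idx)
        table = db.cluster_composition(clusters, identities)
        assert table.pct_doublet.iloc[0] == pytest.approx(12.0)

    def test_single_animal_cluster_flagged(self):
        idx = [f"c{i}" for i in range(20)]
        clusters = pd.Series(["k0"] * 10 + ["k1"] * 10, index=idx)
        identities = pd.Series(["a"] * 10 + ["a", "b"] * 5, index=idx)
        table = db.cluster_composition(clusters, identities, pool_size=2).set_index("cluster")
        assert table.loc["k0", "missing_animals"]
        assert not table.loc["k1", "missing_animals"]


class TestFilterVariantsByMaf:
    def test_inclusive_threshold(self):
        panel = db.simulate_genotypes(2, 1_000_000, 0.5, maf_bounds=(0.01, 0.5), seed=8)
        panel.maf[0] = 0.05
        panel.maf[1] = 0.049
        filtered = db.filter_variants_by_maf(panel, 0.05)
        assert panel.positions[0] in filtered.positions
        assert panel.positions[1] not in filtered.positions
        assert (filtered.maf >= 0.05).all()

    def test_zero_threshold_is_identity(self):
        panel = db.simulate_genotypes(2, 100_000, 0.5, seed=9)
        filtered = db.filter_variants_by_maf(panel, 0.0)
        assert np.array_equal(filtered.positions, panel.positions)
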