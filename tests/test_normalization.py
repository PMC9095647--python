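import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyclicproc.normalization import (ExclusivePair, apply_batch_model,
                                      apply_scaler, combat_adjust,
                                      exclusivity_score, fit_batch_model,
                                      regress_out_batch,
                                      restore_scale, restore_threshold,
                                      reverse_compartment_threshold,
                                      select_exclusive_pairs,
                                      transform_intensity)
from cyclicproc.qc_metrics import ThresholdRecord


class TestTransforms:
    def test_log2_examples(self):
        assert transform_intensity(np.array([0.0]), "log2")[0] == 0.0
        assert transform_intensity(np.array([1023.0]), "log2")[0] == \
            pytest.approx(10.0, abs=1e-3)

    def test_raw_is_identity(self, rng):
        x = rng.random(100) * 100
        np.testing.assert_array_equal(transform_intensity(x, "raw"), x)

    def test_arcsinh_monotone(self, rng):
        x = np.sort(rng.random(500) * 1e4)
        y = transform_intensity(x, "arcsinh")
        assert (np.diff(y) >= 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_intensity(np.array([-1.0]), "log2")


class TestScalers:
    def test_minmax_example(self):
        out = apply_scaler(np.array([2.0, 4.0, 6.0]), "minmax")
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_standard_moments(self, rng):
        out = apply_scaler(rng.lognormal(3, 1, 1000), "standard")
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std() == pytest.approx(1.0, rel=1e-9)

    def test_quantile_output_near_uniform(self, rng):
        out = apply_scaler(rng.lognormal(3, 1, 1000), "quantile")
        d = stats.kstest(out, "uniform").statistic
        assert d < 0.05

    def test_maxabs(self):
        out = apply_scaler(np.array([-2.0, 1.0, 4.0]), "maxabs")
        np.testing.assert_allclose(out, [-0.5, 0.25, 1.0])

    def test_degenerate_column_warns(self):
        with pytest.warns(UserWarning, match="distinct"):
            apply_scaler(np.full(10, 3.0), "standard")


class TestExclusivityScore:
    def test_coexpressed_identical_columns_score_zero(self, rng):
        x = rng.lognormal(4, 1, 500)
        assert exclusivity_score(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_for_bivariate_normal(self, rng):
        """score = sqrt((1-r)/(1+r)) for correlation r."""
        for r in (0.0, 0.5, 0.9):
            c = np.linalg.cholesky(np.array([[1, r], [r, 1]]))
            xy = rng.standard_normal((20000, 2)) @ c.T
            got = exclusivity_score(xy[:, 0], xy[:, 1])
            assert got == pytest.approx(np.sqrt((1 - r) / (1 + r)), abs=0.02)

    def test_exclusive_l_pair_clears_half(self, rng):
        """A 50/50 mutually exclusive pair with realistic heavy-tailed
        intensities clears the 0.5 cut-off."""
        n = 3000
        t = rng.integers(0, 2, n)
        sig = lambda: rng.lognormal(np.log(800), 0.8, n)
        bg = lambda: rng.lognormal(np.log(50), 0.3, n)
        x = np.where(t == 0, sig(), bg())
        y = np.where(t == 1, sig(), bg())
        assert exclusivity_score(x, y) > 0.5

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            exclusivity_score(np.full(200, 5.0), np.arange(200.0))


class TestSelectExclusivePairs:
    @staticmethod
    def _three_marker_table(rng):
        """A exclusive to B; C co-expressed with A."""
        n = 2000
        t = rng.integers(0, 2, n)
        sig = lambda: rng.lognormal(np.log(800), 0.8, n)
        bg = lambda: rng.lognormal(np.log(50), 0.3, n)
        a = np.where(t == 0, sig(), bg())
        b = np.where(t == 1, sig(), bg())
        c = a * rng.lognormal(0, 0.2, n)
        return pd.DataFrame({"A": a, "B": b, "C": c})

    def test_planted_pair_found_coexpressed_excluded(self, rng):
        table = self._three_marker_table(rng)
        pairs, unfixable = select_exclusive_pairs(table, ["A", "B", "C"],
                                                  scope="core")
        partners_of_a = {p.marker_b for p in pairs["A"]}
        assert "B" in partners_of_a and "C" not in partners_of_a

    def test_all_coexpressed_unnormalizable(self, rng):
        base = rng.lognormal(4, 1, 2000)
        table = pd.DataFrame({m: base * rng.lognormal(0, 0.1, 2000)
                              for m in ("A", "B", "C")})
        pairs, unfixable = select_exclusive_pairs(table, ["A", "B", "C"],
                                                  scope="core")
        assert set(unfixable) == {"A", "B", "C"}

    def test_fallback_cutoff_used_when_primary_unmet(self, rng):
        n = 3000
        t = rng.integers(0, 2, n)
        # weak exclusivity: signal barely above background
        a = np.where(t == 0, rng.lognormal(np.log(120), 1.2, n),
                     rng.lognormal(np.log(50), 0.6, n))
        b = np.where(t == 1, rng.lognormal(np.log(120), 1.2, n),
                     rng.lognormal(np.log(50), 0.6, n))
        table = pd.DataFrame({"A": a, "B": b})
        score = exclusivity_score(a, b)
        pairs, unfixable = select_exclusive_pairs(
            table, ["A", "B"], cutoffs=(score + 0.05, score - 0.05))
        assert pairs["A"][0].marker_b == "B"


class TestRestoreThreshold:
    @staticmethod
    def _partner_indicator_table(candidates):
        """Build a table where partner i's positive (top-quartile) population
        has the marker held at the constant candidates[i]."""
        rng = np.random.default_rng(11)
        n_part = len(candidates)
        n = 1200
        rows = {"M": np.zeros(n)}
        for i, cand in enumerate(candidates):
            p = rng.uniform(0, 100, n)
            lo, hi = i * (n // n_part), (i + 1) * (n // n_part)
            p[lo:hi] = rng.uniform(900, 1100, hi - lo)
            rows[f"P{i}"] = p
            rows["M"][lo:hi] = cand
        return pd.DataFrame(rows)

    def test_single_partner_is_that_candidate(self):
        table = self._partner_indicator_table([80.0])
        t = restore_threshold(table, "M", [ExclusivePair("M", "P0", 0.8)])
        assert t.value == pytest.approx(80.0)
        assert t.provenance == "restore"

    def test_median_of_candidates(self):
        table = self._partner_indicator_table([80.0, 100.0, 400.0])
        partners = [ExclusivePair("M", f"P{i}", 0.8) for i in range(3)]
        t = restore_threshold(table, "M", partners)
        assert t.value == pytest.approx(100.0)

    def test_small_subpopulation_skipped_with_warning(self):
        table = self._partner_indicator_table([80.0])
        partners = [ExclusivePair("M", "P0", 0.8)]
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(ValueError, match="skipped"):
                restore_threshold(table, "M", partners, min_cells=10_000)

    def test_parameter_recovery_on_planted_background(self, cell_table):
        """Thresholds recovered within 10% of the planted background
        threshold (batch without gain/offset)."""
        cfg, table, truth = cell_table
        sub = table[table.batch_id == "batch1"]
        pairs, _ = select_exclusive_pairs(sub, list(cfg.markers),
                                          scope="global")
        for marker in cfg.markers:
            t = restore_threshold(sub, marker, pairs[marker])
            true_t = truth.threshold_in_batch(marker, "batch1")
            assert abs(t.value - true_t) / true_t < 0.10, marker


class TestRestoreScale:
    def test_max_maps_to_one_exactly(self, rng):
        vals = rng.lognormal(4, 1, 1000)
        t = ThresholdRecord("M", float(np.quantile(vals, 0.6)))
        out = restore_scale(vals, t, seed=7)
        assert out.max() == 1.0
        assert out[np.argmax(vals)] == 1.0

    def test_below_threshold_at_most_002(self, rng):
        vals = rng.lognormal(4, 1, 1000)
        t = ThresholdRecord("M", float(np.quantile(vals, 0.6)))
        out = restore_scale(vals, t, seed=7)
        below = vals <= t.value
        assert (out[below] <= 0.02).all()
        assert (out[below] > 0).all()
        assert (out > 0).all() and (out <= 1).all()

    def test_order_preserved_above_threshold(self, rng):
        vals = rng.lognormal(4, 1, 1000)
        t = ThresholdRecord("M", float(np.quantile(vals, 0.5)))
        out = restore_scale(vals, t, seed=0)
        above = vals > t.value
        order = np.argsort(vals[above])
        assert (np.diff(out[above][order]) >= 0).all()

    def test_seeded_determinism(self, rng):
        vals = rng.lognormal(4, 1, 500)
        t = ThresholdRecord("M", 50.0)
        np.testing.assert_array_equal(restore_scale(vals, t, seed=3),
                                      restore_scale(vals, t, seed=3))


class TestReverseCompartmentThreshold:
    def test_q3_of_reverse_compartment(self):
        table = pd.DataFrame({"Ki67_nucleus": np.arange(1.0, 101.0),
                              "Ki67_cytoplasm": np.arange(1.0, 101.0)})
        t = reverse_compartment_threshold(table, "Ki67", "nucleus")
        assert t.value == pytest.approx(75.25)
        assert t.provenance == "reverse_quantile"

    def test_missing_compartment_rejected(self):
        table = pd.DataFrame({"Ki67_nucleus": [1.0, 2.0]})
        with pytest.raises(ValueError, match="Ki67_cytoplasm"):
            reverse_compartment_threshold(table, "Ki67", "nucleus")

    def test_empty_reverse_values_rejected(self):
        table = pd.DataFrame({"Ki67_nucleus": [1.0],
                              "Ki67_cytoplasm": [np.nan]})
        with pytest.raises(ValueError, match="no cytoplasm"):
            reverse_compartment_threshold(table, "Ki67", "nucleus")


def _two_batch_table(rng, shift=3.0, n=2000, p=5):
    base = rng.standard_normal((2 * n, p)) + 10.0
    x = base.copy()
    x[n:] += shift
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(p)])
    df["batch_id"] = ["a"] * n + ["b"] * n
    df["core_id"] = "core1"
    return df


class TestCombatAdjust:
    def test_shift_recovery(self, rng):
        df = _two_batch_table(rng)
        feats = [f"f{i}" for i in range(5)]
        adj, _ = combat_adjust(df, "batch_id", feats)
        means = adj.groupby("batch_id")[feats].mean()
        assert np.abs(means.loc["a"] - means.loc["b"]).max() < 0.05

    def test_single_batch_passthrough(self, rng):
        df = _two_batch_table(rng).query("batch_id == 'a'").copy()
        feats = [f"f{i}" for i in range(5)]
        adj, model = combat_adjust(df, "batch_id", feats)
        pd.testing.assert_frame_equal(adj, df)

    def test_training_means_and_variances_equalized_no_shrinkage(self, rng):
        """In the no-shrinkage limit, per-batch feature means and variances
        of the training cells are exactly equalized."""
        df = _two_batch_table(rng)
        feats = [f"f{i}" for i in range(5)]
        adj, _ = combat_adjust(df, "batch_id", feats, shrink=False)
        g = adj.groupby("batch_id")[feats]
        means, variances = g.mean(), g.var()
        assert np.abs(means.loc["a"] - means.loc["b"]).max() < 1e-6
        assert np.abs(variances.loc["a"] - variances.loc["b"]).max() < 1e-6

    def test_matches_scanpy_combat(self, rng):
        """Independent cross-check against the scanpy ComBat implementation
        (training mode 'all')."""
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        df = _two_batch_table(rng, shift=2.0, n=500)
        feats = [f"f{i}" for i in range(5)]
        adj, _ = combat_adjust(df, "batch_id", feats, shrink=True)
        ad = anndata.AnnData(X=df[feats].to_numpy(),
                             obs=pd.DataFrame({"batch": df["batch_id"].values}))
        ad.obs["batch"] = ad.obs["batch"].astype("category")
        scanpy.pp.combat(ad, key="batch")
        np.testing.assert_allclose(adj[feats].to_numpy(), ad.X, rtol=0.02,
                                   atol=0.05)

    def test_training_cell_subset_fit_applies_to_all(self, rng):
        df = _two_batch_table(rng)
        df.loc[: len(df) // 2, "core_id"] = "ctrl"
        feats = [f"f{i}" for i in range(5)]
        adj, model = combat_adjust(df, "batch_id", feats,
                                   training_mode="sampled",
                                   control_core_ids=["ctrl"])
        assert model.training_mode == "sampled"
        assert len(adj) == len(df)

    def test_batch_without_training_cells_rejected(self, rng):
        df = _two_batch_table(rng)
        df["core_id"] = np.where(df["batch_id"] == "a", "ctrl", "other")
        with pytest.raises(ValueError, match="no training cells"):
            combat_adjust(df, "batch_id", [f"f{i}" for i in range(5)],
                          training_mode="same", control_core_ids=["ctrl"])

    def test_zero_variance_feature_rejected(self, rng):
        df = _two_batch_table(rng)
        df["f0"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            combat_adjust(df, "batch_id", [f"f{i}" for i in range(5)])


class TestRegressOutBatch:
    def test_batch_means_equalized_variances_untouched(self, rng):
        df = _two_batch_table(rng)
        feats = [f"f{i}" for i in range(5)]
        adj = regress_out_batch(df, "batch_id", feats)
        means = adj.groupby("batch_id")[feats].mean()
        assert np.abs(means.loc["a"] - means.loc["b"]).max() < 1e-9
        for b in ("a", "b"):
            orig = df[df.batch_id == b][feats].var()
            new = adj[adj.batch_id == b][feats].var()
            np.testing.assert_allclose(new, orig, rtol=1e-12)

    def test_hand_computed_two_by_two(self):
        df = pd.DataFrame({"f": [1.0, 3.0, 5.0, 7.0],
                           "batch_id": ["a", "a", "b", "b"]})
        adj = regress_out_batch(df, "batch_id", ["f"])
        # grand mean 4; batch a mean 2 -> [3, 5]; batch b mean 6 -> [3, 5]
        np.testing.assert_allclose(adj["f"], [3.0, 5.0, 3.0, 5.0])
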