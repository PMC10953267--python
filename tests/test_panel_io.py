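"""Ingestion, scoring, reliability, descriptives, and residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelnet.errors import (ConfigurationError, DataError, ReliabilityError)
from panelnet.panel_io import (CovariateResidualizer, ScaleDefinition,
                               cohort_summary, cronbach_alpha, descriptives,
                               drop_unreliable, read_panel, residualize,
                               reverse_key, score_scales)


class TestScaleDefinition:
    def test_reverse_keyed_must_be_subset(self):
        with pytest.raises(ConfigurationError):
            ScaleDefinition("s", "parenting", ("a", "b"), reverse_keyed=("c",))

    def test_empty_items_rejected(self):
        with pytest.raises(ConfigurationError):
            ScaleDefinition("s", "parenting", ())

    def test_bad_range_rejected(self):
        with pytest.raises(ConfigurationError):
            ScaleDefinition("s", "parenting", ("a",), response_range=(5, 1))


class TestReadPanel:
    def test_well_formed_input(self, toy_panel_csv):
        path, defs = toy_panel_csv
        data = read_panel(path, defs)
        assert data.n == 3
        assert data.n_warnings == 0
        assert set(data.items) == {"T1", "T2"}

    def test_out_of_range_response_becomes_missing(self, toy_panel_csv, tmp_path):
        path, defs = toy_panel_csv
        df = pd.read_csv(path)
        df.loc[0, "w1_t1"] = 9  # outside the 1-5 range
        p2 = tmp_path / "bad.csv"
        df.to_csv(p2, index=False)
        data = read_panel(p2, defs)
        assert data.n_warnings == 1
        assert np.isnan(data.items["T1"].loc[df.loc[0, "participant_id"], "w1"])

    def test_duplicate_participant_names_the_offender(self, toy_panel_csv, tmp_path):
        path, defs = toy_panel_csv
        df = pd.read_csv(path)
        df.loc[1, "participant_id"] = 7
        df.loc[2, "participant_id"] = 7
        p2 = tmp_path / "dup.csv"
        df.to_csv(p2, index=False)
        with pytest.raises(DataError, match="7"):
            read_panel(p2, defs)

    def test_missing_mandatory_column(self, toy_panel_csv, tmp_path):
        path, defs = toy_panel_csv
        df = pd.read_csv(path).drop(columns=["a1_t2"])
        p2 = tmp_path / "missing.csv"
        df.to_csv(p2, index=False)
        with pytest.raises(ConfigurationError, match="a1_t2"):
            read_panel(p2, defs)


class TestScoring:
    def _dataset(self, items_t1, defs):
        from panelnet.panel_io import PanelDataset
        frame = pd.DataFrame(items_t1)
        return PanelDataset(items={"T1": frame},
                            covariates=pd.DataFrame(index=frame.index),
                            scale_defs=defs)

    def test_constant_items_score_is_the_constant(self):
        defs = [ScaleDefinition("warmth", "parenting",
                                tuple(f"w{i}" for i in range(8)))]
        data = self._dataset({f"w{i}": [4, 4] for i in range(8)}, defs)
        score_scales(data)
        assert (data.scores["T1"]["warmth"] == 4.0).all()

    def test_reverse_keyed_item_contributes_lo_plus_hi_minus_x(self):
        defs = [ScaleDefinition("s", "parenting", ("a", "b"),
                                reverse_keyed=("b",), response_range=(1, 5))]
        data = self._dataset({"a": [4.0], "b": [2.0]}, defs)
        score_scales(data)
        assert data.scores["T1"]["s"].iloc[0] == pytest.approx((4 + 4) / 2)

    def test_missing_item_rule_four_of_six_is_missing(self):
        defs = [ScaleDefinition("s", "parenting", tuple("abcdef"))]
        items = {c: [3.0] for c in "abcd"}
        items.update({"e": [np.nan], "f": [np.nan]})
        data = self._dataset(items, defs)
        score_scales(data, min_answered=0.75)
        assert np.isnan(data.scores["T1"]["s"].iloc[0])

    def test_absent_item_column_is_configuration_error(self):
        defs = [ScaleDefinition("s", "parenting", ("a", "zz"))]
        data = self._dataset({"a": [1.0]}, defs)
        with pytest.raises(ConfigurationError, match="zz"):
            score_scales(data)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_reverse_keying_is_an_involution(self, seed):
        rng = np.random.default_rng(seed)
        sd = ScaleDefinition("s", "parenting", ("a", "b", "c"),
                             reverse_keyed=("a", "c"), response_range=(1, 5))
        items = pd.DataFrame(rng.integers(1, 6, size=(10, 3)), columns=["a", "b", "c"])
        twice = reverse_key(reverse_key(items, sd), sd)
        pd.testing.assert_frame_equal(items, twice)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self, rng):
        x = rng.normal(size=(50, 1))
        assert cronbach_alpha(np.repeat(x, 4, axis=1)) == pytest.approx(1.0)

    def test_equicorrelated_items_match_spearman_brown(self, rng):
        # population item correlation 0.3, k=5 -> alpha = 5*.3/(1+4*.3)
        k, n, r = 5, 100_000, 0.3
        f = rng.normal(size=(n, 1))
        x = np.sqrt(r) * f + np.sqrt(1 - r) * rng.normal(size=(n, k))
        expected = k * r / (1 + (k - 1) * r)
        assert cronbach_alpha(x) == pytest.approx(expected, abs=0.01)

    def test_independent_items_give_zero(self, rng):
        x = rng.normal(size=(100_000, 4))
        assert cronbach_alpha(x) == pytest.approx(0.0, abs=0.02)

    def test_zero_total_variance_raises(self):
        with pytest.raises(ReliabilityError):
            cronbach_alpha(np.ones((10, 3)))

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = pd.DataFrame(rng.normal(size=(200, 4)) + rng.normal(size=(200, 1)))
        expected = pingouin.cronbach_alpha(data=x)[0]
        assert cronbach_alpha(x) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_item_shift_and_relabeling(self, rng):
        x = rng.normal(size=(100, 4)) + rng.normal(size=(100, 1))
        shifted = x + np.array([10.0, -3.0, 0.0, 5.0])
        permuted = shifted[:, [2, 0, 3, 1]]
        assert cronbach_alpha(permuted) == pytest.approx(cronbach_alpha(x), abs=1e-12)


class TestDescriptives:
    def _scored(self, values, n_items=3):
        from panelnet.panel_io import PanelDataset
        defs = [ScaleDefinition("s", "parenting",
                                tuple(f"i{j}" for j in range(n_items)))]
        vals = np.asarray(values, float)
        items = pd.DataFrame({f"i{j}": vals for j in range(n_items)})
        data = PanelDataset(items={"T1": items}, covariates=pd.DataFrame(index=items.index),
                            scale_defs=defs)
        return score_scales(data)

    def test_symmetric_sample_has_zero_skewness(self):
        d = descriptives(self._scored([-1, -1, 1, 1]))
        assert d.loc[("s", "T1"), "skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_has_zero_skew_and_excess_kurtosis(self, rng):
        d = descriptives(self._scored(rng.normal(size=100_000)))
        assert d.loc[("s", "T1"), "skewness"] == pytest.approx(0.0, abs=0.05)
        assert d.loc[("s", "T1"), "kurtosis"] == pytest.approx(0.0, abs=0.05)

    def test_constant_column_degenerates_gracefully(self):
        d = descriptives(self._scored([2.0, 2.0, 2.0, 2.0]))
        row = d.loc[("s", "T1")]
        assert row["sd"] == 0.0
        assert np.isnan(row["skewness"]) and np.isnan(row["kurtosis"])

    def test_row_permutation_invariance(self, rng):
        vals = rng.normal(size=500)
        a = descriptives(self._scored(vals))
        b = descriptives(self._scored(rng.permutation(vals)))
        pd.testing.assert_frame_equal(a, b)


class TestReliabilityRule:
    @pytest.mark.parametrize("alphas, retained", [
        ((0.50, 0.54), False),   # sub-threshold at both waves -> dropped
        ((0.59, 0.67), True),    # clears the bar at the second wave -> kept
        ((0.60, 0.60), True),    # boundary: strict < means retained
    ])
    def test_both_waves_rule(self, alphas, retained):
        descr = pd.DataFrame(
            {"alpha": alphas},
            index=pd.MultiIndex.from_tuples([("s", "T1"), ("s", "T2")],
                                            names=["scale", "wave"]),
        )
        assert (["s"] if retained else []) == drop_unreliable(descr, threshold=0.60)


class TestCohortSummary:
    @pytest.mark.parametrize("n1, n2, pct", [
        (642, 591, 7.9),
        (100, 100, 0.0),
        (200, 150, 25.0),
    ])
    def test_attrition_percent(self, n1, n2, pct):
        assert cohort_summary(n1, n2)["attrition_pct"] == pct

    def test_growing_cohort_is_a_data_error(self):
        with pytest.raises(DataError):
            cohort_summary(100, 101)


class TestResidualize:
    def test_orthogonal_covariate_leaves_centered_scores(self, rng):
        n = 200
        cov = pd.DataFrame({"c": np.repeat([0.0, 1.0], n // 2)})
        y = np.tile([1.0, -1.0], n // 2)  # orthogonal to c in-sample
        res = residualize(pd.DataFrame({"y": y}), cov)
        np.testing.assert_allclose(res["y"].to_numpy(), y - y.mean(), atol=1e-10)

    def test_residuals_uncorrelated_with_covariate(self, rng):
        n = 500
        age = rng.uniform(8, 17, n)
        y = 2 * age + rng.normal(size=n)
        res = residualize(pd.DataFrame({"y": y}), pd.DataFrame({"age": age}))
        assert abs(np.corrcoef(res["y"], age)[0, 1]) < 1e-10
        assert abs(res["y"].mean()) < 1e-8

    def test_constant_covariate_dropped_with_warning(self, rng):
        y = rng.normal(size=50)
        cov = pd.DataFrame({"const": np.ones(50)})
        with pytest.warns(UserWarning, match="degenerate"):
            res = residualize(pd.DataFrame({"y": y}), cov)
        np.testing.assert_allclose(res["y"], y - y.mean(), atol=1e-10)

    def test_refit_on_covariates_gives_zero_coefficients(self, rng):
        n = 300
        cov = pd.DataFrame({
            "gender": rng.integers(0, 2, n).astype(float),
            "age": rng.uniform(8, 17, n),
        })
        scores = pd.DataFrame({
            "a": 0.5 * cov["age"] + rng.normal(size=n),
            "b": cov["gender"] - 0.1 * cov["age"] + rng.normal(size=n),
        })
        res = residualize(scores, cov)
        X = np.column_stack([np.ones(n), cov.to_numpy()])
        beta, *_ = np.linalg.lstsq(X, res.to_numpy(), rcond=None)
        np.testing.assert_allclose(beta, 0.0, atol=1e-8)

    def test_too_few_rows_raises(self):
        with pytest.raises(DataError):
            residualize(pd.DataFrame({"y": [1.0, 2.0]}),
                        pd.DataFrame({"c": [0.0, 1.0]}))

    def test_sklearn_transformer_roundtrip(self, rng):
        n = 100
        frame = pd.DataFrame({
            "score": rng.normal(size=n),
            "gender": rng.integers(0, 2, n).astype(float),
        })
        est = CovariateResidualizer(covariate_columns=("gender",))
        out = est.fit(frame).transform(frame)
        assert est.score_columns_ == ["score"]
        assert abs(out["score"].mean()) < 1e-10
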