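"""Normalization pipeline: deselection, log, imputation, residualization, z-score."""

import numpy as np
import pandas as pd
import pytest

from immunoprofile import (
    SimulationConfig,
    deselect_correlated,
    generate_cohort,
    impute_missing,
    log_transform,
    normalize_markers,
    residualize_days,
    standardize,
)
from immunoprofile.simulate import Cohort


def _toy_cohort(values: dict, log_flags: dict | None = None,
                days=None) -> Cohort:
    df = pd.DataFrame(values)
    n = len(df)
    df.index = [f"P{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "hiv_status": ["PWOH"] * n,
            "severity": ["symptomatic"] * n,
            "age": np.linspace(20, 60, n),
            "sex": ["female"] * n,
            "region": ["US"] * n,
            "smoking": ["no"] * n,
            "days_since_dx": days if days is not None else np.arange(13, 13 + n),
        },
        index=df.index,
    )
    mm = pd.DataFrame(
        {
            "assay_family": "fam",
            "antigen_class": "sars2",
            "isotype": "NA",
            "log_transform": [bool((log_flags or {}).get(c, False))
                              for c in df.columns],
            "has_response_call": True,
        },
        index=pd.Index(df.columns, name="marker_id"),
    )
    return Cohort(meta, df, mm)


class TestDeselectCorrelated:
    def test_duplicate_column_drops_exactly_one(self, rng):
        x = rng.normal(size=30)
        c = _toy_cohort({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        reduced, dropped = deselect_correlated(c)
        assert len(dropped) == 1
        assert {dropped[0][0], dropped[0][1]} == {"a", "b"}
        assert reduced.n_markers == 2

    def test_nothing_dropped_below_threshold(self, rng):
        c = _toy_cohort({f"m{i}": rng.normal(size=40) for i in range(5)})
        reduced, dropped = deselect_correlated(c)
        assert dropped == [] and reduced.n_markers == 5

    def test_chain_drops_the_hub(self, rng):
        # a~b and b~c strong, a~c weak: greedy rule removes b only
        n = 400
        a = rng.normal(size=n)
        cvec = rng.normal(size=n)
        b = 5 * (a + cvec) + 0.1 * rng.normal(size=n)
        c = _toy_cohort({"a": a, "b": b, "c": cvec})
        rho = c.markers.corr(method="spearman")
        assert abs(rho.loc["a", "b"]) > 0.65 and abs(rho.loc["b", "c"]) > 0.65
        assert abs(rho.loc["a", "c"]) < 0.3
        reduced, dropped = deselect_correlated(c, threshold=0.65)
        assert [d[0] for d in dropped] == ["b"]
        assert list(reduced.markers.columns) == ["a", "c"]

    def test_all_constant_raises(self):
        c = _toy_cohort({"a": np.ones(10), "b": np.ones(10)})
        with pytest.raises(ValueError):
            deselect_correlated(c)


class TestLogTransform:
    def test_decades(self):
        c = _toy_cohort({"a": [10.0, 100.0, 1000.0]}, {"a": True})
        out = log_transform(c)
        assert np.allclose(out.markers["a"], [1.0, 2.0, 3.0])

    def test_unflagged_unchanged(self):
        c = _toy_cohort({"a": [3.0, 4.0, 5.0]}, {"a": False})
        out = log_transform(c)
        assert np.allclose(out.markers["a"], [3.0, 4.0, 5.0])

    def test_floor_at_half_minimum_positive(self):
        c = _toy_cohort({"a": [0.0, 10.0, 100.0]}, {"a": True})
        out = log_transform(c)
        assert out.markers["a"].iloc[0] == pytest.approx(np.log10(5.0))

    def test_all_nonpositive_flagged_raises(self):
        c = _toy_cohort({"a": [0.0, -1.0, 0.0]}, {"a": True})
        with pytest.raises(ValueError):
            log_transform(c)


class TestImputeMissing:
    def test_no_missing_is_identity(self, rng):
        c = _toy_cohort({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        out, mask = impute_missing(c, seed=1)
        pd.testing.assert_frame_equal(out.markers, c.markers)
        assert not mask.to_numpy().any()

    def test_exact_linear_relation_recovered(self, rng):
        x = rng.normal(size=40)
        y = 2.0 * x
        vals = {"x": x, "y": y, "z": rng.normal(size=40)}
        c = _toy_cohort(vals)
        c.markers.iloc[5, 1] = np.nan
        out, mask = impute_missing(c, seed=1)
        assert out.markers.iloc[5, 1] == pytest.approx(2.0 * x[5], abs=1e-5)
        assert mask.iloc[5, 1]

    def test_observed_cells_never_altered(self, rng):
        cfg = SimulationConfig(n_pwoh=60, n_plwh=20, missing_rate=0.1, seed=4)
        c = generate_cohort(cfg)
        out, mask = impute_missing(c, seed=2)
        obs = ~mask
        pd.testing.assert_frame_equal(out.markers[obs], c.markers[obs])
        assert not out.markers.isna().to_numpy().any()

    def test_beats_median_fill_under_mcar(self, rng):
        cfg = SimulationConfig(
            n_pwoh=150, n_plwh=50, missing_rate=0.0,
            within_block_rho={"PWOH": 0.6, "PLWH": 0.6}, seed=6,
        )
        c = generate_cohort(cfg)
        truth = np.log(c.markers.copy())
        masked = truth.copy()
        holes = rng.random(truth.shape) < 0.10
        masked[holes] = np.nan
        cm = Cohort(c.metadata, masked, c.marker_meta)
        out, _ = impute_missing(cm, seed=3)
        rmse = np.sqrt(np.nanmean((out.markers.to_numpy() - truth.to_numpy())[holes] ** 2))
        med = masked.fillna(masked.median())
        rmse_med = np.sqrt(np.nanmean((med.to_numpy() - truth.to_numpy())[holes] ** 2))
        assert rmse <= rmse_med

    def test_majority_missing_marker_raises(self, rng):
        c = _toy_cohort({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        c.markers.iloc[:6, 0] = np.nan
        with pytest.raises(ValueError):
            impute_missing(c, seed=1)


class TestResidualizeDays:
    def test_pure_day_effect_becomes_constant(self):
        days = np.arange(13, 53)
        c = _toy_cohort({"a": 2.0 * days.astype(float)}, days=days)
        out, model = residualize_days(c)
        assert np.allclose(out.markers["a"], out.markers["a"].iloc[0])
        assert model.slopes["a"] == pytest.approx(2.0)

    def test_refit_slope_is_zero(self, rng):
        days = rng.integers(13, 132, size=500)
        y = 3.0 + 0.5 * days + rng.normal(scale=0.1, size=500)
        c = _toy_cohort({"a": y}, days=days)
        out, _ = residualize_days(c)
        x = days - days.mean()
        resid = out.markers["a"].to_numpy()
        slope = np.dot(x, resid - resid.mean()) / np.dot(x, x)
        assert slope == pytest.approx(0.0, abs=0.01)

    def test_independent_marker_nearly_unchanged(self, rng):
        vals = rng.normal(size=200)
        c = _toy_cohort({"a": vals}, days=rng.integers(13, 132, size=200))
        out, model = residualize_days(c)
        assert abs(model.slopes["a"]) < 0.01
        assert np.allclose(out.markers["a"], vals, atol=1.5)

    def test_constant_days_raises(self):
        c = _toy_cohort({"a": [1.0, 2.0, 3.0]}, days=[50, 50, 50])
        with pytest.raises(ValueError):
            residualize_days(c)


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        c = _toy_cohort({f"m{i}": rng.normal(3, 7, size=30) for i in range(4)})
        out = standardize(c)
        assert np.allclose(out.values.mean(), 0.0, atol=1e-8)
        assert np.allclose(out.values.std(ddof=1), 1.0, atol=1e-8)

    def test_two_point_column(self):
        c = _toy_cohort({"a": [0.0, 10.0]})
        out = standardize(c)
        assert np.allclose(out.values["a"], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_idempotent(self, rng):
        c = _toy_cohort({"a": rng.normal(size=25), "b": rng.normal(size=25)})
        once = standardize(c)
        twice = standardize(Cohort(c.metadata, once.values, c.marker_meta))
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_constant_column_raises(self):
        c = _toy_cohort({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError):
            standardize(c)


class TestFullPipeline:
    def test_end_to_end(self, small_cohort):
        norm = normalize_markers(small_cohort, seed=5)
        v = norm.values
        assert not v.isna().to_numpy().any()
        assert np.allclose(v.mean(), 0.0, atol=1e-8)
        assert np.allclose(v.std(ddof=1), 1.0, atol=1e-8)
        assert norm.imputation_mask is not None
        assert norm.residualization is not None
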