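"""Thermal-time stages, climatic/soil covariates, QC, W and Omega."""

import numpy as np
import pandas as pd
import pytest

from gddrn.env_covariates import (
    CLIMATIC_EC_CODES,
    LOW_RADIATION_MJ,
    SOIL_DEPTHS,
    SOIL_EC_CODES,
    assign_stages,
    build_omega,
    build_W,
    climatic_ec_values,
    compute_gdd,
    compute_soil_ecs,
    compute_stage_ecs,
    qc_ecs,
)

from conftest import make_weather


# ---------------------------------------------------------------- GDD
class TestComputeGdd:
    def test_constant_temperature_accumulates_linearly(self):
        w = make_weather(days=30, tavg=10.0)
        gdd = compute_gdd(w)
        np.testing.assert_allclose(gdd.values, 10.0 * np.arange(1, 31))

    def test_subzero_days_contribute_nothing(self):
        w = make_weather(days=2, tavg=np.array([-5.0, 5.0]))
        gdd = compute_gdd(w)
        np.testing.assert_allclose(gdd.values, [0.0, 5.0])

    def test_missing_day_raises_with_date(self):
        w = make_weather(days=30, tavg=10.0)
        bad_date = w.records.index[10]
        w.records.loc[bad_date, "tavg"] = np.nan
        with pytest.raises(ValueError, match=str(bad_date.date())):
            compute_gdd(w)

    def test_nondecreasing(self):
        rng = np.random.default_rng(0)
        w = make_weather(days=100, tavg=rng.normal(5, 8, 100))
        gdd = compute_gdd(w)
        assert (np.diff(gdd.values) >= 0).all()


# ------------------------------------------------------------- stages
class TestAssignStages:
    def test_constant_10C_stages_span_10_days(self):
        gdd = compute_gdd(make_weather(days=300, tavg=10.0))
        stages = assign_stages(gdd, stage_size=100.0)
        complete = stages[stages["complete"]]
        assert (complete["n_days"] == 10).all()
        assert len(complete) == 30

    def test_constant_25C_stage1_is_days_1_to_4(self):
        gdd = compute_gdd(make_weather(days=40, tavg=25.0))
        stages = assign_stages(gdd, stage_size=100.0)
        first = stages.iloc[0]
        assert first["n_days"] == 4
        assert first["gdd_start"] == 0.0
        assert first["gdd_end"] == 100.0

    def test_boundaries_partition_season(self):
        rng = np.random.default_rng(1)
        gdd = compute_gdd(make_weather(days=200, tavg=rng.uniform(0, 20, 200)))
        stages = assign_stages(gdd)
        assert stages["n_days"].sum() == 200
        # contiguity of day windows
        for prev, nxt in zip(stages.itertuples(), stages.iloc[1:].itertuples()):
            assert (nxt.start_date - prev.end_date).days == 1

    def test_complete_stage_gdd_bounded_by_daily_increment(self):
        rng = np.random.default_rng(2)
        tavg = rng.uniform(0, 18, 250)
        gdd = compute_gdd(make_weather(days=250, tavg=tavg))
        stages = assign_stages(gdd, stage_size=100.0)
        complete = stages[stages["complete"]]
        accum = complete["gdd_end"] - complete["gdd_start"]
        assert (accum >= 100.0).all()
        assert (accum < 100.0 + tavg.max()).all()

    def test_sinusoidal_year_reaches_27_stages(self):
        d = np.arange(320)
        tavg = 10 - 8 * np.cos(2 * np.pi * (d + 274 - 196) / 365)
        gdd = compute_gdd(make_weather(days=320, tavg=tavg))
        # independent oracle: brute-force cumulative sum
        assert np.isclose(gdd.iloc[-1], np.maximum(tavg, 0).sum())
        stages = assign_stages(gdd)
        assert stages["complete"].sum() >= 27

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            assign_stages(pd.Series(dtype=float))


# ------------------------------------------------------ climatic ECs
class TestStageEcs:
    def test_water_balance_hand_example(self):
        # 10-day stage, 2 mm rain and 1 mm evaporation per day
        w = make_weather(days=10, tavg=10.0, precip=2.0, evap=1.0)
        ec = climatic_ec_values(w.records)
        assert ec["cumprec"] == pytest.approx(20.0)
        assert ec["cumpetp"] == pytest.approx(10.0)
        assert ec["cumpospetp"] == pytest.approx(10.0)
        assert ec["cumnegpetp"] == pytest.approx(0.0)
        assert ec["cumntdryd"] == 0

    def test_temperature_radiation_hand_example(self):
        w = make_weather(days=10, tavg=10.0, tmin=10.0, tmax=12.0, glorad=5.0)
        ec = climatic_ec_values(w.records)
        assert ec["ave.temp"] == pytest.approx(10.0)
        assert ec["cumglorad"] == pytest.approx(50.0)
        assert ec["ratrdtmp"] == pytest.approx(0.5)
        assert ec["GDD"] == pytest.approx(100.0)
        assert ec["cumndt0"] == 0

    def test_emits_all_17_codes_per_complete_stage(self):
        w = make_weather(days=300, tavg=12.0)
        stages = assign_stages(compute_gdd(w))
        ecs = compute_stage_ecs(w, stages)
        n_complete = int(stages["complete"].sum())
        assert ecs.shape[1] == 17 * n_complete
        for k in range(1, n_complete + 1):
            cols = [c for c in ecs.columns if c.endswith(f"_s{k}")]
            assert len(cols) == 17
            assert {c.rsplit("_s", 1)[0] for c in cols} == set(CLIMATIC_EC_CODES)

    def test_missing_field_yields_missing_not_zero(self):
        w = make_weather(days=20, tavg=10.0)
        w.records = w.records.drop(columns=["vpd"])
        ec = climatic_ec_values(w.records)
        assert np.isnan(ec["ave.vpd"]) and np.isnan(ec["cumvpd"])
        assert np.isfinite(ec["GDD"])

    def test_zero_day_stage_rejected(self):
        with pytest.raises(ValueError):
            climatic_ec_values(make_weather(days=5).records.iloc[:0])

    def test_every_ec_matches_naive_per_day_oracle(self):
        """Oracle equivalence on random 20-day stages."""
        rng = np.random.default_rng(42)
        for rep in range(10):
            n = 20
            df = pd.DataFrame(
                {
                    "tavg": rng.uniform(-6, 25, n),
                    "precip": rng.exponential(2.5, n) * (rng.random(n) < 0.6),
                    "evap": rng.uniform(0, 3, n),
                    "glorad": rng.uniform(0.5, 22, n),
                    "vpd": rng.uniform(0.05, 1.5, n),
                },
                index=pd.date_range("2016-03-01", periods=n),
            )
            df["tmin"] = df["tavg"] - rng.uniform(0.5, 5, n)
            df["tmax"] = df["tavg"] + rng.uniform(0.5, 5, n)
            got = climatic_ec_values(df)

            # independent naive per-day loop
            exp = {c: 0.0 for c in CLIMATIC_EC_CODES}
            for _, day in df.iterrows():
                exp["cumglorad"] += day.glorad
                exp["GDD"] += max(day.tavg, 0.0)
                exp["cumprec"] += day.precip
                exp["cumvpd"] += day.vpd
                pe = day.precip - day.evap
                exp["cumpetp"] += pe
                if pe > 0:
                    exp["cumpospetp"] += pe
                if pe < 0:
                    exp["cumnegpetp"] += pe
                if pe <= 0:
                    exp["cumntdryd"] += 1
                if day.tmin < -4:
                    exp["cumnsti4"] += day.tmin
                if day.tmin < 0:
                    exp["cumndt0"] += 1
                    exp["cumsti0"] += day.tmin
                if day.glorad < LOW_RADIATION_MJ:
                    exp["ndi10m"] += 1
                    exp["sri10m"] += day.glorad
            exp["ave.glorad"] = exp["cumglorad"] / n
            exp["ave.temp"] = df["tavg"].sum() / n
            exp["ave.vpd"] = exp["cumvpd"] / n
            exp["ratrdtmp"] = exp["cumglorad"] / exp["GDD"]
            for code in CLIMATIC_EC_CODES:
                assert got[code] == pytest.approx(exp[code]), code


# ------------------------------------------------------------ soil ECs
class TestSoilEcs:
    @staticmethod
    def _soil(locations=("A", "B", "C"), seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for loc in locations:
            for top, bottom in SOIL_DEPTHS:
                row = {"location": loc, "depth_top_cm": top, "depth_bottom_cm": bottom}
                row.update({c: rng.uniform(1, 50) for c in SOIL_EC_CODES})
                rows.append(row)
        return pd.DataFrame(rows)

    def test_28_columns_and_distinct_locations(self):
        out = compute_soil_ecs(self._soil())
        assert out.shape == (3, 28)
        assert len(set(map(tuple, out.values.round(6)))) == 3

    def test_rows_constant_across_years_within_location(self):
        out = compute_soil_ecs(self._soil())
        broadcast = out.loc[["A", "A"]]
        assert (broadcast.iloc[0] == broadcast.iloc[1]).all()

    def test_missing_layer_raises_naming_location(self):
        soil = self._soil().iloc[1:]  # drop A's 0-30 layer
        with pytest.raises(ValueError, match="A.*0-30"):
            compute_soil_ecs(soil)


# ----------------------------------------------------------------- QC
class TestQcEcs:
    def test_missing_threshold_strict(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        df.loc[:10, "a"] = np.nan  # 11 % missing -> dropped
        df.loc[:9, "b"] = np.nan   # exactly 10 % -> kept
        out = qc_ecs(df)
        assert "a" not in out.columns and "b" in out.columns

    def test_repeat_threshold_strict(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        df.loc[:30, "a"] = 7.0   # 31 % identical -> dropped
        df.loc[:29, "b"] = 7.0   # exactly 30 % -> kept
        out = qc_ecs(df)
        assert "a" not in out.columns and "b" in out.columns
        assert "repeated" in out.attrs["qc_dropped"]["a"]

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
        out = qc_ecs(df)
        assert list(out.columns) == ["b"]

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        df.loc[:20, "c"] = np.nan
        once = qc_ecs(df)
        twice = qc_ecs(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_dropped_raises(self):
        df = pd.DataFrame({"a": np.ones(10)})
        with pytest.raises(ValueError, match="threshold"):
            qc_ecs(df)


# ------------------------------------------------------------ W, Omega
class TestWAndOmega:
    def test_columns_centered_and_unit_sd(self):
        rng = np.random.default_rng(7)
        ec = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"e{i}" for i in range(6)],
                          columns=list("abcd"))
        obs_env = pd.Series(np.repeat(ec.index, 3), index=[f"o{i}" for i in range(18)])
        W = build_W(ec, obs_env, scale="observation")
        np.testing.assert_allclose(W.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(W.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert len(W) == 18

    def test_two_environment_worked_value(self):
        ec = pd.DataFrame({"x": [3.0, 9.0]}, index=["e1", "e2"])
        obs_env = pd.Series(["e1", "e2"], index=["o1", "o2"])
        W = build_W(ec, obs_env, scale="environment")
        np.testing.assert_allclose(np.abs(W["x"].values), 0.70710678, atol=1e-8)
        omega = build_omega(W)
        np.testing.assert_allclose(
            omega.values, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-10
        )

    def test_environment_scaling_constant_within_environment(self):
        rng = np.random.default_rng(8)
        ec = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"), columns=list("xyz"))
        obs_env = pd.Series(list("aabbccdd"), index=[f"o{i}" for i in range(8)])
        omega = build_omega(build_W(ec, obs_env, scale="environment"))
        v = omega.values
        assert np.allclose(v[0], v[1]) and np.allclose(v[:, 0], v[:, 1])

    def test_omega_matches_bruteforce_and_is_psd(self):
        rng = np.random.default_rng(9)
        W = pd.DataFrame(rng.normal(size=(10, 5)))
        W = (W - W.mean()) / W.std(ddof=1)
        omega = build_omega(W).values
        q = 5
        brute = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                brute[i, j] = sum(W.iloc[i, k] * W.iloc[j, k] for k in range(q)) / q
        np.testing.assert_allclose(omega, brute, atol=1e-12)
        eig = np.linalg.eigvalsh(omega)
        assert eig.min() >= -1e-8 * eig.max()

    def test_duplicated_columns_leave_omega_unchanged(self):
        rng = np.random.default_rng(10)
        W1 = pd.DataFrame({"a": rng.normal(size=6)})
        W1 = (W1 - W1.mean()) / W1.std(ddof=1)
        W3 = pd.concat([W1, W1.rename(columns={"a": "b"}), W1.rename(columns={"a": "c"})], axis=1)
        np.testing.assert_allclose(build_omega(W1).values, build_omega(W3).values, atol=1e-12)

    def test_q_zero_rejected(self):
        with pytest.raises(ValueError):
            build_omega(pd.DataFrame(index=["o1", "o2"]))

    def test_unknown_environment_rejected(self):
        ec = pd.DataFrame({"x": [1.0, 2.0]}, index=["e1", "e2"])
        with pytest.raises(ValueError, match="unknown environments"):
            build_W(ec, pd.Series(["e3"], index=["o1"]))
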