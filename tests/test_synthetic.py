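import math

import numpy as np
import pandas as pd
import pytest

import habsuit as hb
from habsuit.synthetic import (
    SeasonScenario,
    SpeciesResponseSpec,
    expected_yield,
    make_env_fields,
)


def _spec(**kw):
    base = dict(
        species="sp",
        q_max=1000.0,
        mu={"temp": 20.0, "sal": 32.0, "depth": 80.0},
        sigma={"temp": 3.0, "sal": 1.5, "depth": 40.0},
        weight_share={"temp": 0.5, "sal": 0.3, "depth": 0.2},
    )
    base.update(kw)
    return SpeciesResponseSpec(**base)


def _scenario(specs, season="spring", missing=0.0, seed=1, **kw):
    return SeasonScenario(
        season=season,
        temp_field=lambda la, lo: np.full_like(np.asarray(la, float), 20.0),
        sal_field=lambda la, lo: np.full_like(np.asarray(la, float), 32.0),
        depth_field=lambda la, lo: np.full_like(np.asarray(la, float), 80.0),
        species_specs=specs,
        env_missing_fraction=missing,
        seed=seed,
        **kw,
    )


class TestMakeGrid:
    def test_full_survey_lattice_has_165_stations(self):
        g = hb.make_grid((27, 34), (122, 127), 0.5)
        assert len(g) == 15 * 11 == 165
        assert g.lats.min() == 27 and g.lats.max() == 34
        assert g.lons.min() == 122 and g.lons.max() == 127
        assert len(set(g.station_ids)) == 165

    def test_degenerate_single_point(self):
        g = hb.make_grid((27, 27), (122, 122), 0.5)
        assert len(g) == 1

    @pytest.mark.parametrize(
        "lat_range,lon_range,axis",
        [((27, 34), (122, 127.2), "longitude"), ((27, 34.2), (122, 127), "latitude")],
    )
    def test_nondividing_spacing_names_axis(self, lat_range, lon_range, axis):
        with pytest.raises(ValueError, match=axis):
            hb.make_grid(lat_range, lon_range, 0.5)

    def test_spacing_03_does_not_divide(self):
        with pytest.raises(ValueError):
            hb.make_grid((27, 34), (122, 127), 0.3)


class TestEnvFields:
    def test_constant_surface_evaluates_everywhere(self, survey_grid):
        env = make_env_fields(survey_grid, _scenario([_spec()]), with_missing=False)
        assert (env["temp_c"] == 20.0).all()
        assert len(env) == len(survey_grid)

    def test_seeded_reproducibility(self, survey_grid):
        sc = _scenario([_spec()], missing=0.2, seed=9)
        a = make_env_fields(survey_grid, sc)
        b = make_env_fields(survey_grid, sc)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_fraction_count(self, survey_grid):
        env = make_env_fields(survey_grid, _scenario([_spec()], missing=0.2))
        assert (env["source"] == "missing").sum() == round(0.2 * 165) == 33
        assert env.loc[env["source"] == "missing", "temp_c"].isna().all()

    def test_block_missingness_south_of_latitude(self, survey_grid):
        sc = _scenario([_spec()], missing_block_south_of=28.0)
        env = make_env_fields(survey_grid, sc)
        south = env["lat"] < 28.0
        assert (env.loc[south, "source"] == "missing").all()
        assert (env.loc[~south, "source"] == "measured").all()

    def test_nonpositive_depth_rejected(self, survey_grid):
        sc = _scenario([_spec()])
        sc.depth_field = lambda la, lo: np.zeros_like(np.asarray(la, float))
        with pytest.raises(ValueError, match="depth"):
            make_env_fields(survey_grid, sc)


class TestSampleCatch:
    def test_yield_at_optimum_equals_q_max(self, survey_grid):
        env = make_env_fields(survey_grid, _scenario([_spec()]), with_missing=False)
        catch = hb.sample_catch(survey_grid, env, [_spec()], seed=1)
        assert np.allclose(catch["weight_g"], 1000.0)
        assert (catch["tow_h"] == 1.0).all()

    def test_one_sigma_off_optimum_scales_by_exp_minus_one(self, survey_grid):
        spec = _spec(mu={"temp": 23.0, "sal": 32.0, "depth": 80.0})  # temp off by sigma
        env = make_env_fields(survey_grid, _scenario([spec]), with_missing=False)
        catch = hb.sample_catch(survey_grid, env, [spec], seed=1)
        assert np.allclose(catch["weight_g"], 1000.0 * math.exp(-1))

    def test_total_zero_inflation_zeroes_everything(self, survey_grid):
        spec = _spec(zero_inflation=1.0)
        env = make_env_fields(survey_grid, _scenario([spec]), with_missing=False)
        catch = hb.sample_catch(survey_grid, env, [spec], seed=1)
        assert (catch["weight_g"] == 0).all()

    def test_incomplete_env_rejected(self, survey_grid):
        env = make_env_fields(survey_grid, _scenario([_spec()], missing=0.2))
        with pytest.raises(ValueError, match="missing"):
            hb.sample_catch(survey_grid, env, [_spec()], seed=1)

    def test_unknown_station_rejected(self, survey_grid):
        env = make_env_fields(survey_grid, _scenario([_spec()]), with_missing=False)
        with pytest.raises(ValueError, match="absent"):
            hb.sample_catch(survey_grid, env.iloc[1:], [_spec()], seed=1)

    def test_noiseless_expected_yield_argmax_at_mu(self):
        # unimodality / argmax identity of the ground-truth response
        spec = _spec()
        grid_env = pd.DataFrame(
            {
                "temp_c": np.linspace(10, 30, 201),
                "sal_psu": 32.0,
                "depth_m": 80.0,
            }
        )
        y = expected_yield(spec, grid_env)
        assert grid_env["temp_c"][np.argmax(y)] == pytest.approx(20.0)
        assert np.all(np.diff(y[:100]) > 0) and np.all(np.diff(y[101:]) < 0)


class TestImputeEnv:
    def _env_with_hole(self, survey_grid, field):
        sc = _scenario([_spec()])
        sc.temp_field = field
        env = make_env_fields(survey_grid, sc, with_missing=False)
        env.loc[3, ["temp_c", "sal_psu", "depth_m"]] = np.nan
        env.loc[3, "source"] = "missing"
        return env

    def test_no_missing_is_identity(self, survey_grid):
        env = make_env_fields(survey_grid, _scenario([_spec()]), with_missing=False)
        pd.testing.assert_frame_equal(hb.impute_env(env), env)

    def test_nearest_takes_closest_station(self, survey_grid):
        field = lambda la, lo: np.asarray(la, float) + np.asarray(lo, float)
        env = self._env_with_hole(survey_grid, field)
        out = hb.impute_env(env, method="nearest")
        # the hole's nearest measured neighbours are 0.5 degrees away; value
        # must equal one of them exactly
        row = out.loc[3]
        neighbours = env.dropna(subset=["temp_c"])
        d = np.hypot(neighbours["lat"] - row["lat"], neighbours["lon"] - row["lon"])
        assert row["temp_c"] in set(neighbours.loc[d == d.min(), "temp_c"])
        assert row["source"] == "modelled"

    @pytest.mark.parametrize("method", ["idw", "nearest"])
    def test_constant_field_imputes_constant(self, survey_grid, method):
        env = self._env_with_hole(survey_grid, lambda la, lo: np.full_like(np.asarray(la, float), 20.0))
        out = hb.impute_env(env, method=method)
        assert out["temp_c"].notna().all()
        assert out.loc[3, "temp_c"] == pytest.approx(20.0)

    def test_measured_rows_untouched(self, survey_grid):
        env = make_env_fields(survey_grid, _scenario([_spec()], missing=0.2))
        out = hb.impute_env(env)
        measured = env["source"] == "measured"
        pd.testing.assert_frame_equal(out[measured], env[measured])
        assert (out.loc[~measured, "source"] == "modelled").all()
        assert out["temp_c"].notna().all()

    def test_all_missing_factor_rejected(self, survey_grid):
        env = make_env_fields(survey_grid, _scenario([_spec()]), with_missing=False)
        env["temp_c"] = np.nan
        with pytest.raises(ValueError, match="temp"):
            hb.impute_env(env)


def test_generate_survey_is_deterministic():
    scs = hb.default_scenarios(seed=7)
    c1, e1, t1 = hb.generate_survey(scs)
    c2, e2, t2 = hb.generate_survey(hb.default_scenarios(seed=7))
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(e1, e2)
    assert t1 == t2


def test_spec_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        _spec(weight_share={"temp": 0.5, "sal": 0.5, "depth": 0.5})
    with pytest.raises(ValueError, match="q_max"):
        _spec(q_max=0.0)
    with pytest.raises(ValueError, match="zero_inflation"):
        _spec(zero_inflation=1.5)
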