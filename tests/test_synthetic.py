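"""Generator tests: factorial design, response surfaces, noise, CSV I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import photonet as pn
from photonet.errors import ConfigurationError, DomainError, SchemaError
from photonet.synthetic import COLUMNS, FluorSurfaceParams, PnSurfaceParams


# ---------------------------------------------------------------------------
# factorial grid
# ---------------------------------------------------------------------------

class TestFactorialGrid:
    def test_default_design_has_312_combinations(self):
        grid = pn.build_factorial_grid(pn.GeneratorConfig())
        assert len(grid) == 312

    @pytest.mark.parametrize("temps,co2s,pars,expected", [
        ([20], [400], [500], 1),
        ([18, 24], [300, 600, 900], [100, 200, 300, 400], 24),
    ])
    def test_grid_size_is_level_product(self, temps, co2s, pars, expected):
        cfg = pn.GeneratorConfig(temp_levels=temps, co2_levels=co2s,
                                 par_levels=pars)
        assert len(pn.build_factorial_grid(cfg)) == expected

    def test_grid_order_is_tem_outer_par_inner(self):
        cfg = pn.GeneratorConfig(temp_levels=[18, 24], co2_levels=[300, 600],
                                 par_levels=[100, 200])
        assert pn.build_factorial_grid(cfg) == [
            (18, 300, 100), (18, 300, 200), (18, 600, 100), (18, 600, 200),
            (24, 300, 100), (24, 300, 200), (24, 600, 100), (24, 600, 200)]

    @pytest.mark.parametrize("kwargs", [
        {"temp_levels": []},
        {"co2_levels": [600, 300]},
        {"par_levels": [100, 100]},
        {"replicates": 0},
        {"noise_cv": -0.1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            pn.GeneratorConfig(**kwargs)


# ---------------------------------------------------------------------------
# Pn surface
# ---------------------------------------------------------------------------

class TestPnSurface:
    def test_dark_rate_is_negative_respiration(self):
        p = PnSurfaceParams()
        assert pn.pn_surface(25.0, 600.0, 0.0, p) == pytest.approx(-p.r_d)

    def test_negative_light_rejected(self):
        with pytest.raises(DomainError):
            pn.pn_surface(25.0, 600.0, -1.0)

    def test_co2_saturation_limit(self):
        p = PnSurfaceParams()
        lim = pn.pn_surface(28.0, 1e9, 500.0, p)
        # at saturating CO2 the Michaelis-Menten factor approaches 1
        no_co2 = (p.alpha * 500 * (1 - p.beta * 500) / (1 + p.gamma * 500)
                  * np.exp(-(((28 - p.t_opt) / p.t_sigma) ** 2)) - p.r_d)
        assert lim == pytest.approx(no_co2, rel=1e-6)

    def test_light_optimum_near_saturation_point(self):
        # independent oracle: dense 1-unit grid search over the light axis
        par = np.arange(0.0, 1501.0)
        curve = pn.pn_surface(18.0, 600.0, par, PnSurfaceParams())
        argmax = float(par[np.argmax(curve)])
        assert 900.0 <= argmax <= 1100.0

    def test_light_response_regimes(self):
        par = np.arange(0.0, 1501.0)
        curve = pn.pn_surface(18.0, 600.0, par, PnSurfaceParams())
        rising = curve[par <= 300]
        assert np.all(np.diff(rising) > 0), "strict rise on 0-300"
        tail = curve[par >= 1100]
        assert np.all(np.diff(tail) <= 0), "non-increasing on 1100-1500"


# ---------------------------------------------------------------------------
# fluorescence surfaces
# ---------------------------------------------------------------------------

class TestFluorescenceSurface:
    def test_no_excitation_limits(self):
        qp, etr, phips2, fvpfmp, npq, qn = pn.fluorescence_surface(
            25.0, 600.0, 1e-6)
        assert etr == pytest.approx(0.0, abs=1e-6)
        assert npq == pytest.approx(0.0, abs=1e-6)

    def test_etr_identity_absorptance_times_psii_fraction(self, rng):
        params = FluorSurfaceParams()
        for _ in range(20):
            tem = rng.uniform(18, 36)
            co2 = rng.uniform(300, 1200)
            par = rng.uniform(20, 1500)
            _, etr, phips2, _, _, _ = pn.fluorescence_surface(tem, co2, par,
                                                              params)
            assert etr / (phips2 * par) == pytest.approx(0.42, rel=1e-12)

    def test_npq_declines_past_damage_threshold(self):
        params = FluorSurfaceParams()
        at_damage = pn.fluorescence_surface(25.0, 600.0, params.i_damage,
                                            params)[4]
        at_1500 = pn.fluorescence_surface(25.0, 600.0, 1500.0, params)[4]
        assert at_1500 < at_damage

    def test_yield_ordering_and_ranges_across_grid(self):
        cfg = pn.GeneratorConfig()
        grid = np.array(pn.build_factorial_grid(cfg))
        qp, etr, phips2, fvpfmp, npq, qn = pn.fluorescence_surface(
            grid[:, 0], grid[:, 1], grid[:, 2], cfg.fluor_params)
        assert np.all((0 < qp) & (qp <= 1))
        assert np.all(phips2 <= fvpfmp)
        assert np.all(fvpfmp <= 1)
        assert np.all(etr >= 0) and np.all(npq >= 0)

    def test_zero_light_rejected(self):
        with pytest.raises(DomainError):
            pn.fluorescence_surface(25.0, 600.0, 0.0)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

class TestGenerateDataset:
    def test_default_campaign_has_936_records(self, default_dataset):
        assert len(default_dataset) == 936
        cfg = pn.GeneratorConfig()
        assert len(default_dataset) == cfg.grid_size() * cfg.replicates

    def test_record_count_conservation(self):
        cfg = pn.GeneratorConfig(temp_levels=[20, 30], co2_levels=[400],
                                 par_levels=[100, 500, 900], replicates=4)
        assert len(pn.generate_dataset(cfg)) == 2 * 1 * 3 * 4

    def test_zero_noise_makes_replicates_identical(self):
        cfg = pn.GeneratorConfig(noise_cv=0.0, replicates=3)
        frame = pn.generate_dataset(cfg).frame
        groups = frame.groupby(["tem", "co2", "par"]).nunique()
        assert int(groups.drop(columns="rh").max().max()) <= 1

    def test_same_seed_reproduces_dataset_exactly(self):
        a = pn.generate_dataset(pn.GeneratorConfig(seed=7))
        b = pn.generate_dataset(pn.GeneratorConfig(seed=7))
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_different_seeds_differ(self):
        a = pn.generate_dataset(pn.GeneratorConfig(seed=7))
        b = pn.generate_dataset(pn.GeneratorConfig(seed=8))
        assert not a.frame["pn"].equals(b.frame["pn"])

    def test_zero_light_rows_flagged_invalid(self):
        cfg = pn.GeneratorConfig(par_levels=[0, 100, 500])
        frame = pn.generate_dataset(cfg).frame
        dark = frame[frame["par"] == 0]
        lit = frame[frame["par"] > 0]
        assert not dark["valid_fluor"].any()
        assert dark["etr"].isna().all()
        assert lit["valid_fluor"].all()
        assert not lit["etr"].isna().any()

    def test_invariants_hold_under_heavy_noise(self):
        cfg = pn.GeneratorConfig(noise_cv=0.5, seed=3)
        frame = pn.generate_dataset(cfg).frame
        assert frame["qp"].between(0, 1).all()
        assert (frame["phips2"] <= frame["fvpfmp"] + 1e-12).all()
        assert (frame["etr"] >= 0).all()
        assert (frame["npq"] >= 0).all()

    def test_meta_echoes_config_and_seed(self, default_dataset):
        assert default_dataset.meta["seed"] == 0
        assert default_dataset.meta["config"]["replicates"] == 3

    def test_records_accessor_round_trips_rows(self):
        cfg = pn.GeneratorConfig(temp_levels=[20], co2_levels=[400],
                                 par_levels=[100], replicates=2, seed=5)
        ds = pn.generate_dataset(cfg)
        recs = ds.records
        assert len(recs) == 2
        assert recs[0].par == 100.0 and recs[0].valid_fluor


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

class TestDatasetIO:
    def test_round_trip_small_dataset(self, tmp_path):
        cfg = pn.GeneratorConfig(temp_levels=[20], co2_levels=[400],
                                 par_levels=[100], replicates=3, seed=2)
        ds = pn.generate_dataset(cfg)
        path = tmp_path / "d.csv"
        pn.write_dataset(ds, path)
        back = pn.read_dataset(path)
        pd.testing.assert_frame_equal(ds.frame, back.frame,
                                      check_exact=False, rtol=1e-12)
        assert back.meta["seed"] == 2

    def test_default_dataset_writes_936_rows(self, default_dataset, tmp_path):
        path = tmp_path / "d.csv"
        pn.write_dataset(default_dataset, path)
        rows = [l for l in path.read_text().splitlines()
                if l and not l.startswith("#")]
        assert len(rows) == 936 + 1  # header + data

    def test_missing_column_names_offender(self, default_dataset, tmp_path):
        path = tmp_path / "d.csv"
        trimmed = pn.Dataset(default_dataset.frame.drop(columns=["npq"]),
                             default_dataset.meta)
        # bypass write's fixed column list by writing manually
        trimmed.frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="npq"):
            pn.read_dataset(path)

    def test_extra_column_rejected(self, tmp_path):
        frame = pn.generate_dataset(pn.GeneratorConfig(
            temp_levels=[20], co2_levels=[400], par_levels=[100])).frame
        frame["bogus"] = 1.0
        path = tmp_path / "d.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="bogus"):
            pn.read_dataset(path)

    def test_non_numeric_cell_names_column_and_row(self, tmp_path):
        frame = pn.generate_dataset(pn.GeneratorConfig(
            temp_levels=[20], co2_levels=[400], par_levels=[100])).frame
        frame = frame.astype(object)
        frame.loc[1, "pn"] = "oops"
        path = tmp_path / "d.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="pn.*row 1"):
            pn.read_dataset(path)


@given(seed=st.integers(0, 2**31 - 1))
def test_generation_is_deterministic_per_seed(seed):
    cfg = pn.GeneratorConfig(temp_levels=[20], co2_levels=[400],
                             par_levels=[100, 500], replicates=2, seed=seed)
    a = pn.generate_dataset(cfg).frame
    b = pn.generate_dataset(cfg).frame
    pd.testing.assert_frame_equal(a, b)
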