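import numpy as np
import pandas as pd
import pytest

from resburn.attribution import (
    aggregate,
    attribute,
    consistency_check,
    cost_function_J,
    marginal_efficacy,
    per_unit_metrics,
    population_mask,
)
from resburn.diurnal import apply_kernel, build_triangular_kernel
from resburn.synthetic_world import (
    ConcentrationField,
    EmissionInventory,
    PopulationGrid,
    SensitivityField,
    WorldConfig,
    build_adjoint,
    make_emissions,
    make_world,
)


class TestCostFunction:
    def test_constant_field_mean(self):
        chi = ConcentrationField(chi=np.full((5, 3, 3), 7.25))
        pop = PopulationGrid(rho=np.random.default_rng(0).uniform(1, 100, (3, 3)))
        assert cost_function_J(chi, pop).pw_mean == pytest.approx(7.25, rel=1e-12)

    def test_zero_population_mask_rejected(self):
        chi = ConcentrationField(chi=np.ones((2, 3, 3)))
        pop = PopulationGrid(rho=np.ones((3, 3)))
        with pytest.raises(ValueError, match="zero population"):
            cost_function_J(chi, pop, mask=np.zeros((3, 3), dtype=bool))

    def test_random_field_matches_hand_sum(self):
        rng = np.random.default_rng(1)
        chi = rng.uniform(0, 50, (5, 3, 3))
        rho = rng.uniform(0, 1000, (3, 3))
        want = 0.0
        for t in range(5):
            for j in range(3):
                for i in range(3):
                    want += rho[j, i] * chi[t, j, i]
        got = cost_function_J(ConcentrationField(chi=chi), PopulationGrid(rho=rho))
        assert got.total == pytest.approx(want, rel=1e-12)
        assert got.pw_mean == pytest.approx(want / (rho.sum() * 5), rel=1e-12)

    def test_grid_mismatch_rejected(self):
        chi = ConcentrationField(chi=np.ones((2, 3, 3)))
        with pytest.raises(ValueError, match="match"):
            cost_function_J(chi, PopulationGrid(rho=np.ones((4, 4))))


class TestPopulationMask:
    def test_threshold_zero_selects_populated_cells(self):
        rho = np.array([[0.0, 10.0], [5.0, 0.0]])
        mask = population_mask(PopulationGrid(rho=rho), cell_area=1.0, threshold=0.0)
        np.testing.assert_array_equal(mask, rho > 0)

    def test_urban_definition(self, default_world):
        w = default_world
        mask = population_mask(w.pop, w.grid.cell_area, 400.0)
        np.testing.assert_array_equal(mask, w.pop.density(w.grid.cell_area) > 400.0)

    def test_dense_nested_in_urban(self, default_world):
        w = default_world
        urban = population_mask(w.pop, w.grid.cell_area, 400.0)
        dense = population_mask(w.pop, w.grid.cell_area, 1000.0)
        assert (urban | ~dense).all()  # dense subset of urban


class TestAttribute:
    def test_zero_emissions_zero_contribution(self, default_sensitivity, default_hourly):
        E0 = EmissionInventory(
            E=np.zeros_like(default_hourly.E),
            resolution="hourly",
            season_of_day=default_hourly.season_of_day,
        )
        assert attribute(default_sensitivity, E0).total == 0.0

    def test_unit_pulse_reads_off_sensitivity(self, default_sensitivity, default_hourly):
        E = np.zeros_like(default_hourly.E)
        E[100, 2, 1] = 1.0
        inv = EmissionInventory(
            E=E, resolution="hourly", season_of_day=default_hourly.season_of_day
        )
        c = attribute(default_sensitivity, inv)
        assert c.total == pytest.approx(default_sensitivity.S[100, 2, 1], rel=1e-12)

    def test_linearity_exact(self, default_sensitivity, default_hourly):
        rng = np.random.default_rng(2)
        shape = default_hourly.E.shape
        E1, E2 = rng.uniform(0, 2, shape), rng.uniform(0, 2, shape)
        mk = lambda E: EmissionInventory(
            E=E, resolution="hourly", season_of_day=default_hourly.season_of_day
        )
        a, b = 3.0, 0.5
        c12 = attribute(default_sensitivity, mk(a * E1 + b * E2))
        c1 = attribute(default_sensitivity, mk(E1))
        c2 = attribute(default_sensitivity, mk(E2))
        np.testing.assert_allclose(
            c12.delta_P, a * c1.delta_P + b * c2.delta_P, rtol=1e-12
        )

    def test_daily_resolution_rejected(self, default_sensitivity, default_emissions):
        with pytest.raises(ValueError, match="disaggregate"):
            attribute(default_sensitivity, default_emissions)


class TestAggregate:
    @pytest.mark.parametrize("by", ["district", "state", "country", "season", "day"])
    def test_partition_complete(self, default_contribution, default_world, by):
        table = aggregate(default_contribution, default_world.regions, by)
        assert table["delta_P_person_ugm3"].sum() == pytest.approx(
            default_contribution.total, rel=1e-9
        )
        assert table["share_percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_district_gets_all(self, default_world, default_sensitivity, default_hourly):
        w = default_world
        d0 = 3
        cells = w.regions.cells_of("district", d0)
        E = default_hourly.E.copy()
        E[:, ~cells] = 0.0
        inv = EmissionInventory(
            E=E, resolution="hourly", season_of_day=default_hourly.season_of_day
        )
        table = aggregate(attribute(default_sensitivity, inv), w.regions, "district")
        row = table[table["region_id"] == d0]
        assert row["share_percent"].iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_upwind_mega_district_dominates(self):
        """Scaling one upwind district's emissions makes it the top share."""
        w = make_world(WorldConfig(seed=2))
        crops = w.crops.table.copy()
        crops.loc[0, "production"] *= 50.0
        from resburn.synthetic_world import CropTable

        E = make_emissions(
            CropTable(table=crops), w.regions, w.grid, seed=2,
            season_of_day=w.season_of_day,
        )
        S = build_adjoint(w.transport, w.grid, w.pop)
        c = attribute(S, apply_kernel(E, build_triangular_kernel()))
        table = aggregate(c, w.regions, "district").set_index("region_id")
        assert table["share_percent"].idxmax() == 0

    def test_unknown_key_rejected(self, default_contribution, default_world):
        with pytest.raises(ValueError, match="unknown aggregation key"):
            aggregate(default_contribution, default_world.regions, "continent")


class TestPerUnitMetrics:
    def _metrics(self, world, contribution, deaths_total=1000.0):
        agg = aggregate(contribution, world.regions, "district")
        shares = agg.set_index("region_id")["share_percent"] / 100.0
        deaths = pd.DataFrame({"deaths": deaths_total * shares})
        deaths.index.name = "district"
        return per_unit_metrics(agg, world.crops, deaths), deaths

    def test_product_identity(self, default_world, default_contribution):
        metrics, deaths = self._metrics(default_world, default_contribution)
        recon = (
            metrics["emissions_per_production"]
            * metrics["deaths_per_emission"]
            * metrics["production_mt"]
        )
        for d in metrics.index:
            assert recon.loc[d] == pytest.approx(
                deaths.loc[d, "deaths"], rel=1e-6, abs=1e-12
            )

    def test_double_emissions_doubles_x(self, default_world, default_contribution):
        metrics, _ = self._metrics(default_world, default_contribution)
        from resburn.synthetic_world import CropTable

        crops2 = default_world.crops.table.copy()
        crops2["emission_factor"] *= 2.0
        agg = aggregate(default_contribution, default_world.regions, "district")
        deaths = pd.DataFrame(
            {"deaths": np.ones(len(agg))}, index=agg["region_id"].to_numpy()
        )
        deaths.index.name = "district"
        m2 = per_unit_metrics(agg, CropTable(table=crops2), deaths)
        np.testing.assert_allclose(
            m2["emissions_per_production"],
            2.0 * metrics.loc[m2.index, "emissions_per_production"],
            rtol=1e-12,
        )

    def test_zero_production_excluded_with_warning(self, default_world, default_contribution, caplog):
        from resburn.synthetic_world import CropTable

        crops = default_world.crops.table.copy()
        d0 = int(crops.index[0])
        crops.loc[d0, "production"] = 0.0
        metrics, _ = self._metrics(default_world, default_contribution)
        agg = aggregate(default_contribution, default_world.regions, "district")
        deaths = pd.DataFrame(
            {"deaths": np.ones(len(agg))}, index=agg["region_id"].to_numpy()
        )
        deaths.index.name = "district"
        with caplog.at_level("WARNING"):
            m = per_unit_metrics(agg, CropTable(table=crops), deaths)
        assert d0 not in m.index
        assert "zero production" in caplog.text


class TestMarginalEfficacy:
    def test_zero_emission_region_zero(self, default_world, default_contribution):
        # the neighbor country's district burns nothing
        neighbor_district = int(default_world.regions.districts.max())
        eff = marginal_efficacy(
            default_contribution,
            default_world.regions,
            neighbor_district,
            level="district",
        )
        assert eff == 0.0

    def test_share_formula_matches_explicit_rerun(
        self, default_world, default_sensitivity, default_hourly, default_contribution
    ):
        """Scaling a region's emissions by 99% reproduces the linear formula."""
        w = default_world
        sid = int(w.regions.states[0])
        season = "post_monsoon"
        eff = marginal_efficacy(
            default_contribution, w.regions, sid, season=season, level="state"
        )
        cells = w.regions.cells_of("state", sid)
        step_season = np.repeat(np.asarray(default_hourly.season_of_day), 24)
        E = default_hourly.E.copy()
        mask3d = np.zeros_like(E, dtype=bool)
        mask3d[step_season == season] = cells
        E[mask3d] *= 0.99
        inv = EmissionInventory(
            E=E, resolution="hourly", season_of_day=default_hourly.season_of_day
        )
        scaled_total = attribute(default_sensitivity, inv).total
        pct_reduction = 100.0 * (default_contribution.total - scaled_total) / default_contribution.total
        assert pct_reduction == pytest.approx(eff, rel=1e-9, abs=1e-12)

    def test_share_interpretation(self, default_contribution, default_world):
        """A region holding share s of delta_P has efficacy s (% per 1%)."""
        w = default_world
        table = aggregate(default_contribution, w.regions, "state").set_index("region_id")
        for sid in w.regions.states:
            eff = marginal_efficacy(
                default_contribution, w.regions, int(sid), level="state"
            )
            assert eff == pytest.approx(
                table.loc[sid, "share_percent"] / 100.0, rel=1e-9, abs=1e-15
            )


class TestConsistencyCheck:
    def test_zero_emissions_zero_discrepancy(self, default_world, default_hourly):
        E0 = EmissionInventory(
            E=np.zeros_like(default_hourly.E),
            resolution="hourly",
            season_of_day=default_hourly.season_of_day,
        )
        assert consistency_check(default_world, E0) == 0.0

    def test_default_world_below_10_percent(self, default_world, default_hourly):
        assert consistency_check(default_world, default_hourly) <= 0.10

    def test_small_world_machine_precision(self):
        w = make_world(WorldConfig(n_lon=4, n_lat=4, n_days=6, seed=3))
        E = make_emissions(w.crops, w.regions, w.grid, seed=3,
                           season_of_day=w.season_of_day)
        Eh = apply_kernel(E, build_triangular_kernel())
        assert consistency_check(w, Eh) <= 1e-8


class TestInvariants:
    def test_nested_mask_monotonicity(self, default_world, default_hourly):
        w = default_world
        totals = []
        for threshold in (None, 400.0, 1000.0):
            mask = (
                None
                if threshold is None
                else population_mask(w.pop, w.grid.cell_area, threshold)
            )
            S = build_adjoint(w.transport, w.grid, w.pop, mask=mask)
            totals.append(attribute(S, default_hourly).total)
        assert totals[0] >= totals[1] >= totals[2] >= 0

    def test_parameter_recovery_of_injected_share(
        self, default_world, default_sensitivity, default_hourly
    ):
        """Scale district 0 so it holds exactly f of delta_P; recover f."""
        w = default_world
        f = 0.4321
        base = attribute(default_sensitivity, default_hourly)
        table = aggregate(base, w.regions, "district").set_index("region_id")
        p_d = table.loc[0, "delta_P_person_ugm3"]
        rest = base.total - p_d
        s = f * rest / ((1.0 - f) * p_d)
        E = default_hourly.E.copy()
        cells = w.regions.cells_of("district", 0)
        E[:, cells] *= s
        inv = EmissionInventory(
            E=E, resolution="hourly", season_of_day=default_hourly.season_of_day
        )
        table2 = aggregate(
            attribute(default_sensitivity, inv), w.regions, "district"
        ).set_index("region_id")
        assert table2.loc[0, "share_percent"] / 100.0 == pytest.approx(f, abs=1e-6)
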