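"""Serialization round trips, case-fixture integrity, generator, CLI."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from ppealloc import (AllocationPlan, evaluate, load_instance, save_instance,
                      synthetic_instance, wenzhou_case)
from ppealloc.cli import main as cli_main
from ppealloc.data_io import (CASE_CURVE, InstanceFormatError, SyntheticConfig,
                              csv_to_flows, flows_to_csv, flows_to_plan,
                              instance_from_document, instance_to_document,
                              load_solution, plan_to_flows, save_solution,
                              synthetic_distances)
from ppealloc.formulation import build_formulation

from conftest import random_feasible_plan, tiny_instance


# Tables of the case study, transcribed once for integrity checking.
CASE_DEMAND_KKG = {  # (masks, protective clothing), thousands of kg
    "Ruian": (146, 0), "Pingyang": (150, 0), "Cangnan": (165, 0.16),
    "Wencheng": (150, 11.4), "Taishun": (320, 3.04),
}
CASE_RESERVES = {  # masks kkg, clothing kkg, light/medium/heavy vehicles
    "Shiqu": (500, 6, 30, 15, 10),
    "Yongjia": (150, 2, 10, 5, 2),
    "Yueqing": (300, 4, 20, 10, 5),
}
CASE_DCS = {
    "DC1": (800, 10, 50, 25, 12),
    "DC2": (600, 8, 40, 20, 10),
}


class TestCaseFixture:
    def test_demand_table(self, wenzhou):
        for j, area in enumerate(wenzhou.area_ids):
            masks, clothing = CASE_DEMAND_KKG[area]
            assert wenzhou.demand[j, 0] == masks * 1000
            assert wenzhou.demand[j, 1] == clothing * 1000
        assert wenzhou.demand[:, 0].sum() == 931000.0
        assert wenzhou.demand[:, 1].sum() == pytest.approx(14600.0)

    def test_reserve_table(self, wenzhou):
        for h, name in enumerate(wenzhou.reserve_ids):
            masks, clothing, *veh = CASE_RESERVES[name]
            assert wenzhou.ppe_supply[h, 0] == masks * 1000
            assert wenzhou.ppe_supply[h, 1] == clothing * 1000
            assert tuple(wenzhou.vehicle_supply[h]) == tuple(veh)

    def test_dc_table(self, wenzhou):
        for i, name in enumerate(wenzhou.dc_ids):
            masks, clothing, *veh = CASE_DCS[name]
            assert wenzhou.dc_ppe_cap[i, 0] == masks * 1000
            assert wenzhou.dc_ppe_cap[i, 1] == clothing * 1000
            assert tuple(wenzhou.dc_vehicle_cap[i]) == tuple(veh)

    def test_scalar_parameters(self, wenzhou):
        assert tuple(wenzhou.rent) == (800000.0, 600000.0)
        assert tuple(wenzhou.ppe_weight) == (0.6, 0.4)
        assert tuple(wenzhou.vehicle_capacity) == (5000.0, 10000.0, 20000.0)
        assert tuple(wenzhou.unit_cost) == (0.1, 0.2, 0.3)
        assert tuple(wenzhou.unit_time) == (0.06, 0.07, 0.09)
        assert wenzhou.coverage == 150000.0
        for curve in wenzhou.curves:
            assert curve.quad_coeff == pytest.approx(1 / 7315661)
            assert curve.breakpoint == 604800.0
            assert curve.plateau == 50000.0

    def test_seeded_distances_reach_every_area(self):
        for seed in (0, 1, 7):
            inst = wenzhou_case(seed=seed)
            assert inst.distance.shape == (3, 2, 5)
            assert np.all(inst.distance > 0)
            assert np.all(inst.distance.min(axis=(0, 1)) <= inst.coverage)

    def test_explicit_distances_validated(self):
        with pytest.raises(ValueError):
            wenzhou_case(np.zeros((3, 2, 5)))
        with pytest.raises(ValueError):
            wenzhou_case(np.ones((2, 2, 5)))
        with pytest.raises(ValueError):
            wenzhou_case()


class TestInstanceDocuments:
    def test_round_trip_identity(self, wenzhou, tmp_path):
        path = tmp_path / "case.yaml"
        save_instance(wenzhou, path)
        back = load_instance(path)
        assert back.name == wenzhou.name
        assert back.reserve_ids == list(wenzhou.reserve_ids)
        for fld in ("distance", "ppe_weight", "vehicle_capacity",
                    "vehicle_supply", "ppe_supply", "dc_vehicle_cap",
                    "dc_ppe_cap", "demand", "unit_cost", "unit_time", "rent"):
            np.testing.assert_allclose(getattr(back, fld),
                                       getattr(wenzhou, fld), err_msg=fld)
        assert back.coverage == wenzhou.coverage
        assert [c.plateau for c in back.curves] == [
            c.plateau for c in wenzhou.curves]

    def test_missing_entry_names_path(self, wenzhou):
        doc = instance_to_document(wenzhou)
        del doc["demand"]["Ruian"]
        with pytest.raises(InstanceFormatError, match="demand.Ruian"):
            instance_from_document(doc)

    def test_dangling_id_rejected(self, wenzhou):
        doc = instance_to_document(wenzhou)
        doc["demand"]["Atlantis"] = {"masks": 1, "protective_clothing": 1}
        with pytest.raises(InstanceFormatError, match="Atlantis"):
            instance_from_document(doc)

    def test_kilo_kg_units_converted(self, wenzhou):
        doc = instance_to_document(wenzhou)
        doc["units"]["mass"] = "1000kg"
        for table in ("demand", "ppe_supply", "dc_ppe_cap"):
            for row in doc[table].values():
                for key in row:
                    row[key] = row[key] / 1000.0
        inst = instance_from_document(doc)
        assert inst.demand[0, 0] == 146000.0  # declared as 146 in the table
        np.testing.assert_allclose(inst.demand, wenzhou.demand)

    def test_unknown_unit_rejected(self, wenzhou):
        doc = instance_to_document(wenzhou)
        doc["units"]["mass"] = "stone"
        with pytest.raises(InstanceFormatError, match="unit"):
            instance_from_document(doc)


class TestSyntheticGenerator:
    def test_same_seed_same_instance(self):
        cfg = SyntheticConfig(seed=5)
        a, b = synthetic_instance(cfg), synthetic_instance(cfg)
        np.testing.assert_array_equal(a.distance, b.distance)
        np.testing.assert_array_equal(a.demand, b.demand)
        np.testing.assert_array_equal(a.ppe_supply, b.ppe_supply)

    @pytest.mark.parametrize("rho", [0.5, 0.8, 1.2])
    def test_supply_tracks_shortage_ratio(self, rho):
        inst = synthetic_instance(SyntheticConfig(shortage_ratio=rho, seed=2))
        per_ppe_supply = inst.ppe_supply.sum(axis=0)
        per_ppe_demand = inst.demand.sum(axis=0)
        np.testing.assert_allclose(per_ppe_supply, rho * per_ppe_demand,
                                   rtol=1e-9)

    def test_small_region_keeps_all_paths_reachable(self):
        cfg = SyntheticConfig(region=5000.0, coverage=150000.0, seed=3)
        form = build_formulation(synthetic_instance(cfg))
        assert all(v.ub > 0 for v in form.variables if v.symbol == "x")

    def test_shortage_forces_unmet_demand_at_loss_optimum(self):
        """With supply < demand, even the loss-optimal plan leaves a gap."""
        from ppealloc import improved_solve
        inst = tiny_instance(190)  # shortage_ratio 0.8 by default
        form = build_formulation(inst)
        res = improved_solve(form)
        delivered = res.plan.shipped.sum()
        assert delivered < inst.demand.sum() - 1e-6

    def test_distance_generator_is_positive_and_covering(self):
        D = synthetic_distances(n_reserves=2, n_dcs=2, n_areas=3,
                                region=50000.0, road_factor=1.2,
                                coverage=150000.0, seed=9)
        assert np.all(D > 0)
        assert np.all(D.min(axis=(0, 1)) <= 150000.0)


class TestSolutionDocuments:
    def test_flow_round_trip_preserves_objectives(self, tmp_path):
        rng = np.random.default_rng(21)
        inst = tiny_instance(191)
        plan = random_feasible_plan(inst, rng, open_all=True)
        obj = evaluate(inst, plan)

        flows = plan_to_flows(inst, plan)
        csv_path = tmp_path / "flows.csv"
        flows_to_csv(flows, csv_path)
        open_dcs = [inst.dc_ids[i]
                    for i in np.nonzero(plan.open_dc > 0.5)[0]]
        back = flows_to_plan(inst, csv_to_flows(csv_path), open_dcs)
        obj2 = evaluate(inst, back)
        assert obj2.total_loss == pytest.approx(obj.total_loss, rel=1e-9)
        assert obj2.logistics_cost == pytest.approx(obj.logistics_cost,
                                                    rel=1e-9)

    def test_solution_document_round_trip(self, tmp_path):
        rng = np.random.default_rng(22)
        inst = tiny_instance(192)
        plan = random_feasible_plan(inst, rng)
        path = tmp_path / "solution.yaml"
        save_solution(path, inst, plan, meta={"note": "test"})
        back, doc = load_solution(path, inst)
        assert doc["meta"]["note"] == "test"
        np.testing.assert_allclose(back.vehicles, plan.vehicles)


class TestCLI:
    def test_bounds_reports_worst_case_loss(self, tmp_path):
        runner = CliRunner()
        case = tmp_path / "case.yaml"
        save_instance(wenzhou_case(seed=1), case)
        result = runner.invoke(cli_main, ["bounds", str(case),
                                          "--node-limit", "150"])
        assert result.exit_code == 0, result.output
        assert "2.8222e+10" in result.output

    def test_solve_zero_demand_gives_empty_plan(self, tmp_path):
        runner = CliRunner()
        inst = tiny_instance(193)
        inst.demand[:] = 0.0
        path = tmp_path / "inst.yaml"
        save_instance(inst, path)
        out = tmp_path / "sol.yaml"
        result = runner.invoke(cli_main, ["solve", str(path),
                                          "--out", str(out)])
        assert result.exit_code == 0, result.output
        plan, doc = load_solution(out, inst)
        assert plan.vehicles.sum() == 0
        assert doc["objectives"]["total_loss"] == pytest.approx(0.0)
        assert doc["objectives"]["logistics_cost"] == pytest.approx(0.0)

    def test_validate_flags_tampered_plan(self, tmp_path):
        runner = CliRunner()
        inst = tiny_instance(194)
        ipath = tmp_path / "inst.yaml"
        save_instance(inst, ipath)
        plan = AllocationPlan.zero(inst)
        plan.vehicles[0, 0, 0, 0] = 999  # far above any supply
        spath = tmp_path / "sol.yaml"
        save_solution(spath, inst, plan)
        result = runner.invoke(cli_main, ["validate", str(ipath), str(spath)])
        assert result.exit_code == 1

    def test_generate_writes_loadable_instance(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "gen.yaml"
        result = runner.invoke(cli_main, ["--seed", "3", "generate",
                                          "--out", str(out)])
        assert result.exit_code == 0, result.output
        inst = load_instance(out)
        assert inst.n_areas == 5

    def test_usage_error_exits_2(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["solve", "/no/such/file.yaml"])
        assert result.exit_code == 2

    def test_pareto_writes_csv(self, tmp_path):
        import pandas as pd
        runner = CliRunner()
        inst = tiny_instance(195)
        ipath = tmp_path / "inst.yaml"
        save_instance(inst, ipath)
        out = tmp_path / "pareto.csv"
        result = runner.invoke(cli_main, ["pareto", str(ipath),
                                          "--mults", "1,2",
                                          "--out", str(out)])
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out)
        assert len(table) == 2
        assert table["min_G2"].iloc[0] >= table["min_G2"].iloc[1] - 1e-6
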