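"""Experiment drivers: grid-study arithmetic, sweeps, reference-table checks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from aneuflow.case import CaseConfig
from aneuflow.experiments import (REFERENCE_GRID_SIZES_MM, REFERENCE_GRID_WSS,
                                  SweepSpec, grid_study_rows, percent_change,
                                  run_grid_study, run_sweep, table1_consistency,
                                  trend_check)
from aneuflow.geometry import GeometryParams
from aneuflow.indices import report as indices_report
from aneuflow.solver import SolverConfig, run_transient


class TestPercentChange:
    @pytest.mark.parametrize("prev,cur,expect", [
        (12.73, 14.97, 17.59),
        (14.97, 15.84, 5.81),
        (15.84, 15.88, 0.25),
        (10.0, 10.0, 0.0),
    ])
    def test_truncated_two_decimals(self, prev, cur, expect):
        assert percent_change(prev, cur) == expect

    def test_truncation_not_rounding(self):
        # 17.596... must truncate to 17.59, not round to 17.60
        assert percent_change(12.73, 14.97) == 17.59
        assert round(100 * (14.97 - 12.73) / 12.73, 2) == 17.60

    def test_nonpositive_previous_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
        with pytest.raises(ValueError):
            percent_change(-2.0, 1.0)


class TestGridStudyRows:
    def test_reference_wss_column_reproduced(self):
        rows = grid_study_rows(REFERENCE_GRID_WSS, REFERENCE_GRID_SIZES_MM)
        assert [r.change_pct for r in rows] == [None, 17.59, 5.81, 0.25]
        # the first sub-1% grid is selected
        assert [r.selected for r in rows] == [False, False, False, True]

    def test_identical_rows_select_first_refinement(self):
        rows = grid_study_rows([5.0, 5.0], [0.4, 0.2])
        assert rows[1].change_pct == 0.0
        assert rows[1].selected


class TestRunGridStudy:
    def test_input_validation(self):
        case = CaseConfig()
        with pytest.raises(ValueError):
            run_grid_study(case, [0.4e-3])
        with pytest.raises(ValueError):
            run_grid_study(case, [0.3e-3, 0.4e-3])

    def test_two_size_study_runs_and_reports(self):
        case = CaseConfig(
            geometry=GeometryParams(mesh_size=0.6e-3),
            solver=SolverConfig(dt=0.01, cycles=1, snapshot_stride=4))
        rows = run_grid_study(case, [0.6e-3, 0.45e-3])
        assert len(rows) == 2
        assert rows[1].n_elements > rows[0].n_elements
        assert rows[0].change_pct is None
        assert isinstance(rows[1].change_pct, float)
        assert all(r.avg_wss_sac > 0 for r in rows)


class TestSweep:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SweepSpec(hematocrits=())
        with pytest.raises(ValueError):
            SweepSpec(porosities=(0.0,))
        with pytest.raises(ValueError):
            SweepSpec(hematocrits=(1.5,))

    def test_single_cell_matches_direct_run_bitwise(self):
        base = CaseConfig(geometry=GeometryParams(mesh_size=0.6e-3),
                          solver=SolverConfig(dt=0.01, cycles=1,
                                              snapshot_stride=4))
        spec = SweepSpec(hematocrits=(0.40,), porosities=(1.0,), base_case=base)
        df = run_sweep(spec)
        assert len(df) == 1 and df.loc[0, "status"] == "ok"
        case = base.with_(hematocrit=0.40, porosity=1.0)
        traj = run_transient(case)
        rep = indices_report(traj, rheology=case.rheology_params())
        sac = rep.region_stats["WALL_SAC"]
        assert df.loc[0, "avg_osi_sac"] == sac["avg_osi"]
        assert df.loc[0, "avg_tawss_sac"] == sac["avg_tawss"]
        assert df.loc[0, "max_pressure_sac_systole"] == sac["max_pressure_peak_systole"]

    def test_default_sweep_invariants(self, sweep_results):
        df, _ = sweep_results
        assert len(df) == 9
        assert (df["status"] == "ok").all()
        assert ((df["max_osi_sac"] >= 0) & (df["max_osi_sac"] <= 0.5)).all()
        assert (df["avg_osi_sac"] <= df["max_osi_sac"] + 1e-15).all()
        assert (df["avg_tawss_sac"] > 0).all()


class TestTrendCheck:
    def test_pass_and_warn_logic(self):
        df = pd.DataFrame({
            "hct": [0.4, 0.4], "porosity": [0.75, 1.0],
            "avg_osi_sac": [0.02, 0.01]})
        assert trend_check(df)["status"] == "pass"
        df2 = df.assign(avg_osi_sac=[0.01, 0.02])
        assert trend_check(df2)["status"] == "warn"

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"hct": [0.4], "porosity": [0.85],
                           "avg_osi_sac": [0.01]})
        with pytest.raises(ValueError):
            trend_check(df)


def test_table1_consistency_all_match():
    out = table1_consistency()
    assert out["all_match"]
    assert out["coil"]["porosity"] == pytest.approx(0.8536, abs=2e-4)
    recips = [r["reciprocal_3sf"] for r in out["rows"]]
    assert recips == [pytest.approx(2.70e7), pytest.approx(1.85e7)]
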