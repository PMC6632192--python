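"""Supply side: activity rate, graduate pipeline, register diff, stock projection."""

import datetime

import numpy as np
import pytest

import oralforce as of
from oralforce.errors import DataError


def entry(rid, yq=2000, origin="domestic", reg_year=None):
    return of.RegisterEntry(
        registrant_id=rid,
        date_registered=datetime.date(reg_year or max(yq, 2005), 6, 1),
        year_qualified=yq,
        qualification_origin=origin,
    )


class TestActivityRate:
    @pytest.mark.parametrize(
        "share,fraction,expected",
        [
            (0.30, 0.50, 0.85),  # 30% part-time at half hours
            (0.0, 0.7, 1.0),  # no part-time workers
            (1.0, 1.0, 1.0),  # part-time at full hours is full-time
            (0.5, 0.0, 0.5),
        ],
    )
    def test_values(self, share, fraction, expected):
        assert of.activity_rate(share, fraction) == pytest.approx(expected)

    @pytest.mark.parametrize("share,fraction", [(-0.1, 0.5), (0.5, 1.2), (2, 0)])
    def test_rejects_out_of_range(self, share, fraction):
        with pytest.raises(ValueError):
            of.activity_rate(share, fraction)


class TestGraduatePipeline:
    def test_pipeline_discounting(self):
        # 100 x 0.9 x 0.95 x 0.8 by hand
        p = of.GraduatePipeline(100, 0.10, 0.05, 0.80)
        assert of.new_graduates(p) == pytest.approx(68.4)

    def test_total_attrition_and_empty_cohort(self):
        assert of.new_graduates(of.GraduatePipeline(100, attrition_rate=1.0)) == 0
        assert of.new_graduates(of.GraduatePipeline(0)) == 0

    def test_cohort_arrival_year(self):
        p = of.GraduatePipeline(50, course_length=5)
        assert of.graduate_arrival_year(p, 2017) == 2022


class TestDiffRegisters:
    def test_identical_snapshots_give_zero_flows(self):
        snap = of.RegisterSnapshot(2017, (entry("A"), entry("B")))
        later = of.RegisterSnapshot(2018, snap.entries)
        est = of.diff_registers(snap, later)
        assert est.total_inflow == 0 and est.total_outflow == 0

    def test_set_difference_classification(self):
        earlier = of.RegisterSnapshot(2017, (entry("A"), entry("B")))
        later = of.RegisterSnapshot(
            2018, (entry("B"), entry("C", yq=2010, origin="foreign", reg_year=2018))
        )
        est = of.diff_registers(earlier, later)
        assert est.inflow_foreign_trained == 1
        assert est.inflow_new_graduates == 0
        assert est.inflow_returning_domestic == 0
        assert est.total_outflow == 1

    def test_newly_qualified_domestic_is_graduate_inflow(self):
        earlier = of.RegisterSnapshot(2017, (entry("A"),))
        later = of.RegisterSnapshot(
            2018,
            (entry("A"), entry("G", yq=2018, reg_year=2018), entry("R", yq=1995, reg_year=2018)),
        )
        est = of.diff_registers(earlier, later)
        assert est.inflow_new_graduates == 1
        assert est.inflow_returning_domestic == 1

    def test_conservation(self):
        earlier = of.RegisterSnapshot(2017, tuple(entry(f"E{i}") for i in range(20)))
        later = of.RegisterSnapshot(
            2018,
            tuple(entry(f"E{i}") for i in range(15))
            + tuple(entry(f"N{i}", yq=2018, reg_year=2018) for i in range(7)),
        )
        est = of.diff_registers(earlier, later)
        assert est.n_later == est.n_earlier + est.total_inflow - est.total_outflow

    def test_retirement_heuristic_splits_old_qualifiers(self):
        old = entry("OLD", yq=1970, reg_year=1975)
        young = entry("YNG", yq=2005)
        earlier = of.RegisterSnapshot(2017, (old, young, entry("K")))
        later = of.RegisterSnapshot(2018, (entry("K"),))
        est = of.diff_registers(earlier, later, retirement_heuristic=True)
        assert est.outflow_retirement_estimate == 1  # qualified 48 years before 2018
        assert est.outflow_unclassified == 1
        assert est.total_outflow == 2

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            of.RegisterSnapshot(2017, (entry("A"), entry("A")))

    def test_wrong_year_order_rejected(self):
        snap = of.RegisterSnapshot(2018, (entry("A"),))
        with pytest.raises(ValueError, match="precede"):
            of.diff_registers(snap, of.RegisterSnapshot(2017, (entry("A"),)))


class TestProjectStock:
    def test_zero_flows_constant_stock(self):
        series = of.project_stock(3053, None, None, range(2017, 2051))
        assert (series == 3053).all()

    def test_hand_recursion_net_plus_ten(self):
        flows = of.FlowAssumptions(inflow_foreign_trained=15, outflow_emigration=5)
        series = of.project_stock(100, flows, None, [2020, 2021, 2022])
        assert list(series) == [110, 120, 130]

    def test_floor_at_zero_with_warning(self, caplog):
        flows = of.FlowAssumptions(outflow_emigration=80)
        with caplog.at_level("WARNING"):
            series = of.project_stock(100, flows, None, [2020, 2021])
        assert list(series) == [20, 0]
        assert any("floor" in r.message for r in caplog.records)

    def test_carry_forward_of_last_specified_year(self):
        flows = {
            2020: of.FlowAssumptions(inflow_foreign_trained=10),
            2022: of.FlowAssumptions(outflow_emigration=5),
        }
        series = of.project_stock(100, flows, None, range(2020, 2024))
        # +10, +10 (carried), -5, -5 (carried)
        assert list(series) == [110, 120, 115, 110]

    def test_missing_carry_forward_is_config_error(self):
        flows = {2025: of.FlowAssumptions()}
        with pytest.raises(of.ConfigurationError, match="2020"):
            of.project_stock(100, flows, None, [2020])

    def test_graduate_inflow_joins_stock(self):
        p = of.GraduatePipeline(100, 0.10, 0.05, 0.80)
        series = of.project_stock(1000, None, p, [2020, 2021])
        assert list(series) == pytest.approx([1068.4, 1136.8])

    def test_conservation_invariant(self):
        flows = {2020: of.FlowAssumptions(inflow_foreign_trained=12.5, outflow_absence=3.25)}
        p = of.GraduatePipeline(40, 0.05, 0.02, 0.9)
        series = of.project_stock(500, flows, p, range(2020, 2050))
        net = 12.5 - 3.25 + of.new_graduates(p)
        diffs = np.diff(np.concatenate([[500], series.to_numpy()]))
        assert np.allclose(diffs, net, atol=1e-9)

    def test_round_trip_with_negated_flows(self):
        fwd = of.FlowAssumptions(inflow_foreign_trained=30, outflow_emigration=12)
        back = of.FlowAssumptions(inflow_foreign_trained=12, outflow_emigration=30)
        up = of.project_stock(200, fwd, None, range(2020, 2025))
        down = of.project_stock(float(up.iloc[-1]), back, None, range(2025, 2030))
        assert float(down.iloc[-1]) == pytest.approx(200, abs=1e-9)

    def test_empty_horizon_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            of.project_stock(100, None, None, [])


class TestFteSupply:
    def test_participation_and_activity(self):
        params = of.SupplyParams(0.95, 0.30, 0.50)
        assert of.fte_supply(1000, params) == pytest.approx(807.5)

    def test_identity_when_full_participation_full_time(self):
        params = of.SupplyParams(1.0, 0.0, 0.5)
        assert of.fte_supply(1234.5, params) == 1234.5

    def test_zero_stock(self):
        assert of.fte_supply(0, of.SupplyParams()) == 0

    def test_never_exceeds_stock(self):
        params = of.SupplyParams(0.99, 0.1, 0.9)
        assert of.fte_supply(500, params) <= 500
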