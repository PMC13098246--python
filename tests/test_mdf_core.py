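"""MDF linear program: bound rules, closed forms and grid-search oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from fermdf.mdf_core import (
    BoundEntry,
    ConcentrationBounds,
    bounds_from_measurements,
    cumulative_profile,
    mdf_timecourse,
    solve_mdf,
)
from fermdf.pathway_model import reaction_drg
from fermdf.quantification import FermentationDataset
from fermdf.synthetic_data import GeneratorConfig, generate

from conftest import fixed_bounds, grid_search_mdf, make_chain, random_small_network

RT298 = 8.3145e-3 * 298.15


class TestBoundsFromMeasurements:
    def test_measured_value_fixes_both_bounds(self):
        b = bounds_from_measurements({"pep": 5.0})
        e = b.entry("pep")
        assert (e.lower, e.upper, e.source) == (5e-3, 5e-3, "measured_fixed")

    def test_absent_metabolite_gets_default_box(self):
        b = bounds_from_measurements({})
        e = b.entry("bpg")
        assert (e.lower, e.upper, e.source) == (1e-6, 0.1, "free_default")

    def test_zero_measurement_pinned_at_floor(self):
        b = bounds_from_measurements({"f6p": 0.0})
        e = b.entry("f6p")
        assert (e.lower, e.upper, e.source) == (1e-6, 1e-6, "measured_zero")

    def test_zero_measurement_free_ceiling_mode(self):
        b = bounds_from_measurements({"f6p": 0.0}, zero_measured="free_ceiling")
        e = b.entry("f6p")
        assert (e.lower, e.upper) == (1e-6, 0.1)

    def test_measurement_above_default_ceiling_kept(self):
        b = bounds_from_measurements({"pyr": 150.0})
        e = b.entry("pyr")
        assert e.lower == e.upper == pytest.approx(0.15)

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValueError):
            bounds_from_measurements({"pep": -1.0})

    def test_nan_measurement_treated_as_absent(self):
        b = bounds_from_measurements({"pep": float("nan")})
        assert b.entry("pep").source == "free_default"

    def test_empty_box_rejected(self):
        with pytest.raises(ValueError):
            BoundEntry(1e-3, 1e-4)


class TestSolveMdfClosedForms:
    def test_single_reaction_all_fixed(self):
        net, th = make_chain([-10.0])
        res = solve_mdf(net, th, fixed_bounds({"m0": 1e-3, "m1": 1e-3}))
        assert res.mdf == pytest.approx(10.0, abs=1e-6)
        assert res.bottlenecks == {"R0"}
        assert res.feasible_flag

    def test_single_free_reaction_span_closed_form(self):
        net, th = make_chain([0.0])
        res = solve_mdf(net, th, ConcentrationBounds())
        assert res.mdf == pytest.approx(RT298 * math.log(1e5), abs=1e-6)

    def test_equalization_chain(self):
        # A→B→C, ΔrG′°=0 each, ends fixed at 1 mM: optimum equalizes both
        net, th = make_chain([0.0, 0.0])
        bounds = fixed_bounds({"m0": 1e-3, "m2": 1e-3})
        res = solve_mdf(net, th, bounds)
        assert res.mdf == pytest.approx(0.0, abs=1e-6)
        assert res.bottlenecks == {"R0", "R1"}
        assert math.exp(res.ln_conc["m1"]) == pytest.approx(1e-3, rel=1e-4)

    def test_all_fixed_chain_min_rule(self):
        net, th = make_chain([-30.0, 5.0, -30.0])
        res = solve_mdf(net, th, fixed_bounds({f"m{i}": 1e-3 for i in range(4)}))
        assert res.mdf == pytest.approx(-5.0, abs=1e-6)
        assert res.bottlenecks == {"R1"}
        assert not res.feasible_flag

    def test_single_reaction_closed_form_with_asymmetric_box(self):
        # one reaction, both metabolites free: mdf = −ΔrG′° + RT·ln(hi0/lo1)
        net, th = make_chain([3.0])
        bounds = ConcentrationBounds(entries={
            "m0": BoundEntry(1e-5, 1e-2), "m1": BoundEntry(1e-4, 1e-1)})
        res = solve_mdf(net, th, bounds)
        expected = -3.0 + RT298 * (math.log(1e-2) - math.log(1e-4))
        assert res.mdf == pytest.approx(expected, abs=1e-6)


class TestSolveMdfProperties:
    def test_constraint_audit_on_every_solve(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            net, th, bounds, _ = random_small_network(rng)
            res = solve_mdf(net, th, bounds)
            for rid, drg in res.drg.items():
                assert -drg >= res.mdf - 1e-6
            for m, x in res.ln_conc.items():
                e = bounds.entry(m)
                assert math.log(e.lower) - 1e-9 <= x <= math.log(e.upper) + 1e-9

    def test_all_fixed_equals_direct_minimum(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(2, 6))
            net, th = make_chain(rng.normal(0, 10, n).tolist())
            conc = {f"m{i}": float(rng.uniform(1e-6, 1e-1)) for i in range(n + 1)}
            res = solve_mdf(net, th, fixed_bounds(conc))
            direct = min(-reaction_drg(r, th, conc) for r in net.reactions)
            assert res.mdf == pytest.approx(direct, abs=1e-6)

    def test_widening_bounds_never_decreases_mdf(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            net, th, bounds, _ = random_small_network(rng)
            base = solve_mdf(net, th, bounds).mdf
            met = f"m{int(rng.integers(0, len(net.metabolites)))}"
            e = bounds.entry(met)
            widened = bounds.with_entry(met, BoundEntry(
                e.lower / float(rng.uniform(1.5, 10)),
                e.upper * float(rng.uniform(1.5, 10)), "user"))
            assert solve_mdf(net, th, widened).mdf >= base - 1e-7

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(12):
            net, th, bounds, free_boxes = random_small_network(rng)
            lp = solve_mdf(net, th, bounds).mdf
            grid = grid_search_mdf(net, th, bounds, free_boxes)
            assert lp == pytest.approx(grid, abs=0.05)


class TestCumulativeProfile:
    def test_reference_profile_at_one_millimolar(self):
        net, th = make_chain([-3.0, 7.0])
        prof = cumulative_profile(net, th)  # 1 mM, net molecularity 0 per step
        assert [p[0] for p in prof] == ["R0", "R1"]
        assert prof[0][1] == pytest.approx(-3.0)
        assert prof[1][1] == pytest.approx(4.0)

    def test_last_value_is_total_gibbs_change(self, eco_network, eco_thermo):
        conc = {m: 1e-3 for m in eco_network.metabolite_ids}
        prof = cumulative_profile(eco_network, eco_thermo, conc)
        total = sum(reaction_drg(r, eco_thermo, conc)
                    for r in eco_network.reactions)
        assert prof[-1][1] == pytest.approx(total, abs=1e-9)

    def test_accepts_mdf_result_optimum(self):
        net, th = make_chain([0.0, 0.0])
        res = solve_mdf(net, th, fixed_bounds({"m0": 1e-3, "m2": 1e-3}))
        prof = cumulative_profile(net, th, res)
        # at the optimum each step contributes −mdf
        assert prof[-1][1] == pytest.approx(-2 * res.mdf, abs=1e-6)


class TestMdfTimecourse:
    def _dataset_all_absent(self, n=5):
        t = np.linspace(0, 8, n)
        return FermentationDataset(
            time_h=t, od=pd.Series(np.ones(n)),
            extracellular=pd.DataFrame(index=range(n)),
            intracellular_mm=pd.DataFrame(index=range(n)))

    def test_no_data_flagged_skipped(self, eco_network, eco_thermo):
        tc = mdf_timecourse(eco_network, eco_thermo, self._dataset_all_absent())
        assert all(r is None for r in tc.results)
        assert tc.to_frame()["skipped"].all()

    def test_resolving_at_optimum_is_idempotent(self, eco_network, eco_thermo):
        free = solve_mdf(eco_network, eco_thermo, ConcentrationBounds())
        measured = {m: c * 1e3 for m, c in free.concentrations_m.items()}
        again = solve_mdf(eco_network, eco_thermo,
                          bounds_from_measurements(measured))
        assert again.mdf == pytest.approx(free.mdf, abs=1e-5)

    def test_timecourse_tracks_injected_decline(self, eco_network, eco_thermo):
        ds, gt = generate(GeneratorConfig(seed=5))
        tc = mdf_timecourse(eco_network, eco_thermo, ds)
        series = tc.mdf_series
        late = series[series.index > gt.t_production_end]
        early = series[(series.index > 2) & (series.index <= gt.t_growth_end)]
        assert late.abs().max() < 2.0         # near equilibrium after cessation
        assert early.min() > 2.0              # comfortably feasible while growing
        for i, r in enumerate(tc.results):
            if r is not None and ds.time_h[i] > gt.t_production_end:
                assert gt.bottleneck_id in r.bottlenecks
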