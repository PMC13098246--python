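"""Synthetic fermentation generator: determinism, invariants, calibration."""

import numpy as np
import pytest

from fermdf.quantification import (
    CELL_PARAMS,
    fit_calibration,
    intracellular_volume,
    peak_to_concentration,
)
from fermdf.synthetic_data import (
    CalibrationConfig,
    GeneratorConfig,
    emit_peak_areas,
    generate,
)


class TestGenerate:
    def test_same_seed_identical_outputs(self):
        a, _ = generate(GeneratorConfig(seed=42))
        b, _ = generate(GeneratorConfig(seed=42))
        assert np.array_equal(a.time_h, b.time_h)
        assert a.od.equals(b.od)
        assert a.extracellular.equals(b.extracellular)
        assert a.intracellular_mm.equals(b.intracellular_mm)

    def test_different_seeds_differ(self):
        a, _ = generate(GeneratorConfig(seed=1))
        b, _ = generate(GeneratorConfig(seed=2))
        assert not a.intracellular_mm.equals(b.intracellular_mm)

    def test_zero_noise_emits_ground_truth(self):
        cfg = GeneratorConfig(seed=3, noise_cv=0.0)
        ds, gt = generate(cfg)
        truth = gt.true_concentrations_mm[ds.intracellular_mm.columns]
        assert np.allclose(ds.intracellular_mm.to_numpy(),
                           truth.to_numpy(), rtol=1e-12)

    def test_unmeasured_metabolites_masked(self):
        cfg = GeneratorConfig(seed=0)
        ds, gt = generate(cfg)
        assert not (set(ds.intracellular_mm.columns) & cfg.unmeasured)
        assert set(gt.true_concentrations_mm.columns) >= set(
            ds.intracellular_mm.columns)

    def test_substrate_remains_at_horizon(self):
        ds, _ = generate(GeneratorConfig(seed=4))
        assert (ds.extracellular["glc"] > 0).all()

    def test_carbon_balance_bound(self):
        # ethanol produced ≤ 2 × glucose consumed (mol/mol) at every point
        ds, _ = generate(GeneratorConfig(seed=6, noise_cv_ext=0.0))
        consumed = ds.extracellular["glc"].iloc[0] - ds.extracellular["glc"]
        assert (ds.extracellular["etoh"] <= 2 * consumed + 1e-9).all()

    def test_injected_min_driving_force_decays(self):
        ds, gt = generate(GeneratorConfig(seed=8))
        t_pe = gt.t_production_end
        at_pe = gt.true_min_driving_force.loc[t_pe]
        assert at_pe <= 1.0
        growth = gt.true_min_driving_force[
            gt.true_min_driving_force.index <= gt.t_growth_end]
        assert growth.min() > 2.0

    def test_bottleneck_not_in_network_rejected(self):
        with pytest.raises(ValueError, match="not in network"):
            generate(GeneratorConfig(bottleneck_reaction="NOPE"))

    def test_fully_masked_bottleneck_rejected(self):
        cfg = GeneratorConfig(unmeasured=frozenset(
            {"pep", "adp", "pyr", "atp"}))
        with pytest.raises(ValueError, match="undetectable"):
            generate(cfg)

    def test_phase_times_validated(self):
        with pytest.raises(ValueError):
            generate(GeneratorConfig(t_growth_end=50, t_production_end=40))

    def test_phase_labels_match_boundaries(self):
        ds, gt = generate(GeneratorConfig(seed=9))
        lab = gt.true_phase_labels
        t = ds.time_h
        assert all(lab[i] == "growth_coupled" for i in range(len(t))
                   if t[i] <= gt.t_growth_end)
        assert all(lab[i] == "no_production" for i in range(len(t))
                   if t[i] > gt.t_production_end)


class TestEmitPeakAreas:
    def test_zero_noise_round_trip_exact(self):
        cfg = GeneratorConfig(
            seed=11, noise_cv=0.0, noise_cv_od=0.0,
            calibration=CalibrationConfig(noise_cv=0.0))
        ds, _ = generate(cfg)
        areas, standards, curves = emit_peak_areas(ds, cfg)
        params = CELL_PARAMS[cfg.organism]
        for met in areas.columns:
            for i in (0, 10, 24):
                icv = intracellular_volume(float(ds.od.iloc[i]),
                                           float(ds.filtered_volume_ml.iloc[i]),
                                           params)
                back = peak_to_concentration(areas.iloc[i][met], curves[met], icv)
                assert back == pytest.approx(ds.intracellular_mm.iloc[i][met],
                                             rel=1e-9)

    def test_intercept_only_areas_give_zero(self):
        cal_cfg = CalibrationConfig(noise_cv=0.0)
        cfg = GeneratorConfig(seed=12, calibration=cal_cfg)
        ds, _ = generate(cfg)
        _, _, curves = emit_peak_areas(ds, cfg)
        met = next(iter(curves))
        assert peak_to_concentration(curves[met].intercept, curves[met],
                                     1e-3) == 0.0

    def test_standards_table_shape(self):
        cfg = GeneratorConfig(seed=13)
        ds, _ = generate(cfg)
        _, standards, _ = emit_peak_areas(ds, cfg)
        counts = standards.groupby("metabolite").size()
        assert (counts == cfg.calibration.n_standards).all()
        assert set(counts.index) == set(ds.intracellular_mm.columns)

    def test_ols_recovers_slope_on_average(self):
        # 5 standards at 5 % multiplicative noise: the OLS slope estimate is
        # unbiased, so its average over many draws sits within 2 % of truth
        rng = np.random.default_rng(99)
        slope, intercept = 3e13, 200.0
        amounts = np.linspace(1e-9, 5e-9, 5)
        estimates = []
        for _ in range(400):
            noise = np.exp(rng.normal(-0.5 * np.log(1.0025), np.sqrt(np.log(1.0025)),
                                      5))
            areas = slope * amounts * noise + intercept
            estimates.append(fit_calibration("x", amounts, areas).slope)
        assert np.mean(estimates) == pytest.approx(slope, rel=0.02)

    def test_measurement_round_trip_within_noise(self):
        # concentration → noisy peak area → concentration: at CV ≤ 10 % the
        # median relative error over many draws stays below 10 %
        cfg = GeneratorConfig(
            seed=17, noise_cv=0.0, noise_cv_od=0.0,
            calibration=CalibrationConfig(noise_cv=0.10, intercept_range=(0, 0)))
        ds, _ = generate(cfg)
        params = CELL_PARAMS[cfg.organism]
        rel_errors = []
        for rep in range(8):
            areas, _, curves = emit_peak_areas(ds, cfg, seed=1000 + rep)
            for met in list(areas.columns)[:5]:
                for i in range(0, ds.n_timepoints, 5):
                    icv = intracellular_volume(
                        float(ds.od.iloc[i]),
                        float(ds.filtered_volume_ml.iloc[i]), params)
                    back = peak_to_concentration(areas.iloc[i][met],
                                                 curves[met], icv)
                    truth = ds.intracellular_mm.iloc[i][met]
                    rel_errors.append(abs(back - truth) / truth)
        assert len(rel_errors) >= 100
        assert np.median(rel_errors) < 0.10
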