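"""Synthetic batch-fermentation datasets with thermodynamic ground truth.

The generator emulates the *shapes* of high-substrate batch ethanol
fermentations: a logistic OD curve that plateaus at the end of the
growth-coupled phase, ethanol production that continues after growth stops
and then ceases with residual substrate ("stuck" fermentation), intracellular
pools with multiplicative log-normal measurement noise, and — the injected
signal — one designated reaction whose mass-action ratio is driven
exponentially toward equilibrium after growth ends, so that its driving
force decays to ≈0 kJ/mol by the end of the production phase.

Ground truth (true concentrations, phase boundaries, the injected bottleneck
and the true minimum driving force per time point) is returned alongside the
emitted dataset so every downstream stage can be scored against it.

Baseline pool levels are chosen so that every reaction starts with a
comfortably positive driving force (at least 60 % of the network's all-free
MDF) while staying as close to a physiological 1 mM as those constraints
allow; a per-seed log-normal jitter then individualizes each run.  This makes
the injected near-equilibrium reaction the unambiguous thermodynamic
bottleneck, and keeps every true pool strictly inside the 1 µM – 100 mM
default bound box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.optimize import linprog

from .mdf_core import ConcentrationBounds, solve_mdf
from .pathway_model import (
    PathwayNetwork,
    ThermoTable,
    bundled_network,
    bundled_thermo_table,
    reaction_drg,
)
from .quantification import CELL_PARAMS, CalibrationCurve, CellParams, intracellular_volume

__all__ = ["CalibrationConfig", "GeneratorConfig", "GroundTruth", "generate",
           "emit_peak_areas"]


@dataclass(frozen=True)
class CalibrationConfig:
    """How simulated LC-MS calibration curves are drawn."""

    slope_log10_range: tuple[float, float] = (12.0, 14.0)  # peak-area per mol
    intercept_range: tuple[float, float] = (0.0, 1e3)
    noise_cv: float = 0.05
    n_standards: int = 6
    standard_amount_range_mol: tuple[float, float] = (1e-11, 1e-7)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic fermentation.

    Defaults emulate the engineered E. coli condition: 120 g/L glucose
    (≈666 mM), a final ethanol titer near 450 mM reached well before the
    substrate runs out, growth ending at 20 h and ethanol production ceasing
    at 45 h over a 60 h horizon sampled at 25 points (2.5 h spacing).
    """

    organism: str = "eco"
    seed: int = 0
    n_timepoints: int = 25
    t_end_h: float = 60.0
    t_growth_end: float = 20.0
    t_production_end: float = 45.0
    od_max: float = 2.0
    substrate0_mm: float = 666.0
    yield_mol_per_mol: float = 1.45
    ethanol_max_mm: float = 450.0
    bottleneck_reaction: str = "PYK"
    equilibrium_approach_rate: float | None = None  # h⁻¹; None → reach 0.5 kJ/mol
    noise_cv: float = 0.10          # intracellular LC-MS noise
    noise_cv_ext: float = 0.01      # extracellular HPLC noise
    noise_cv_od: float = 0.02
    baseline_jitter_sd: float = 0.15   # per-seed log-jitter of baseline pools
    temporal_wiggle_sd: float = 0.05   # smooth within-run log-variation
    unmeasured: frozenset[str] = frozenset({"bpg", "acald", "co2", "pi",
                                            "fdox", "fdred"})
    filtered_volume_ml: float = 4.0
    cell_params: CellParams | None = None
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    # fraction of the peak OD growth rate / ethanol rate that defines the two
    # injected phase boundaries (matches the segmentation defaults)
    growth_rate_cutoff: float = 0.10
    production_rate_cutoff: float = 0.05


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    true_concentrations_mm: pd.DataFrame   # time × metabolite, noise-free
    true_phase_labels: pd.Series
    bottleneck_id: str
    true_min_driving_force: pd.Series      # kJ/mol per time point
    t_growth_end: float
    t_production_end: float


def _lognormal_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=shape))


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _baseline_pools_mm(network: PathwayNetwork, thermo: ThermoTable,
                       driving_fraction: float = 0.6) -> dict[str, float]:
    """Physiological baseline pools with uniformly positive driving forces.

    Solves a second LP after the all-free MDF: keep every reaction's driving
    force at ≥ ``driving_fraction`` × MDF while minimizing the total
    |ln c − ln 1 mM| deviation, inside a box slightly shrunken from the
    default 1 µM – 100 mM so that measurement jitter cannot push a true pool
    outside the default bounds.
    """
    free = solve_mdf(network, thermo, ConcentrationBounds())
    if free.mdf <= 0:
        raise ValueError(
            "network is thermodynamically infeasible even with free pools; "
            "cannot stage a positive-driving-force baseline")
    floor_d = driving_fraction * free.mdf
    from .mdf_core import _stoich_matrix

    S, mets = _stoich_matrix(network)
    n_m, n_r = S.shape
    rt = thermo.rt
    drg0 = np.array([thermo.drg0[r.id] for r in network.reactions])
    c0 = math.log(1e-3)  # 1 mM
    lo, hi = math.log(2e-6), math.log(5e-2)
    # variables: x (ln conc), u (|x - c0| majorants); minimize sum(u)
    c = np.concatenate([np.zeros(n_m), np.ones(n_m)])
    A = np.zeros((n_r + 2 * n_m, 2 * n_m))
    b = np.zeros(n_r + 2 * n_m)
    A[:n_r, :n_m] = rt * S.T
    b[:n_r] = -drg0 - floor_d
    eye = np.eye(n_m)
    A[n_r:n_r + n_m, :n_m] = eye
    A[n_r:n_r + n_m, n_m:] = -eye
    b[n_r:n_r + n_m] = c0
    A[n_r + n_m:, :n_m] = -eye
    A[n_r + n_m:, n_m:] = -eye
    b[n_r + n_m:] = -c0
    bounds = [(lo, hi)] * n_m + [(0, None)] * n_m
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if not res.success:
        raise ValueError("could not stage baseline pools at the requested "
                         f"driving-force floor ({floor_d:.2f} kJ/mol)")
    return {m: math.exp(res.x[i]) * 1e3 for i, m in enumerate(mets)}


def _resolve_network(config: GeneratorConfig,
                     network: PathwayNetwork | None,
                     thermo: ThermoTable | None):
    if network is None:
        network = bundled_network(config.organism)
    if thermo is None:
        thermo = bundled_thermo_table(config.organism)
    return network, thermo


def generate(
    config: GeneratorConfig,
    network: PathwayNetwork | None = None,
    thermo: ThermoTable | None = None,
):
    """Generate one fermentation dataset plus its ground truth.

    Returns ``(FermentationDataset, GroundTruth)``.  All randomness flows
    from ``config.seed`` through a single generator instance, so identical
    configs produce identical outputs.
    """
    from .quantification import FermentationDataset  # avoid cycle at import time

    network, thermo = _resolve_network(config, network, thermo)
    if config.bottleneck_reaction not in network.reaction_ids:
        raise ValueError(
            f"bottleneck reaction {config.bottleneck_reaction!r} not in network")
    if not (0 < config.t_growth_end < config.t_production_end < config.t_end_h):
        raise ValueError("phase times must satisfy 0 < growth end < production "
                         "end < horizon")
    if min(config.noise_cv, config.noise_cv_ext, config.noise_cv_od) < 0:
        raise ValueError("noise CVs must be non-negative")
    bottleneck = network.reaction(config.bottleneck_reaction)
    measured_participants = [m for m in bottleneck.participants
                             if m not in config.unmeasured]
    if not measured_participants:
        raise ValueError(
            "all participants of the bottleneck reaction are unmeasured; "
            "the injected signal would be undetectable by design")

    rng = np.random.default_rng(config.seed)
    t = np.linspace(0.0, config.t_end_h, config.n_timepoints)
    rt = thermo.rt

    # --- OD: logistic whose growth rate falls to `growth_rate_cutoff` of its
    # peak exactly at t_growth_end (the injected boundary).
    frac = config.growth_rate_cutoff
    s_at_end = 0.5 * (1.0 + math.sqrt(1.0 - frac))
    z_end = math.log(s_at_end / (1.0 - s_at_end))
    tm = config.t_growth_end / 2.0
    k_od = z_end / (config.t_growth_end - tm)
    od_true = config.od_max * _logistic(k_od * (t - tm))

    # --- ethanol: rate proportional to biomass, shut down by a logistic gate
    # that reaches `production_rate_cutoff` of the open gate at
    # t_production_end; monotone decline afterwards (terminal cessation).
    beta = config.production_rate_cutoff
    tp_mid = 0.5 * (config.t_growth_end + config.t_production_end)
    k_p = math.log((1 - beta) / beta) / (config.t_production_end - tp_mid)
    rate = (od_true / config.od_max) * (1.0 - _logistic(k_p * (t - tp_mid)))
    rate[t > config.t_production_end] = 0.0  # cessation is literal
    etoh = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))])
    etoh *= config.ethanol_max_mm / etoh[-1]
    substrate = config.substrate0_mm - etoh / config.yield_mol_per_mol
    if substrate[-1] <= 0:
        raise ValueError("substrate exhausted before horizon end; the study "
                         "conditions require residual substrate")

    # --- intracellular pools: staged physiological baseline, per-seed
    # log-normal jitter, smooth temporal wiggle.
    mets = network.metabolite_ids
    base_mm = _baseline_pools_mm(network, thermo)
    jitter = {m: math.exp(rng.normal(0.0, config.baseline_jitter_sd)) for m in mets}
    n = config.n_timepoints
    true_mm = pd.DataFrame(index=range(n), columns=mets, dtype=float)
    kernel = np.ones(5) / 5.0
    for m in mets:
        wiggle = np.convolve(rng.normal(0.0, config.temporal_wiggle_sd, n + 4),
                             kernel, mode="valid")
        true_mm[m] = base_mm[m] * jitter[m] * np.exp(wiggle)

    # --- inject the near-equilibrium trajectory: after growth ends, the
    # bottleneck reaction's driving force decays exponentially toward 0.
    # The required mass-action-ratio shift is spread over the reaction's
    # non-cofactor participants (e.g. pep down, pyr up for PYK), so each
    # pool moves only a few-fold and stays physiological.
    cofactors = {ms.id for ms in network.metabolites if ms.is_cofactor}
    adjust = [m for m in bottleneck.participants if m not in cofactors]
    if not adjust:
        adjust = list(bottleneck.participants)
    weight = 1.0 / sum(abs(float(bottleneck.stoichiometry[m])) for m in adjust)

    def driving_at(i: int) -> float:
        conc = {m: true_mm.iloc[i][m] * 1e-3 for m in bottleneck.participants}
        return -reaction_drg(bottleneck, thermo, conc)

    i_ge = int(np.searchsorted(t, config.t_growth_end))
    d_ref = max(driving_at(min(i_ge, n - 1)), 1.0)
    rate_eq = config.equilibrium_approach_rate
    if rate_eq is None:
        rate_eq = math.log(d_ref / 0.5) / (config.t_production_end
                                           - config.t_growth_end)
    for i in range(n):
        if t[i] <= config.t_growth_end:
            continue
        d_target = d_ref * math.exp(-rate_eq * (t[i] - config.t_growth_end))
        delta_lnq = (driving_at(i) - d_target) / rt
        for m in adjust:
            sign = 1.0 if bottleneck.stoichiometry[m] > 0 else -1.0
            true_mm.loc[i, m] = (true_mm.iloc[i][m]
                                 * math.exp(sign * delta_lnq * weight))

    # --- ground truth min driving force and phase labels
    min_df = []
    for i in range(n):
        conc = {m: true_mm.iloc[i][m] * 1e-3 for m in mets}
        min_df.append(min(-reaction_drg(r, thermo, conc) for r in network.reactions))
    labels = np.where(t <= config.t_growth_end, "growth_coupled",
                      np.where(t <= config.t_production_end,
                               "growth_uncoupled", "no_production"))

    # --- emit noisy measurements, masking unmeasured metabolites
    measured_cols = [m for m in mets if m not in config.unmeasured]
    meas = true_mm[measured_cols] * _lognormal_factor(
        rng, config.noise_cv, (n, len(measured_cols)))
    od_meas = od_true * _lognormal_factor(rng, config.noise_cv_od, n)
    ext = pd.DataFrame({
        "glc": substrate * _lognormal_factor(rng, config.noise_cv_ext, n),
        "etoh": etoh * _lognormal_factor(rng, config.noise_cv_ext, n),
    })
    # noise-free zero stays zero under multiplicative noise
    dataset = FermentationDataset(
        time_h=t,
        od=pd.Series(od_meas),
        extracellular=ext,
        intracellular_mm=meas.reset_index(drop=True),
        filtered_volume_ml=pd.Series(np.full(n, config.filtered_volume_ml)),
    )
    truth = GroundTruth(
        true_concentrations_mm=true_mm,
        true_phase_labels=pd.Series(labels),
        bottleneck_id=bottleneck.id,
        true_min_driving_force=pd.Series(min_df, index=pd.Index(t, name="time_h")),
        t_growth_end=config.t_growth_end,
        t_production_end=config.t_production_end,
    )
    return dataset, truth


def emit_peak_areas(
    dataset,
    config: GeneratorConfig,
    seed: int | None = None,
):
    """Re-express a dataset's intracellular mM series as LC-MS peak areas.

    Draws one linear calibration per metabolite, converts each sample's
    concentration to an amount via the per-sample intracellular volume, and
    emits area = slope·amount + intercept with multiplicative noise on the
    signal term.  Returns ``(areas, standards, true_curves)``: a time ×
    metabolite area table, a standards table (metabolite, amount_mol, area)
    with ``n_standards`` known amounts per metabolite, and the true
    :class:`~fermdf.quantification.CalibrationCurve` objects.
    """
    cal = config.calibration
    params = config.cell_params or CELL_PARAMS[config.organism]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if dataset.filtered_volume_ml is None:
        raise ValueError("dataset lacks filtered volumes")

    areas = {}
    standards_rows = []
    curves: dict[str, CalibrationCurve] = {}
    lo10, hi10 = cal.slope_log10_range
    for met in dataset.intracellular_mm.columns:
        slope = 10.0 ** rng.uniform(lo10, hi10)
        intercept = rng.uniform(*cal.intercept_range)
        curves[met] = CalibrationCurve(met, slope, intercept)
        vals = []
        for i in range(dataset.n_timepoints):
            conc = dataset.intracellular_mm.iloc[i][met]
            if not np.isfinite(conc):
                vals.append(np.nan)
                continue
            icv = intracellular_volume(float(dataset.od.iloc[i]),
                                       float(dataset.filtered_volume_ml.iloc[i]),
                                       params)
            amount = conc * icv * 1e-6  # mM × mL → mol
            noise = _lognormal_factor(rng, cal.noise_cv, ())
            vals.append(slope * amount * float(noise) + intercept)
        areas[met] = vals
        amounts = np.geomspace(*cal.standard_amount_range_mol, cal.n_standards)
        for a in amounts:
            noise = float(_lognormal_factor(rng, cal.noise_cv, ()))
            standards_rows.append((met, a, slope * a * noise + intercept))

    areas_df = pd.DataFrame(areas)
    standards_df = pd.DataFrame(standards_rows,
                                columns=["metabolite", "amount_mol", "area"])
    return areas_df, standards_df, curves
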