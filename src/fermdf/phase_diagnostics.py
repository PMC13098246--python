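"""Fermentation phase segmentation and diagnostic ratio trajectories.

Batch ethanol fermentations pass through three phases: growth-coupled
fermentation (biomass and ethanol both increase), growth-uncoupled
fermentation (ethanol still increases after growth stops) and no ethanol
production.  In experimental practice these phases are annotated visually;
here the boundaries are operationalized with rate thresholds on smoothed
series:

* growth-coupled while the smoothed OD rate exceeds ``alpha`` × its maximum;
* no-production once the smoothed ethanol rate falls below ``beta`` × its
  maximum and never exceeds it again (the phase is terminal);
* growth-uncoupled in between.

Manual phase labels supplied with the input data always override this rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.signal import medfilt

__all__ = [
    "PHASES",
    "PhaseSegmentation",
    "smooth",
    "segment_phases",
    "ratio_series",
    "energy_charge",
    "diagnostics_table",
]

PHASES = ("growth_coupled", "growth_uncoupled", "no_production")


@dataclass
class PhaseSegmentation:
    """Two boundary times and a per-time-point phase label array."""

    t_growth_end: float
    t_production_end: float
    labels: pd.Series  # values from PHASES, indexed like the input series

    def __post_init__(self) -> None:
        if self.t_growth_end > self.t_production_end:
            raise ValueError("t_growth_end must not exceed t_production_end")
        bad = set(self.labels) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")


def smooth(series, window: int = 3):
    """Centered rolling mean with edge windows truncated to available points.

    ``window`` must be a positive odd integer; ``window=1`` is the identity.
    Output has the same length (and index, for pandas input) as the input.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    s = pd.Series(np.asarray(series, dtype=float))
    out = s.rolling(window, center=True, min_periods=1).mean()
    if isinstance(series, pd.Series):
        return pd.Series(out.to_numpy(), index=series.index)
    return out.to_numpy()


def _smoothed_rate(
    time: np.ndarray, values, window: int, passes: int = 3
) -> np.ndarray:
    """Noise-robust rate estimate for threshold-based boundary detection.

    Both OD and ethanol are non-decreasing up to measurement noise in these
    batch fermentations, so the series is median-filtered (to drop isolated
    outlier samples) and projected onto the nearest monotone sequence
    (isotonic regression), which removes plateau noise without blurring the
    rise.  The projection is then smoothed ``passes`` times with the
    centered rolling window before central differencing; the one-sided edge
    slopes are replaced by their interior neighbours, which are estimated
    from full windows.
    """
    x = np.asarray(values, dtype=float)
    if len(x) >= 5:
        x = medfilt(x, 5)
    elif len(x) >= 3:
        x = medfilt(x, 3)
    x = isotonic_regression(x).x
    for _ in range(passes):
        x = smooth(x, window)
    g = np.gradient(x, time)
    if len(g) > 2:
        g[0], g[-1] = g[1], g[-2]
    return g


def segment_phases(
    time_h,
    od,
    ethanol,
    alpha: float = 0.10,
    beta: float = 0.05,
    window: int = 3,
) -> PhaseSegmentation:
    """Segment a fermentation into the three phases by rate thresholds.

    Parameters
    ----------
    time_h, od, ethanol : array-like
        Shared time grid (hours, strictly increasing, ≥4 points), OD600 and
        ethanol concentration series.
    alpha, beta : float
        Fractions of the maximum smoothed OD / ethanol rate that define the
        end of growth and the (terminal) end of production.
    """
    t = np.asarray(time_h, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")

    g = _smoothed_rate(t, od, window)
    growing = g > alpha * g.max()
    growth_idx = int(np.flatnonzero(growing)[-1]) if growing.any() else -1

    e = _smoothed_rate(t, ethanol, window)
    thr = beta * e.max()
    below = e < thr
    # no-production is terminal: find the first index after which the rate
    # never again reaches the threshold
    noprod_start = len(t)
    for i in range(len(t) - 1, -1, -1):
        if below[i]:
            noprod_start = i
        else:
            break
    noprod_start = max(noprod_start, growth_idx + 1)

    labels = []
    for i in range(len(t)):
        if i <= growth_idx:
            labels.append("growth_coupled")
        elif i >= noprod_start:
            labels.append("no_production")
        else:
            labels.append("growth_uncoupled")
    index = od.index if isinstance(od, pd.Series) else pd.RangeIndex(len(t))
    t_growth_end = t[growth_idx] if growth_idx >= 0 else t[0]
    t_production_end = t[noprod_start - 1] if noprod_start > 0 else t[0]
    t_production_end = max(t_production_end, t_growth_end)
    return PhaseSegmentation(
        t_growth_end=float(t_growth_end),
        t_production_end=float(t_production_end),
        labels=pd.Series(labels, index=index),
    )


def ratio_series(num, den) -> pd.Series:
    """Element-wise metabolite ratio; zero denominators yield missing values.

    Used for the bottleneck indicator ratios (f6p:fbp, dhap:3pg, pyr:accoa,
    nad:nadh, ...).  Inputs must share a time index.
    """
    num = pd.Series(num).astype(float)
    den = pd.Series(den).astype(float)
    if len(num) != len(den):
        raise ValueError("numerator and denominator must share the time index")
    if isinstance(den, pd.Series) and not num.index.equals(den.index):
        raise ValueError("numerator and denominator must share the time index")
    out = num / den.where(den != 0)
    return out


def energy_charge(atp, adp, amp) -> pd.Series:
    """Adenylate energy charge (ATP + ½·ADP) / (ATP + ADP + AMP), in [0, 1].

    Scale-invariant in the total adenylate pool.  Points where the whole pool
    is zero (or any input is missing) are emitted as missing values.
    """
    atp = pd.Series(atp).astype(float)
    adp = pd.Series(adp).astype(float)
    amp = pd.Series(amp).astype(float)
    if not (len(atp) == len(adp) == len(amp)):
        raise ValueError("atp, adp, amp must share the time index")
    for s in (atp, adp, amp):
        if (s.dropna() < 0).any():
            raise ValueError("adenylate concentrations must be non-negative")
    total = atp + adp + amp
    return (atp + 0.5 * adp) / total.where(total > 0)


def diagnostics_table(
    dataset,
    ratios: dict[str, tuple[str, str]] | None = None,
    window: int = 3,
    alpha: float = 0.10,
    beta: float = 0.05,
    ethanol_id: str = "etoh",
) -> pd.DataFrame:
    """Assemble the per-time-point diagnostics table for one fermentation.

    ``ratios`` maps an output column name to a (numerator, denominator) pair
    of intracellular metabolite ids.  Adds an ``energy_charge`` column when
    atp/adp/amp are all present, and a ``phase`` column from the segmentation
    rule (or the dataset's own labels when provided).
    """
    out = pd.DataFrame({"time_h": dataset.time_h})
    if dataset.phase_labels is not None:
        out["phase"] = dataset.phase_labels.to_numpy()
    else:
        seg = segment_phases(
            dataset.time_h, dataset.od,
            dataset.extracellular.get(ethanol_id, pd.Series(np.zeros(dataset.n_timepoints))),
            alpha=alpha, beta=beta, window=window)
        out["phase"] = seg.labels.to_numpy()
    conc = dataset.intracellular_mm
    for name, (num, den) in (ratios or {}).items():
        if num in conc.columns and den in conc.columns:
            out[name] = ratio_series(conc[num], conc[den]).to_numpy()
    if all(m in conc.columns for m in ("atp", "adp", "amp")):
        out["energy_charge"] = energy_charge(
            conc["atp"], conc["adp"], conc["amp"]).to_numpy()
    return out
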