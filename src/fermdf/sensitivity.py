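"""Error analysis of MDF scores by concentration-bound relaxation.

Two procedures probe how measurement error could explain low or negative MDF
scores:

* **global relaxation** — every measured metabolite's fixed bound (c, c)
  becomes (c/f, c·f) for a multiplicative factor f ≥ 1, emulating random
  measurement error spread across all metabolites;
* **single-metabolite relaxation** — one measured metabolite's bounds are
  replaced by the free default box (1 µM, 100 mM), emulating a specific
  error in that metabolite.

Relaxation can only enlarge the feasible set, so neither procedure can lower
the MDF.  Metabolites whose relaxation raises the MDF most are the ones whose
measured values pin the bottleneck reaction — for a fermentation stalled at
pyruvate kinase, its participants pep, pyr, atp and adp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .mdf_core import (
    DEFAULT_BOUNDS_M,
    BoundEntry,
    ConcentrationBounds,
    MDFTimecourse,
    mdf_timecourse,
)
from .pathway_model import PathwayNetwork, ThermoTable

__all__ = [
    "DEFAULT_RELAXATION_FACTORS",
    "RelaxationReport",
    "global_relaxation",
    "single_relaxation",
    "relaxation_scan",
]

#: Standard ladder of multiplicative factors for the global error analysis.
DEFAULT_RELAXATION_FACTORS: tuple[float, ...] = (1.0, 1.5, 2.0, 5.0, 100.0)


def global_relaxation(bounds: ConcentrationBounds, factor: float) -> ConcentrationBounds:
    """Relax every measured bound (c, c) to (c/f, c·f) for f ≥ 1.

    Free-default entries are unchanged.  Zero-measured entries (pinned at the
    1 µM floor) keep their floor as lower bound and get floor·f as upper —
    the multiplicative rule applied at the floor.
    """
    if factor < 1:
        raise ValueError("relaxation factor must be ≥ 1")
    entries = {}
    for met, e in bounds.entries.items():
        if e.source == "measured_fixed":
            entries[met] = BoundEntry(e.lower / factor, e.upper * factor, e.source)
        elif e.source == "measured_zero":
            entries[met] = BoundEntry(e.lower, e.upper * factor, e.source)
        else:
            entries[met] = e
    return ConcentrationBounds(entries=entries, default=bounds.default)


def single_relaxation(bounds: ConcentrationBounds, metabolite: str) -> ConcentrationBounds:
    """Replace one measured metabolite's bounds by the free default box.

    Relaxing a metabolite that was not measured is a no-op (with a warning):
    its bounds are already the free default.
    """
    if metabolite not in bounds.entries or bounds.entry(metabolite).source == "free_default":
        warnings.warn(
            f"{metabolite!r} is not a measured metabolite; relaxation is a no-op",
            stacklevel=2,
        )
        return bounds
    return bounds.with_entry(
        metabolite, BoundEntry(bounds.default[0], bounds.default[1], "user")
    )


@dataclass
class RelaxationReport:
    """One relaxed MDF time course next to its baseline."""

    mode: Literal["global", "single"]
    key: float | str                    # factor (global) or metabolite id (single)
    time_h: np.ndarray
    mdf_baseline: np.ndarray
    mdf_relaxed: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.mdf_relaxed - self.mdf_baseline

    def mean_delta(self, mask: np.ndarray | None = None) -> float:
        d = self.delta if mask is None else self.delta[mask]
        d = d[np.isfinite(d)]
        return float(d.mean()) if d.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode": self.mode, "key": str(self.key), "time_h": self.time_h,
            "mdf_baseline": self.mdf_baseline, "mdf_relaxed": self.mdf_relaxed,
            "delta": self.delta,
        })


def relaxation_scan(
    network: PathwayNetwork,
    thermo: ThermoTable,
    dataset,
    mode: Literal["global", "single"],
    keys: Sequence[float] | Sequence[str] | None = None,
    baseline: MDFTimecourse | None = None,
    defaults: tuple[float, float] = DEFAULT_BOUNDS_M,
    no_production_mask: np.ndarray | None = None,
    **solve_kwargs,
) -> list[RelaxationReport]:
    """Run a family of relaxations and rank them by their effect on the MDF.

    ``keys`` are multiplicative factors (``mode="global"``; defaults to the
    standard factor ladder) or measured-metabolite ids (``mode="single"``;
    defaults to every metabolite measured anywhere in the dataset).  Reports
    are sorted by descending mean MDF gain, evaluated over the no-production
    phase when ``no_production_mask`` is given (otherwise over all solved
    time points).
    """
    if baseline is None:
        baseline = mdf_timecourse(network, thermo, dataset, defaults=defaults,
                                  **solve_kwargs)
    base = baseline.mdf_series.to_numpy()

    if keys is None:
        if mode == "global":
            keys = list(DEFAULT_RELAXATION_FACTORS)
        else:
            net_mets = set(network.metabolite_ids)
            keys = [m for m in dataset.intracellular_mm.columns if m in net_mets]

    reports = []
    for key in keys:
        if mode == "global":
            transform = lambda b, f=float(key): global_relaxation(b, f)
        else:
            transform = lambda b, m=str(key): single_relaxation(b, m)
        relaxed = mdf_timecourse(network, thermo, dataset, defaults=defaults,
                                 bounds_transform=transform, **solve_kwargs)
        reports.append(RelaxationReport(
            mode=mode, key=key, time_h=baseline.time_h,
            mdf_baseline=base, mdf_relaxed=relaxed.mdf_series.to_numpy(),
        ))
    reports.sort(key=lambda r: -r.mean_delta(no_production_mask))
    return reports
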