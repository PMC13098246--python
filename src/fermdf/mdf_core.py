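"""Max-min driving force (MDF) linear program and per-time-point application.

The MDF of a pathway is the largest B such that every reaction can run with a
driving force of at least B under the allowed metabolite concentrations:

    maximize  B
    s.t.      ΔrG′°_j + R·T · Σ_i S_ij · x_i  ≤  −B      for every reaction j
              ln(lower_i) ≤ x_i ≤ ln(upper_i)            x_i = ln c_i (molar)

A positive MDF means the whole pathway is thermodynamically feasible; the
*bottleneck* reactions are those whose driving force equals the MDF at the
optimum — the steps closest to equilibrium.

Concentration-bound conventions: metabolites quantified by LC-MS are fixed to
their measured values (lower = upper); unquantified metabolites range over a
default box of 1 µM – 100 mM; metabolites measured at zero are pinned at the
1 µM floor (configurable to a free ceiling instead).  Measured values above
100 mM keep their measured bound — the fixing rule takes precedence over the
default ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .pathway_model import PathwayNetwork, Reaction, ThermoTable, reaction_drg

__all__ = [
    "DEFAULT_BOUNDS_M",
    "BoundEntry",
    "ConcentrationBounds",
    "MDFResult",
    "MDFTimecourse",
    "bounds_from_measurements",
    "solve_mdf",
    "cumulative_profile",
    "mdf_timecourse",
]

#: Default (lower, upper) molar bounds for unquantified metabolites: 1 µM – 100 mM.
DEFAULT_BOUNDS_M: tuple[float, float] = (1e-6, 0.1)

Source = Literal["measured_fixed", "measured_zero", "free_default", "user"]


@dataclass(frozen=True)
class BoundEntry:
    """A (lower, upper) molar concentration interval with provenance."""

    lower: float
    upper: float
    source: Source = "user"

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper):
            raise ValueError(
                f"need 0 < lower <= upper, got ({self.lower}, {self.upper})"
            )


@dataclass
class ConcentrationBounds:
    """Per-metabolite molar bounds; metabolites without an entry get the default box."""

    entries: dict[str, BoundEntry] = field(default_factory=dict)
    default: tuple[float, float] = DEFAULT_BOUNDS_M

    def entry(self, met: str) -> BoundEntry:
        if met in self.entries:
            return self.entries[met]
        return BoundEntry(self.default[0], self.default[1], "free_default")

    def with_entry(self, met: str, entry: BoundEntry) -> "ConcentrationBounds":
        new = dict(self.entries)
        new[met] = entry
        return ConcentrationBounds(entries=new, default=self.default)

    def measured_ids(self) -> list[str]:
        return [m for m, e in self.entries.items()
                if e.source in ("measured_fixed", "measured_zero")]


def bounds_from_measurements(
    measured: Mapping[str, float],
    defaults: tuple[float, float] = DEFAULT_BOUNDS_M,
    zero_measured: Literal["fixed_floor", "free_ceiling"] = "fixed_floor",
) -> ConcentrationBounds:
    """Build concentration bounds from measured intracellular mM values.

    Measured c > 0 → fixed at (c, c); absent → default box; measured 0 →
    pinned at the 1 µM floor (``"fixed_floor"``) or allowed the full
    (1 µM, 100 mM) box (``"free_ceiling"``).  Input is mM; bounds are molar.
    """
    floor = defaults[0]
    entries: dict[str, BoundEntry] = {}
    for met, mm in measured.items():
        if mm is None or (isinstance(mm, float) and math.isnan(mm)):
            continue
        if mm < 0:
            raise ValueError(f"negative measurement for {met!r}: {mm}")
        if mm == 0:
            if zero_measured == "fixed_floor":
                entries[met] = BoundEntry(floor, floor, "measured_zero")
            else:
                entries[met] = BoundEntry(floor, defaults[1], "measured_zero")
        else:
            c = mm * 1e-3
            entries[met] = BoundEntry(c, c, "measured_fixed")
    return ConcentrationBounds(entries=entries, default=defaults)


@dataclass
class MDFResult:
    """Solution of one MDF program."""

    mdf: float                       # optimal B, kJ/mol (may be negative)
    ln_conc: dict[str, float]        # optimal ln molar concentrations
    drg: dict[str, float]            # ΔrG′ per reaction at the optimum, kJ/mol
    bottlenecks: set[str]            # reactions with driving force ≈ MDF
    tol: float = 1e-6

    @property
    def feasible_flag(self) -> bool:
        return self.mdf > 0

    @property
    def concentrations_m(self) -> dict[str, float]:
        return {m: math.exp(x) for m, x in self.ln_conc.items()}


class MDFSolverError(RuntimeError):
    """LP solver failure, with a dump of the program for diagnosis."""


def _stoich_matrix(network: PathwayNetwork) -> tuple[np.ndarray, list[str]]:
    mets = network.metabolite_ids
    idx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met, coeff in rxn.stoichiometry.items():
            S[idx[met], j] = float(coeff)
    return S, mets


def solve_mdf(
    network: PathwayNetwork,
    thermo: ThermoTable,
    bounds: ConcentrationBounds,
    tol: float = 1e-6,
) -> MDFResult:
    """Solve the MDF linear program for one network and bound set.

    Returns the optimal B together with an optimal log-concentration vector,
    per-reaction ΔrG′ at that optimum, and the bottleneck set (all reactions
    whose driving force lies within ``tol`` of the MDF — ties allowed).

    The optimal concentration vector is generally degenerate, and at an
    arbitrary vertex reactions involving only free metabolites can sit at
    the minimum driving force without being genuine constraints.  A second
    LP therefore maximizes the (capped) sum of driving-force slacks at the
    optimal B, so the reported bottlenecks are exactly the reactions that
    *cannot* be moved off the minimum.  Only the MDF value and the
    bottleneck set are unique; downstream code must not rely on uniqueness
    of ln_conc.
    """
    thermo.validate_against(network)
    S, mets = _stoich_matrix(network)
    n_m, n_r = S.shape
    rt = thermo.rt
    drg0 = np.array([thermo.drg0[r.id] for r in network.reactions])

    lo = np.empty(n_m)
    hi = np.empty(n_m)
    for i, met in enumerate(mets):
        e = bounds.entry(met)
        lo[i], hi[i] = math.log(e.lower), math.log(e.upper)

    # variables: x (n_m log-concentrations), B
    c = np.zeros(n_m + 1)
    c[-1] = -1.0  # maximize B
    A_ub = np.hstack([rt * S.T, np.ones((n_r, 1))])
    b_ub = -drg0
    var_bounds = [(lo[i], hi[i]) for i in range(n_m)] + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=var_bounds, method="highs")
    if not res.success:
        dump = {
            "status": res.status, "message": res.message,
            "drg0": drg0.tolist(), "lo": lo.tolist(), "hi": hi.tolist(),
            "reactions": network.reaction_ids, "metabolites": mets,
        }
        raise MDFSolverError(f"MDF LP failed: {dump}")

    mdf = float(res.x[-1])

    # stage 2: at B = mdf, maximize the capped slack of every reaction so
    # that only genuinely pinned reactions remain at the minimum
    slack_cap = 1.0  # kJ/mol; any positive separation marks a non-bottleneck
    c2 = np.concatenate([np.zeros(n_m), -np.ones(n_r)])
    A2 = np.hstack([rt * S.T, np.eye(n_r)])
    b2 = -drg0 - mdf + 1e-9
    var_bounds2 = [(lo[i], hi[i]) for i in range(n_m)] + [(0, slack_cap)] * n_r
    res2 = linprog(c2, A_ub=A2, b_ub=b2, bounds=var_bounds2, method="highs")
    if not res2.success:  # fall back to the stage-1 vertex
        x = res.x[:n_m]
    else:
        x = res2.x[:n_m]
    drg = drg0 + rt * (S.T @ x)
    driving = -drg
    if (driving < mdf - max(tol, 1e-7)).any():
        raise MDFSolverError("solver returned an infeasible vertex")
    bottlenecks = {
        network.reactions[j].id for j in range(n_r) if driving[j] <= mdf + tol
    }
    return MDFResult(
        mdf=mdf,
        ln_conc={m: float(x[i]) for i, m in enumerate(mets)},
        drg={network.reactions[j].id: float(drg[j]) for j in range(n_r)},
        bottlenecks=bottlenecks,
        tol=tol,
    )


def cumulative_profile(
    network: PathwayNetwork,
    thermo: ThermoTable,
    conc: MDFResult | Mapping[str, float] | None = None,
) -> list[tuple[str, float]]:
    """Cumulative ΔrG′ along the pathway, in pathway-position order.

    ``conc`` may be an :class:`MDFResult` (its optimal concentrations are
    used), a mapping metabolite → molar concentration, or ``None`` for the
    reference profile with every metabolite fixed at 1 mM.
    """
    if conc is None:
        conc_map: Mapping[str, float] = {m: 1e-3 for m in network.metabolite_ids}
    elif isinstance(conc, MDFResult):
        conc_map = conc.concentrations_m
    else:
        conc_map = conc
    out = []
    total = 0.0
    for rxn in network.reactions_in_pathway_order():
        total += reaction_drg(rxn, thermo, conc_map)
        out.append((rxn.id, total))
    return out


@dataclass
class MDFTimecourse:
    """Per-time-point MDF solutions over a fermentation dataset."""

    time_h: np.ndarray
    results: list[MDFResult | None]   # None = skipped (no intracellular data)
    network: PathwayNetwork
    thermo: ThermoTable

    @property
    def mdf_series(self) -> pd.Series:
        return pd.Series(
            [r.mdf if r is not None else np.nan for r in self.results],
            index=pd.Index(self.time_h, name="time_h"), name="mdf_kj_mol",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, r in zip(self.time_h, self.results):
            if r is None:
                rows.append((t, np.nan, False, "", True))
            else:
                rows.append((t, r.mdf, r.feasible_flag,
                             ";".join(sorted(r.bottlenecks)), False))
        return pd.DataFrame(
            rows, columns=["time_h", "mdf_kj_mol", "feasible", "bottlenecks",
                           "skipped"])

    def per_reaction_frame(self) -> pd.DataFrame:
        rows = []
        for t, r in zip(self.time_h, self.results):
            if r is None:
                continue
            total = 0.0
            for rxn in self.network.reactions_in_pathway_order():
                drg = r.drg[rxn.id]
                total += drg
                rows.append((t, rxn.id, drg, total, rxn.id in r.bottlenecks))
        return pd.DataFrame(
            rows, columns=["time_h", "reaction", "drg_kj_mol",
                           "cumulative_drg", "is_bottleneck"])


def mdf_timecourse(
    network: PathwayNetwork,
    thermo: ThermoTable,
    dataset,
    defaults: tuple[float, float] = DEFAULT_BOUNDS_M,
    zero_measured: Literal["fixed_floor", "free_ceiling"] = "fixed_floor",
    tol: float = 1e-6,
    bounds_transform=None,
) -> MDFTimecourse:
    """Solve the MDF program at every time point of a fermentation dataset.

    At each time point the measured intracellular concentrations (mM) fix
    their metabolites' bounds; metabolites missing at that time point are
    free within ``defaults``.  Time points with no intracellular data at all
    are skipped (result ``None``).  ``bounds_transform``, when given, maps
    each time point's :class:`ConcentrationBounds` to a modified set — the
    hook used by the sensitivity analyses.
    """
    results: list[MDFResult | None] = []
    for i in range(dataset.n_timepoints):
        measured = {
            m: v for m, v in dataset.intracellular_at(i).items()
            if m in set(network.metabolite_ids)
        }
        if not measured:
            results.append(None)
            continue
        bounds = bounds_from_measurements(measured, defaults, zero_measured)
        if bounds_transform is not None:
            bounds = bounds_transform(bounds)
        results.append(solve_mdf(network, thermo, bounds, tol=tol))
    return MDFTimecourse(
        time_h=np.asarray(dataset.time_h, dtype=float),
        results=results, network=network, thermo=thermo,
    )
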