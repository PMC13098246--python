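"""Shared fixtures: bundled networks and small hand-built test networks."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from fermdf.mdf_core import BoundEntry, ConcentrationBounds
from fermdf.pathway_model import (
    PathwayNetwork,
    MetaboliteSpec,
    Reaction,
    ThermoTable,
    bundled_network,
    bundled_thermo_table,
)


@pytest.fixture(scope="session")
def eco_network():
    return bundled_network("eco")


@pytest.fixture(scope="session")
def eco_thermo():
    return bundled_thermo_table("eco")


def make_chain(drg0s, organism="chain", temperature=298.15):
    """Linear chain m0 → m1 → ... with one reaction per ΔrG′° value."""
    n = len(drg0s)
    mets = [MetaboliteSpec(id=f"m{i}") for i in range(n + 1)]
    rxns = [
        Reaction(id=f"R{j}",
                 stoichiometry={f"m{j}": Fraction(-1), f"m{j+1}": Fraction(1)},
                 pathway_position=j)
        for j in range(n)
    ]
    network = PathwayNetwork(organism=organism, metabolites=mets, reactions=rxns)
    thermo = ThermoTable(drg0={f"R{j}": float(g) for j, g in enumerate(drg0s)},
                         temperature=temperature)
    return network, thermo


def fixed_bounds(conc_m: dict[str, float]) -> ConcentrationBounds:
    """All listed metabolites fixed at the given molar concentrations."""
    return ConcentrationBounds(entries={
        m: BoundEntry(c, c, "measured_fixed") for m, c in conc_m.items()
    })


def random_small_network(rng: np.random.Generator):
    """A random chain network with random fixed/free bounds (≤3 free).

    Free metabolites get narrow random ln-boxes so a 200-point grid resolves
    the optimum to well under the comparison tolerance.
    """
    n_rxn = int(rng.integers(2, 5))
    network, _ = make_chain([0.0] * n_rxn)
    thermo = ThermoTable(
        drg0={f"R{j}": float(rng.normal(0, 10)) for j in range(n_rxn)},
        temperature=298.15)
    n_met = n_rxn + 1
    n_free = int(rng.integers(1, min(3, n_met) + 1))
    free_idx = set(rng.choice(n_met, size=n_free, replace=False).tolist())
    entries = {}
    free_boxes = {}
    for i in range(n_met):
        met = f"m{i}"
        center = float(rng.uniform(np.log(1e-6), np.log(1e-1)))
        if i in free_idx:
            half = float(rng.uniform(0.25, 1.0))
            free_boxes[met] = (center - half, center + half)
            entries[met] = BoundEntry(np.exp(center - half), np.exp(center + half),
                                      "user")
        else:
            entries[met] = BoundEntry(np.exp(center), np.exp(center),
                                      "measured_fixed")
    bounds = ConcentrationBounds(entries=entries)
    return network, thermo, bounds, free_boxes


def grid_search_mdf(network, thermo, bounds, free_boxes, n_points=201,
                    refine=True):
    """Dense grid-search oracle for the max-min driving force.

    Evaluates the minimum driving force on a full ``n_points``-per-dimension
    lattice over the free metabolites' ln-boxes (fixed metabolites enter as
    constants) and returns the lattice maximum; optionally refines once
    around the incumbent with another lattice of the same density.
    """
    rt = thermo.rt
    free_mets = list(free_boxes)
    fixed_term = {}
    for rxn in network.reactions:
        val = thermo.drg0[rxn.id]
        for met, coeff in rxn.stoichiometry.items():
            if met not in free_boxes:
                val += rt * float(coeff) * np.log(bounds.entry(met).lower)
        fixed_term[rxn.id] = val

    def lattice_max(boxes):
        axes = [np.linspace(lo, hi, n_points) for lo, hi in boxes.values()]
        grids = np.meshgrid(*axes, indexing="ij") if axes else []
        min_driving = None
        for rxn in network.reactions:
            drg = np.full(grids[0].shape if grids else (), fixed_term[rxn.id])
            for k, met in enumerate(boxes):
                coeff = rxn.stoichiometry.get(met)
                if coeff:
                    drg = drg + rt * float(coeff) * grids[k]
            driving = -drg
            min_driving = driving if min_driving is None else np.minimum(
                min_driving, driving)
        best = int(np.argmax(min_driving))
        best_idx = np.unravel_index(best, min_driving.shape) if grids else ()
        best_x = {met: axes[k][best_idx[k]] for k, met in enumerate(boxes)}
        return float(min_driving.max()), best_x

    if not free_mets:
        val, _ = lattice_max({})
        return val
    value, best_x = lattice_max(free_boxes)
    if refine:
        shrink = {}
        for met, (lo, hi) in free_boxes.items():
            step = (hi - lo) / (n_points - 1)
            shrink[met] = (max(lo, best_x[met] - 2 * step),
                           min(hi, best_x[met] + 2 * step))
        value2, _ = lattice_max(shrink)
        value = max(value, value2)
    return value


def brute_force_upgma(dist: np.ndarray):
    """Reference UPGMA on a condensed/square distance matrix.

    Returns a scipy-style linkage matrix built by repeatedly merging the
    closest pair, averaging distances weighted by cluster sizes.  Ties break
    on the lowest involved original index.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim == 1:
        from scipy.spatial.distance import squareform
        d = squareform(d)
    n = d.shape[0]
    active = {i: ([i], i) for i in range(n)}  # cluster id → (members, label)
    dmat = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = d[i, j]
    next_label = n
    link = []
    ids = list(range(n))
    while len(ids) > 1:
        best = None
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                i, j = ids[a], ids[b]
                key = (min(i, j), max(i, j))
                cand = (dmat[key], min(active[i][1], active[j][1]),
                        max(active[i][1], active[j][1]), i, j)
                if best is None or cand < best:
                    best = cand
        dist_ij, _, _, i, j = best
        mi, li = active[i]
        mj, lj = active[j]
        link.append([min(li, lj), max(li, lj), dist_ij, len(mi) + len(mj)])
        new_id = max(ids) + 1
        for k in ids:
            if k in (i, j):
                continue
            kij = dmat[(min(i, k), max(i, k))]
            kjj = dmat[(min(j, k), max(j, k))]
            merged = (len(mi) * kij + len(mj) * kjj) / (len(mi) + len(mj))
            dmat[(min(k, new_id), max(k, new_id))] = merged
        active[new_id] = (mi + mj, next_label)
        next_label += 1
        ids = [k for k in ids if k not in (i, j)] + [new_id]
    return np.asarray(link)
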