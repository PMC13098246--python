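"""Stoichiometric pathway networks and standard reaction Gibbs energies.

A fermentation pathway is represented as an ordered list of reactions over
named metabolites (the stoichiometric matrix ``S``), together with a table of
standard transformed Gibbs energies of reaction (ΔrG′°, kJ/mol) at a stated
temperature.  ΔrG′° is always an *input* to this package — typically derived
from a thermodynamic database such as eQuilibrator at a documented pH and
ionic strength — never computed here.

The transformed Gibbs energy of reaction *j* at metabolite concentrations
``c`` (molar) is

    ΔrG′_j = ΔrG′°_j + R·T · Σ_i  S_ij · ln c_i

and the *driving force* of the reaction is −ΔrG′_j.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "GAS_CONSTANT_KJ",
    "MetaboliteSpec",
    "Reaction",
    "PathwayNetwork",
    "ThermoTable",
    "NetworkError",
    "parse_equation",
    "load_network",
    "load_thermo_table",
    "bundled_network",
    "bundled_thermo_table",
    "reaction_drg",
]

#: Gas constant in kJ mol⁻¹ K⁻¹.
GAS_CONSTANT_KJ = 8.3145e-3


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network definitions."""


@dataclass(frozen=True)
class MetaboliteSpec:
    """A named metabolite.

    Parameters
    ----------
    id : str
        Short lowercase code used throughout the package (e.g. ``"pep"``,
        ``"fbp"``).
    kegg_id : str or None
        Optional KEGG compound identifier (e.g. ``"C00074"``).
    name : str
        Free-text name.
    is_cofactor : bool
        Informational flag; cofactors (atp/adp, nad(h), coa, ...) take part
        in many reactions and dominate bound-sensitivity analyses.
    """

    id: str
    kegg_id: str | None = None
    name: str = ""
    is_cofactor: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be nonempty")


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (negative = substrate)."""

    id: str
    stoichiometry: Mapping[str, Fraction]
    pathway_position: int = 0

    def __post_init__(self) -> None:
        coeffs = list(self.stoichiometry.values())
        if not any(c < 0 for c in coeffs) or not any(c > 0 for c in coeffs):
            raise NetworkError(
                f"reaction {self.id!r} needs at least one substrate and one product"
            )

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]

    @property
    def participants(self) -> list[str]:
        return list(self.stoichiometry)

    def reversed(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            pathway_position=self.pathway_position,
        )


@dataclass
class PathwayNetwork:
    """An ordered set of reactions over declared metabolites."""

    organism: str
    metabolites: list[MetaboliteSpec]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise NetworkError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise NetworkError(f"duplicate reaction ids: {dup}")
        declared = set(met_ids)
        used: set[str] = set()
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in declared:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )
            used.update(rxn.stoichiometry)
        orphans = declared - used
        if orphans:
            raise NetworkError(
                f"metabolites not used by any reaction: {sorted(orphans)}"
            )

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reactions_in_pathway_order(self) -> list[Reaction]:
        return sorted(self.reactions, key=lambda r: r.pathway_position)


@dataclass
class ThermoTable:
    """Standard transformed Gibbs energies ΔrG′° (kJ/mol) per reaction."""

    drg0: dict[str, float]
    temperature: float = 298.15
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise NetworkError("temperature must be positive (kelvin)")

    @property
    def rt(self) -> float:
        """R·T in kJ/mol."""
        return GAS_CONSTANT_KJ * self.temperature

    def validate_against(self, network: PathwayNetwork) -> None:
        missing = [r for r in network.reaction_ids if r not in self.drg0]
        if missing:
            raise NetworkError(f"no ΔrG′° entry for reactions: {missing}")


# ---------------------------------------------------------------------------
# Equation / file parsing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:/\d+)?(?:\.\d+)?)\s+)?([A-Za-z0-9_]+)$")


def _parse_side(side: str, sign: int, out: dict[str, Fraction]) -> None:
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise NetworkError(f"empty term in equation side {side!r}")
        m = _TERM_RE.match(term)
        if m is None:
            raise NetworkError(f"cannot parse equation term {term!r}")
        coeff = Fraction(m.group(1)) if m.group(1) else Fraction(1)
        met = m.group(2)
        out[met] = out.get(met, Fraction(0)) + sign * coeff


def parse_equation(equation: str) -> dict[str, Fraction]:
    """Parse ``"2 a + b = c"`` into signed coefficients (substrates negative)."""
    if equation.count("=") != 1:
        raise NetworkError(f"equation must contain exactly one '=': {equation!r}")
    lhs, rhs = equation.split("=")
    stoich: dict[str, Fraction] = {}
    _parse_side(lhs, -1, stoich)
    _parse_side(rhs, +1, stoich)
    return {m: c for m, c in stoich.items() if c != 0}


def _read_tsv_lines(path: Path) -> tuple[list[str], list[list[str]]]:
    header_comments: list[str] = []
    rows: list[list[str]] = []
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            header_comments.append(line.lstrip().lstrip("#").strip())
            continue
        rows.append(line.split("\t"))
    return header_comments, rows


def load_network(path: str | Path, organism: str | None = None) -> PathwayNetwork:
    """Load a pathway network from a stoichiometry TSV file.

    The file holds ``#``-prefixed comment lines, a header row, then one row
    per reaction with columns ``reaction_id``, ``equation`` (``"2 a + b = c"``
    dialect), ``pathway_position`` and optionally ``kegg_ids`` — a
    semicolon-separated list of ``met=KEGGID`` pairs.  Metabolites are
    declared implicitly by their appearance in equations; cofactors may be
    flagged with a ``# cofactors: atp adp ...`` comment line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    comments, rows = _read_tsv_lines(path)
    if not rows:
        raise NetworkError(f"no reaction rows in {path}")
    header = rows[0]
    try:
        i_id = header.index("reaction_id")
        i_eq = header.index("equation")
        i_pos = header.index("pathway_position")
    except ValueError as exc:
        raise NetworkError(f"missing required column in {path}: {exc}") from exc
    i_kegg = header.index("kegg_ids") if "kegg_ids" in header else None

    cofactors: set[str] = set()
    org_from_file = None
    for c in comments:
        if c.lower().startswith("cofactors:"):
            cofactors.update(c.split(":", 1)[1].split())
        if c.lower().startswith("organism:"):
            org_from_file = c.split(":", 1)[1].strip()

    kegg_map: dict[str, str] = {}
    reactions: list[Reaction] = []
    seen_ids: set[str] = set()
    for row in rows[1:]:
        rid = row[i_id].strip()
        if rid in seen_ids:
            raise NetworkError(f"duplicate reaction id {rid!r} in {path}")
        seen_ids.add(rid)
        stoich = parse_equation(row[i_eq].strip())
        if not stoich:
            raise NetworkError(f"reaction {rid!r} has empty net stoichiometry")
        position = int(row[i_pos])
        if i_kegg is not None and len(row) > i_kegg and row[i_kegg].strip():
            for pair in row[i_kegg].split(";"):
                met, _, kegg = pair.strip().partition("=")
                if kegg:
                    kegg_map[met] = kegg
        reactions.append(Reaction(id=rid, stoichiometry=stoich, pathway_position=position))

    met_ids = sorted({m for r in reactions for m in r.stoichiometry})
    metabolites = [
        MetaboliteSpec(id=m, kegg_id=kegg_map.get(m), is_cofactor=m in cofactors)
        for m in met_ids
    ]
    return PathwayNetwork(
        organism=organism or org_from_file or path.stem,
        metabolites=metabolites,
        reactions=reactions,
    )


def load_thermo_table(path: str | Path) -> ThermoTable:
    """Load a two-column (reaction_id, drg0_kj_mol) TSV with a header block.

    Comment lines ``# temperature_k: <float>`` and ``# provenance: <text>``
    populate the table metadata.
    """
    path = Path(path)
    comments, rows = _read_tsv_lines(path)
    temperature = 298.15
    provenance = []
    for c in comments:
        if c.lower().startswith("temperature_k:"):
            temperature = float(c.split(":", 1)[1])
        elif c.lower().startswith("provenance:"):
            provenance.append(c.split(":", 1)[1].strip())
    if not rows:
        raise NetworkError(f"no rows in {path}")
    header = rows[0]
    i_id = header.index("reaction_id")
    i_g = header.index("drg0_kj_mol")
    drg0 = {row[i_id].strip(): float(row[i_g]) for row in rows[1:]}
    return ThermoTable(drg0=drg0, temperature=temperature, provenance="; ".join(provenance))


_BUNDLED = {
    "eco": ("eco_emp.tsv", "eco_emp_drg0.tsv"),
    "tsac": ("tsac_emp.tsv", "tsac_emp_drg0.tsv"),
    "zmo": ("zmo_ed.tsv", "zmo_ed_drg0.tsv"),
}


def _data_path(fname: str) -> Path:
    return Path(str(resources.files("fermdf").joinpath("data", fname)))


def bundled_network(organism: str) -> PathwayNetwork:
    """Load one of the packaged networks: ``"eco"``, ``"tsac"`` or ``"zmo"``."""
    try:
        fname, _ = _BUNDLED[organism]
    except KeyError:
        raise KeyError(
            f"unknown organism {organism!r}; choose from {sorted(_BUNDLED)}"
        ) from None
    return load_network(_data_path(fname), organism=organism)


def bundled_thermo_table(organism: str) -> ThermoTable:
    try:
        _, fname = _BUNDLED[organism]
    except KeyError:
        raise KeyError(
            f"unknown organism {organism!r}; choose from {sorted(_BUNDLED)}"
        ) from None
    return load_thermo_table(_data_path(fname))


# ---------------------------------------------------------------------------
# Gibbs energy evaluation
# ---------------------------------------------------------------------------

def reaction_drg(
    reaction: Reaction,
    thermo: ThermoTable,
    conc: Mapping[str, float],
) -> float:
    """ΔrG′ (kJ/mol) of one reaction at molar concentrations ``conc``.

    ΔrG′ = ΔrG′° + R·T · Σ_i S_ij · ln c_i — exactly linear in the
    log-concentrations.  All participating metabolites must have a strictly
    positive molar concentration.
    """
    try:
        drg0 = thermo.drg0[reaction.id]
    except KeyError:
        raise NetworkError(f"no ΔrG′° entry for reaction {reaction.id!r}") from None
    total = 0.0
    for met, coeff in reaction.stoichiometry.items():
        c = conc[met]
        if c <= 0:
            raise ValueError(
                f"non-positive concentration {c!r} for metabolite {met!r}"
            )
        total += float(coeff) * math.log(c)
    return drg0 + thermo.rt * total
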