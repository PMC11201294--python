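"""Reaction free energies for syntrophic acid oxidation.

Standard free-energy changes are assembled from tabulated formation
energies, translated to cultivation temperature with the Gibbs-Helmholtz
relation, and corrected to in-situ conditions through the reaction
quotient:

    dG = dG0(T) + R * T * ln(Q)

Activity conventions: aqueous solutes are molar concentrations relative
to 1 mol/L; gases are partial pressures relative to 1 bar (1e5 Pa);
liquid water has unit activity; the proton activity is 10**(-pH).  The
standard free energies returned here therefore refer to unit activity of
every species *including* H+ (pH 0 reference); pH enters exclusively
through Q.  A pH-referenced convenience view is provided by
:func:`delta_g_standard_at_ph`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

#: Gas constant, kJ/(mol K).
R_KJ = 8.314462618e-3
#: Reference temperature for the bundled formation energies, K.
T_REF = 298.15
#: Standard-state gas pressure, Pa (1 bar).
P_STANDARD = 1.0e5

PHASES = ("aqueous", "gas", "liquid-water", "proton")

#: Elemental composition of the bundled species (used for balance checks).
FORMULAS: dict[str, dict[str, int]] = {
    "acetate": {"C": 2, "H": 3, "O": 2},
    "propionate": {"C": 3, "H": 5, "O": 2},
    "H+": {"H": 1},
    "H2": {"H": 2},
    "CO2": {"C": 1, "O": 2},
    "H2O": {"H": 2, "O": 1},
    "CH4": {"C": 1, "H": 4},
}


class ThermoError(ValueError):
    """Raised for invalid thermodynamic inputs (missing species, bad state)."""


@dataclass(frozen=True)
class ThermoSpecies:
    """A chemical species with standard formation energies at 298.15 K."""

    name: str
    phase: str
    delta_g_f: float  # kJ/mol
    delta_h_f: float  # kJ/mol
    charge: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ThermoError(f"unknown phase {self.phase!r} for species {self.name!r}")
        if not (math.isfinite(self.delta_g_f) and math.isfinite(self.delta_h_f)):
            raise ThermoError(f"non-finite formation energy for species {self.name!r}")


@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometry over species names (reactants < 0, products > 0)."""

    name: str
    stoichiometry: Mapping[str, float]
    reference: str = ""

    def species(self) -> list[str]:
        return list(self.stoichiometry)

    def coefficient(self, species: str) -> float:
        return self.stoichiometry.get(species, 0.0)

    def charge_imbalance(self, species_table: Mapping[str, ThermoSpecies]) -> float:
        return sum(
            coeff * species_table[name].charge for name, coeff in self.stoichiometry.items()
        )

    def elemental_imbalance(
        self, formulas: Mapping[str, Mapping[str, int]] = FORMULAS
    ) -> dict[str, float]:
        """Net element counts (products minus reactants); all zero when balanced."""
        net: dict[str, float] = {}
        for name, coeff in self.stoichiometry.items():
            for element, count in formulas[name].items():
                net[element] = net.get(element, 0.0) + coeff * count
        return {el: v for el, v in net.items() if abs(v) > 1e-12}


@dataclass
class ChemicalState:
    """In-situ condition of a culture: solutes, gas partial pressures, pH, T.

    Solute concentrations are mol/L; partial pressures are Pa.
    """

    solute_concentrations: dict[str, float] = field(default_factory=dict)
    gas_partial_pressures: dict[str, float] = field(default_factory=dict)
    pH: float = 7.0
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ThermoError("temperature must be positive (Kelvin)")
        for name, c in self.solute_concentrations.items():
            if c < 0:
                raise ThermoError(f"negative concentration for {name!r}")
        for name, p in self.gas_partial_pressures.items():
            if p < 0:
                raise ThermoError(f"negative partial pressure for {name!r}")


@dataclass
class GibbsResult:
    """Per-state free-energy breakdown for one reaction."""

    reaction: str
    delta_g0_298: float
    delta_h0_298: float
    delta_g0_T: float
    reaction_quotient: float
    delta_g: float
    temperature: float
    unbounded_exergonic: bool = False


def load_species_table(path=None) -> dict[str, ThermoSpecies]:
    """Load a formation-energy table (TSV); defaults to the bundled one."""
    import pandas as pd

    if path is None:
        with resources.as_file(
            resources.files("syntherm.data") / "formation_energies.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"species", "phase", "charge", "dGf_kJ_mol", "dHf_kJ_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ThermoError(f"constants file missing columns: {sorted(missing)}")
    table: dict[str, ThermoSpecies] = {}
    for row in df.itertuples(index=False):
        table[row.species] = ThermoSpecies(
            name=row.species,
            phase=row.phase,
            delta_g_f=float(row.dGf_kJ_mol),
            delta_h_f=float(row.dHf_kJ_mol),
            charge=int(row.charge),
            source=getattr(row, "source", ""),
        )
    return table


def load_reactions(path=None) -> dict[str, Reaction]:
    """Load reaction definitions (YAML); defaults to the bundled three."""
    if path is None:
        text = (resources.files("syntherm.data") / "reactions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    reactions = {}
    for name, spec in raw.items():
        reactions[name] = Reaction(
            name=name,
            stoichiometry={k: float(v) for k, v in spec["stoichiometry"].items()},
            reference=spec.get("reference", ""),
        )
    return reactions


def compute_delta_g_standard(
    reaction: Reaction, species_table: Mapping[str, ThermoSpecies] | Iterable[ThermoSpecies]
) -> tuple[float, float]:
    """(dG0_298, dH0_298) in kJ/mol from formation energies.

    All species at unit activity, including H+ (the conventional pH 0
    standard state); see the module docstring.
    """
    table = _as_table(species_table)
    dg = 0.0
    dh = 0.0
    for name, coeff in reaction.stoichiometry.items():
        if name not in table:
            raise ThermoError(
                f"species {name!r} of reaction {reaction.name!r} missing from constants table"
            )
        sp = table[name]
        dg += coeff * sp.delta_g_f
        dh += coeff * sp.delta_h_f
    return dg, dh


def gibbs_helmholtz(delta_g0_298: float, delta_h0_298: float, target_T: float) -> float:
    """Translate a standard free energy from 298.15 K to ``target_T``.

    dG0(T2) = dG0(T1) * T2/T1 + dH0(T1) * (T1 - T2)/T1  with T1 = 298.15 K.
    """
    if target_T <= 0:
        raise ThermoError("target temperature must be positive (Kelvin)")
    return delta_g0_298 * target_T / T_REF + delta_h0_298 * (T_REF - target_T) / T_REF


def delta_g_standard_at_ph(
    reaction: Reaction,
    species_table,
    pH: float = 7.0,
    temperature: float = T_REF,
) -> float:
    """Standard free energy with H+ referenced to the given pH (biochemists'
    dG0' when pH = 7), other species at unit activity."""
    dg298, dh298 = compute_delta_g_standard(reaction, species_table)
    dg0 = gibbs_helmholtz(dg298, dh298, temperature)
    nu_h = reaction.coefficient("H+")
    return dg0 + nu_h * R_KJ * temperature * math.log(10.0 ** (-pH))


def _as_table(species_table) -> dict[str, ThermoSpecies]:
    if isinstance(species_table, Mapping):
        return dict(species_table)
    return {sp.name: sp for sp in species_table}


def _activity(
    name: str,
    state: ChemicalState,
    table: Mapping[str, ThermoSpecies] | None,
) -> float:
    """Activity of one species under the phase conventions."""
    phase = None
    if table is not None and name in table:
        phase = table[name].phase
    elif name == "H2O":
        phase = "liquid-water"
    elif name == "H+":
        phase = "proton"
    elif name in state.solute_concentrations:
        phase = "aqueous"
    elif name in state.gas_partial_pressures:
        phase = "gas"
    if phase == "liquid-water":
        return 1.0
    if phase == "proton":
        return 10.0 ** (-state.pH)
    if phase == "aqueous":
        if name not in state.solute_concentrations:
            raise ThermoError(f"missing concentration for solute {name!r}")
        return state.solute_concentrations[name]
    if phase == "gas":
        if name not in state.gas_partial_pressures:
            raise ThermoError(f"missing partial pressure for gas {name!r}")
        return state.gas_partial_pressures[name] / P_STANDARD
    raise ThermoError(f"no measurement or phase information for species {name!r}")


def compute_reaction_quotient(
    reaction: Reaction, state: ChemicalState, species_table=None
) -> float:
    """Reaction quotient Q = prod(activity ** coefficient).

    Zero product activity yields Q = 0 (the reaction is unboundedly
    exergonic there); zero reactant activity raises, since ln Q diverges
    to +inf and dG is undefined.
    """
    table = _as_table(species_table) if species_table is not None else None
    log_q = 0.0
    zero_product = False
    for name, coeff in reaction.stoichiometry.items():
        a = _activity(name, state, table)
        if a == 0.0:
            if coeff < 0:
                raise ThermoError(
                    f"reactant {name!r} has zero activity; dG undefined"
                )
            zero_product = True
            continue
        log_q += coeff * math.log(a)
    if zero_product:
        return 0.0
    return math.exp(log_q)


def compute_delta_g(
    reaction: Reaction, state: ChemicalState, species_table
) -> GibbsResult:
    """Full chain: formation energies -> Gibbs-Helmholtz -> quotient -> dG.

    A zero-activity product gives the sentinel ``unbounded_exergonic``
    result with dG = -inf rather than an exception (early timepoints may
    have no measurable product yet).
    """
    table = _as_table(species_table)
    dg298, dh298 = compute_delta_g_standard(reaction, table)
    T = state.temperature
    dg0_T = gibbs_helmholtz(dg298, dh298, T)
    q = compute_reaction_quotient(reaction, state, table)
    if q == 0.0:
        return GibbsResult(
            reaction=reaction.name,
            delta_g0_298=dg298,
            delta_h0_298=dh298,
            delta_g0_T=dg0_T,
            reaction_quotient=0.0,
            delta_g=-math.inf,
            temperature=T,
            unbounded_exergonic=True,
        )
    dg = dg0_T + R_KJ * T * math.log(q)
    return GibbsResult(
        reaction=reaction.name,
        delta_g0_298=dg298,
        delta_h0_298=dh298,
        delta_g0_T=dg0_T,
        reaction_quotient=q,
        delta_g=dg,
        temperature=T,
    )


def critical_concentration(
    reaction: Reaction,
    state: ChemicalState,
    species_table,
    target_species: str,
) -> float:
    """Concentration of ``target_species`` at which dG = 0 (equilibrium).

    All other activities are held at the values in ``state``.  Closed
    form: with Q = c**nu * Q_rest,

        c = exp[ (-dG0_T / (R T) - ln Q_rest) / nu ]

    Only an aqueous species can be inverted.
    """
    table = _as_table(species_table)
    nu = reaction.coefficient(target_species)
    if nu == 0:
        raise ThermoError(
            f"{target_species!r} has zero coefficient in reaction {reaction.name!r}"
        )
    if target_species not in table:
        raise ThermoError(f"unknown species {target_species!r}")
    if table[target_species].phase != "aqueous":
        raise ThermoError(
            f"critical-concentration inversion requires an aqueous species; "
            f"{target_species!r} is {table[target_species].phase}"
        )
    dg298, dh298 = compute_delta_g_standard(reaction, table)
    T = state.temperature
    dg0_T = gibbs_helmholtz(dg298, dh298, T)
    log_q_rest = 0.0
    for name, coeff in reaction.stoichiometry.items():
        if name == target_species:
            continue
        a = _activity(name, state, table)
        if a == 0.0:
            raise ThermoError(f"species {name!r} has zero activity; cannot invert")
        log_q_rest += coeff * math.log(a)
    return math.exp((-dg0_T / (R_KJ * T) - log_q_rest) / nu)


def gibbs_trace(
    states: Iterable[tuple[float, ChemicalState]],
    reaction: Reaction,
    species_table,
) -> list[tuple[float, GibbsResult]]:
    """Evaluate compute_delta_g along a time course of (day, state) pairs."""
    return [(day, compute_delta_g(reaction, st, species_table)) for day, st in states]
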