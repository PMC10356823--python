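"""Conservative fluid mixing and catabolic Gibbs-energy landscapes.

A hydrothermal plume forms when hot, reduced end-member vent fluid mixes with
cold, oxygenated bottom seawater.  Neglecting conductive cooling, both the
temperature and every conservative species concentration of the mixture are
linear in the vent-fluid mass fraction ``f``:

    m_i(f) = f * m_i_vent + (1 - f) * m_i_sw
    T(f)   = f * T_vent   + (1 - f) * T_sw

For each catabolic reaction r available to microorganisms in the mixture the
in-situ Gibbs energy is

    dG_r = dG0_r(T) + R * T_K * ln Q,    Q = prod_i a_i ** nu_i

with activities a_i = gamma_i * m_i (mol/kg), activity coefficients from the
Davies equation, solids and water at unit activity, and dG0_r(T) linearly
interpolated from a packaged per-reaction table (2–121 °C, nominal 500 bar).
The available energy density of a reaction is the exergonic energy released if
it runs to exhaustion of its limiting reagent,

    E_r = max(0, -dG_r) * min_i( m_i / |nu_i| )        [J per kg fluid]

and the percent yield P_r = 100 * E_r / sum(E).  Biomass is estimated as total
available energy divided by a configurable energetic cost per gram of dry
cells.  Mineral precipitation/dissolution and redox re-speciation along the
mixing path are deliberately omitted (conservative mixing only); this is a
documented fidelity limit relative to full reaction-path models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._tsv import read_tsv, write_tsv

R_J_PER_MOL_K = 8.314
DAVIES_A = 0.51
DEFAULT_SEAWATER_T = 2.0

#: ion charges for the default species set; species not listed are neutral.
CHARGES: dict[str, int] = {
    "H+": 1, "OH-": -1, "Na+": 1, "K+": 1, "Cl-": -1, "Ca++": 2, "Mg++": 2,
    "SO4--": -2, "HS-": -1, "S2O3--": -2, "NO3-": -1, "NO2-": -1,
    "HCO3-": -1, "NH4+": 1, "Fe++": 2, "Fe+++": 3, "Mn++": 2,
}

#: pure phases at unit activity (precipitates / native sulfur).
SOLID_SPECIES = frozenset({"S0", "MnO2"})

#: species excluded from the limiting-reagent rule: water is the solvent and
#: protons are buffered in seawater, so neither can meaningfully limit yields.
#: Solid phases keep unit activity but still count as limiting reagents via
#: their (suspended-particle) concentration entries; absent means zero energy.
UNLIMITED_SPECIES = frozenset({"H2O", "H+", "OH-"})

#: elemental composition of the default species, used to validate reactions.
COMPOSITIONS: dict[str, dict[str, float]] = {
    "H+": {"H": 1}, "OH-": {"H": 1, "O": 1}, "H2O": {"H": 2, "O": 1},
    "O2": {"O": 2}, "H2": {"H": 2}, "N2": {"N": 2},
    "CH4": {"C": 1, "H": 4}, "HCO3-": {"C": 1, "H": 1, "O": 3},
    "HS-": {"H": 1, "S": 1}, "S0": {"S": 1}, "SO4--": {"S": 1, "O": 4},
    "S2O3--": {"S": 2, "O": 3}, "NO3-": {"N": 1, "O": 3},
    "NO2-": {"N": 1, "O": 2}, "NH4+": {"N": 1, "H": 4},
    "Fe++": {"Fe": 1}, "Fe+++": {"Fe": 1}, "Mn++": {"Mn": 1},
    "MnO2": {"Mn": 1, "O": 2}, "Na+": {"Na": 1}, "K+": {"K": 1},
    "Cl-": {"Cl": 1}, "Ca++": {"Ca": 1}, "Mg++": {"Mg": 1},
}

DG0_TEMPERATURES_C = (2.0, 25.0, 55.0, 100.0, 121.0)


class ParameterError(ValueError):
    """A parameter is outside its documented range."""


class DataError(ValueError):
    """An input table violates its contract."""


@dataclass
class EndmemberFluid:
    """End-member vent-fluid chemistry (mmol/kg) at temperature ``temperature`` (°C)."""

    label: str
    temperature: float
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        bad = {s: c for s, c in self.concentrations.items() if c < 0}
        if bad:
            raise DataError(f"negative concentrations: {bad}")


@dataclass
class SeawaterComposition:
    """Bottom-seawater chemistry (mmol/kg); default temperature 2 °C."""

    concentrations: dict[str, float]
    temperature: float = DEFAULT_SEAWATER_T

    def __post_init__(self) -> None:
        bad = {s: c for s, c in self.concentrations.items() if c < 0}
        if bad:
            raise DataError(f"negative concentrations: {bad}")


@dataclass
class MixtureState:
    """Chemistry of a vent-fluid/seawater mixture at mass fraction ``f``."""

    f: float
    temperature: float                 # °C
    concentrations: dict[str, float]   # mmol/kg
    ionic_strength: float              # mol/kg
    gamma: dict[str, float]

    @property
    def temperature_k(self) -> float:
        return self.temperature + 273.15

    def activity(self, species: str) -> float:
        """Thermodynamic activity: unit for water and solids, gamma*m (mol/kg) otherwise."""
        if species == "H2O" or species in SOLID_SPECIES:
            return 1.0
        m = self.concentrations.get(species, 0.0) / 1000.0  # mol/kg
        return self.gamma.get(species, 1.0) * m


@dataclass
class CatabolicReaction:
    """One catabolic reaction: signed stoichiometry (products > 0) and a dG0(T) table.

    ``delta_g0`` maps temperature (°C) to the standard-state Gibbs energy of
    reaction in kJ/mol (as written); intermediate temperatures are linearly
    interpolated.
    """

    id: str
    donor: str
    acceptor: str
    stoichiometry: dict[str, float]
    delta_g0: dict[float, float]
    aerobic: bool = True

    def reactants(self) -> dict[str, float]:
        return {s: -nu for s, nu in self.stoichiometry.items() if nu < 0}

    def validate_balance(self, charges: Mapping[str, int] = CHARGES,
                         compositions: Mapping[str, Mapping[str, float]] = COMPOSITIONS,
                         tol: float = 1e-9) -> None:
        """Raise :class:`DataError` if charge or elements are unbalanced."""
        q = sum(nu * charges.get(s, 0) for s, nu in self.stoichiometry.items())
        if abs(q) > tol:
            raise DataError(f"{self.id}: charge imbalance {q}")
        elements: dict[str, float] = {}
        for s, nu in self.stoichiometry.items():
            comp = compositions.get(s)
            if comp is None:
                raise DataError(f"{self.id}: unknown composition for {s}")
            for el, n in comp.items():
                elements[el] = elements.get(el, 0.0) + nu * n
        bad = {el: v for el, v in elements.items() if abs(v) > tol}
        if bad:
            raise DataError(f"{self.id}: element imbalance {bad}")


@dataclass
class EnergyLandscape:
    """Per-reaction energetics of one plume condition (one mixture state)."""

    temperature: float
    table: pd.DataFrame  # columns: reaction, donor, aerobic, delta_g, energy_density, percent_yield
    total_energy: float  # J per kg fluid
    biomass: float       # g dry cells per kg fluid
    biomass_yield: float
    degenerate: bool = False

    def delta_g(self, reaction_id: str) -> float:
        row = self.table.loc[self.table["reaction"] == reaction_id]
        if row.empty:
            raise KeyError(reaction_id)
        return float(row["delta_g"].iloc[0])


# ---------------------------------------------------------------------------
# operations


def mix_fluids(vent: EndmemberFluid, sw: SeawaterComposition, f: float,
               charges: Mapping[str, int] = CHARGES) -> MixtureState:
    """Conservatively mix vent fluid into seawater at mass fraction ``f`` in [0, 1]."""
    if not 0.0 <= f <= 1.0:
        raise ParameterError(f"mixing fraction f={f} outside [0, 1]")
    species = sorted(set(vent.concentrations) | set(sw.concentrations))
    conc = {
        s: f * vent.concentrations.get(s, 0.0) + (1.0 - f) * sw.concentrations.get(s, 0.0)
        for s in species
    }
    temperature = f * vent.temperature + (1.0 - f) * sw.temperature
    ionic_strength, gamma = activity_coefficients(conc, charges)
    return MixtureState(f=f, temperature=temperature, concentrations=conc,
                        ionic_strength=ionic_strength, gamma=gamma)


def activity_coefficients(concentrations: Mapping[str, float],
                          charges: Mapping[str, int] = CHARGES,
                          ) -> tuple[float, dict[str, float]]:
    """Ionic strength (mol/kg) and Davies-equation activity coefficients.

    log10(gamma_i) = -A z_i^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I) with A = 0.51.
    Neutral species get gamma = 1.
    """
    bad = {s: c for s, c in concentrations.items() if c < 0}
    if bad:
        raise DataError(f"negative concentrations: {bad}")
    ionic_strength = 0.5 * sum(
        (c / 1000.0) * charges.get(s, 0) ** 2 for s, c in concentrations.items()
    )
    sqrt_i = math.sqrt(ionic_strength)
    davies = sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength
    gamma = {}
    for s in concentrations:
        z = charges.get(s, 0)
        gamma[s] = 10.0 ** (-DAVIES_A * z * z * davies) if z else 1.0
    return ionic_strength, gamma


def interp_delta_g0(rxn: CatabolicReaction, temperature_c: float) -> float:
    """dG0 (kJ/mol) at ``temperature_c``, linearly interpolated from the reaction table."""
    temps = np.array(sorted(rxn.delta_g0), dtype=float)
    if not temps[0] <= temperature_c <= temps[-1]:
        raise ParameterError(
            f"{rxn.id}: T={temperature_c} °C outside dG0 table range "
            f"[{temps[0]}, {temps[-1]}]"
        )
    values = np.array([rxn.delta_g0[t] for t in temps])
    return float(np.interp(temperature_c, temps, values))


#: nominal trace activity used for product species with zero concentration so
#: that ln Q stays finite; reactions lacking a reactant are +inf (no energy).
TRACE_ACTIVITY = 1e-12


def reaction_delta_g(rxn: CatabolicReaction, state: MixtureState) -> float:
    """In-situ Gibbs energy dG_r = dG0(T) + R T ln Q in kJ/mol."""
    dg0 = interp_delta_g0(rxn, state.temperature)
    ln_q = 0.0
    for s, nu in rxn.stoichiometry.items():
        if s == "H2O" or s in SOLID_SPECIES:
            continue
        a = state.activity(s)
        if a <= 0.0:
            if nu < 0:
                return math.inf  # missing reactant: reaction cannot proceed
            a = TRACE_ACTIVITY
        ln_q += nu * math.log(a)
    return dg0 + R_J_PER_MOL_K * state.temperature_k * ln_q / 1000.0


def energy_landscape(reactions: Iterable[CatabolicReaction], state: MixtureState,
                     biomass_yield: float = 1.0e4) -> EnergyLandscape:
    """Available energy density, percent yields and biomass for one mixture state.

    ``biomass_yield`` is the energetic cost of biosynthesis in J per g dry
    cells; it rescales the biomass estimate only and no canonical constant is
    asserted.
    """
    if biomass_yield <= 0:
        raise ParameterError("biomass_yield must be positive")
    rows = []
    for rxn in reactions:
        dg = reaction_delta_g(rxn, state)
        limiting = math.inf
        for s, nu in rxn.reactants().items():
            if s in UNLIMITED_SPECIES:
                continue
            limiting = min(limiting, state.concentrations.get(s, 0.0) / 1000.0 / nu)
        if math.isinf(limiting):
            limiting = 0.0
        energy = max(0.0, -dg) * limiting * 1000.0  # kJ/mol * mol/kg -> J/kg
        rows.append({"reaction": rxn.id, "donor": rxn.donor, "aerobic": rxn.aerobic,
                     "delta_g": dg, "energy_density": energy})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ParameterError("no reactions supplied")
    total = float(table["energy_density"].sum())
    degenerate = total <= 0.0
    table["percent_yield"] = 0.0 if degenerate else 100.0 * table["energy_density"] / total
    biomass = total / biomass_yield
    return EnergyLandscape(temperature=state.temperature, table=table,
                           total_energy=total, biomass=biomass,
                           biomass_yield=biomass_yield, degenerate=degenerate)


# ---------------------------------------------------------------------------
# default reaction set
#
# Aerobic oxidation of the eight plume electron donors plus nitrate-coupled
# variants for the sulfur species and hydrogen.  dG0 magnitudes are rounded
# literature values for the reactions as written (25 °C, ~500 bar scale); the
# temperature dependence is encoded as a mild linear trend and every table is
# user-overridable via load_reactions().


def _dg0_table(dg25: float, slope: float = 0.10) -> dict[float, float]:
    return {t: round(dg25 + slope * (t - 25.0), 3) for t in DG0_TEMPERATURES_C}


def default_reactions() -> list[CatabolicReaction]:
    specs = [
        ("sulfide_O2", "HS-", "O2", True, -209.0,
         {"HS-": -1, "O2": -0.5, "H+": -1, "S0": 1, "H2O": 1}),
        ("sulfur_O2", "S0", "O2", True, -519.0,
         {"S0": -1, "O2": -1.5, "H2O": -1, "SO4--": 1, "H+": 2}),
        ("thiosulfate_O2", "S2O3--", "O2", True, -785.0,
         {"S2O3--": -1, "O2": -2, "H2O": -1, "SO4--": 2, "H+": 2}),
        ("hydrogen_O2", "H2", "O2", True, -237.0,
         {"H2": -1, "O2": -0.5, "H2O": 1}),
        ("methane_O2", "CH4", "O2", True, -814.0,
         {"CH4": -1, "O2": -2, "HCO3-": 1, "H+": 1, "H2O": 1}),
        ("ammonia_O2", "NH4+", "O2", True, -275.0,
         {"NH4+": -1, "O2": -1.5, "NO2-": 1, "H+": 2, "H2O": 1}),
        ("iron_O2", "Fe++", "O2", True, -44.0,
         {"Fe++": -1, "O2": -0.25, "H+": -1, "Fe+++": 1, "H2O": 0.5}),
        ("manganese_O2", "Mn++", "O2", True, -50.0,
         {"Mn++": -1, "O2": -0.5, "H2O": -1, "MnO2": 1, "H+": 2}),
        ("sulfide_NO3", "HS-", "NO3-", False, -195.0,
         {"HS-": -1, "NO3-": -0.4, "H+": -1.4, "S0": 1, "N2": 0.2, "H2O": 1.2}),
        ("sulfur_NO3", "S0", "NO3-", False, -480.0,
         {"S0": -1, "NO3-": -1.2, "H2O": -0.4, "SO4--": 1, "N2": 0.6, "H+": 0.8}),
        ("thiosulfate_NO3", "S2O3--", "NO3-", False, -725.0,
         {"S2O3--": -1, "NO3-": -1.6, "H2O": -0.2, "SO4--": 2, "N2": 0.8, "H+": 0.4}),
        ("hydrogen_NO3", "H2", "NO3-", False, -224.0,
         {"H2": -1, "NO3-": -0.4, "H+": -0.4, "N2": 0.2, "H2O": 1.2}),
    ]
    reactions = []
    for rid, donor, acceptor, aerobic, dg25, stoich in specs:
        rxn = CatabolicReaction(id=rid, donor=donor, acceptor=acceptor,
                                stoichiometry=stoich, delta_g0=_dg0_table(dg25),
                                aerobic=aerobic)
        rxn.validate_balance()
        reactions.append(rxn)
    return reactions


# ---------------------------------------------------------------------------
# serialization


def write_chemistry(fluid: EndmemberFluid | SeawaterComposition, path) -> None:
    label = getattr(fluid, "label", "seawater")
    df = pd.DataFrame({
        "species": sorted(fluid.concentrations),
        "mmol_per_kg": [fluid.concentrations[s] for s in sorted(fluid.concentrations)],
    })
    df["temperature_c"] = fluid.temperature
    df["label"] = label
    write_tsv(df, path)


def read_chemistry(path) -> EndmemberFluid:
    df = read_tsv(path)
    conc = dict(zip(df["species"], df["mmol_per_kg"].astype(float)))
    temperature = float(df["temperature_c"].iloc[0])
    label = str(df["label"].iloc[0]) if "label" in df else "fluid"
    return EndmemberFluid(label=label, temperature=temperature, concentrations=conc)


def write_reactions(reactions: Iterable[CatabolicReaction], path) -> None:
    payload = [
        {"id": r.id, "donor": r.donor, "acceptor": r.acceptor,
         "aerobic": r.aerobic, "stoichiometry": r.stoichiometry,
         "delta_g0": {str(t): v for t, v in r.delta_g0.items()}}
        for r in reactions
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_reactions(path) -> list[CatabolicReaction]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for rec in payload:
        rxn = CatabolicReaction(
            id=rec["id"], donor=rec["donor"], acceptor=rec["acceptor"],
            aerobic=bool(rec["aerobic"]), stoichiometry=dict(rec["stoichiometry"]),
            delta_g0={float(t): float(v) for t, v in rec["delta_g0"].items()})
        rxn.validate_balance()
        out.append(rxn)
    return out


def write_landscape(landscape: EnergyLandscape, path) -> None:
    df = landscape.table.copy()
    df.insert(0, "temperature_c", landscape.temperature)
    write_tsv(df, path)
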