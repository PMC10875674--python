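"""Kinetic mechanism construction and interchange.

Two packaged models describe the early pyrolysis chemistry:

* model 1 - the ten initial decomposition channels of xylopyranose
  (ring opening to xylose, two ring contractions, seven dehydrations),
  reactions R1-R10 over 12 species;
* model 2 - ring opening followed by the four competing consumption
  channels of open-chain xylose (dehydration to A1 + H2O, cyclization
  to xylofuranose B1, retro-aldol C-C fission to C1 + C2, isomerization
  to xylulose D1), reactions R1 + R11-R14 over 8 species.

Every reaction is reversible.  Forward rates come from the packaged
Arrhenius fits; reverse rate coefficients are evaluated pointwise as
``k_r(T) = k_f(T)/Kc(T)`` from the fitted NASA-7 thermochemistry, which
enforces detailed balance exactly at every temperature (no Arrhenius
refit of the reverse direction).

The stoichiometric formula of ADX is corrected to C5H8O4 for element
balance; the packaged table retains the printed value alongside the
correction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .constants import P_REF
from .thermo_core import (
    ElementCount,
    Nasa7Poly,
    SpeciesRecord,
    equilibrium_constants,
    fit_nasa7,
    parse_formula,
    reaction_thermo,
)
from .tst_kinetics import ArrheniusParams, arrhenius_eval

__all__ = [
    "Reaction",
    "Mechanism",
    "load_species_table",
    "load_arrhenius_table",
    "load_barrier_table",
    "build_model1",
    "build_model2",
    "validate_elements",
    "forward_rate",
    "reverse_rate",
    "to_yaml",
    "from_yaml",
    "write_chemkin_mechanism",
]

MODEL1_REACTIONS = tuple(f"R{i}" for i in range(1, 11))
MODEL2_REACTIONS = ("R1", "R11", "R12", "R13", "R14")


@dataclass
class Reaction:
    """One reversible mass-action reaction.

    ``stoichiometry`` maps species name to the signed coefficient
    (negative for reactants).  All packaged reactions are unimolecular
    in the forward direction.
    """

    id: str
    stoichiometry: Mapping[str, int]
    arrhenius: ArrheniusParams
    reversible: bool = True

    @property
    def reactants(self) -> dict[str, int]:
        return {s: -nu for s, nu in self.stoichiometry.items() if nu < 0}

    @property
    def products(self) -> dict[str, int]:
        return {s: nu for s, nu in self.stoichiometry.items() if nu > 0}

    @property
    def dn(self) -> int:
        return sum(self.stoichiometry.values())


@dataclass
class Mechanism:
    """Species set with fitted thermochemistry plus a reaction list."""

    species: dict[str, SpeciesRecord]
    polys: dict[str, Nasa7Poly]
    reactions: list[Reaction]
    p_ref: float = P_REF

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        for rxn in self.reactions:
            for name in rxn.stoichiometry:
                if name not in self.polys:
                    raise ValueError(
                        f"{rxn.id}: species {name!r} lacks fitted thermochemistry"
                    )

    @property
    def thermo_map(self) -> dict[str, tuple[ElementCount, Nasa7Poly]]:
        return {
            name: (rec.formula, self.polys[name])
            for name, rec in self.species.items()
        }

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)


def _read_packaged_csv(name: str) -> pd.DataFrame:
    text = resources.files("xylokin.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def load_species_table(corrected_formulas: bool = True) -> dict[str, SpeciesRecord]:
    """Load the packaged species thermochemistry table.

    With ``corrected_formulas`` (default), the element-balanced formula
    replaces the printed one where a correction is recorded (ADX).
    """
    df = _read_packaged_csv("species_thermo.csv")
    cp_temps = [300.0, 400.0, 500.0, 600.0, 800.0, 1000.0, 1500.0]
    out: dict[str, SpeciesRecord] = {}
    for _, row in df.iterrows():
        formula_text = row["formula"]
        if corrected_formulas and isinstance(row["formula_corrected"], str):
            formula_text = row["formula_corrected"]
        cp_grid = [
            (t, float(row[f"cp{int(t)}"])) for t in cp_temps
        ]
        out[row["name"]] = SpeciesRecord(
            name=row["name"],
            formula=parse_formula(formula_text),
            dhf298=float(row["dhf298"]),
            s298=float(row["s298"]),
            cp_grid=cp_grid,
            dhf298_so=float(row["dhf298_so"]),
            atct_ref=float(row["atct_ref"]) if pd.notna(row["atct_ref"]) else None,
        )
    return out


def load_arrhenius_table() -> pd.DataFrame:
    """Packaged Arrhenius parameters of R1-R14 (A in 1/s, Ea in kJ/mol)."""
    return _read_packaged_csv("arrhenius_fits.csv")


def load_barrier_table() -> pd.DataFrame:
    """Forward/reverse barriers of the ten initial channels (kJ/mol)."""
    return _read_packaged_csv("barriers_initial.csv")


def _build(reaction_ids: tuple[str, ...]) -> Mechanism:
    table = load_arrhenius_table().set_index("id")
    records = load_species_table()
    reactions: list[Reaction] = []
    needed: set[str] = set()
    for rid in reaction_ids:
        row = table.loc[rid]
        stoich: dict[str, int] = {}
        for name in str(row["reactants"]).split(";"):
            stoich[name] = stoich.get(name, 0) - 1
        for name in str(row["products"]).split(";"):
            stoich[name] = stoich.get(name, 0) + 1
        needed.update(stoich)
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                arrhenius=ArrheniusParams(A=float(row["A"]), Ea=float(row["Ea"])),
            )
        )
    species = {name: records[name] for name in records if name in needed}
    polys = {name: fit_nasa7(rec) for name, rec in species.items()}
    mech = Mechanism(species=species, polys=polys, reactions=reactions)
    report = validate_elements(mech)
    bad = {rid: imb for rid, imb in report.items() if imb}
    if bad:
        raise ValueError(f"element imbalance in packaged mechanism: {bad}")
    return mech


def build_model1() -> Mechanism:
    """The xylopyranose initial-decomposition model (R1-R10, 12 species)."""
    return _build(MODEL1_REACTIONS)


def build_model2() -> Mechanism:
    """The xylose decomposition model (R1 + R11-R14, 8 species)."""
    return _build(MODEL2_REACTIONS)


def validate_elements(mech: Mechanism) -> dict[str, dict[str, int]]:
    """Per-reaction element imbalance vectors; empty dicts mean balanced."""
    report: dict[str, dict[str, int]] = {}
    for rxn in mech.reactions:
        balance: dict[str, int] = {}
        for name, nu in rxn.stoichiometry.items():
            for el, cnt in mech.species[name].formula.items():
                balance[el] = balance.get(el, 0) + nu * cnt
        report[rxn.id] = {el: n for el, n in balance.items() if n != 0}
    return report


def forward_rate(rxn: Reaction, T: float) -> float:
    """Forward rate coefficient at T (1/s for the packaged reactions)."""
    return float(arrhenius_eval(rxn.arrhenius, T))


def equilibrium_kc(mech: Mechanism, rxn: Reaction, T: float) -> float:
    """Concentration-based equilibrium constant of a reaction at T."""
    rt = reaction_thermo(mech.thermo_map, rxn.stoichiometry, T)
    _, kc = equilibrium_constants(rt, p_ref=mech.p_ref)
    return kc


def reverse_rate(mech: Mechanism, rxn: Reaction, T: float) -> float:
    """Reverse rate coefficient k_f(T)/Kc(T) (exact detailed balance).

    For a net mole change dn the result carries (m^3/mol)**dn / s.
    Irreversible reactions return 0.
    """
    if not rxn.reversible:
        return 0.0
    return forward_rate(rxn, T) / equilibrium_kc(mech, rxn, T)


# ---------------------------------------------------------------------------
# Interchange formats
# ---------------------------------------------------------------------------

def to_yaml(mech: Mechanism, path) -> None:
    """Serialise a mechanism (species records + reactions) to YAML."""
    doc = {
        "p_ref_Pa": float(mech.p_ref),
        "units": {
            "A": "1/s",
            "Ea": "kJ/mol",
            "dhf298": "kJ/mol",
            "s298": "J/mol/K",
            "cp": "J/mol/K",
        },
        "species": {
            name: {
                "formula": {k: int(v) for k, v in rec.formula.items()},
                "dhf298": float(rec.dhf298),
                "s298": float(rec.s298),
                "cp_grid": [[float(t), float(c)] for t, c in rec.cp_grid],
            }
            for name, rec in mech.species.items()
        },
        "reactions": [
            {
                "id": rxn.id,
                "stoichiometry": {k: int(v) for k, v in rxn.stoichiometry.items()},
                "A": float(rxn.arrhenius.A),
                "Ea": float(rxn.arrhenius.Ea),
                "reversible": bool(rxn.reversible),
            }
            for rxn in mech.reactions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def from_yaml(path) -> Mechanism:
    """Load a mechanism written by :func:`to_yaml`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    species = {}
    for name, spec in doc["species"].items():
        species[name] = SpeciesRecord(
            name=name,
            formula=dict(spec["formula"]),
            dhf298=spec["dhf298"],
            s298=spec["s298"],
            cp_grid=[tuple(pair) for pair in spec["cp_grid"]],
        )
    polys = {name: fit_nasa7(rec) for name, rec in species.items()}
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry=dict(r["stoichiometry"]),
            arrhenius=ArrheniusParams(A=r["A"], Ea=r["Ea"]),
            reversible=r["reversible"],
        )
        for r in doc["reactions"]
    ]
    return Mechanism(
        species=species, polys=polys, reactions=reactions, p_ref=doc["p_ref_Pa"]
    )


def write_chemkin_mechanism(mech: Mechanism, path) -> None:
    """Write ELEMENTS/SPECIES/THERMO/REACTIONS blocks in CHEMKIN layout.

    Rate units are declared on the REACTIONS line: mole-cm-s with
    activation energies in joules/mole (all packaged forward steps are
    unimolecular, so A is 1/s in any concentration convention).
    """
    from .thermo_core import _chemkin_card

    elements = sorted({el for rec in mech.species.values() for el in rec.formula})
    with open(path, "w") as fh:
        fh.write("! units: A in mole-cm-s (1/s for unimolecular), Ea in J/mol\n")
        fh.write("ELEMENTS\n" + " ".join(elements) + "\nEND\n")
        fh.write("SPECIES\n" + "\n".join(mech.species) + "\nEND\n")
        fh.write("THERMO ALL\n")
        poly0 = next(iter(mech.polys.values()))
        fh.write(f"{poly0.t_low:10.2f}{poly0.t_mid:10.2f}{poly0.t_high:10.2f}\n")
        for name, rec in mech.species.items():
            fh.write(_chemkin_card(name, rec.formula, mech.polys[name]) + "\n")
        fh.write("END\n")
        fh.write("REACTIONS JOULES/MOLE\n")
        for rxn in mech.reactions:
            lhs = " + ".join(
                (f"{n}" if c == 1 else f"{c}{n}") for n, c in rxn.reactants.items()
            )
            rhs = " + ".join(
                (f"{n}" if c == 1 else f"{c}{n}") for n, c in rxn.products.items()
            )
            arrow = "=" if rxn.reversible else "=>"
            fh.write(
                f"{lhs} {arrow} {rhs}  {rxn.arrhenius.A:.9E}  0.0  "
                f"{rxn.arrhenius.Ea * 1000.0:.9E}\n"
            )
        fh.write("END\n")
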