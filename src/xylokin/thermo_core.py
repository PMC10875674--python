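"""Species thermochemistry: chemical formulas, NASA-7 polynomials,
reaction thermodynamics and equilibrium constants.

The packaged tables provide, for each species, the standard enthalpy of
formation and entropy at 298.15 K together with heat capacities on a
seven-point grid (300-1500 K).  :func:`fit_nasa7` converts such a record
into a NASA-7 polynomial whose H and S reproduce the 298.15 K anchors
exactly and whose C_p follows the grid in the least-squares sense.  All
downstream equilibrium constants (and hence all reverse rate constants
of the kinetic models) are evaluated from these polynomials.

Sign and unit conventions: enthalpies and Gibbs energies in kJ/mol,
entropies and heat capacities in J/mol/K, ``dG = dH - T*dS/1000`` on a
single shared evaluation path so the identity holds to machine precision.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import P_REF, R, T_STANDARD

__all__ = [
    "FormulaError",
    "StoichiometryError",
    "ElementCount",
    "SpeciesRecord",
    "Nasa7Poly",
    "ReactionThermo",
    "parse_formula",
    "hill_formula",
    "fit_nasa7",
    "eval_cp_h_s_g",
    "reaction_thermo",
    "equilibrium_constants",
    "write_chemkin_thermo",
    "read_chemkin_thermo",
]


class FormulaError(ValueError):
    """Raised for unparsable or chemically invalid formula strings."""


class StoichiometryError(ValueError):
    """Raised when a reaction's stoichiometry does not element-balance."""


#: Elements recognised in formulas.  The species set is CHO chemistry, but
#: the parser accepts any symbol listed here for extensibility.
KNOWN_ELEMENTS = ("C", "H", "O", "N", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


ElementCount = dict  # mapping element symbol -> non-negative integer count


def parse_formula(text: str) -> ElementCount:
    """Parse a formula string such as ``"C5H10O5"`` into element counts.

    Returns a plain dict mapping element symbol to count.  Symbols not in
    :data:`KNOWN_ELEMENTS` raise :class:`FormulaError`, as does an empty
    or partially unparsable string.
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula string")
    counts: ElementCount = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unparsable formula {text!r} at position {pos}")
        pos = m.end()
        symbol, digits = m.groups()
        if symbol not in KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(text):
        raise FormulaError(f"unparsable formula {text!r} at position {pos}")
    if sum(counts.values()) < 1:
        raise FormulaError(f"formula {text!r} contains no atoms")
    return counts


def hill_formula(counts: Mapping[str, int]) -> str:
    """Canonical Hill-order formula string (C first, H second, then others)."""
    parts = []
    for sym in ("C", "H"):
        n = counts.get(sym, 0)
        if n:
            parts.append(sym + (str(n) if n != 1 else ""))
    for sym in sorted(k for k in counts if k not in ("C", "H")):
        n = counts[sym]
        if n:
            parts.append(sym + (str(n) if n != 1 else ""))
    return "".join(parts)


@dataclass
class SpeciesRecord:
    """One species of the thermochemical table.

    Parameters
    ----------
    name:
        Species label (e.g. ``"xylopyranose"``, ``"AXP_1"``).
    formula:
        Element counts.
    dhf298:
        Standard enthalpy of formation at 298.15 K, kJ/mol.
    s298:
        Standard entropy at 298.15 K, J/mol/K.
    cp_grid:
        Ordered ``(T, C_p)`` pairs, K and J/mol/K, strictly increasing in T.
    dhf298_so:
        Optional spin-orbit-corrected enthalpy of formation, kJ/mol.
    atct_ref:
        Optional reference (ATcT) enthalpy of formation, kJ/mol.
    """

    name: str
    formula: ElementCount
    dhf298: float
    s298: float
    cp_grid: Sequence[tuple[float, float]]
    dhf298_so: float | None = None
    atct_ref: float | None = None

    def __post_init__(self) -> None:
        ts = np.asarray([t for t, _ in self.cp_grid], dtype=float)
        cps = np.asarray([c for _, c in self.cp_grid], dtype=float)
        if ts.size and np.any(np.diff(ts) <= 0):
            raise ValueError(f"{self.name}: cp_grid temperatures must increase")
        if ts.size and np.any(cps <= 0):
            raise ValueError(f"{self.name}: C_p must be positive")
        if self.s298 <= 0:
            raise ValueError(f"{self.name}: s298 must be positive")

    @property
    def cp_temperatures(self) -> np.ndarray:
        return np.asarray([t for t, _ in self.cp_grid], dtype=float)

    @property
    def cp_values(self) -> np.ndarray:
        return np.asarray([c for _, c in self.cp_grid], dtype=float)


@dataclass
class Nasa7Poly:
    """Two-range NASA-7 thermodynamic polynomial.

    ``C_p/R = a1 + a2 T + a3 T^2 + a4 T^3 + a5 T^4``;
    ``H/(RT) = a1 + a2 T/2 + a3 T^2/3 + a4 T^3/4 + a5 T^4/5 + a6/T``;
    ``S/R = a1 ln T + a2 T + a3 T^2/2 + a4 T^3/3 + a5 T^4/4 + a7``.

    The evaluation helpers return C_p and S in J/mol/K and H, G in kJ/mol.
    Evaluation outside ``[t_low, t_high]`` extrapolates with a warning.
    """

    t_low: float
    t_mid: float
    t_high: float
    coeffs_low: np.ndarray
    coeffs_high: np.ndarray
    p_ref: float = P_REF
    fit_residual: float = 0.0  # max |C_p fit residual| over grid, J/mol/K
    t_data_max: float | None = None  # end of the fitted C_p grid, K

    def __post_init__(self) -> None:
        self.coeffs_low = np.asarray(self.coeffs_low, dtype=float)
        self.coeffs_high = np.asarray(self.coeffs_high, dtype=float)
        if self.coeffs_low.shape != (7,) or self.coeffs_high.shape != (7,):
            raise ValueError("NASA-7 polynomial requires 7 coefficients per range")

    def _coeffs(self, T: float) -> np.ndarray:
        if T < self.t_low or T > self.t_high:
            warnings.warn(
                f"T = {T:.1f} K outside NASA-7 range "
                f"[{self.t_low:.1f}, {self.t_high:.1f}] K; extrapolating",
                stacklevel=3,
            )
        elif self.t_data_max is not None and T > self.t_data_max:
            warnings.warn(
                f"T = {T:.1f} K beyond the fitted C_p grid "
                f"(ends at {self.t_data_max:.1f} K); extrapolating the polynomial",
                stacklevel=3,
            )
        return self.coeffs_low if T <= self.t_mid else self.coeffs_high

    def cp(self, T: float) -> float:
        """Heat capacity C_p(T), J/mol/K."""
        a = self._coeffs(T)
        return R * (a[0] + a[1] * T + a[2] * T**2 + a[3] * T**3 + a[4] * T**4)

    def h(self, T: float) -> float:
        """Enthalpy H(T) on the formation-enthalpy scale, kJ/mol."""
        a = self._coeffs(T)
        return (
            R
            * T
            * (
                a[0]
                + a[1] * T / 2
                + a[2] * T**2 / 3
                + a[3] * T**3 / 4
                + a[4] * T**4 / 5
                + a[5] / T
            )
            / 1000.0
        )

    def s(self, T: float) -> float:
        """Standard entropy S(T) at p_ref, J/mol/K."""
        a = self._coeffs(T)
        return R * (
            a[0] * np.log(T)
            + a[1] * T
            + a[2] * T**2 / 2
            + a[3] * T**3 / 3
            + a[4] * T**4 / 4
            + a[6]
        )

    def g(self, T: float) -> float:
        """Gibbs energy G(T) = H(T) - T S(T)/1000, kJ/mol."""
        return self.h(T) - T * self.s(T) / 1000.0


@dataclass
class ReactionThermo:
    """Reaction thermodynamics at one temperature.

    dH in kJ/mol, dS in J/mol/K, dG in kJ/mol, dn the mole-number change
    (sum of stoichiometric coefficients) and T in K.
    """

    dH: float
    dS: float
    dG: float
    dn: int
    T: float


def fit_nasa7(
    rec: SpeciesRecord,
    t_mid: float = 1000.0,
    t_max: float = 2000.0,
    t_low: float = T_STANDARD,
) -> Nasa7Poly:
    """Fit a NASA-7 polynomial to a species record.

    The quartic C_p/R is obtained by unweighted least squares over the
    record's C_p grid; a6 and a7 are then fixed so that H(298.15 K) equals
    ``rec.dhf298`` and S(298.15 K) equals ``rec.s298`` exactly.  The same
    coefficient set is used for both temperature ranges, which makes C_p,
    H and S trivially continuous at ``t_mid``.  The C_p grid ends at
    1500 K, so the span up to ``t_max`` is polynomial extrapolation.

    Raises ``np.linalg.LinAlgError`` via lstsq for degenerate grids and
    :class:`ValueError` for fewer than 5 points.
    """
    ts = rec.cp_temperatures
    cps = rec.cp_values
    if ts.size < 5:
        raise ValueError(
            f"{rec.name}: need at least 5 C_p points to fit NASA-7, got {ts.size}"
        )
    if not (ts[0] <= t_mid <= t_max):
        raise ValueError(f"t_mid={t_mid} outside [{ts[0]}, {t_max}]")
    design = np.vander(ts, 5, increasing=True)
    sol, *_ = np.linalg.lstsq(design, cps / R, rcond=None)
    a = np.zeros(7)
    a[:5] = sol
    T0 = t_low
    # Anchor H(T0) = dhf298 (kJ/mol) and S(T0) = s298 (J/mol/K) exactly.
    h_poly = T0 * (
        a[0] + a[1] * T0 / 2 + a[2] * T0**2 / 3 + a[3] * T0**3 / 4 + a[4] * T0**4 / 5
    )
    a[5] = rec.dhf298 * 1000.0 / R - h_poly
    s_poly = (
        a[0] * np.log(T0)
        + a[1] * T0
        + a[2] * T0**2 / 2
        + a[3] * T0**3 / 3
        + a[4] * T0**4 / 4
    )
    a[6] = rec.s298 / R - s_poly
    residual = float(np.max(np.abs(design @ sol * R - cps))) if ts.size else 0.0
    return Nasa7Poly(
        t_low=t_low,
        t_mid=t_mid,
        t_high=t_max,
        coeffs_low=a,
        coeffs_high=a.copy(),
        fit_residual=residual,
        t_data_max=float(ts[-1]),
    )


def eval_cp_h_s_g(poly: Nasa7Poly, T: float) -> tuple[float, float, float, float]:
    """Evaluate (C_p, H, S, G) at T: J/mol/K, kJ/mol, J/mol/K, kJ/mol."""
    return poly.cp(T), poly.h(T), poly.s(T), poly.g(T)


def reaction_thermo(
    species: Mapping[str, tuple[ElementCount, Nasa7Poly]],
    stoichiometry: Mapping[str, int],
    T: float,
) -> ReactionThermo:
    """Reaction Delta-quantities at T from fitted species polynomials.

    ``species`` maps name -> (element counts, fitted polynomial);
    ``stoichiometry`` maps name -> signed coefficient (negative for
    reactants).  The stoichiometry must element-balance.
    """
    balance: dict[str, int] = {}
    for name, nu in stoichiometry.items():
        if name not in species:
            raise StoichiometryError(f"species {name!r} missing from the set")
        for el, cnt in species[name][0].items():
            balance[el] = balance.get(el, 0) + nu * cnt
    imbalance = {el: n for el, n in balance.items() if n != 0}
    if imbalance:
        raise StoichiometryError(f"element imbalance {imbalance}")
    dH = 0.0
    dS = 0.0
    dn = 0
    for name, nu in stoichiometry.items():
        poly = species[name][1]
        dH += nu * poly.h(T)
        dS += nu * poly.s(T)
        dn += nu
    dG = dH - T * dS / 1000.0
    return ReactionThermo(dH=dH, dS=dS, dG=dG, dn=dn, T=T)


def equilibrium_constants(rt: ReactionThermo, p_ref: float = P_REF) -> tuple[float, float]:
    """Equilibrium constants (Kp, Kc) from reaction thermodynamics.

    ``Kp = exp(-dG*1000/(R T))`` is dimensionless on the p_ref standard
    state; ``Kc = Kp * (p_ref/(R T))**dn`` carries (mol/m^3)**dn so that
    mass-action rates written in mol/m^3 satisfy detailed balance.
    """
    kp = float(np.exp(-rt.dG * 1000.0 / (R * rt.T)))
    kc = kp * (p_ref / (R * rt.T)) ** rt.dn
    return kp, kc


# ---------------------------------------------------------------------------
# CHEMKIN fixed-column THERMO interchange
# ---------------------------------------------------------------------------

def _chemkin_card(name: str, formula: Mapping[str, int], poly: Nasa7Poly) -> str:
    """Format one 4-line fixed-column THERMO card."""
    comp = ""
    for el, n in list(formula.items())[:4]:
        comp += f"{el:<2s}{n:>3d}"
    comp = comp.ljust(20)
    line1 = (
        f"{name:<18s}{'':6s}{comp}G{poly.t_low:10.2f}{poly.t_high:10.2f}"
        f"{poly.t_mid:8.2f}{'':6s}1"
    )
    coeffs = list(poly.coeffs_high) + list(poly.coeffs_low)
    lines = [line1]
    for i, count in enumerate((5, 5, 4), start=2):
        chunk = coeffs[: count]
        coeffs = coeffs[count:]
        body = "".join(f"{c:15.8E}" for c in chunk)
        lines.append(f"{body:<75s}{i}")
    return "\n".join(lines)


def write_chemkin_thermo(
    species: Mapping[str, tuple[ElementCount, Nasa7Poly]], path
) -> None:
    """Write a CHEMKIN THERMO ALL block (NASA-7, 15-column coefficients)."""
    first = next(iter(species.values()))[1]
    with open(path, "w") as fh:
        fh.write("THERMO ALL\n")
        fh.write(f"{first.t_low:10.2f}{first.t_mid:10.2f}{first.t_high:10.2f}\n")
        for name, (formula, poly) in species.items():
            fh.write(_chemkin_card(name, formula, poly) + "\n")
        fh.write("END\n")


def read_chemkin_thermo(path) -> dict[str, tuple[ElementCount, Nasa7Poly]]:
    """Read a CHEMKIN THERMO block written by :func:`write_chemkin_thermo`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("THERMO"):
        raise ValueError("not a CHEMKIN THERMO file")
    out: dict[str, tuple[ElementCount, Nasa7Poly]] = {}
    i = 2  # skip header + default temperature line
    while i < len(lines):
        line = lines[i]
        if line.strip().upper().startswith("END"):
            break
        name = line[:18].strip()
        comp: ElementCount = {}
        for k in range(4):
            seg = line[24 + 5 * k : 24 + 5 * (k + 1)]
            el = seg[:2].strip()
            if el:
                comp[el] = int(seg[2:].strip())
        t_low = float(line[45:55])
        t_high = float(line[55:65])
        t_mid = float(line[65:73])
        raw = lines[i + 1][:75] + lines[i + 2][:75] + lines[i + 3][:60]
        coeffs = [float(raw[15 * j : 15 * (j + 1)]) for j in range(14)]
        poly = Nasa7Poly(
            t_low=t_low,
            t_mid=t_mid,
            t_high=t_high,
            coeffs_low=np.array(coeffs[7:]),
            coeffs_high=np.array(coeffs[:7]),
        )
        out[name] = (comp, poly)
        i += 4
    return out
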