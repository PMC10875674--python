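"""Seeded synthetic-data generators with known ground truth.

Every stage of the pipeline can be exercised without external data:

* :func:`make_nasa_species` draws a physically plausible NASA-7
  polynomial (positive, increasing C_p) and samples it on the packaged
  seven-temperature grid, so the NASA-7 fitter can be checked by
  round trip;
* :func:`make_arrhenius_samples` draws rate constants from known
  Arrhenius parameters with optional multiplicative log-normal noise;
* :func:`make_toy_network` builds minimal one/two-reaction mechanisms
  (A->B, A<=>B, A->B->C) whose trajectories have textbook closed forms,
  with fabricated thermochemistry tuned to a requested equilibrium
  constant for the reversible case.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import R
from .mechanism_io import Mechanism, Reaction
from .thermo_core import Nasa7Poly, SpeciesRecord, fit_nasa7
from .tst_kinetics import ArrheniusParams

__all__ = [
    "CP_GRID_TEMPS",
    "ToySolution",
    "make_nasa_species",
    "make_arrhenius_samples",
    "make_toy_network",
]

#: The seven-temperature C_p grid used by the packaged species table, K.
CP_GRID_TEMPS = (300.0, 400.0, 500.0, 600.0, 800.0, 1000.0, 1500.0)


def make_nasa_species(seed: int) -> tuple[SpeciesRecord, Nasa7Poly]:
    """Random valid NASA-7 polynomial plus its sampled species record.

    C_p is constructed monotonically increasing within 20-500 J/mol/K by
    integrating a non-negative cubic; H/S anchors are drawn uniformly.
    Identical seeds produce identical cases.
    """
    rng = np.random.default_rng(seed)
    cp_start = rng.uniform(25.0, 150.0)
    rise = rng.uniform(10.0, min(250.0, 480.0 - cp_start))
    b = rng.uniform(0.0, 1.0, size=4)  # dC_p/ds coefficients, s = T/1000 K
    s0, s1 = 0.29815, 1.5
    powers = np.arange(1, 5)
    total = np.sum(b * (s1**powers - s0**powers) / powers)
    b *= rise / total
    # C_p(s) = c0 + sum_k b_k s^k / k; shift c0 so C_p(s0) = cp_start.
    c = np.zeros(5)
    c[1:] = b / powers
    c[0] = cp_start - np.sum(c[1:] * s0**powers)
    a = np.zeros(7)
    a[:5] = c / (R * 1000.0 ** np.arange(5))
    dhf298 = rng.uniform(-900.0, -100.0)
    s298 = rng.uniform(180.0, 430.0)
    T0 = 298.15
    h_poly = T0 * (
        a[0] + a[1] * T0 / 2 + a[2] * T0**2 / 3 + a[3] * T0**3 / 4 + a[4] * T0**4 / 5
    )
    a[5] = dhf298 * 1000.0 / R - h_poly
    s_poly = (
        a[0] * np.log(T0)
        + a[1] * T0
        + a[2] * T0**2 / 2
        + a[3] * T0**3 / 3
        + a[4] * T0**4 / 4
    )
    a[6] = s298 / R - s_poly
    truth = Nasa7Poly(
        t_low=T0, t_mid=1000.0, t_high=2000.0, coeffs_low=a, coeffs_high=a.copy()
    )
    rec = SpeciesRecord(
        name=f"synthetic_{seed}",
        formula={"C": 1, "H": 2, "O": 1},
        dhf298=dhf298,
        s298=s298,
        cp_grid=[(t, truth.cp(t)) for t in CP_GRID_TEMPS],
    )
    return rec, truth


def make_arrhenius_samples(
    A: float,
    Ea: float,
    T_grid: Sequence[float],
    sigma_ln: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Rate-constant samples k_i = A exp(-Ea/(R T_i)) exp(eps_i).

    ``eps_i`` are seeded normal deviates with standard deviation
    ``sigma_ln`` (multiplicative log-normal noise); Ea in kJ/mol.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    T_grid = np.asarray(T_grid, dtype=float)
    k = A * np.exp(-Ea * 1000.0 / (R * T_grid))
    if sigma_ln > 0:
        rng = np.random.default_rng(seed)
        k = k * np.exp(rng.normal(0.0, sigma_ln, size=T_grid.shape))
    return k


@dataclass
class ToySolution:
    """Closed-form solution handle of a toy network.

    ``fractions(t)`` returns the exact mole fractions at time t (scalar
    or array) as a dict of arrays; ``equilibrium`` holds the t->inf
    fractions where defined.
    """

    kind: str
    parameters: dict
    fractions: Callable[[np.ndarray], dict[str, np.ndarray]]
    equilibrium: dict[str, float] | None = None


def _toy_species(name: str, s298: float) -> SpeciesRecord:
    # Flat C_p and shared formula: reaction Delta-Cp and element balance
    # vanish identically, so the fabricated Kp is temperature-independent.
    return SpeciesRecord(
        name=name,
        formula={"C": 1, "H": 2, "O": 1},
        dhf298=-100.0,
        s298=s298,
        cp_grid=[(t, 100.0) for t in CP_GRID_TEMPS],
    )


def make_toy_network(
    kind: str, params: Mapping[str, float] | None = None
) -> tuple[Mechanism, ToySolution]:
    """Minimal mechanism with a textbook closed-form solution.

    ``kind`` is one of ``"A->B"`` (irreversible, rate ``k1``),
    ``"A<=>B"`` (forward ``k1``, equilibrium constant ``Kp``) or
    ``"A->B->C"`` (rates ``k1``, ``k2``).  Defaults: k1 = k2 = 1.0 /s,
    Kp = 4.0.  Fabricated thermochemistry keeps dn = 0 and a
    temperature-independent Kp, so the closed forms hold exactly in the
    constant-pressure reactor.
    """
    p = {"k1": 1.0, "k2": 1.0, "Kp": 4.0}
    p.update(params or {})
    k1, k2, kp = p["k1"], p["k2"], p["Kp"]
    s_base = 250.0

    if kind == "A->B":
        species = {
            "A": _toy_species("A", s_base),
            "B": _toy_species("B", s_base),
        }
        reactions = [
            Reaction(
                id="T1",
                stoichiometry={"A": -1, "B": 1},
                arrhenius=ArrheniusParams(A=k1, Ea=0.0),
                reversible=False,
            )
        ]

        def fractions(t):
            t = np.asarray(t, dtype=float)
            xa = np.exp(-k1 * t)
            return {"A": xa, "B": 1.0 - xa}

        solution = ToySolution(kind=kind, parameters=p, fractions=fractions)

    elif kind == "A<=>B":
        species = {
            "A": _toy_species("A", s_base),
            "B": _toy_species("B", s_base + R * np.log(kp)),
        }
        reactions = [
            Reaction(
                id="T1",
                stoichiometry={"A": -1, "B": 1},
                arrhenius=ArrheniusParams(A=k1, Ea=0.0),
                reversible=True,
            )
        ]
        kr = k1 / kp
        xa_eq = kr / (k1 + kr)

        def fractions(t):
            t = np.asarray(t, dtype=float)
            xa = xa_eq + (1.0 - xa_eq) * np.exp(-(k1 + kr) * t)
            return {"A": xa, "B": 1.0 - xa}

        solution = ToySolution(
            kind=kind,
            parameters=p,
            fractions=fractions,
            equilibrium={"A": xa_eq, "B": 1.0 - xa_eq},
        )

    elif kind == "A->B->C":
        species = {
            "A": _toy_species("A", s_base),
            "B": _toy_species("B", s_base),
            "C": _toy_species("C", s_base),
        }
        reactions = [
            Reaction(
                id="T1",
                stoichiometry={"A": -1, "B": 1},
                arrhenius=ArrheniusParams(A=k1, Ea=0.0),
                reversible=False,
            ),
            Reaction(
                id="T2",
                stoichiometry={"B": -1, "C": 1},
                arrhenius=ArrheniusParams(A=k2, Ea=0.0),
                reversible=False,
            ),
        ]

        def fractions(t):
            t = np.asarray(t, dtype=float)
            xa = np.exp(-k1 * t)
            if np.isclose(k1, k2):
                xb = k1 * t * np.exp(-k1 * t)
            else:
                xb = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
            return {"A": xa, "B": xb, "C": 1.0 - xa - xb}

        solution = ToySolution(kind=kind, parameters=p, fractions=fractions)

    else:
        raise ValueError(f"unknown toy-network kind {kind!r}")

    polys = {name: fit_nasa7(rec) for name, rec in species.items()}
    mech = Mechanism(species=species, polys=polys, reactions=reactions)
    return mech, solution
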