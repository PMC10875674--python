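"""0-D constant-pressure batch reactor with prescribed temperature.

The reactor integrates reversible mass-action kinetics for an ideal-gas
mixture held at constant pressure while the temperature follows a
prescribed program (fixed temperature, or a linear heating ramp that
emulates a thermogravimetric experiment).  The state vector is the set
of species mole numbers, so element conservation can be checked exactly;
the volume ``V = n_tot R T / P`` is recomputed continuously and the
energy balance is never solved (the reactor is thermostatted).

Reverse rate coefficients are evaluated from the equilibrium constant at
the current temperature, ``k_r = k_f / Kc``, so detailed balance holds
exactly at every solver step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import P_REF, R
from .mechanism_io import Mechanism

__all__ = [
    "TemperatureProgram",
    "Trajectory",
    "IntegrationError",
    "simulate",
    "tga_onset",
    "export_trajectory",
]

#: Default heating rate for ramp programs, K/min.
DEFAULT_RAMP_RATE = 20.0


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the last valid state."""

    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class TemperatureProgram:
    """Prescribed reactor temperature.

    ``kind`` is ``"isothermal"`` (temperature ``T0`` for ``t_end``
    seconds) or ``"ramp"`` (linear heating from ``T0`` at ``rate`` K/min
    until ``T_end``).
    """

    kind: str
    T0: float
    t_end: float | None = None
    rate: float | None = None  # K/min
    T_end: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("isothermal", "ramp"):
            raise ValueError(f"unknown program kind {self.kind!r}")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if self.kind == "isothermal":
            if self.t_end is None or self.t_end <= 0:
                raise ValueError("isothermal program needs t_end > 0")
        else:
            if self.rate is None or self.rate <= 0:
                raise ValueError("ramp program needs rate > 0 (K/min)")
            if self.T_end is None or self.T_end <= self.T0:
                raise ValueError("ramp program needs T_end > T0")

    def temperature(self, t: float | np.ndarray) -> float | np.ndarray:
        if self.kind == "isothermal":
            return self.T0 + 0.0 * np.asarray(t, dtype=float)
        return self.T0 + self.rate / 60.0 * np.asarray(t, dtype=float)

    @property
    def duration(self) -> float:
        if self.kind == "isothermal":
            return float(self.t_end)
        return (self.T_end - self.T0) * 60.0 / self.rate

    @classmethod
    def isothermal(cls, T: float, t_end: float) -> "TemperatureProgram":
        return cls(kind="isothermal", T0=T, t_end=t_end)

    @classmethod
    def ramp(
        cls, T0: float, T_end: float, rate: float = DEFAULT_RAMP_RATE
    ) -> "TemperatureProgram":
        return cls(kind="ramp", T0=T0, rate=rate, T_end=T_end)


@dataclass
class Trajectory:
    """Saved reactor states: times (s), temperatures (K), moles (mol),
    volumes (m^3) and per-reaction net rates (mol/m^3/s)."""

    species: list[str]
    reaction_ids: list[str]
    times: np.ndarray
    temperatures: np.ndarray
    moles: np.ndarray  # (n_times, n_species)
    volumes: np.ndarray
    net_rates: np.ndarray  # (n_times, n_reactions)
    pressure: float
    #: Per-reaction net extents integrated along with the state (mol).
    extents: np.ndarray | None = None

    @property
    def mole_fractions(self) -> np.ndarray:
        return self.moles / self.moles.sum(axis=1, keepdims=True)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def mole_fraction(self, name: str) -> np.ndarray:
        return self.mole_fractions[:, self.index(name)]

    def consumed_fraction(self, name: str) -> np.ndarray:
        n0 = self.moles[0, self.index(name)]
        return 1.0 - self.moles[:, self.index(name)] / n0


class _Kinetics:
    """Vectorised rate/thermo evaluation for one mechanism."""

    def __init__(self, mech: Mechanism):
        self.mech = mech
        self.names = list(mech.species)
        idx = {n: i for i, n in enumerate(self.names)}
        nr, ns = len(mech.reactions), len(self.names)
        self.nu = np.zeros((nr, ns))
        self.react_nu = np.zeros((nr, ns))
        self.prod_nu = np.zeros((nr, ns))
        self.A = np.empty(nr)
        self.Ea = np.empty(nr)
        self.reversible = np.zeros(nr, dtype=bool)
        for j, rxn in enumerate(mech.reactions):
            self.A[j] = rxn.arrhenius.A
            self.Ea[j] = rxn.arrhenius.Ea * 1000.0
            self.reversible[j] = rxn.reversible
            for name, nu in rxn.stoichiometry.items():
                i = idx[name]
                self.nu[j, i] += nu
                if nu < 0:
                    self.react_nu[j, i] += -nu
                else:
                    self.prod_nu[j, i] += nu
        self.dn = self.nu.sum(axis=1)
        self.coeffs_low = np.array([mech.polys[n].coeffs_low for n in self.names])
        self.coeffs_high = np.array([mech.polys[n].coeffs_high for n in self.names])
        self.t_mid = next(iter(mech.polys.values())).t_mid

    def _g_rt(self, T: float) -> np.ndarray:
        """Dimensionless standard Gibbs energy g_i/(R T) per species."""
        a = self.coeffs_low if T <= self.t_mid else self.coeffs_high
        h_rt = (
            a[:, 0]
            + a[:, 1] * T / 2
            + a[:, 2] * T**2 / 3
            + a[:, 3] * T**3 / 4
            + a[:, 4] * T**4 / 5
            + a[:, 5] / T
        )
        s_r = (
            a[:, 0] * np.log(T)
            + a[:, 1] * T
            + a[:, 2] * T**2 / 2
            + a[:, 3] * T**3 / 3
            + a[:, 4] * T**4 / 4
            + a[:, 6]
        )
        return h_rt - s_r

    def rate_coefficients(self, T: float) -> tuple[np.ndarray, np.ndarray]:
        kf = self.A * np.exp(-self.Ea / (R * T))
        dg_rt = self.nu @ self._g_rt(T)
        ln_kc = -dg_rt + self.dn * np.log(self.mech.p_ref / (R * T))
        kr = np.where(self.reversible, kf * np.exp(-ln_kc), 0.0)
        return kf, kr

    def net_rates(self, n: np.ndarray, T: float, P: float) -> np.ndarray:
        """Per-reaction net rates, mol/m^3/s."""
        kf, kr = self.rate_coefficients(T)
        V = max(n.sum(), 1e-300) * R * T / P
        conc = np.clip(n, 0.0, None) / V
        log_c = np.log(np.clip(conc, 1e-300, None))
        fwd = kf * np.exp(self.react_nu @ log_c)
        rev = kr * np.exp(self.prod_nu @ log_c)
        # A species with zero concentration contributes zero flux in the
        # direction that consumes it (the log-clip floor would otherwise
        # leave a tiny spurious rate).
        fwd[np.asarray((self.react_nu > 0) @ (conc <= 0.0), dtype=bool)] = 0.0
        rev[np.asarray((self.prod_nu > 0) @ (conc <= 0.0), dtype=bool)] = 0.0
        return fwd - rev


def simulate(
    mech: Mechanism,
    program: TemperatureProgram,
    P: float = P_REF,
    initial: Mapping[str, float] | None = None,
    n0_total: float = 1.0,
    n_points: int = 400,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-20,
    stop_at_conversion: tuple[str, float] | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the reactor and return the saved trajectory.

    ``initial`` maps species names to mole fractions (normalised to 1);
    the default is pure first-listed species (pure xylopyranose for the
    packaged models).  ``stop_at_conversion=(name, f)``
    terminates the run once the named species' consumed fraction reaches
    ``f``.  Output points are log-spaced in time for isothermal runs and
    1 K-spaced for ramps.
    """
    kin = _Kinetics(mech)
    if initial is None:
        initial = {kin.names[0]: 1.0}
    x0 = np.zeros(len(kin.names))
    for name, x in initial.items():
        x0[kin.names.index(name)] = x
    if not np.isclose(x0.sum(), 1.0):
        raise ValueError("initial composition must normalise to 1")
    n0 = n0_total * x0

    t_end = program.duration
    if program.kind == "isothermal":
        t_eval = np.concatenate(
            [[0.0], np.geomspace(t_end * 1e-10, t_end, max(n_points, 200))]
        )
    else:
        n_steps = max(int(round(program.T_end - program.T0)), 2)
        t_eval = np.linspace(0.0, t_end, n_steps + 1)

    ns = len(kin.names)

    # State vector: species moles followed by per-reaction net extents,
    # so integrated fluxes carry the solver's accuracy rather than a
    # quadrature over saved points.
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n = y[:ns]
        T = float(program.temperature(t))
        r = kin.net_rates(n, T, P)
        V = max(n.sum(), 1e-300) * R * T / P
        return np.concatenate([V * (kin.nu.T @ r), V * r])

    events = []
    if stop_at_conversion is not None:
        name, frac = stop_at_conversion
        i_target = kin.names.index(name)
        target = (1.0 - frac) * n0[i_target]

        def conversion_event(t: float, y: np.ndarray) -> float:
            return y[i_target] - target

        conversion_event.terminal = True
        conversion_event.direction = -1
        events.append(conversion_event)

    y0 = np.concatenate([n0, np.zeros(len(mech.reactions))])
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        events=events or None,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"stiff integration failed: {sol.message}")

    times = sol.t
    states = sol.y.T
    if events and sol.t_events[0].size:
        times = np.append(times, sol.t_events[0][0])
        states = np.vstack([states, sol.y_events[0][0]])
    moles = states[:, :ns]
    extents = states[:, ns:]
    temps = np.asarray(program.temperature(times), dtype=float)
    volumes = moles.sum(axis=1) * R * temps / P
    rates = np.empty((times.size, len(mech.reactions)))
    for k in range(times.size):
        rates[k] = kin.net_rates(moles[k], float(temps[k]), P)
    return Trajectory(
        species=kin.names,
        reaction_ids=[rxn.id for rxn in mech.reactions],
        times=times,
        temperatures=temps,
        moles=moles,
        volumes=volumes,
        net_rates=rates,
        pressure=P,
        extents=extents,
    )


def tga_onset(
    traj: Trajectory, threshold: float, species: str | None = None
) -> float:
    """Onset temperature: first T at which the consumed fraction of the
    initial reactant exceeds ``threshold`` (linear interpolation).

    Returns NaN with a warning if the threshold is never reached;
    ``threshold <= 0`` returns the starting temperature.
    """
    if species is None:
        species = traj.species[int(np.argmax(traj.moles[0]))]
    if threshold <= 0:
        return float(traj.temperatures[0])
    consumed = traj.consumed_fraction(species)
    above = np.nonzero(consumed >= threshold)[0]
    if above.size == 0:
        warnings.warn(
            f"consumed fraction of {species} never reached {threshold}; "
            "returning NaN"
        )
        return float("nan")
    k = above[0]
    if k == 0:
        return float(traj.temperatures[0])
    f0, f1 = consumed[k - 1], consumed[k]
    T0, T1 = traj.temperatures[k - 1], traj.temperatures[k]
    return float(T0 + (threshold - f0) / (f1 - f0) * (T1 - T0))


def export_trajectory(traj: Trajectory, path) -> None:
    """Write the trajectory as delimited text (time, T, mole fractions)."""
    header = "time_s\tT_K\t" + "\t".join(f"x_{s}" for s in traj.species)
    data = np.column_stack([traj.times, traj.temperatures, traj.mole_fractions])
    np.savetxt(path, data, header=header, comments="", delimiter="\t")
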