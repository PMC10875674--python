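"""Conventional transition-state-theory rate constants.

The high-pressure-limit rate constant of a unimolecular channel is

    k(T) = kappa(T) * (m_ts/m_r) * (sigma_r/sigma_ts) * (k_B T/h)
           * (Z_ts/Z_r) * exp(-E0/(R T))

with ``kappa`` the one-dimensional asymmetric Eckart transmission
coefficient (tunneling plus nonclassical reflection), ``m`` enantiomer
counts, ``sigma`` external rotational symmetry numbers, ``Z`` RRHO
partition functions with the vibrational zero at the ZPE level, and
``E0`` the ZPE-inclusive barrier.  Harmonic frequencies and the ZPE are
scaled by 0.970 throughout.

Thermochemistry-side entropies can use Grimme's quasi-harmonic
interpolation toward a free rotor for low-frequency torsions; the rate
expression itself stays purely RRHO.

Arrhenius utilities fit ``ln k`` against ``1/T`` and evaluate
``k = A exp(-Ea/(R T))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import quad

from .constants import C_LIGHT, HC_K, H_PLANCK, K_B, N_A, P_REF, R, WAVENUMBER_KJ

__all__ = [
    "StationaryPoint",
    "ReactionChannel",
    "ArrheniusParams",
    "ChannelError",
    "scaled_zpe",
    "vibrational_factor",
    "rrho_partition",
    "qh_entropy",
    "eckart_kappa",
    "tst_rate",
    "eyring_rate",
    "arrhenius_fit",
    "arrhenius_eval",
    "load_stationary_points",
    "DEFAULT_FIT_GRID",
]

AMU = 1.66053906660e-27  # kg

#: Temperature grid used for Arrhenius fitting of computed rate constants:
#: 300-1000 K in 25 K steps.
DEFAULT_FIT_GRID = np.arange(300.0, 1000.0 + 1e-9, 25.0)

#: Default harmonic frequency / ZPE scale factor.
DEFAULT_FREQ_SCALE = 0.970


class ChannelError(ValueError):
    """Raised for incomplete reaction channels (e.g. no imaginary mode)."""


@dataclass
class StationaryPoint:
    """Rovibrational data of a minimum or saddle point.

    Frequencies and rotational constants in cm^-1, mass in amu, energies
    in kJ/mol.  ``sigma_ext`` is the external rotational symmetry number
    and ``m_enantiomers`` the number of distinguishable enantiomers.
    Transition states carry the magnitude of their single imaginary
    frequency in ``imaginary_freq``.
    """

    name: str
    frequencies: Sequence[float]
    rot_constants: Sequence[float]
    mass: float
    electronic_energy: float = 0.0
    zpe: float | None = None
    freq_scale: float = DEFAULT_FREQ_SCALE
    sigma_ext: int = 1
    m_enantiomers: int = 1
    linear: bool = False
    imaginary_freq: float | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.size and np.any(freqs <= 0):
            raise ValueError(f"{self.name}: real frequencies must be positive")
        if self.sigma_ext < 1 or self.m_enantiomers < 1:
            raise ValueError(f"{self.name}: symmetry/enantiomer numbers must be >= 1")
        if self.imaginary_freq is not None and self.imaginary_freq <= 0:
            raise ValueError(f"{self.name}: imaginary_freq must be positive")

    @property
    def is_ts(self) -> bool:
        return self.imaginary_freq is not None


@dataclass
class ReactionChannel:
    """A reactant/transition-state pair with ZPE-inclusive barriers (kJ/mol)."""

    reactants: Sequence[StationaryPoint]
    ts: StationaryPoint
    E0: float
    E0_reverse: float


@dataclass
class ArrheniusParams:
    """Arrhenius parameters: A in 1/s (unimolecular), Ea in kJ/mol.

    ``fit_rss`` is the residual sum of squares of the ln-space fit.
    """

    A: float
    Ea: float
    fit_rss: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("pre-exponential factor must be positive")


def scaled_zpe(freqs: Sequence[float], scale: float = DEFAULT_FREQ_SCALE) -> float:
    """Zero-point energy 0.5*h*c*sum(nu)*scale in kJ/mol."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        return 0.0
    return float(0.5 * WAVENUMBER_KJ * scale * freqs.sum())


def vibrational_factor(nu: float, T: float, scale: float = 1.0) -> float:
    """ZPE-referenced harmonic partition function of one mode."""
    theta = HC_K * nu * scale
    return 1.0 / (1.0 - np.exp(-theta / T))


def rrho_partition(sp: StationaryPoint, T: float) -> float:
    """RRHO partition function (translation per m^3, rotation, vibration).

    The vibrational zero is the ZPE level and frequencies are scaled by
    ``sp.freq_scale``.  Rotational symmetry is *not* folded in here; the
    symmetry-number ratio enters the rate expression explicitly.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    m = sp.mass * AMU
    q_trans = (2.0 * np.pi * m * K_B * T / H_PLANCK**2) ** 1.5
    rot = np.asarray(sp.rot_constants, dtype=float)
    if sp.linear:
        q_rot = T / (HC_K * rot[0])
    else:
        q_rot = np.sqrt(np.pi) * (T / HC_K) ** 1.5 / np.sqrt(np.prod(rot[:3]))
    freqs = np.asarray(sp.frequencies, dtype=float)
    theta = HC_K * freqs * sp.freq_scale
    q_vib = float(np.prod(1.0 / (1.0 - np.exp(-theta / T))))
    return float(q_trans * q_rot * q_vib)


def _ho_mode_entropy(theta: np.ndarray, T: float) -> np.ndarray:
    x = theta / T
    return R * (x / np.expm1(x) - np.log(-np.expm1(-x)))


def qh_entropy(
    sp: StationaryPoint,
    T: float,
    omega0: float = 100.0,
    p_ref: float = P_REF,
    b_average: float = 1.0e-44,
) -> float:
    """Quasi-harmonic (Grimme-damped) standard entropy, J/mol/K.

    Each mode's entropy interpolates between the harmonic-oscillator
    value and that of a free rotor with the same frequency, with weight
    ``w = 1/(1 + (omega0/nu)^4)``; ``omega0 = 0`` recovers pure RRHO.
    Translational (Sackur-Tetrode at ``p_ref``) and rigid-rotor terms
    (including the symmetry number) are added.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    m = sp.mass * AMU
    q_trans = (2.0 * np.pi * m * K_B * T / H_PLANCK**2) ** 1.5 * K_B * T / p_ref
    s_trans = R * (np.log(q_trans) + 2.5)
    rot = np.asarray(sp.rot_constants, dtype=float)
    if sp.linear:
        q_rot = T / (HC_K * rot[0] * sp.sigma_ext)
        s_rot = R * (np.log(q_rot) + 1.0)
    else:
        q_rot = (
            np.sqrt(np.pi)
            / sp.sigma_ext
            * (T / HC_K) ** 1.5
            / np.sqrt(np.prod(rot[:3]))
        )
        s_rot = R * (np.log(q_rot) + 1.5)
    freqs = np.asarray(sp.frequencies, dtype=float) * sp.freq_scale
    if freqs.size == 0:
        return float(s_trans + s_rot)
    theta = HC_K * freqs
    s_ho = _ho_mode_entropy(theta, T)
    # Free rotor with the effective moment of inertia of each mode.
    mu = H_PLANCK / (8.0 * np.pi**2 * C_LIGHT * 100.0 * freqs)
    mu_eff = mu * b_average / (mu + b_average)
    q_fr = np.sqrt(8.0 * np.pi**3 * mu_eff * K_B * T) / H_PLANCK
    s_fr = R * (0.5 + np.log(q_fr))
    w = 1.0 / (1.0 + (omega0 / freqs) ** 4) if omega0 > 0 else np.ones_like(freqs)
    s_vib = float(np.sum(w * s_ho + (1.0 - w) * s_fr))
    return float(s_trans + s_rot + s_vib)


def _log_cosh(x: float) -> float:
    x = abs(x)
    return x - np.log(2.0) + np.log1p(np.exp(-2.0 * x))


def _log_sinh(x: float) -> float:
    if x <= 0:
        raise ValueError("log sinh requires x > 0")
    return x - np.log(2.0) + np.log1p(-np.exp(-2.0 * x))


def _eckart_log_p(e_red: float, alpha1: float, alpha2: float) -> float:
    """log of the asymmetric-Eckart transmission probability.

    ``e_red = E/V1`` with E from the reactant asymptote; ``alpha_i =
    2*pi*V_i/(h*nu*)``.  Valid for energies above both asymptotes.
    """
    denom_root = 1.0 / np.sqrt(alpha1) + 1.0 / np.sqrt(alpha2)
    a = 2.0 * np.sqrt(alpha1 * e_red) / denom_root
    b_sq = (e_red - 1.0) * alpha1 + alpha2
    if b_sq <= 0.0:
        return -np.inf
    b = 2.0 * np.sqrt(b_sq) / denom_root
    d_sq = alpha1 * alpha2 - np.pi**2 / 4.0
    log_num = np.log(2.0) + _log_sinh(a) + _log_sinh(b)
    log_cosh_ab = _log_cosh(a + b)
    if d_sq >= 0.0:
        log_den = np.logaddexp(log_cosh_ab, _log_cosh(2.0 * np.sqrt(d_sq)))
    else:
        cos_term = np.cos(2.0 * np.sqrt(-d_sq))
        log_den = log_cosh_ab + np.log1p(cos_term * np.exp(-log_cosh_ab))
    log_p = log_num - log_den
    return min(log_p, 0.0)


def eckart_kappa(
    E0_forward: float,
    E0_reverse: float,
    nu_im: float,
    T: float,
    rel_tol: float = 1.0e-8,
) -> float:
    """Asymmetric-Eckart transmission coefficient kappa(T).

    ``E0_forward``/``E0_reverse`` are the ZPE-inclusive barriers in
    kJ/mol, ``nu_im`` the magnitude of the imaginary frequency in cm^-1.
    The Boltzmann average of the transmission probability is normalised
    by the classical step function, so kappa -> 1 as ``nu_im -> 0`` or
    ``T -> inf`` and kappa >= 1 for ordinary barriers.
    """
    if E0_forward <= 0 or E0_reverse <= 0:
        raise ValueError("Eckart barriers must be positive")
    if nu_im <= 0:
        raise ValueError("imaginary frequency must be positive")
    beta_v1 = E0_forward * 1000.0 / (R * T)
    beta_v2 = E0_reverse * 1000.0 / (R * T)
    u_star = HC_K * nu_im / T  # h*c*nu/(k_B T)
    alpha1 = 2.0 * np.pi * beta_v1 / u_star
    alpha2 = 2.0 * np.pi * beta_v2 / u_star
    u_min = max(0.0, beta_v1 - beta_v2)

    def integrand(u: float) -> float:
        log_p = _eckart_log_p(u / beta_v1, alpha1, alpha2)
        return float(np.exp(log_p + beta_v1 - u))

    # The integrand peaks near u = beta_v1; integrate the rising and
    # decaying flanks separately for the adaptive quadrature.
    u_top = beta_v1 + max(50.0, 10.0 * u_star)
    val1, err1 = quad(
        integrand, u_min, beta_v1, epsrel=rel_tol, epsabs=0.0, limit=400
    )
    val2, err2 = quad(
        integrand, beta_v1, u_top, epsrel=rel_tol, epsabs=0.0, limit=400
    )
    kappa = val1 + val2
    if not np.isfinite(kappa) or kappa <= 0:
        raise RuntimeError(
            f"Eckart quadrature failed: kappa={kappa}, errors=({err1}, {err2})"
        )
    return float(kappa)


def tst_rate(
    channel: ReactionChannel,
    T: float,
    tunneling: bool = True,
    symmetry_ratio: float | None = None,
) -> float:
    """Conventional TST rate constant of a channel, 1/s (unimolecular).

    ``symmetry_ratio`` overrides the default external-symmetry ratio
    ``sigma_r/sigma_ts`` when the reactant/TS assignment is ambiguous.
    """
    if not channel.ts.is_ts:
        raise ChannelError(f"{channel.ts.name} carries no imaginary frequency")
    if tunneling and channel.ts.imaginary_freq > 1.0e-6:
        kappa = eckart_kappa(
            channel.E0, channel.E0_reverse, channel.ts.imaginary_freq, T
        )
    else:
        kappa = 1.0
    z_react = 1.0
    m_react = 1
    sigma_react = 1
    for sp in channel.reactants:
        z_react *= rrho_partition(sp, T)
        m_react *= sp.m_enantiomers
        sigma_react *= sp.sigma_ext
    if symmetry_ratio is None:
        symmetry_ratio = sigma_react / channel.ts.sigma_ext
    z_ts = rrho_partition(channel.ts, T)
    enantiomer_ratio = channel.ts.m_enantiomers / m_react
    return float(
        kappa
        * enantiomer_ratio
        * symmetry_ratio
        * (K_B * T / H_PLANCK)
        * (z_ts / z_react)
        * np.exp(-channel.E0 * 1000.0 / (R * T))
    )


def eyring_rate(dG_act: float, T: float) -> float:
    """Thermodynamic-formulation TST rate (k_B T/h) exp(-dG_act/(R T)), 1/s."""
    if T <= 0:
        raise ValueError("T must be positive")
    return float(K_B * T / H_PLANCK * np.exp(-dG_act * 1000.0 / (R * T)))


def arrhenius_fit(
    T_grid: Sequence[float], k_values: Sequence[float]
) -> ArrheniusParams:
    """Least-squares Arrhenius fit of ln k against 1/T.

    Requires at least 3 strictly positive rate constants.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    k_values = np.asarray(k_values, dtype=float)
    if T_grid.size < 3:
        raise ValueError("Arrhenius fit requires at least 3 points")
    if np.any(k_values <= 0):
        raise ValueError("rate constants must be positive")
    x = 1.0 / T_grid
    y = np.log(k_values)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return ArrheniusParams(
        A=float(np.exp(intercept)),
        Ea=float(-slope * R / 1000.0),
        fit_rss=float(np.sum(resid**2)),
    )


def arrhenius_eval(p: ArrheniusParams, T: float | np.ndarray) -> float | np.ndarray:
    """Evaluate A*exp(-Ea/(R T)); Ea in kJ/mol."""
    return p.A * np.exp(-p.Ea * 1000.0 / (R * np.asarray(T, dtype=float)))


def load_stationary_points(path) -> dict[str, StationaryPoint]:
    """Read stationary-point records from a YAML file.

    The file maps record names to the :class:`StationaryPoint` fields
    (``frequencies`` in cm^-1, ``rot_constants`` in cm^-1, ``mass`` in
    amu, energies in kJ/mol); units are fixed by this contract and
    should be restated in an in-file comment.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, fields in raw.items():
        out[name] = StationaryPoint(name=name, **fields)
    return out
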