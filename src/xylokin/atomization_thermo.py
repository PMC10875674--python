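"""Enthalpies of formation from atomization enthalpies.

The atomization route obtains the formation enthalpy of a molecule M at
298.15 K as ``sum_X n_X * dHf(X) - dH_atomization(M)``, where the atomic
formation enthalpies come from the Active Thermochemical Tables and the
atomization enthalpy is a quantum-chemical input.  A per-atom spin-orbit
correction (0.35 kJ/mol per C, 0.93 kJ/mol per O) is *subtracted* from
the uncorrected value, making the corrected enthalpies more negative.

Benchmark statistics (mean unsigned error and root-mean-square deviation)
quantify the agreement of computed values against a reference column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .thermo_core import ElementCount

__all__ = [
    "ATOM_REFS",
    "SO_CORRECTION_PER_ATOM",
    "BenchmarkReport",
    "hf_from_atomization",
    "spin_orbit_correction",
    "benchmark_mue_rmsd",
]

#: ATcT formation enthalpies of the gaseous atoms at 298.15 K, kJ/mol.
ATOM_REFS: Mapping[str, float] = {
    "H": 217.998,
    "C": 716.881,
    "O": 249.229,
}

#: Spin-orbit correction per atom, kJ/mol (subtracted from uncorrected dHf).
SO_CORRECTION_PER_ATOM: Mapping[str, float] = {"C": 0.35, "O": 0.93}


class ReferenceError(KeyError):
    """Raised when an atomic reference enthalpy is missing."""


@dataclass
class BenchmarkReport:
    """MUE/RMSD summary of value-vs-reference deviations, kJ/mol."""

    n: int
    mue: float
    rmsd: float
    deviations: np.ndarray = field(repr=False)


def hf_from_atomization(
    formula: ElementCount,
    atomization_dh: float,
    refs: Mapping[str, float] = ATOM_REFS,
) -> float:
    """Formation enthalpy (kJ/mol) from the atomization enthalpy at 298.15 K.

    ``atomization_dh`` is the (positive, for bound molecules) enthalpy of
    M -> atoms.  Missing atomic references raise :class:`ReferenceError`.
    """
    total = 0.0
    for sym, n in formula.items():
        if n == 0:
            continue
        if sym not in refs:
            raise ReferenceError(f"no atomic reference enthalpy for {sym!r}")
        total += n * refs[sym]
    return total - atomization_dh


def spin_orbit_correction(formula: ElementCount) -> float:
    """Total spin-orbit correction for a formula, kJ/mol.

    The returned magnitude is to be subtracted from the uncorrected
    formation enthalpy: ``corrected = uncorrected - correction``.
    """
    return sum(
        SO_CORRECTION_PER_ATOM.get(sym, 0.0) * n for sym, n in formula.items()
    )


def benchmark_mue_rmsd(
    values: Sequence[float], references: Sequence[float]
) -> BenchmarkReport:
    """Mean unsigned error and RMSD of ``values`` against ``references``."""
    v = np.asarray(values, dtype=float)
    r = np.asarray(references, dtype=float)
    if v.shape != r.shape or v.ndim != 1 or v.size < 1:
        raise ValueError("values and references must be equal-length 1-D, n >= 1")
    dev = v - r
    return BenchmarkReport(
        n=int(v.size),
        mue=float(np.mean(np.abs(dev))),
        rmsd=float(np.sqrt(np.mean(dev**2))),
        deviations=dev,
    )
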