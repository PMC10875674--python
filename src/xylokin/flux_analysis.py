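"""Reaction-flux and branching-ratio analysis.

Integrating each reaction's net volumetric rate over a reactor run gives
the net extent (mol) carried by that reaction.  At a chosen species node
the consumption is then apportioned among the channels that consume the
species; a reversible production channel (such as ring opening when the
node is xylose) is counted through its reverse direction.  Channels
whose net flux runs in the producing direction are floored at zero
before normalisation, so branching fractions are non-negative and sum
to one wherever there is net consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanism_io import Mechanism
from .reactor import Trajectory

__all__ = [
    "FluxReport",
    "UndefinedBranchingError",
    "integrated_fluxes",
    "branching",
    "to_dot",
]


class UndefinedBranchingError(ValueError):
    """Raised when a node has no net consumption to apportion."""


def isothermal_flux_report(
    mech: Mechanism,
    T: float,
    P: float | None = None,
    conversion: float = 0.99,
    t_cap: float = 1.0e6,
    parent: str = "xylopyranose",
):
    """Run an isothermal reactor from pure ``parent`` and integrate fluxes.

    The run terminates at ``conversion`` net consumption of the parent or
    at ``t_cap`` seconds, whichever comes first.  A 99% endpoint probes
    the long-time repartition of the network; a small endpoint (e.g. 10%)
    probes the initial kinetic competition before product pools
    re-equilibrate.  Returns ``(trajectory, flux_report)``.
    """
    from .constants import P_REF
    from .reactor import TemperatureProgram, simulate

    traj = simulate(
        mech,
        TemperatureProgram.isothermal(T, t_cap),
        P=P if P is not None else P_REF,
        initial={parent: 1.0},
        stop_at_conversion=(parent, conversion),
    )
    report = integrated_fluxes(traj, mech)
    report.endpoint = (
        f"{conversion:.0%} {parent} conversion"
        if traj.times[-1] < t_cap
        else f"t_cap = {t_cap:g} s"
    )
    return traj, report


@dataclass
class FluxReport:
    """Integrated net reaction extents (mol) for one reactor run."""

    reaction_ids: list[str]
    extents: np.ndarray  # signed net extent per reaction, mol
    mechanism: Mechanism = field(repr=False)
    T: float | None = None
    P: float | None = None
    endpoint: str = ""

    def extent(self, rxn_id: str) -> float:
        return float(self.extents[self.reaction_ids.index(rxn_id)])


def integrated_fluxes(traj: Trajectory, mech: Mechanism) -> FluxReport:
    """Net extent of every reaction, integral of V*r_j over the run.

    Extents co-integrated with the state by the stiff solver are used
    when available; otherwise the saved points (log-spaced for
    isothermal runs, which resolves the fast initial transient) are
    integrated trapezoidally.
    """
    if traj.reaction_ids != [rxn.id for rxn in mech.reactions]:
        raise ValueError("trajectory was not produced by this mechanism")
    if traj.extents is not None:
        extents = traj.extents[-1].copy()
    else:
        mol_rates = traj.net_rates * traj.volumes[:, None]  # mol/s
        extents = np.trapezoid(mol_rates, traj.times, axis=0)
    temps = np.unique(traj.temperatures)
    return FluxReport(
        reaction_ids=list(traj.reaction_ids),
        extents=extents,
        mechanism=mech,
        T=float(temps[0]) if temps.size == 1 else None,
        P=traj.pressure,
        endpoint=f"t = {traj.times[-1]:.6g} s",
    )


def branching(report: FluxReport, node: str) -> dict[str, float]:
    """Branching fractions of the channels consuming ``node``.

    For every reaction in which the node appears, the net integrated
    flux in the node-consuming direction is taken (floored at zero);
    fractions are normalised over all consuming channels.  Keys are
    reaction ids.
    """
    fluxes: dict[str, float] = {}
    participates = False
    for rxn, extent in zip(report.mechanism.reactions, report.extents):
        nu = rxn.stoichiometry.get(node, 0)
        if nu == 0:
            continue
        participates = True
        # nu < 0: forward direction consumes the node; nu > 0: the
        # reverse direction does.
        consuming = -nu * extent
        fluxes[rxn.id] = max(consuming, 0.0)
    if not participates:
        raise UndefinedBranchingError(f"{node!r} participates in no reaction")
    total = sum(fluxes.values())
    if total <= 0.0:
        raise UndefinedBranchingError(f"no net consumption of {node!r}")
    return {rid: f / total for rid, f in fluxes.items()}


def to_dot(report: FluxReport, nodes: list[str] | None = None) -> str:
    """Render the flux network as a DOT digraph.

    Each analysed node contributes one edge per consuming channel,
    labeled with the branching percentage; edges point from the node to
    the channel's complementary species.  Node order is deterministic.
    """
    if nodes is None:
        nodes = sorted(
            {
                name
                for rxn in report.mechanism.reactions
                for name, nu in rxn.stoichiometry.items()
                if nu < 0
            }
        )
    lines = ["digraph flux {", '  rankdir="LR";']
    for node in nodes:
        try:
            fractions = branching(report, node)
        except UndefinedBranchingError:
            continue
        for rxn_id in sorted(fractions):
            frac = fractions[rxn_id]
            if frac <= 0.0:
                continue
            rxn = report.mechanism.reaction(rxn_id)
            if rxn.stoichiometry.get(node, 0) < 0:
                partners = [s for s, nu in rxn.stoichiometry.items() if nu > 0]
            else:
                partners = [
                    s for s, nu in rxn.stoichiometry.items() if nu < 0
                ]
            target = " + ".join(sorted(partners))
            lines.append(
                f'  "{node}" -> "{target}" '
                f'[label="{rxn_id}: {100.0 * frac:.1f}%"];'
            )
    lines.append("}")
    return "\n".join(lines)
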