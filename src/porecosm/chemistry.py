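"""Solute diffusion on the hydrated network.

Fickian exchange between neighbouring nodes is limited by the water-filled
cross-section of the connecting pore: the pore conductance is
g = A_w * D / L (m^3 s^-1 per unit concentration difference).  Mass balance
at each node (water volume V_w) gives

    V_w dC/dt = sum_j g_j (C_j - C) - R,

integrated with an unconditionally stable backward-Euler step; the sparse
factorisation is cached and reused while the hydration state is unchanged.
Fixed-concentration boundaries are identity rows; oxygen (or any gas-phase
solute) is additionally clamped at every node touching an unsaturated pore,
treating gas-phase transport as instantaneous relative to the time step.

Concentrations are mol m^-3 internally, which is numerically the same as
mM; the sink/source term is applied in moles per node per step *before* the
diffusion solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hydrology import HydrationState
from .network import PoreNetwork

__all__ = [
    "Solute",
    "ChemicalField",
    "DiffusionOperator",
    "henry_equilibrium",
    "air_equilibrium_nodes",
    "apply_air_equilibrium",
    "step_chemistry",
]

log = logging.getLogger(__name__)

#: Aqueous diffusion coefficient used for all solutes unless configured
#: (m^2 s^-1), following the surface-colony comparison convention.
DEFAULT_D = 5e-10


@dataclass
class Solute:
    """A dissolved species with its transport and boundary behaviour.

    ``boundary_type`` is one of ``"none"``, ``"fixed_concentration"`` (the
    nodes of ``boundary_nodes`` are held at ``boundary_value`` mM) or
    ``"air_equilibrium"`` (additionally clamped wherever air is present;
    value from Henry's law unless given explicitly).
    """

    name: str
    D: float = DEFAULT_D
    boundary_type: str = "none"
    boundary_value: float = 0.0  # mM
    boundary_nodes: str | None = None  # name of a boundary set
    henry_constant: float | None = None  # mol L^-1 atm^-1
    partial_pressure: float | None = None  # atm
    initial_value: float = 0.0  # mM

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diffusion coefficient must be positive, got {self.D}")
        if self.boundary_type not in ("none", "fixed_concentration", "air_equilibrium"):
            raise ValueError(f"unknown boundary type {self.boundary_type!r}")
        if self.boundary_type == "air_equilibrium" and self.boundary_value == 0.0:
            if self.henry_constant is None or self.partial_pressure is None:
                raise ValueError(
                    "air_equilibrium solutes need a Henry constant and partial "
                    "pressure (or an explicit boundary_value)"
                )
            self.boundary_value = henry_equilibrium(
                self.partial_pressure, self.henry_constant
            )


def henry_equilibrium(partial_pressure: float, k_h: float) -> float:
    """Dissolved-gas saturation concentration in mM from Henry's law,
    C = k_H * p with k_H in mol L^-1 atm^-1 and p in atm."""
    if partial_pressure < 0 or k_h < 0:
        raise ValueError("partial pressure and Henry constant must be non-negative")
    return k_h * partial_pressure * 1000.0  # mol/L -> mM


def air_equilibrium_nodes(network: PoreNetwork, state: HydrationState) -> np.ndarray:
    """Nodes incident to at least one unsaturated pore (air-contact nodes)."""
    unsat = ~state.saturated
    mask = np.zeros(network.n_nodes, dtype=bool)
    mask[network.pores[unsat, 0]] = True
    mask[network.pores[unsat, 1]] = True
    return np.flatnonzero(mask)


class DiffusionOperator:
    """Backward-Euler diffusion step for one solute on one hydration state.

    Solves (I + dt*M) C+ = C with M the conductance Laplacian scaled by node
    water volumes; rows of clamped nodes are replaced by identity so the
    solve returns the boundary value there exactly.
    """

    def __init__(
        self,
        network: PoreNetwork,
        state: HydrationState,
        solute: Solute,
        dt: float,
        extra_clamped: np.ndarray | None = None,
        extra_clamp_values: np.ndarray | None = None,
    ) -> None:
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        v_w = state.node_water_volume
        bad = np.flatnonzero(v_w <= 0)
        if len(bad):
            raise ValueError(
                f"node {int(bad[0])} has zero water volume; the implicit system "
                "would be singular"
            )
        self.network = network
        self.solute = solute
        self.dt = dt
        self.node_volume = v_w

        clamped = np.zeros(network.n_nodes, dtype=bool)
        clamp_values = np.full(network.n_nodes, solute.boundary_value)
        if solute.boundary_type in ("fixed_concentration", "air_equilibrium"):
            if solute.boundary_nodes is not None:
                if solute.boundary_nodes == "all":
                    clamped[:] = True
                else:
                    clamped[network.boundary_sets[solute.boundary_nodes]] = True
        if extra_clamped is not None:
            clamped[extra_clamped] = True
            if extra_clamp_values is not None:
                clamp_values[extra_clamped] = extra_clamp_values
        self.clamped = clamped
        self.clamp_values = clamp_values

        g = state.water_area * solute.D / network.lengths  # m^3/s
        a, b = network.pores[:, 0], network.pores[:, 1]
        n = network.n_nodes
        diag = np.zeros(n)
        np.add.at(diag, a, g)
        np.add.at(diag, b, g)
        rows = np.concatenate([a, b, np.arange(n)])
        cols = np.concatenate([b, a, np.arange(n)])
        vals = np.concatenate([-g, -g, diag]) / v_w[rows]
        m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        system = sp.eye(n, format="csr") + dt * m
        if clamped.any():
            # identity rows for clamped nodes
            keep = ~clamped[system.tocoo().row]
            coo = system.tocoo()
            rows2 = np.concatenate([coo.row[keep], np.flatnonzero(clamped)])
            cols2 = np.concatenate([coo.col[keep], np.flatnonzero(clamped)])
            vals2 = np.concatenate([coo.data[keep], np.ones(int(clamped.sum()))])
            system = sp.csr_matrix((vals2, (rows2, cols2)), shape=(n, n))
        self._lu = spla.splu(system.tocsc())

    def step(self, concentration: np.ndarray) -> np.ndarray:
        """Advance one dt; boundary rows are set to their clamp value."""
        rhs = concentration.copy()
        rhs[self.clamped] = self.clamp_values[self.clamped]
        out = self._lu.solve(rhs)
        if self.clamped.any():
            out[self.clamped] = self.clamp_values[self.clamped]
        return out


@dataclass
class ChemicalField:
    """Per-node concentrations (mol m^-3 == mM) for a set of solutes."""

    solutes: list[Solute]
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def initialize(cls, network: PoreNetwork, solutes: list[Solute]) -> "ChemicalField":
        field_ = cls(solutes=list(solutes))
        for s in solutes:
            field_.concentrations[s.name] = np.full(network.n_nodes, float(s.initial_value))
        return field_

    def total_moles(self, name: str, node_volume: np.ndarray) -> float:
        return float((self.concentrations[name] * node_volume).sum())

    def copy(self) -> "ChemicalField":
        return ChemicalField(
            solutes=list(self.solutes),
            concentrations={k: v.copy() for k, v in self.concentrations.items()},
        )


def build_operators(
    network: PoreNetwork,
    state: HydrationState,
    solutes: list[Solute],
    dt: float,
) -> dict[str, DiffusionOperator]:
    """One cached operator per solute; air-equilibrium solutes get the
    air-contact nodes added to their clamp set."""
    air_nodes = air_equilibrium_nodes(network, state)
    ops = {}
    for s in solutes:
        extra = air_nodes if s.boundary_type == "air_equilibrium" else None
        ops[s.name] = DiffusionOperator(network, state, s, dt, extra_clamped=extra)
    return ops


def apply_air_equilibrium(
    field_: ChemicalField, network: PoreNetwork, state: HydrationState, solute: Solute
) -> None:
    """Clamp a gas-phase solute to its air-equilibrium value at every node
    touching an unsaturated pore (in place)."""
    nodes = air_equilibrium_nodes(network, state)
    field_.concentrations[solute.name][nodes] = solute.boundary_value


def step_chemistry(
    field_: ChemicalField,
    operators: dict[str, DiffusionOperator],
    consumption: dict[str, np.ndarray] | None = None,
    record: dict | None = None,
    unlimited: dict[str, np.ndarray] | None = None,
) -> ChemicalField:
    """One chemistry step: apply the biological sink/source, then diffuse,
    then re-apply boundary clamps.

    ``consumption`` maps solute name to per-node moles removed this step
    (consumption positive, production negative).  A negative concentration
    after the sink is clipped to zero and logged — reaching that branch
    indicates an uptake-bound bug upstream, because dFBA bounds uptake by
    availability — except at nodes flagged in ``unlimited`` (clamped nodes
    sitting on a gas reservoir, whose dissolved inventory may be over-drawn
    within a step and is restored by the clamp).  If ``record`` is given,
    per-solute mole ledgers (before, after_reaction, after_diffusion) are
    stored into it.
    """
    out = field_.copy()
    for s in field_.solutes:
        op = operators[s.name]
        c = out.concentrations[s.name]
        ledger = {"before": float((c * op.node_volume).sum())}
        if consumption is not None and s.name in consumption:
            c = c - consumption[s.name] / op.node_volume
            negative = c < 0
            if negative.any():
                watched = negative
                if unlimited is not None and s.name in unlimited:
                    watched = negative & ~unlimited[s.name]
                    gas_nodes = negative & unlimited[s.name]
                    # moles drawn from the gas phase beyond the dissolved
                    # inventory: book them as gas supply
                    ledger["gas_supply"] = float(
                        (-c[gas_nodes] * op.node_volume[gas_nodes]).sum()
                    )
                shortfall = float((-c[watched] * op.node_volume[watched]).sum())
                # rounding at the availability cap leaves eps-scale residues;
                # only a genuine overdraw indicates an uptake-bound bug
                if shortfall > 1e-12 * max(abs(ledger["before"]), 1e-18):
                    log.error(
                        "clipped %.3e mol of %s below zero at %d nodes "
                        "(uptake-bound bug upstream?)",
                        shortfall, s.name, int(negative.sum()),
                    )
                c = np.where(negative, 0.0, c)
        ledger["after_reaction"] = float((c * op.node_volume).sum())
        c = op.step(c)
        ledger["after_diffusion"] = float((c * op.node_volume).sum())
        out.concentrations[s.name] = c
        if record is not None:
            record[s.name] = ledger
    return out
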