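"""Individual bacterial agents: motility, chemotaxis, growth, division.

Agents live on pores at a fractional coordinate s in [0, 1] and run along
the pore axis at a velocity set by the local water film.  The restricted
swimming velocity follows a force balance between flagellar propulsion F_m,
cell-surface hydrodynamic drag F_lambda and capillary pinning F_c:

    V = V0 * (F_m - F_lambda - F_c) / F_m   (0 when the balance is <= 0).

F_lambda and F_c as functions of film thickness come from a pluggable force
model; the default uses an exponential drag F_lambda = a*exp(-WFT/lambda_d)
and a hard pinning cutoff (F_c = inf) once the film is thinner than the
cell diameter.  Saturated pores impose no film restriction.

Chemotaxis modulates the per-step tumbling probability from the growth-rate
history of the individual cell,

    p_t = p0 * exp(-X * dmu / (2 v mu_max)),   dmu = (mu_t - mu_{t-1})/(v dt),

so runs up a growth-rate gradient lengthen.  Tumbling inside a pore flips
the direction with probability 1/2; at a node the next pore is drawn
uniformly from all incident pores (the arrival pore included).  An agent in
a pore whose film is thinner than its diameter is immobilised and escapes
back to the node it entered from with probability 0.1 per step.

A "super agent" represents ``scaling_ratio`` identical cells moving and
growing synchronously; ``mass`` is always the per-cell mass.

Populations are stored as flat numpy arrays (struct-of-arrays) so that a
step over 1e5 agents is a handful of vector operations; the single-`Agent`
view exists for inspection and the fine-grained operations of the API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np

from .hydrology import HydrationState
from .network import PoreNetwork

__all__ = [
    "SpeciesTraits",
    "MotilityForces",
    "Agent",
    "AgentPopulation",
    "restricted_velocity",
    "tumbling_probability",
    "default_force_model",
    "move_agent",
    "grow_agent",
    "divide_or_die",
    "pool_by_node",
]

#: Probability per step that an immobilised cell detaches back to the node
#: it entered the pore from.
DETACH_PROBABILITY = 0.10


@dataclass
class MotilityForces:
    """Force balance inputs (N); all non-negative."""

    F_m: float
    F_lambda: float
    F_c: float


@dataclass
class SpeciesTraits:
    """Per-species physiological and motility parameters."""

    name: str
    model: str  # metabolic model reference
    V0: float = 2e-5  # unrestricted swimming velocity, m/s
    p0: float = 0.1  # base tumbling probability per step
    chi: float = 0.0  # chemotactic sensitivity X, m^2/s
    mu_max: float = 2.0e-4  # maximum growth rate, s^-1
    mass_at_division: float = 2e-15  # kg per cell
    critical_mass: float = 0.5e-15  # kg per cell
    initial_mass: float = 1e-15  # kg per cell
    maintenance_rate: float = 1e-5  # s^-1 standing cost (decay at mu = 0)
    cell_diameter: float = 1e-6  # m, motility cutoff
    pinning_film: float = 0.0  # m; films thinner than this pin the cell
    scaling_ratio: int = 1  # cells per (super) agent
    F_m: float = 1.0  # flagellar propulsion, arbitrary force unit
    drag_amplitude: float = 0.5  # a in F_lambda = a*exp(-WFT/lambda_d)
    drag_decay: float = 2e-6  # lambda_d, m

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if self.critical_mass >= self.mass_at_division:
            raise ValueError("critical_mass must be below mass_at_division")
        if min(self.V0, self.chi, self.mu_max) < 0:
            raise ValueError("V0, chi and mu_max must be non-negative")


def default_force_model(traits: SpeciesTraits, wft: float) -> MotilityForces:
    """Exponential hydrodynamic drag plus hard capillary pinning below the
    cell diameter.  The mapping from film thickness to forces is not fixed
    by the governing equations; this default preserves their structure
    (thin films slow, then stop, cells) with configurable coefficients."""
    if math.isinf(wft):
        return MotilityForces(F_m=traits.F_m, F_lambda=0.0, F_c=0.0)
    f_lambda = traits.drag_amplitude * math.exp(-wft / traits.drag_decay)
    # capillary pinning: hard stop below the cell diameter, and optionally
    # already at thicker films (motility in unsaturated media ceases at
    # modest suctions, well before films reach cell size)
    cutoff = max(traits.cell_diameter, traits.pinning_film)
    f_c = 0.0 if wft >= cutoff else math.inf
    return MotilityForces(F_m=traits.F_m, F_lambda=f_lambda, F_c=f_c)


def restricted_velocity(V0: float, forces: MotilityForces) -> float:
    """Film-restricted swimming velocity; zero when the net force is."""
    if V0 < 0:
        raise ValueError("V0 must be non-negative")
    if forces.F_m <= 0:
        return 0.0
    net = forces.F_m - forces.F_lambda - forces.F_c
    return V0 * net / forces.F_m if net > 0 else 0.0


def tumbling_probability(
    p0: float, chi: float, v: float, mu_max: float, delta_mu: float
) -> float:
    """Chemotactic tumbling probability, clipped to [0, 1].

    ``delta_mu`` is the growth-rate change per distance travelled
    (m^-1 s^-1); an immobile cell (v = 0) senses no gradient and keeps p0.
    """
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    if chi == 0.0 or v <= 0.0:
        return float(np.clip(p0, 0.0, 1.0))
    expo = np.clip(-chi * delta_mu / (2.0 * v * mu_max), -60.0, 60.0)
    p = p0 * math.exp(expo)
    return float(np.clip(p, 0.0, 1.0))


@dataclass
class Agent:
    """One bacterial cell or super agent (record view)."""

    species: int
    mass: float
    pore: int
    s: float
    direction: int
    mu_prev: float = 0.0  # s^-1, growth rate of the previous step
    prev_node: int = -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"fractional coordinate s={self.s} outside [0, 1]")


class AgentPopulation:
    """Struct-of-arrays container for all agents of a simulation."""

    _FIELDS = ("species", "mass", "pore", "s", "direction", "mu_prev", "prev_node")

    def __init__(self, species_traits: list[SpeciesTraits]) -> None:
        self.traits = list(species_traits)
        self.species = np.zeros(0, dtype=np.int32)
        self.mass = np.zeros(0)
        self.pore = np.zeros(0, dtype=np.int64)
        self.s = np.zeros(0)
        self.direction = np.zeros(0, dtype=np.int8)
        self.mu_prev = np.zeros(0)
        self.prev_node = np.zeros(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.mass)

    @property
    def n_species(self) -> int:
        return len(self.traits)

    def add(self, species, mass, pore, s, direction, prev_node) -> None:
        self.species = np.concatenate([self.species, np.asarray(species, dtype=np.int32)])
        self.mass = np.concatenate([self.mass, np.asarray(mass, dtype=float)])
        self.pore = np.concatenate([self.pore, np.asarray(pore, dtype=np.int64)])
        self.s = np.concatenate([self.s, np.asarray(s, dtype=float)])
        self.direction = np.concatenate([self.direction, np.asarray(direction, dtype=np.int8)])
        self.mu_prev = np.concatenate([self.mu_prev, np.zeros(len(np.asarray(mass)))])
        self.prev_node = np.concatenate([self.prev_node, np.asarray(prev_node, dtype=np.int64)])

    def keep(self, mask: np.ndarray) -> None:
        for name in self._FIELDS:
            setattr(self, name, getattr(self, name)[mask])

    def agent(self, i: int) -> Agent:
        return Agent(
            species=int(self.species[i]), mass=float(self.mass[i]),
            pore=int(self.pore[i]), s=float(self.s[i]),
            direction=int(self.direction[i]), mu_prev=float(self.mu_prev[i]),
            prev_node=int(self.prev_node[i]),
        )

    def total_biomass(self) -> np.ndarray:
        """Summed cell biomass (kg) per species, scaling ratios included."""
        ratios = np.array([t.scaling_ratio for t in self.traits], dtype=float)
        out = np.zeros(self.n_species)
        np.add.at(out, self.species, self.mass * ratios[self.species])
        return out

    # -- spatial pooling --------------------------------------------------

    def node_assignment(self, network: PoreNetwork) -> np.ndarray:
        """Nearest pore endpoint per agent (ties at s = 0.5 go to node_a)."""
        a = network.pores[self.pore, 0]
        b = network.pores[self.pore, 1]
        return np.where(self.s <= 0.5, a, b)

    def pool_by_node(self, network: PoreNetwork):
        """Per-(node, species) biomass (kg) and cell counts.

        Returns ``(nodes, biomass, cells, assignment)`` where ``nodes`` is
        the sorted array of occupied nodes and ``biomass``/``cells`` have
        shape (len(nodes), n_species); ``assignment`` maps each agent to
        its row in ``nodes``.
        """
        node_of = self.node_assignment(network)
        nodes, inverse = np.unique(node_of, return_inverse=True)
        ratios = np.array([t.scaling_ratio for t in self.traits], dtype=float)
        biomass = np.zeros((len(nodes), self.n_species))
        cells = np.zeros((len(nodes), self.n_species))
        np.add.at(biomass, (inverse, self.species), self.mass * ratios[self.species])
        np.add.at(cells, (inverse, self.species), ratios[self.species])
        return nodes, biomass, cells, inverse

    # -- growth / division ------------------------------------------------

    def grow(self, mu: np.ndarray, dt: float) -> None:
        """Per-agent mass update m += (mu - r_m)*m*dt: the maintenance rate
        r_m is a standing cost, so cells growing slower than it shrink and
        starving cells (mu = 0) decay at r_m."""
        maint = np.array([t.maintenance_rate for t in self.traits])
        rate = mu - maint[self.species]
        self.mass = self.mass * (1.0 + rate * dt)

    def divide_or_die(self, rng: np.random.Generator) -> None:
        """Remove agents at/below critical mass; split agents at/above the
        division mass into two half-mass daughters with random directions."""
        crit = np.array([t.critical_mass for t in self.traits])
        mdiv = np.array([t.mass_at_division for t in self.traits])
        dead = self.mass <= crit[self.species]
        self.keep(~dead)
        dividing = np.flatnonzero(self.mass >= mdiv[self.species])
        if len(dividing):
            self.mass[dividing] *= 0.5
            self.direction[dividing] = rng.choice(np.array([-1, 1], dtype=np.int8),
                                                  size=len(dividing))
            n_before = len(self)
            self.add(
                self.species[dividing], self.mass[dividing], self.pore[dividing],
                self.s[dividing], rng.choice(np.array([-1, 1], dtype=np.int8),
                                             size=len(dividing)),
                self.prev_node[dividing],
            )
            self.mu_prev[n_before:] = self.mu_prev[dividing]

    # -- motility ---------------------------------------------------------

    def species_velocity_table(
        self, network: PoreNetwork, state: HydrationState
    ) -> tuple[np.ndarray, np.ndarray]:
        """(n_species, n_pores) restricted velocities and immobility mask."""
        v = np.zeros((self.n_species, network.n_pores))
        immobile = np.zeros((self.n_species, network.n_pores), dtype=bool)
        for si, tr in enumerate(self.traits):
            cutoff = max(tr.cell_diameter, tr.pinning_film)
            for j in range(network.n_pores):
                wft = float(state.film[j])
                forces = default_force_model(tr, wft)
                v[si, j] = restricted_velocity(tr.V0, forces)
                immobile[si, j] = (not state.saturated[j]) and wft < cutoff
        return v, immobile

    def tumbling_probabilities(self, mu_now: np.ndarray, v_agent: np.ndarray,
                               dt: float) -> np.ndarray:
        """Vectorised chemotactic tumbling probability per agent."""
        p0 = np.array([t.p0 for t in self.traits])[self.species]
        chi = np.array([t.chi for t in self.traits])[self.species]
        mu_max = np.array([t.mu_max for t in self.traits])[self.species]
        p = p0.copy()
        sensing = (chi > 0) & (v_agent > 0)
        if sensing.any():
            dmu = (mu_now[sensing] - self.mu_prev[sensing]) / (v_agent[sensing] * dt)
            expo = -chi[sensing] * dmu / (2.0 * v_agent[sensing] * mu_max[sensing])
            p[sensing] = p0[sensing] * np.exp(np.clip(expo, -60.0, 60.0))
        return np.clip(p, 0.0, 1.0)

    def move(
        self,
        network: PoreNetwork,
        velocities: np.ndarray,
        immobile: np.ndarray,
        p_tumble: np.ndarray,
        dt: float,
        rng: np.random.Generator,
        max_crossings: int = 64,
    ) -> None:
        """Advance every agent by one run-and-tumble step of length dt."""
        n = len(self)
        if n == 0:
            return
        ptr, pidx, _ = network.incidence()
        lengths = network.lengths
        stuck = immobile[self.species, self.pore]

        # immobilised agents: 10% escape back to the entry node (no further
        # run within the escape step)
        escape = stuck & (rng.random(n) < DETACH_PROBABILITY)
        if escape.any():
            self._place_at_node(np.flatnonzero(escape), self.prev_node[escape],
                                ptr, pidx, network, rng)
        mobile = ~stuck
        # tumble; half of tumbles flip direction
        tumble = mobile & (rng.random(n) < p_tumble)
        flip = tumble & (rng.random(n) < 0.5)
        self.direction[flip] = -self.direction[flip]

        time_left = np.where(mobile, dt, 0.0)
        for _ in range(max_crossings):
            v = velocities[self.species, self.pore]
            active = (time_left > 0) & (v > 0)
            if not active.any():
                break
            idx = np.flatnonzero(active)
            L = lengths[self.pore[idx]]
            d = self.direction[idx].astype(float)
            to_node = np.where(d > 0, (1.0 - self.s[idx]) * L, self.s[idx] * L)
            travel = v[idx] * time_left[idx]
            arrive = travel >= to_node - 1e-18
            run = idx[~arrive]
            self.s[run] = np.clip(
                self.s[run]
                + self.direction[run] * (v[run] * time_left[run]) / lengths[self.pore[run]],
                0.0, 1.0,
            )
            time_left[run] = 0.0

            hit = idx[arrive]
            if len(hit) == 0:
                break
            time_left[hit] -= to_node[arrive] / v[hit]
            node = np.where(self.direction[hit] > 0,
                            network.pores[self.pore[hit], 1],
                            network.pores[self.pore[hit], 0])
            self._place_at_node(hit, node, ptr, pidx, network, rng)
            # stopping on entry into an immobilising pore
            now_stuck = immobile[self.species[hit], self.pore[hit]]
            time_left[hit[now_stuck]] = 0.0
        # truncate any residual (pathological max_crossings overflow)

    def _place_at_node(self, agents: np.ndarray, nodes: np.ndarray,
                       ptr: np.ndarray, pidx: np.ndarray,
                       network: PoreNetwork, rng: np.random.Generator) -> None:
        """Put agents at a node: record it as previous node, pick an incident
        pore uniformly at random and head into it."""
        deg = ptr[nodes + 1] - ptr[nodes]
        pick = ptr[nodes] + rng.integers(0, deg)
        new_pore = pidx[pick]
        self.pore[agents] = new_pore
        at_a = network.pores[new_pore, 0] == nodes
        self.s[agents] = np.where(at_a, 0.0, 1.0)
        self.direction[agents] = np.where(at_a, 1, -1).astype(np.int8)
        self.prev_node[agents] = nodes


# -- single-agent convenience wrappers ------------------------------------


def grow_agent(agent: Agent, mu: float, dt: float,
               maintenance_rate: float = 0.0) -> Agent:
    """Mass update for one agent: m' = m(1 + (mu - r_m) dt), the
    maintenance rate r_m acting as a standing cost (pure decay at mu = 0)."""
    if mu < 0:
        raise ValueError("growth rate must be non-negative")
    return replace(agent, mass=agent.mass * (1.0 + (mu - maintenance_rate) * dt))


def divide_or_die(agent: Agent, traits: SpeciesTraits,
                  rng: np.random.Generator) -> list[Agent]:
    """Division at the prescribed mass (two half-mass daughters at the same
    position, random directions), removal at the critical mass."""
    if agent.mass <= traits.critical_mass:
        return []
    if agent.mass >= traits.mass_at_division:
        d1, d2 = rng.choice([-1, 1], size=2)
        half = agent.mass / 2.0
        return [
            replace(agent, mass=half, direction=int(d1)),
            replace(agent, mass=half, direction=int(d2)),
        ]
    return [agent]


def move_agent(agent: Agent, network: PoreNetwork, state: HydrationState,
               traits: SpeciesTraits, dt: float,
               rng: np.random.Generator,
               mu_now: float | None = None) -> Agent:
    """Single-agent wrapper around the vectorised move step."""
    pop = AgentPopulation([traits])
    pop.add([0], [agent.mass], [agent.pore], [agent.s], [agent.direction],
            [agent.prev_node])
    pop.mu_prev[0] = agent.mu_prev
    v, immobile = pop.species_velocity_table(network, state)
    v_agent = v[0, agent.pore]
    p = pop.tumbling_probabilities(
        np.array([agent.mu_prev if mu_now is None else mu_now]),
        np.array([v_agent]), dt,
    )
    pop.move(network, v, immobile, p, dt, rng)
    return pop.agent(0)


def pool_by_node(agents: list[Agent], traits: list[SpeciesTraits],
                 network: PoreNetwork):
    """Functional form of :meth:`AgentPopulation.pool_by_node`."""
    pop = AgentPopulation(traits)
    if agents:
        pop.add(
            [a.species for a in agents], [a.mass for a in agents],
            [a.pore for a in agents], [a.s for a in agents],
            [a.direction for a in agents], [a.prev_node for a in agents],
        )
        pop.mu_prev = np.array([a.mu_prev for a in agents])
    return pop.pool_by_node(network)
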