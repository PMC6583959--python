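"""Motility, chemotaxis, growth, division and pooling."""

import math

import numpy as np
import pytest

from porecosm import agents as ag
from porecosm import hydrology as hyd
from porecosm import network as netmod
from porecosm.agents import (
    Agent,
    AgentPopulation,
    MotilityForces,
    SpeciesTraits,
    default_force_model,
    divide_or_die,
    grow_agent,
    move_agent,
    restricted_velocity,
    tumbling_probability,
)


def traits(**over):
    base = dict(
        name="sp", model="m", V0=1e-5, p0=0.1, chi=0.0, mu_max=2.78e-4,
        mass_at_division=2e-15, critical_mass=0.5e-15, initial_mass=1e-15,
        maintenance_rate=0.0, cell_diameter=1e-6, scaling_ratio=1,
    )
    base.update(over)
    return SpeciesTraits(**base)


def saturated(net):
    return hyd.classify_saturation(net, 0.0, air_boundary="edge")


def make_population(tr, n, pore, s, direction, net):
    pop = AgentPopulation([tr])
    pop.add(
        np.zeros(n, dtype=int), np.full(n, tr.initial_mass),
        np.full(n, pore, dtype=int), np.full(n, float(s)),
        np.full(n, direction, dtype=int),
        np.full(n, net.pores[pore, 0], dtype=int),
    )
    return pop


def positions(pop, net):
    xa = net.node_coordinates[net.pores[pop.pore, 0], 0]
    xb = net.node_coordinates[net.pores[pop.pore, 1], 0]
    return xa + pop.s * (xb - xa)


class TestRestrictedVelocity:
    def test_unrestricted_limit(self):
        assert restricted_velocity(2e-5, MotilityForces(1.0, 0.0, 0.0)) == 2e-5

    def test_immobilised_when_net_force_nonpositive(self):
        assert restricted_velocity(2e-5, MotilityForces(1.0, 0.7, 0.5)) == 0.0
        assert restricted_velocity(2e-5, MotilityForces(1.0, 0.5, math.inf)) == 0.0

    def test_half_force_halves_velocity(self):
        assert restricted_velocity(2e-5, MotilityForces(2.0, 0.5, 0.5)) == pytest.approx(1e-5)

    def test_no_flagella_no_motion(self):
        assert restricted_velocity(2e-5, MotilityForces(0.0, 0.0, 0.0)) == 0.0

    def test_force_model_monotone_in_film(self):
        tr = traits()
        wfts = [1.5e-6, 3e-6, 1e-5, 1e-4]
        vels = [
            restricted_velocity(tr.V0, default_force_model(tr, w)) for w in wfts
        ]
        assert all(v2 >= v1 for v1, v2 in zip(vels, vels[1:]))
        # below the cell diameter: pinned
        assert restricted_velocity(tr.V0, default_force_model(tr, 0.5e-6)) == 0.0
        # saturated pores: full speed
        assert restricted_velocity(tr.V0, default_force_model(tr, math.inf)) == tr.V0


class TestTumblingProbability:
    def test_no_gradient_returns_p0(self):
        assert tumbling_probability(0.1, 1e-10, 2e-5, 2.78e-4, 0.0) == pytest.approx(0.1)

    def test_insensitive_species(self):
        assert tumbling_probability(0.1, 0.0, 2e-5, 2.78e-4, 1.0) == pytest.approx(0.1)

    def test_worked_value(self):
        # X*dmu/(2 v mu_max) = 0.5 for this parameter set
        p = tumbling_probability(0.1, 1e-10, 2e-5, 2.78e-4, 55.6)
        assert p == pytest.approx(0.1 * math.exp(-0.5), rel=1e-2)

    def test_immobile_cell_keeps_p0(self):
        assert tumbling_probability(0.1, 1e-10, 0.0, 2.78e-4, 1.0) == pytest.approx(0.1)

    def test_clipped_to_unit_interval(self):
        assert tumbling_probability(0.9, 1e-6, 1e-9, 2.78e-4, -10.0) == 1.0


class TestGrowth:
    def test_no_growth_no_maintenance(self):
        a = Agent(0, 1e-15, 0, 0.3, 1)
        assert grow_agent(a, 0.0, 10.0).mass == 1e-15

    def test_arithmetic(self):
        a = Agent(0, 1e-15, 0, 0.3, 1)
        assert grow_agent(a, 1e-4, 10.0).mass == pytest.approx(1.001e-15)

    def test_geometric_closed_form(self):
        a = Agent(0, 1e-15, 0, 0.3, 1)
        mu, dt = 3e-4, 10.0
        for _ in range(50):
            a = grow_agent(a, mu, dt)
        assert a.mass == pytest.approx(1e-15 * (1 + mu * dt) ** 50, rel=1e-12)

    def test_maintenance_decay(self):
        a = Agent(0, 1e-15, 0, 0.3, 1)
        assert grow_agent(a, 0.0, 10.0, maintenance_rate=1e-3).mass == pytest.approx(0.99e-15)


class TestDivideOrDie:
    def test_division_conserves_mass(self, rng):
        tr = traits()
        a = Agent(0, 2e-15, 0, 0.3, 1)
        out = divide_or_die(a, tr, rng)
        assert len(out) == 2
        assert sum(d.mass for d in out) == 2e-15
        assert all(d.s == 0.3 and d.pore == 0 for d in out)

    def test_death_at_critical_mass(self, rng):
        assert divide_or_die(Agent(0, 0.5e-15, 0, 0.3, 1), traits(), rng) == []

    def test_between_thresholds_unchanged(self, rng):
        a = Agent(0, 1.2e-15, 0, 0.3, 1)
        assert divide_or_die(a, traits(), rng) == [a]

    def test_population_biomass_conserved_by_division(self, rng):
        net = netmod.build_chain(5, 1e-4)
        tr = traits()
        pop = make_population(tr, 100, 2, 0.5, 1, net)
        pop.mass[:] = np.linspace(1.9e-15, 2.1e-15, 100)
        total = pop.mass.sum()
        pop.divide_or_die(rng)
        assert pop.mass.sum() == pytest.approx(total, rel=1e-12)
        assert len(pop) > 100


class TestPooling:
    def test_assignment_sides(self):
        net = netmod.build_chain(3, 1e-4)
        tr = traits()
        pop = AgentPopulation([tr])
        pop.add([0, 0, 0], [1e-15] * 3, [0, 0, 1], [0.2, 0.5, 0.9], [1, 1, 1], [0, 0, 1])
        nodes = pop.node_assignment(net)
        assert nodes.tolist() == [0, 0, 2]

    def test_partition_identity(self, rng):
        net = netmod.build_lattice("hexagonal", 6, 6, 1e-4)
        tr = [traits(name="a"), traits(name="b", scaling_ratio=100)]
        pop = AgentPopulation(tr)
        n = 500
        pop.add(
            rng.integers(0, 2, n), rng.uniform(1e-15, 2e-15, n),
            rng.integers(0, net.n_pores, n), rng.uniform(0, 1, n),
            rng.choice([-1, 1], n), np.zeros(n, dtype=int),
        )
        _, biomass, cells, _ = pop.pool_by_node(net)
        assert biomass.sum() == pytest.approx(pop.total_biomass().sum(), rel=1e-12)
        ratio1 = pop.species == 1
        assert cells[:, 1].sum() == pytest.approx(100 * ratio1.sum())

    def test_super_agent_inoculum_biomass(self):
        # 3000 super agents of 100 cells at 1e-15 kg -> 3e-7 g
        net = netmod.build_chain(3, 1e-4)
        tr = traits(scaling_ratio=100)
        pop = make_population(tr, 3000, 0, 0.2, 1, net)
        assert pop.total_biomass().sum() * 1e3 == pytest.approx(3e-7)


class TestMovement:
    def test_ballistic_with_zero_tumbling(self):
        net = netmod.build_chain(3, 1e-3)
        tr = traits(p0=0.0)
        pop = make_population(tr, 10, 0, 0.0, 1, net)
        state = saturated(net)
        v, imm = pop.species_velocity_table(net, state)
        rng = np.random.default_rng(0)
        # V dt / L = 1e-5*10/1e-3 = 0.1 per step
        for k in range(1, 6):
            pop.move(net, v, imm, np.zeros(len(pop)), 10.0, rng)
            assert np.allclose(pop.s, 0.1 * k)

    def test_zero_velocity_only_detachment_moves(self):
        net = netmod.build_chain(4, 1e-4)
        # strong suction: drained pores with films thinner than the cell
        state = hyd.classify_saturation(net, -2e5, air_boundary="edge")
        assert (~state.saturated).all()
        tr = traits()
        pop = make_population(tr, 2000, 1, 0.4, 1, net)
        v, imm = pop.species_velocity_table(net, state)
        assert imm.all()
        rng = np.random.default_rng(0)
        s_before = pop.s.copy()
        pop.move(net, v, imm, np.full(len(pop), 0.1), 10.0, rng)
        moved = pop.s != s_before
        # about 10% detach to the previous node; nobody else moves
        assert 0.06 < moved.mean() < 0.14

    def test_msd_matches_telegraph_closed_form(self):
        """Unbiased run-and-tumble far from any node follows the discrete
        telegraph process: flip probability q = p0/2 per step, so
        Var(x_n) = (V dt)^2 [ n(1+rho)/(1-rho) - 2 rho (1-rho^n)/(1-rho)^2 ]
        with rho = 1 - 2q.  Checked at 1e5 agents to within 5%."""
        L = 1.0  # one very long pore: no node interactions
        net = netmod.build_chain(2, L)
        tr = traits(p0=0.1, V0=1e-5)
        n_agents, n_steps, dt = 100_000, 400, 10.0
        pop = make_population(tr, n_agents, 0, 0.5, 1, net)
        rng = np.random.default_rng(7)
        pop.direction = rng.choice(np.array([-1, 1], dtype=np.int8), n_agents)
        state = saturated(net)
        v, imm = pop.species_velocity_table(net, state)
        for _ in range(n_steps):
            pop.move(net, v, imm, np.full(n_agents, tr.p0), dt, rng)
        x = (pop.s - 0.5) * L
        assert abs(x.mean()) < 5 * x.std() / math.sqrt(n_agents)
        q = tr.p0 / 2.0
        rho = 1.0 - 2.0 * q
        step = tr.V0 * dt
        var = step**2 * (
            n_steps * (1 + rho) / (1 - rho)
            - 2 * rho * (1 - rho**n_steps) / (1 - rho) ** 2
        )
        assert np.mean(x**2) == pytest.approx(var, rel=0.05)

    def test_node_choice_includes_arrival_pore(self):
        # on a chain interior node, arriving agents should sometimes bounce
        net = netmod.build_chain(3, 1e-4)
        tr = traits(p0=0.0, V0=1e-5)
        pop = make_population(tr, 4000, 0, 0.95, 1, net)
        state = saturated(net)
        v, imm = pop.species_velocity_table(net, state)
        rng = np.random.default_rng(1)
        pop.move(net, v, imm, np.zeros(len(pop)), 10.0, rng)
        # all reach node 1 and choose pore 0 or 1 roughly evenly
        frac_back = (pop.pore == 0).mean()
        assert 0.45 < frac_back < 0.55

    def test_total_biomass_unchanged_by_motion(self, rng):
        net = netmod.build_lattice("hexagonal", 8, 8, 1e-4)
        tr = traits()
        pop = AgentPopulation([tr])
        n = 3000
        pop.add(np.zeros(n, dtype=int), rng.uniform(1e-15, 2e-15, n),
                rng.integers(0, net.n_pores, n), rng.uniform(0, 1, n),
                rng.choice([-1, 1], n), np.zeros(n, dtype=int))
        state = saturated(net)
        v, imm = pop.species_velocity_table(net, state)
        total = pop.mass.sum()
        for _ in range(20):
            pop.move(net, v, imm, np.full(n, 0.1), 10.0, rng)
        assert pop.mass.sum() == total
        assert (pop.s >= 0).all() and (pop.s <= 1).all()

    def test_identical_seeds_identical_trajectories(self):
        net = netmod.build_lattice("hexagonal", 6, 6, 1e-4)
        state = saturated(net)
        tr = traits()
        outs = []
        for _ in range(2):
            pop = make_population(tr, 500, 0, 0.5, 1, net)
            v, imm = pop.species_velocity_table(net, state)
            rng = np.random.default_rng(99)
            for _ in range(50):
                pop.move(net, v, imm, np.full(len(pop), 0.1), 10.0, rng)
            outs.append((pop.pore.copy(), pop.s.copy(), pop.direction.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])


class TestChemotaxis:
    def run_drift(self, chi, n_agents=1000, n_steps=4000, seed=5):
        """Drift along an imposed linear growth-rate field on a long chain."""
        pore_len = 1e-4
        n_nodes = 20001
        net = netmod.build_chain(n_nodes, pore_len)
        tr = traits(chi=chi, V0=2e-5, p0=0.1, mu_max=2.78e-4)
        start = n_nodes // 2
        pop = make_population(tr, n_agents, start, 0.5, 1, net)
        rng = np.random.default_rng(seed)
        pop.direction = rng.choice(np.array([-1, 1], dtype=np.int8), n_agents)
        state = saturated(net)
        v, imm = pop.species_velocity_table(net, state)
        k = 55.6  # growth-rate gradient, s^-1 per metre: exponent 0.5 at V0
        dt = 10.0
        x0 = positions(pop, net)
        mu_prev = k * x0
        pop.mu_prev = mu_prev
        for _ in range(n_steps):
            x = positions(pop, net)
            mu_now = k * x
            v_agent = v[pop.species, pop.pore]
            p = pop.tumbling_probabilities(mu_now, v_agent, dt)
            pop.move(net, v, imm, p, dt, rng)
            pop.mu_prev = mu_now
        return positions(pop, net) - x0

    def test_bias_up_gradient_versus_null(self):
        from scipy import stats

        disp_chemo = self.run_drift(chi=1e-10)
        disp_null = self.run_drift(chi=0.0)
        test = stats.ttest_ind(disp_chemo, disp_null, alternative="greater",
                               equal_var=False)
        assert test.pvalue < 0.01
        assert disp_chemo.mean() > disp_null.mean()


class TestSuperAgentCongruence:
    def dispersal(self, ratio, n_cells, seed):
        """Final positions after dispersal from the chain centre."""
        net = netmod.build_chain(100, 2000e-6 / 99)
        tr = traits(scaling_ratio=ratio, V0=1e-5, p0=0.1)
        n_agents = n_cells // ratio
        pop = make_population(tr, n_agents, 49, 0.5, 1, net)
        rng = np.random.default_rng(seed)
        pop.direction = rng.choice(np.array([-1, 1], dtype=np.int8), n_agents)
        state = saturated(net)
        v, imm = pop.species_velocity_table(net, state)
        for _ in range(300):
            pop.move(net, v, imm, np.full(len(pop), tr.p0), 10.0, rng)
        return positions(pop, net)

    def test_super_agents_match_individuals(self):
        """Dispersal profiles of matched-biomass individual and super-agent
        populations are statistically indistinguishable (two-sample KS over
        10 seeds, judged jointly by Fisher's method and the median p)."""
        from scipy import stats

        pvals = []
        for seed in range(10):
            ind = self.dispersal(1, 20000, seed)
            sup = self.dispersal(100, 20000, 1000 + seed)
            pvals.append(stats.ks_2samp(ind, sup).pvalue)
        fisher = stats.combine_pvalues(pvals, method="fisher").pvalue
        assert np.median(pvals) > 0.05
        assert fisher > 0.05
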