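"""FBA/FVA/dFBA engine against hand LPs and an independent solver."""

import numpy as np
import pytest

from porecosm import metabolism as met
from porecosm import toymodels
from porecosm import units
from porecosm.metabolism import (
    MetabolicModel,
    allocate_node_moles,
    compare_models_fva,
    condition_grid,
    fba,
    fva,
    node_dfba,
    parse_equation,
    read_tabular,
    write_tabular,
)


def simple_chain_model():
    """Hand LP: uptake A <= bound, A -> 0.1 biomass => mu = 0.1 * bound...
    here yield 1 biomass per 10 A, i.e. mu = bound/10."""
    rows = [
        ("EX_a", "a_e <->", -1000.0, 1000.0),
        ("T_a", "a_e -> a_c", 0.0, 1000.0),
        ("BIO", "10 a_c ->", 0.0, 1000.0),
    ]
    return toymodels._build(
        "chain", "BIO", rows, exchanges={"a": "EX_a"}, max_uptake={"a": 10.0},
        carbon={"a_e": 1, "a_c": 1}, biomass_carbon=10.0,
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (independent oracle path)."""
    import cobra

    cm = cobra.Model(model.name)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    for j, rid in enumerate(model.reactions):
        r = cobra.Reaction(rid)
        r.lower_bound, r.upper_bound = float(model.lb[j]), float(model.ub[j])
        r.add_metabolites(
            {mets[m]: float(model.S[i, j]) for i, m in enumerate(model.metabolites)
             if model.S[i, j] != 0}
        )
        cm.add_reactions([r])
    cm.objective = model.biomass
    return cm


def cobra_fba(model, uptake_bounds):
    cm = to_cobra(model)
    for sol, rid in model.exchanges.items():
        cm.reactions.get_by_id(rid).lower_bound = -float(uptake_bounds.get(sol, 0.0))
    return cm.optimize()


class TestEquationDialect:
    def test_parse_coefficients_and_sides(self):
        st = parse_equation("r", "2 A + B -> 3 C")
        assert st == {"A": -2.0, "B": -1.0, "C": 3.0}

    def test_parse_reversible_and_empty_side(self):
        assert parse_equation("r", "glc_e <->") == {"glc_e": -1.0}

    def test_malformed_coefficient_names_reaction(self):
        with pytest.raises(ValueError, match="badrxn"):
            parse_equation("badrxn", "2x A -> B")

    def test_missing_arrow(self):
        with pytest.raises(ValueError, match="arrow"):
            parse_equation("r", "A + B")


class TestTabularIO:
    def test_round_trip(self, tmp_path):
        model = toymodels.make_toy_facultative()
        write_tabular(model, tmp_path / "fac.tsv")
        back = read_tabular(tmp_path / "fac.tsv")
        assert back.reactions == model.reactions
        # metabolite order may differ; compare stoichiometry by name
        for j, rid in enumerate(model.reactions):
            orig = {m: model.S[i, j] for i, m in enumerate(model.metabolites)
                    if model.S[i, j]}
            got = {m: back.S[i, j] for i, m in enumerate(back.metabolites)
                   if back.S[i, j]}
            assert got == orig
        assert np.allclose(back.lb, model.lb) and np.allclose(back.ub, model.ub)
        assert back.exchanges == model.exchanges
        assert back.max_uptake == model.max_uptake

    def test_missing_biomass_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("id\tequation\tlb\tub\nr\tA ->\t0\t1\n")
        with pytest.raises(ValueError, match="biomass"):
            read_tabular(tmp_path / "bad.tsv")

    def test_sbml_round_trip_via_cobra(self, tmp_path):
        import cobra.io

        model = simple_chain_model()
        cm = to_cobra(model)
        cobra.io.write_sbml_model(cm, str(tmp_path / "chain.xml"))
        back = met.read_model(tmp_path / "chain.xml",
                              exchanges={"a": "EX_a"}, max_uptake={"a": 10.0})
        assert sorted(back.reactions) == sorted(model.reactions)
        assert fba(back, {"a": 10}).mu == pytest.approx(1.0)


class TestFBA:
    def test_chain_optimum_is_yield_times_bound(self):
        model = simple_chain_model()
        assert fba(model, {"a": 10}).mu == pytest.approx(1.0)
        assert fba(model, {"a": 4}).mu == pytest.approx(0.4)

    def test_closed_uptakes_no_growth(self):
        for name in ("toy_aerobe", "toy_facultative", "toy_pair_a", "toy_pair_b"):
            toymodels.toy_model(name).check_consistency()

    def test_monotone_in_uptake_bounds(self):
        model = toymodels.make_toy_facultative()
        mus = [
            fba(model, {"glucose": g, "oxygen": 30}).mu for g in (0, 2, 4, 8)
        ]
        assert all(m2 >= m1 - 1e-12 for m1, m2 in zip(mus, mus[1:]))

    def test_facultative_route_switching(self):
        model = toymodels.make_toy_facultative()
        aerobic = fba(model, {"glucose": 8, "oxygen": 30, "nitrate": 20})
        assert aerobic.exchange_fluxes["acetate"] == pytest.approx(0.0, abs=1e-9)
        assert aerobic.exchange_fluxes["nitrate"] == pytest.approx(0.0, abs=1e-9)
        anoxic = fba(model, {"glucose": 8, "nitrate": 20})
        assert anoxic.mu > 0
        assert anoxic.exchange_fluxes["nitrate"] < -1e-6
        fermenting = fba(model, {"glucose": 8})
        assert fermenting.mu > 0
        assert fermenting.exchange_fluxes["acetate"] > 1e-6

    def test_overflow_iff_acceptor_limited(self):
        model = toymodels.make_toy_facultative()
        for o2 in (30.0, 20.0, 12.5):
            sol = fba(model, {"glucose": 8, "oxygen": o2})
            assert sol.exchange_fluxes["acetate"] <= 1e-9
        for o2 in (10.0, 5.0, 1.0, 0.0):
            sol = fba(model, {"glucose": 8, "oxygen": o2})
            assert sol.exchange_fluxes["acetate"] > 1e-6

    def test_agrees_with_cobra_oracle(self):
        model = toymodels.make_toy_facultative()
        cases = [
            {"glucose": 8, "oxygen": 30},
            {"glucose": 8, "nitrate": 20},
            {"glucose": 8},
            {"glucose": 4.8, "oxygen": 18, "nitrate": 6, "acetate": 10},
        ]
        for bounds in cases:
            ours = fba(model, bounds).mu
            theirs = cobra_fba(model, bounds).objective_value
            assert ours == pytest.approx(theirs, rel=1e-6)

    def test_uptake_never_exceeds_bound(self):
        model = toymodels.make_toy_facultative()
        sol = fba(model, {"glucose": 3.3, "oxygen": 7.1})
        for name, flux in sol.exchange_fluxes.items():
            assert -flux <= {"glucose": 3.3, "oxygen": 7.1}.get(name, 0.0) + 1e-9


class TestFVA:
    def test_single_route_envelope_is_tight(self):
        model = simple_chain_model()
        env = fva(model, {"a": 10})
        sol = fba(model, {"a": 10})
        for rid, (lo, hi) in env.items():
            assert lo == pytest.approx(hi, abs=1e-9)
            assert lo == pytest.approx(sol.fluxes[rid], abs=1e-9)

    def test_blocked_reaction_is_zero(self):
        rows = [
            ("EX_a", "a_e <->", -1000.0, 1000.0),
            ("T_a", "a_e -> a_c", 0.0, 1000.0),
            ("BIO", "10 a_c ->", 0.0, 1000.0),
            ("ORPHAN", "x_c -> y_c", 0.0, 1000.0),
        ]
        model = toymodels._build("blocked", "BIO", rows,
                                 exchanges={"a": "EX_a"}, max_uptake={"a": 10},
                                 carbon={}, biomass_carbon=0.0)
        env = fva(model, {"a": 10})
        assert env["ORPHAN"] == (pytest.approx(0.0), pytest.approx(0.0))

    def test_parallel_routes_widen_envelope(self):
        rows = [
            ("EX_a", "a_e <->", -1000.0, 1000.0),
            ("T1", "a_e -> a_c", 0.0, 1000.0),
            ("T2", "a_e -> a_c", 0.0, 1000.0),
            ("BIO", "10 a_c ->", 0.0, 1000.0),
        ]
        model = toymodels._build("par", "BIO", rows, exchanges={"a": "EX_a"},
                                 max_uptake={"a": 10}, carbon={},
                                 biomass_carbon=0.0)
        env = fva(model, {"a": 10})
        assert env["T1"][0] == pytest.approx(0.0, abs=1e-9)
        assert env["T1"][1] == pytest.approx(10.0, rel=1e-9)
        assert fba(model, {"a": 10}).mu == pytest.approx(1.0)

    def test_agrees_with_cobra_fva(self):
        from cobra.flux_analysis import flux_variability_analysis

        model = toymodels.make_toy_facultative()
        bounds = {"glucose": 8, "oxygen": 10}
        ours = fva(model, bounds, fraction=1.0)
        cm = to_cobra(model)
        for sol, rid in model.exchanges.items():
            cm.reactions.get_by_id(rid).lower_bound = -float(bounds.get(sol, 0.0))
        theirs = flux_variability_analysis(cm, fraction_of_optimum=1.0)
        for rid in model.reactions:
            assert ours[rid][0] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-6)
            assert ours[rid][1] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-6)


class TestConditionGrid:
    def test_sizes(self):
        maxu = {s: 8.0 for s in "abcd"}
        assert len(condition_grid(list("abcd"), maxu)) == 81
        assert len(condition_grid(list("abc"), maxu)) == 27

    def test_single_substrate_values(self):
        grid = condition_grid(["glc"], {"glc": 8.0})
        assert sorted(g["glc"] for g in grid) == [1.6, 4.8, 8.0]

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            condition_grid([], {})


class TestCompareModels:
    def test_self_comparison_all_in_first_bin(self):
        model = toymodels.make_toy_facultative()
        grid = condition_grid(["glucose", "oxygen"], model.max_uptake)
        table = compare_models_fva(model, model, grid)
        assert len(table) == 9
        assert (table["<0.1"] == 1.0).all()
        bins = table[list(met.BIN_LABELS)].sum(axis=1)
        assert np.allclose(bins, 1.0)

    def test_missing_reaction_excluded_from_denominator(self):
        full = toymodels.make_toy_facultative()
        reduced = toymodels.make_toy_facultative()
        # drop the denitrification route from the "reduced" model
        keep = [r for r in reduced.reactions if r != "DEN"]
        idx = [reduced.reactions.index(r) for r in keep]
        reduced = MetabolicModel(
            name="fac_red", metabolites=reduced.metabolites, reactions=keep,
            S=reduced.S[:, idx], lb=reduced.lb[idx], ub=reduced.ub[idx],
            biomass=reduced.biomass, exchanges=reduced.exchanges,
            max_uptake=reduced.max_uptake,
        )
        grid = condition_grid(["glucose", "oxygen"], full.max_uptake)
        table = compare_models_fva(full, reduced, grid)
        assert np.allclose(table[list(met.BIN_LABELS)].sum(axis=1), 1.0)

    def test_no_common_reactions_rejected(self):
        a = simple_chain_model()
        b = toymodels.make_toy_pair()[1]
        with pytest.raises(ValueError, match="common"):
            compare_models_fva(a, b, [{}])


class TestNodeDFBA:
    def test_abundant_nutrients_hit_max_uptake(self):
        model = toymodels.make_toy_facultative()
        sol, moles = node_dfba(model, 1e-12, {"glucose": 50.0, "oxygen": 50.0},
                               v_w=1e-9, dt=10.0)
        assert sol.exchange_fluxes["glucose"] == pytest.approx(-8.0)

    def test_scarce_nutrient_drained_in_one_step(self):
        model = simple_chain_model()
        v_w, dt = 1e-12, 10.0
        conc = {"a": 0.01}  # 1e-14 mol available
        biomass = 1e-9  # large biomass -> availability cap binds
        sol, moles = node_dfba(model, biomass, conc, v_w, dt)
        avail = conc["a"] * v_w
        assert -moles["a"] == pytest.approx(avail, rel=1e-12)

    def test_consumption_never_exceeds_availability_randomised(self, rng):
        model = toymodels.make_toy_facultative()
        for _ in range(300):
            conc = {s: float(rng.uniform(0, 2)) for s in model.exchanges}
            v_w = 10 ** rng.uniform(-14, -9)
            biomass = 10 ** rng.uniform(-15, -8)
            dt = float(rng.choice([1.0, 10.0, 60.0]))
            _, moles = node_dfba(model, biomass, conc, v_w, dt)
            for s, dm in moles.items():
                if dm < 0:
                    assert -dm <= conc[s] * v_w * (1 + 1e-12)

    def test_carbon_mass_closure(self, rng):
        """Carbon consumed equals carbon fixed into biomass plus carbon
        excreted, on the carbon-balanced toy models."""
        for name in ("toy_aerobe", "toy_facultative"):
            model = toymodels.toy_model(name)
            assert max(abs(v) for v in model.carbon_imbalance().values()) == 0.0
            for _ in range(50):
                conc = {s: float(rng.uniform(0, 5)) for s in model.exchanges}
                biomass = 10 ** rng.uniform(-13, -10)
                dt = 10.0
                sol, moles = node_dfba(model, biomass, conc, 1e-11, dt)
                c_in = -sum(
                    moles[s] * model.carbon.get(f"{pref}_e", 0.0)
                    for s, pref in (("glucose", "glc"), ("acetate", "ac"))
                    if s in moles and moles[s] < 0
                )
                c_out = sum(
                    moles[s] * model.carbon.get(f"{pref}_e", 0.0)
                    for s, pref in (("acetate", "ac"),)
                    if s in moles and moles[s] > 0
                )
                # CO2 is unmapped: recover it from the full flux vector
                co2 = sol.fluxes.get("EX_co2", 0.0)
                c_out += units.flux_to_moles(co2, biomass, dt) * model.carbon["co2_e"]
                c_bio = (
                    units.flux_to_moles(sol.mu, biomass, dt) * model.biomass_carbon
                )
                if c_in > 0:
                    assert c_in == pytest.approx(c_out + c_bio, rel=1e-9)

    def test_rejects_nonpositive_inputs(self):
        model = simple_chain_model()
        with pytest.raises(ValueError):
            node_dfba(model, 0.0, {"a": 1.0}, 1e-12, 10.0)
        with pytest.raises(ValueError):
            node_dfba(model, 1e-12, {"a": 1.0}, 0.0, 10.0)


class TestAllocation:
    def test_equal_split_when_unconstrained(self):
        alloc = allocate_node_moles(6.0, np.array([1.0, 2.0]), np.array([10.0, 10.0]))
        assert alloc == pytest.approx([2.0, 4.0])

    def test_surplus_redistributed(self):
        # pool 0 saturates at 1; its unused share flows to pool 1
        alloc = allocate_node_moles(6.0, np.array([1.0, 1.0]), np.array([1.0, 10.0]))
        assert alloc == pytest.approx([1.0, 5.0])

    def test_never_oversubscribed(self, rng):
        for _ in range(200):
            n = rng.integers(1, 5)
            avail = float(rng.uniform(0, 10))
            cells = rng.uniform(0.1, 100, n)
            caps = rng.uniform(0, 5, n)
            alloc = allocate_node_moles(avail, cells, caps)
            assert alloc.sum() <= avail * (1 + 1e-12) + 1e-15
            assert (alloc <= caps * (1 + 1e-12)).all()
            # work-conserving: either everything allocated or all pools full
            if avail < caps.sum() * (1 - 1e-9):
                assert alloc.sum() == pytest.approx(avail, rel=1e-9)
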