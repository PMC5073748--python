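import random

import pytest

from exaptmap import (
    FBASolver,
    InviableGenotypeError,
    disconnected_reactions,
    full_genotype,
    make_genotype,
    make_toy_universe,
)
from exaptmap.model_io import Environment, Genotype

from conftest import chain_spec, parallel_spec, toy_corpus


@pytest.fixture(scope="module")
def chain3():
    universe, envs = make_toy_universe(chain_spec(3))
    return universe, envs["src0"]


class TestSolveFBA:
    def test_linear_pathway_objective_equals_uptake_bound(self, chain3):
        """A unit-stoichiometry chain converts the whole uptake into biomass."""
        universe, env = chain3
        solver = FBASolver(universe)
        sol = solver.solve_fba(full_genotype(universe), env)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(env.uptake_bounds[env.carbon_source])

    def test_empty_genotype_yields_zero_biomass(self, chain3, core_solver, core_envs):
        universe, env = chain3
        assert FBASolver(universe).max_biomass(0, env) == pytest.approx(0.0)
        for e in core_envs.values():
            assert core_solver.max_biomass(0, e) == pytest.approx(0.0, abs=1e-9)

    def test_full_network_grows_on_all_ten_sources(self, core_solver, core_envs):
        full = full_genotype(core_solver.universe)
        for env in core_envs.values():
            assert core_solver.max_biomass(full, env) > 0.1

    def test_mass_balance_and_bounds_hold_at_optimum(self, core_solver, core_envs):
        import numpy as np

        env = core_envs["glucose"]
        sol = core_solver.solve_fba(full_genotype(core_solver.universe), env)
        v = np.array([sol.fluxes[r] for r in core_solver.reaction_ids])
        assert np.abs(core_solver.S @ v).max() < 1e-6
        lb, ub = core_solver.env_bounds(env)
        assert (v >= lb - 1e-6).all() and (v <= ub + 1e-6).all()

    def test_flux_vector_tsv_round_trip(self, chain3, tmp_path):
        universe, env = chain3
        sol = FBASolver(universe).solve_fba(full_genotype(universe), env)
        sol.to_tsv(tmp_path / "fluxes.tsv")
        lines = (tmp_path / "fluxes.tsv").read_text().splitlines()
        assert lines[0] == "reaction\tflux"
        back = {r: float(v) for r, v in (l.split("\t") for l in lines[1:])}
        assert back == pytest.approx(sol.fluxes)

    def test_glpk_and_scipy_backends_agree(self):
        universe, envs = make_toy_universe(toy_corpus(6)[3])
        fast = FBASolver(universe, backend="glpk")
        slow = FBASolver(universe, backend="scipy")
        rng = random.Random(7)
        n = universe.n_internal
        for _ in range(25):
            mask = rng.getrandbits(n)
            for env in envs.values():
                assert fast.max_biomass(mask, env) == pytest.approx(
                    slow.max_biomass(mask, env), abs=1e-7
                )


class TestViability:
    def test_full_genotype_viable_everywhere(self, core_solver, core_envs, core_thresholds):
        full = full_genotype(core_solver.universe)
        assert all(
            core_solver.is_viable(full, env, core_thresholds)
            for env in core_envs.values()
        )

    def test_missing_universal_essential_kills_every_source(
        self, core_solver, core_envs, core_thresholds
    ):
        ess = core_solver.essential_reactions(core_envs, core_thresholds)
        rid = sorted(ess)[0]
        g = make_genotype(
            core_solver.universe,
            [r for r in core_solver.universe.internal_ids if r != rid],
        )
        for env in core_envs.values():
            assert not core_solver.is_viable(g, env, core_thresholds)

    def test_monotone_under_reaction_addition_on_core_model(
        self, core_solver, core_envs, core_thresholds
    ):
        """For random nested genotype pairs g within g', viability of g
        implies viability of g' (deletion only restricts the LP)."""
        rng = random.Random(11)
        env = core_envs["glucose"]
        viable = core_solver.viability_oracle(env, core_thresholds)
        n = core_solver.n_internal
        full = (1 << n) - 1
        checked = 0
        for _ in range(60):
            # dense genotypes: random genotypes are almost surely inviable
            g = full
            for j in range(n):
                if rng.random() < 0.15:
                    g &= ~(1 << j)
            sup = g | rng.getrandbits(n)
            if viable(g):
                checked += 1
                assert viable(sup)
        assert checked > 0

    def test_full_network_is_flux_upper_bound_for_subgenotypes(
        self, core_solver, core_envs
    ):
        rng = random.Random(3)
        env = core_envs["pyruvate"]
        top = core_solver.max_biomass(full_genotype(core_solver.universe), env)
        for _ in range(20):
            assert core_solver.max_biomass(rng.getrandbits(51), env) <= top + 1e-9


class TestEssentiality:
    def test_single_chain_all_steps_essential(self):
        universe, envs = make_toy_universe(chain_spec(4))
        solver = FBASolver(universe)
        th = solver.viability_thresholds(envs)
        ess = solver.essential_reactions(envs, th)
        assert ess == set(universe.internal_ids)

    def test_parallel_pathways_are_not_essential(self):
        universe, envs = make_toy_universe(parallel_spec(3, 4))
        solver = FBASolver(universe)
        th = solver.viability_thresholds(envs)
        # brute-force single deletions: every deletion leaves the other path
        ess = solver.essential_reactions(envs, th)
        assert ess == set()


class TestYield:
    def test_yield_invariant_to_uptake_rescaling(self, core_universe, core_envs):
        solver = FBASolver(core_universe)
        env = core_envs["glucose"]
        doubled = Environment(
            name=env.name,
            carbon_source=env.carbon_source,
            fixed_nutrients=env.fixed_nutrients,
            uptake_bounds={m: 2 * b for m, b in env.uptake_bounds.items()},
        )
        g = full_genotype(core_universe)
        assert solver.yield_per_carbon(g, env) == pytest.approx(
            solver.yield_per_carbon(g, doubled), rel=1e-6
        )

    def test_hand_solved_toy_yield_per_carbon(self):
        """One-to-one conversion of an nc-carbon source gives yield 1/nc."""
        spec = chain_spec(2, seed=4)
        universe, envs = make_toy_universe(spec)
        env = next(iter(envs.values()))
        nc = universe.metabolite_index[env.carbon_source].carbon_atoms
        solver = FBASolver(universe)
        got = solver.yield_per_carbon(full_genotype(universe), env)
        assert got == pytest.approx(1.0 / nc)

    def test_inviable_genotype_signals_explicitly(self, chain3):
        universe, env = chain3
        with pytest.raises(InviableGenotypeError):
            FBASolver(universe).yield_per_carbon(0, env)


class TestWaste:
    def test_clean_pathway_excretes_nothing(self, chain3):
        universe, env = chain3
        solver = FBASolver(universe)
        assert solver.count_waste_metabolites(full_genotype(universe), env) == 0

    def test_forced_byproduct_counts_as_one_waste_molecule(self):
        spec = chain_spec(1)
        universe, envs = make_toy_universe(
            type(spec)(**{**spec.__dict__, "byproduct_rate": 1.0})
        )
        env = next(iter(envs.values()))
        solver = FBASolver(universe)
        assert solver.count_waste_metabolites(full_genotype(universe), env) == 1

    def test_core_model_waste_bounded_by_excretable_metabolites(
        self, core_solver, core_envs
    ):
        env = core_envs["glucose"]
        w = core_solver.count_waste_metabolites(
            full_genotype(core_solver.universe), env
        )
        assert 0 <= w <= len(core_solver.universe.exchange_reactions)


class TestDisconnected:
    def test_fully_wired_toy_has_no_disconnected_reactions(self, chain3):
        universe, env = chain3
        assert disconnected_reactions(universe, full_genotype(universe), env) == set()

    def test_reaction_with_unproducible_substrate_is_flagged(self):
        universe, envs = make_toy_universe(parallel_spec(2, 3))
        env = envs["src0"]
        # keep a mid-pathway reaction whose substrate is never made
        n = universe.n_internal
        inner = [
            i for i, r in enumerate(universe.internal_reactions)
            if not any(m.endswith("src0_c") for m in r.substrates())
        ]
        g = Genotype(1 << inner[0], n)
        assert universe.internal_reactions[inner[0]].id in disconnected_reactions(
            universe, g, env
        )

    def test_agrees_with_independent_reachability_implementation(self):
        rng = random.Random(5)
        for spec in toy_corpus(8):
            universe, envs = make_toy_universe(spec)
            env = next(iter(envs.values()))
            n = universe.n_internal
            for _ in range(20):
                mask = rng.getrandbits(n)
                got = disconnected_reactions(universe, mask, env)
                assert got == _disconnected_reference(universe, mask, env)


def _disconnected_reference(universe, mask, env):
    """Re-evaluation of the two disconnection criteria from scratch."""
    present = [r for i, r in enumerate(universe.internal_reactions) if (mask >> i) & 1]
    others_pool = present + universe.transport_reactions + [universe.biomass_reaction]
    nutrients = {m for m, b in env.uptake_bounds.items() if b > 0}
    precursors = set(universe.biomass_precursors)

    def sides(r):
        subs = tuple(m for m, c in r.stoichiometry.items() if c < 0)
        prods = tuple(m for m, c in r.stoichiometry.items() if c > 0)
        if r.reversible:
            return [(subs, prods), (prods, subs)]
        return [(subs, prods)]

    flagged = set()
    for r in present:
        consumable, producible = set(), set(nutrients)
        for o in others_pool:
            if o.id == r.id:
                continue
            for s, p in sides(o):
                consumable.update(s)
                producible.update(p)
        ok = False
        for subs, prods in sides(r):
            i_fails = all(p not in precursors and p not in consumable for p in prods)
            ii_fails = any(s not in producible for s in subs)
            if not i_fails and not ii_fails:
                ok = True
        if not ok:
            flagged.add(r.id)
    return flagged
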