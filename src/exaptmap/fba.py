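"""Flux balance analysis: the viability oracle and per-genotype metrics.

Viability of a genotype on a carbon source is decided by the linear program

    max  c^T v   s.t.   S v = 0,   a <= v <= b

where ``S`` is the stoichiometric matrix over all reactions of the universe
(internal, transport, exchange, biomass), ``c`` selects the biomass reaction,
and absent internal reactions are clamped to zero flux.  A genotype is viable
on a source if its maximal biomass synthesis rate exceeds 1 % of the rate of
the full network (all internal reactions present) on that same source.

Because deleting a reaction only restricts the feasible flux polytope,
viability is monotone under reaction addition; all downstream enumeration
and counting relies on this.

Two LP backends are provided: a persistent GLPK problem per environment
(warm-started simplex re-solves; the default, used for the millions of
viability queries of the enumeration), and scipy's HiGHS ``linprog``
(stateless; used as an independent cross-check and by the brute-force
oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .model_io import Environment, Genotype, ReactionUniverse, full_genotype

__all__ = [
    "ZERO_TOL",
    "VIABILITY_GUARD",
    "OptimalFlux",
    "ViabilityThresholds",
    "FBAProblem",
    "FBAError",
    "InviableGenotypeError",
    "FBASolver",
    "disconnected_reactions",
]

#: absolute tolerance below which a flux is treated as zero
ZERO_TOL = 1e-9
#: relative guard applied to the viability threshold comparison
VIABILITY_GUARD = 1e-6
#: uptake bound placed on the sole carbon source (results are scale-invariant)
CARBON_UPTAKE = 10.0


class FBAError(RuntimeError):
    pass


class InviableGenotypeError(FBAError):
    """Raised when a metric is requested for a genotype that is not viable."""


@dataclass
class FBAProblem:
    """Explicit LP data for one (genotype, environment) pair:
    max c^T v subject to S v = 0 and a <= v <= b."""

    S: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    reaction_index: Mapping[str, int]


@dataclass
class OptimalFlux:
    """One optimal flux distribution; ``objective`` is the biomass rate."""

    objective: float
    fluxes: Dict[str, float]
    status: str  # "optimal" | "infeasible"

    def to_tsv(self, path) -> None:
        """Write the flux vector as a two-column TSV (reaction id, flux)."""
        with open(path, "w") as fh:
            fh.write("reaction\tflux\n")
            for rid, v in self.fluxes.items():
                fh.write(f"{rid}\t{v:.10g}\n")


@dataclass(frozen=True)
class ViabilityThresholds:
    """Per-source viability thresholds: 1 % of the full network's rate."""

    values: Mapping[str, float]
    fraction: float = 0.01

    def __post_init__(self) -> None:
        bad = [s for s, v in self.values.items() if not v > 0]
        if bad:
            raise FBAError(f"full network is not viable on {bad}; thresholds undefined")

    def __getitem__(self, source: str) -> float:
        return self.values[source]

    def sources(self) -> List[str]:
        return list(self.values)


# ---------------------------------------------------------------------------
# GLPK backend (persistent problems, warm-started re-solves)
# ---------------------------------------------------------------------------

class _GlpkLP:
    """A persistent GLPK linear program ``max c^T v : S v = 0, lb <= v <= ub``."""

    def __init__(self, S: np.ndarray, lb: np.ndarray, ub: np.ndarray, obj_col: int):
        import swiglpk as glp

        self._glp = glp
        glp.glp_term_out(glp.GLP_OFF)
        m, n = S.shape
        self.n = n
        lp = glp.glp_create_prob()
        glp.glp_add_rows(lp, m)
        glp.glp_add_cols(lp, n)
        for i in range(m):
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        nzi, nzj = np.nonzero(S)
        ne = len(nzi)
        ia, ja, ar = glp.intArray(ne + 1), glp.intArray(ne + 1), glp.doubleArray(ne + 1)
        for k in range(ne):
            ia[k + 1] = int(nzi[k]) + 1
            ja[k + 1] = int(nzj[k]) + 1
            ar[k + 1] = float(S[nzi[k], nzj[k]])
        glp.glp_load_matrix(lp, ne, ia, ja, ar)
        self.lp = lp
        self.lb0 = lb.copy()
        self.ub0 = ub.copy()
        for j in range(n):
            self.set_col_bounds(j, lb[j], ub[j])
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        glp.glp_set_obj_coef(lp, obj_col + 1, 1.0)
        self._obj_cols = [obj_col]
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        self.parm = parm
        glp.glp_adv_basis(lp, 0)

    def set_col_bounds(self, j: int, lo: float, hi: float) -> None:
        glp = self._glp
        if lo == hi:
            glp.glp_set_col_bnds(self.lp, j + 1, glp.GLP_FX, lo, hi)
        else:
            glp.glp_set_col_bnds(self.lp, j + 1, glp.GLP_DB, lo, hi)

    def reset_col_bounds(self, j: int) -> None:
        self.set_col_bounds(j, self.lb0[j], self.ub0[j])

    def set_objective(self, cols: Mapping[int, float], maximize: bool = True) -> None:
        glp = self._glp
        for j in self._obj_cols:
            glp.glp_set_obj_coef(self.lp, j + 1, 0.0)
        for j, c in cols.items():
            glp.glp_set_obj_coef(self.lp, j + 1, c)
        glp.glp_set_obj_dir(self.lp, glp.GLP_MAX if maximize else glp.GLP_MIN)
        self._obj_cols = list(cols)

    def solve(self) -> bool:
        """Warm-started simplex; True iff an optimal solution was found."""
        glp = self._glp
        ret = glp.glp_simplex(self.lp, self.parm)
        if ret != 0:  # numerical trouble: retry from a fresh advanced basis
            glp.glp_adv_basis(self.lp, 0)
            ret = glp.glp_simplex(self.lp, self.parm)
            if ret != 0:
                raise FBAError(f"GLPK simplex failed (code {ret})")
        return glp.glp_get_status(self.lp) == glp.GLP_OPT

    def refresh_basis(self) -> None:
        self._glp.glp_adv_basis(self.lp, 0)

    def objective_value(self) -> float:
        return self._glp.glp_get_obj_val(self.lp)

    def col_values(self) -> np.ndarray:
        glp = self._glp
        return np.array([glp.glp_get_col_prim(self.lp, j + 1) for j in range(self.n)])


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

class FBASolver:
    """FBA viability oracle and per-genotype metrics for one universe.

    Columns are ordered: internal reactions (genotype bit order), transport,
    exchange, biomass last.  One persistent GLPK problem is kept per
    environment; a genotype is applied by clamping the bounds of absent
    internal reactions to zero.
    """

    def __init__(self, universe: ReactionUniverse, backend: str = "glpk"):
        if backend not in ("glpk", "scipy"):
            raise ValueError(f"unknown backend {backend!r}")
        self.universe = universe
        self.backend = backend
        rxns = universe.all_reactions()
        self.reaction_ids = [r.id for r in rxns]
        self.reaction_index = {r.id: j for j, r in enumerate(rxns)}
        mets = [m.id for m in universe.metabolites]
        met_index = {m: i for i, m in enumerate(mets)}
        self.metabolite_ids = mets
        S = np.zeros((len(mets), len(rxns)))
        for j, r in enumerate(rxns):
            for mid, coef in r.stoichiometry.items():
                S[met_index[mid], j] = coef
        self.S = S
        self.lb = np.array([r.lower_bound for r in rxns])
        self.ub = np.array([r.upper_bound for r in rxns])
        self.biomass_col = len(rxns) - 1
        self.n_internal = universe.n_internal
        self._full_mask = (1 << self.n_internal) - 1
        self._lp_cache: Dict[tuple, _GlpkLP] = {}
        self._envs: Dict[str, Environment] = {}

    # -- problem assembly ---------------------------------------------------
    def env_bounds(self, env: Environment) -> Tuple[np.ndarray, np.ndarray]:
        """Bound vectors (a, b) for the full network in this environment."""
        lb, ub = self.lb.copy(), self.ub.copy()
        for met, r in self.universe.exchange_by_metabolite.items():
            j = self.reaction_index[r.id]
            lb[j] = -float(env.uptake_bounds.get(met, 0.0))
        return lb, ub

    def fba_problem(self, genotype: Genotype | int, env: Environment) -> FBAProblem:
        """The explicit LP for one genotype in one environment."""
        mask = self._mask_of(genotype)
        lb, ub = self.env_bounds(env)
        for j in range(self.n_internal):
            if not (mask >> j) & 1:
                lb[j] = ub[j] = 0.0
        c = np.zeros(len(lb))
        c[self.biomass_col] = 1.0
        return FBAProblem(
            S=self.S, a=lb, b=ub, c=c, reaction_index=dict(self.reaction_index)
        )

    def _lp(self, env: Environment) -> _GlpkLP:
        key = (env.name, tuple(sorted(env.uptake_bounds.items())))
        lp = self._lp_cache.get(key)
        if lp is None:
            lb, ub = self.env_bounds(env)
            lp = _GlpkLP(self.S, lb, ub, self.biomass_col)
            self._lp_cache[key] = lp
            self._envs[env.name] = env
        return lp

    # -- core solves --------------------------------------------------------
    def _mask_of(self, genotype: Genotype | int) -> int:
        if isinstance(genotype, Genotype):
            if genotype.n != self.n_internal:
                raise ValueError("genotype length does not match universe")
            return genotype.bits
        return int(genotype)

    def _solve_mask_glpk(self, mask: int, env: Environment) -> float:
        lp = self._lp(env)
        absent = [j for j in range(self.n_internal) if not (mask >> j) & 1]
        for j in absent:
            lp.set_col_bounds(j, 0.0, 0.0)
        try:
            ok = lp.solve()
            if not ok:  # confirm: warm starts can misreport infeasibility
                lp.refresh_basis()
                ok = lp.solve()
            return lp.objective_value() if ok else 0.0
        finally:
            for j in absent:
                lp.reset_col_bounds(j)

    def _solve_mask_scipy(self, mask: int, env: Environment) -> Tuple[float, Optional[np.ndarray]]:
        from scipy.optimize import linprog

        lb, ub = self.env_bounds(env)
        for j in range(self.n_internal):
            if not (mask >> j) & 1:
                lb[j] = ub[j] = 0.0
        c = np.zeros(len(lb))
        c[self.biomass_col] = -1.0
        res = linprog(
            c, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]), method="highs",
        )
        if res.status == 3:
            raise FBAError("FBA problem unbounded; model encoding is inconsistent")
        if res.status != 0:
            return 0.0, None
        return -res.fun, res.x

    def max_biomass(self, genotype: Genotype | int, env: Environment) -> float:
        mask = self._mask_of(genotype)
        if self.backend == "glpk":
            return self._solve_mask_glpk(mask, env)
        return self._solve_mask_scipy(mask, env)[0]

    def solve_fba(self, genotype: Genotype | int, env: Environment) -> OptimalFlux:
        """Maximal biomass rate and one optimal flux vector."""
        mask = self._mask_of(genotype)
        if self.backend == "glpk":
            lp = self._lp(env)
            absent = [j for j in range(self.n_internal) if not (mask >> j) & 1]
            for j in absent:
                lp.set_col_bounds(j, 0.0, 0.0)
            try:
                ok = lp.solve()
                if not ok:
                    return OptimalFlux(0.0, {}, "infeasible")
                v = lp.col_values()
                obj = lp.objective_value()
            finally:
                for j in absent:
                    lp.reset_col_bounds(j)
        else:
            obj, v = self._solve_mask_scipy(mask, env)
            if v is None:
                return OptimalFlux(0.0, {}, "infeasible")
        fluxes = {rid: float(v[j]) for j, rid in enumerate(self.reaction_ids)}
        return OptimalFlux(float(obj), fluxes, "optimal")

    # -- viability ----------------------------------------------------------
    def viability_thresholds(
        self, environments: Mapping[str, Environment]
    ) -> ViabilityThresholds:
        full = self._full_mask
        vals = {name: 0.01 * self.max_biomass(full, env) for name, env in environments.items()}
        return ViabilityThresholds(vals)

    def is_viable(
        self,
        genotype: Genotype | int,
        env: Environment,
        thresholds: ViabilityThresholds,
    ) -> bool:
        cut = thresholds[env.name] * (1.0 + VIABILITY_GUARD)
        return self.max_biomass(genotype, env) > cut

    def viability_oracle(
        self, env: Environment, thresholds: ViabilityThresholds
    ) -> Callable[[int], bool]:
        """Fast mask -> bool closure bound to one environment (GLPK path)."""
        if self.backend != "glpk":
            return lambda mask: self.is_viable(mask, env, thresholds)
        lp = self._lp(env)
        cut = thresholds[env.name] * (1.0 + VIABILITY_GUARD)
        n = self.n_internal
        set_bounds, reset = lp.set_col_bounds, lp.reset_col_bounds
        solve, objval = lp.solve, lp.objective_value

        def viable(mask: int) -> bool:
            absent = [j for j in range(n) if not (mask >> j) & 1]
            for j in absent:
                set_bounds(j, 0.0, 0.0)
            try:
                if solve() and objval() > cut:
                    return True
                # negative verdicts are confirmed from a fresh basis: a warm
                # start can misreport infeasibility on degenerate problems
                lp.refresh_basis()
                return solve() and objval() > cut
            finally:
                for j in absent:
                    reset(j)

        return viable

    def flux_oracle(
        self, env: Environment, thresholds: ViabilityThresholds
    ) -> Callable[[int], Optional[int]]:
        """mask -> bit mask of internal reactions carrying flux in one
        optimal solution, or None if the genotype is inviable.

        The returned active-set is a viability certificate: any reaction
        outside it can be deleted without re-solving, because the same flux
        vector stays feasible.  Greedy minimization uses this to skip most
        LP calls.
        """
        if self.backend != "glpk":
            def slow(mask: int) -> Optional[int]:
                cut = thresholds[env.name] * (1.0 + VIABILITY_GUARD)
                obj, v = self._solve_mask_scipy(mask, env)
                if v is None or obj <= cut:
                    return None
                active = 0
                for j in range(self.n_internal):
                    if abs(v[j]) > ZERO_TOL:
                        active |= 1 << j
                return active

            return slow
        lp = self._lp(env)
        cut = thresholds[env.name] * (1.0 + VIABILITY_GUARD)
        n = self.n_internal
        glp = lp._glp

        def oracle(mask: int) -> Optional[int]:
            absent = [j for j in range(n) if not (mask >> j) & 1]
            for j in absent:
                lp.set_col_bounds(j, 0.0, 0.0)
            try:
                if not (lp.solve() and lp.objective_value() > cut):
                    lp.refresh_basis()
                    if not (lp.solve() and lp.objective_value() > cut):
                        return None
                active = 0
                for j in range(n):
                    if abs(glp.glp_get_col_prim(lp.lp, j + 1)) > ZERO_TOL:
                        active |= 1 << j
                return active
            finally:
                for j in absent:
                    lp.reset_col_bounds(j)

        return oracle

    def phenotype_mask(
        self,
        genotype: Genotype | int,
        environments: Mapping[str, Environment],
        thresholds: ViabilityThresholds,
    ) -> int:
        """Viability bits over ``environments`` in their iteration order."""
        mask = 0
        for i, env in enumerate(environments.values()):
            if self.is_viable(genotype, env, thresholds):
                mask |= 1 << i
        return mask

    # -- essentiality -------------------------------------------------------
    def source_essential(
        self, env: Environment, thresholds: ViabilityThresholds
    ) -> Set[str]:
        """Internal reactions whose single deletion from the full network
        abolishes viability on this source; present in every minimal network."""
        viable = self.viability_oracle(env, thresholds)
        full = self._full_mask
        return {
            self.universe.internal_ids[j]
            for j in range(self.n_internal)
            if not viable(full ^ (1 << j))
        }

    def essential_reactions(
        self,
        environments: Mapping[str, Environment],
        thresholds: ViabilityThresholds,
    ) -> Set[str]:
        """Universally essential reactions: single deletion abolishes
        viability on every listed source."""
        out: Optional[Set[str]] = None
        for env in environments.values():
            ess = self.source_essential(env, thresholds)
            out = ess if out is None else out & ess
        return out or set()

    # -- flux variability (tight gating bounds for the MILP) ----------------
    def flux_caps(self, env: Environment) -> Dict[str, Tuple[float, float]]:
        """Per-internal-reaction flux ranges of the full network, by FVA.

        A genotype's flux polytope is a restriction of the full network's,
        so these ranges bound the flux of the reaction in *every* genotype
        and serve as exact big-M values when gating bounds with binaries.
        """
        lp = self._lp(env)
        caps: Dict[str, Tuple[float, float]] = {}
        try:
            for j, rid in enumerate(self.universe.internal_ids):
                vals = []
                for maximize in (True, False):
                    lp.set_objective({j: 1.0}, maximize=maximize)
                    vals.append(lp.objective_value() if lp.solve() else 0.0)
                caps[rid] = (min(vals), max(vals))
        finally:
            lp.set_objective({self.biomass_col: 1.0}, maximize=True)
        return caps

    # -- parsimonious solution, yield and waste ------------------------------
    def pfba(self, genotype: Genotype | int, env: Environment) -> OptimalFlux:
        """Optimal flux vector of minimal total absolute flux.

        FBA optima are degenerate; the minimal-total-flux solution is the
        designated representative used for yield and waste accounting.
        """
        from scipy.optimize import linprog

        mask = self._mask_of(genotype)
        obj = self.max_biomass(mask, env)
        if obj <= 0:
            return OptimalFlux(0.0, {}, "infeasible")
        lb, ub = self.env_bounds(env)
        for j in range(self.n_internal):
            if not (mask >> j) & 1:
                lb[j] = ub[j] = 0.0
        m, n = self.S.shape
        # variables: v (n) and t (n) with t >= |v|; minimize sum t
        A_eq = np.hstack([self.S, np.zeros((m, n))])
        A_ub = np.vstack(
            [
                np.hstack([np.eye(n), -np.eye(n)]),   # v - t <= 0
                np.hstack([-np.eye(n), -np.eye(n)]),  # -v - t <= 0
            ]
        )
        lb_full = np.concatenate([lb, np.zeros(n)])
        ub_full = np.concatenate([ub, np.full(n, np.inf)])
        lb_full[self.biomass_col] = obj * (1.0 - 1e-9)  # hold the optimum
        c = np.concatenate([np.zeros(n), np.ones(n)])
        res = linprog(
            c, A_eq=A_eq, b_eq=np.zeros(m), A_ub=A_ub, b_ub=np.zeros(2 * n),
            bounds=np.column_stack([lb_full, ub_full]), method="highs",
        )
        if res.status != 0:
            raise FBAError(f"pFBA solve failed (status {res.status})")
        v = res.x[:n]
        fluxes = {rid: float(v[j]) for j, rid in enumerate(self.reaction_ids)}
        return OptimalFlux(float(v[self.biomass_col]), fluxes, "optimal")

    def yield_per_carbon(self, genotype: Genotype | int, env: Environment) -> float:
        """Biomass rate per mole of carbon taken up; invariant to rescaling
        of the uptake bound (LP homogeneity)."""
        sol = self.pfba(genotype, env)
        if sol.status != "optimal":
            raise InviableGenotypeError(f"genotype not viable on {env.name}")
        met = self.universe.metabolite_index[env.carbon_source]
        if met.carbon_atoms <= 0:
            raise FBAError(f"carbon source {met.id} has no carbon atoms recorded")
        ex = self.universe.exchange_by_metabolite[env.carbon_source]
        uptake = -sol.fluxes[ex.id]
        if uptake <= ZERO_TOL:
            raise FBAError("optimal solution takes up no carbon source")
        return sol.objective / (uptake * met.carbon_atoms)

    def count_waste_metabolites(self, genotype: Genotype | int, env: Environment) -> int:
        """Number of excreted carbon-containing molecules that are not
        biomass precursors, in the parsimonious optimal solution."""
        sol = self.pfba(genotype, env)
        if sol.status != "optimal":
            raise InviableGenotypeError(f"genotype not viable on {env.name}")
        precursor_bases = {_base(m) for m in self.universe.biomass_precursors}
        count = 0
        for met_id, ex in self.universe.exchange_by_metabolite.items():
            if sol.fluxes[ex.id] > ZERO_TOL:
                met = self.universe.metabolite_index[met_id]
                if met.carbon_atoms > 0 and _base(met_id) not in precursor_bases:
                    count += 1
        return count


def _base(met_id: str) -> str:
    """Strip the compartment suffix so e.g. pyr_c and pyr_e are one molecule."""
    return met_id[:-2] if met_id.endswith(("_c", "_e")) else met_id


# ---------------------------------------------------------------------------
# disconnected reactions (purely structural)
# ---------------------------------------------------------------------------

def disconnected_reactions(
    universe: ReactionUniverse,
    genotype: Genotype | int,
    env: Optional[Environment] = None,
) -> Set[str]:
    """Internal reactions of the genotype that are disconnected.

    A reaction is disconnected if, in every orientation it can run,
    (i) none of its products is a biomass precursor or a substrate of any
    other reaction of the metabolism, or (ii) at least one of its substrates
    is neither a product of another reaction nor a nutrient.  Reversible
    reactions contribute both orientations wherever substrate/product roles
    matter.  With no environment given, every external metabolite with an
    exchange reaction counts as a potential nutrient.
    """
    mask = genotype.bits if isinstance(genotype, Genotype) else int(genotype)
    present = [
        r for i, r in enumerate(universe.internal_reactions) if (mask >> i) & 1
    ]
    always_on = list(universe.transport_reactions) + [universe.biomass_reaction]
    if env is not None:
        nutrients = {m for m, b in env.uptake_bounds.items() if b > 0}
    else:
        nutrients = set(universe.exchange_by_metabolite)

    def orientations(r) -> List[Tuple[Set[str], Set[str]]]:
        subs, prods = set(r.substrates()), set(r.products())
        return [(subs, prods), (prods, subs)] if r.reversible else [(subs, prods)]

    precursors = set(universe.biomass_precursors)
    out: Set[str] = set()
    for r in present:
        consumable: Set[str] = set()
        producible: Set[str] = set(nutrients)
        for other in present + always_on:
            if other.id == r.id:
                continue
            for s, p in orientations(other):
                consumable |= s
                producible |= p
        connected = False
        for subs, prods in orientations(r):
            crit_i = not any(p in precursors or p in consumable for p in prods)
            crit_ii = any(s not in producible for s in subs)
            if not crit_i and not crit_ii:
                connected = True
                break
        if not connected:
            out.add(r.id)
    return out
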