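"""Exhaustive enumeration of inclusion-minimal viable networks.

A minimal metabolism for a carbon source is a genotype viable on that source
from which no single reaction can be removed without losing viability.  By
monotonicity of FBA viability, the full viable set is exactly the union of
the supersets of these minimal networks, so a complete minimal-network list
is the compressed representation of the whole genotype-phenotype map that
the counting module consumes.

The enumeration is MILP-driven: a mixed-integer program couples binary
presence variables to flux bounds (``a_i x_i <= v_i <= b_i x_i``, with
``a_i, b_i`` tightened to the exact flux ranges of the full network) and
requires biomass above the viability threshold.  Blocking cuts exclude the
up-set of every minimal network already found; each feasible solution is
re-verified by LP and greedily minimized; the loop ends when the MILP is
infeasible, which certifies completeness.  Two safeguards address MILP
tolerance artifacts: per-reaction flux caps keep the gating tight, and any
candidate whose LP verification fails is excluded by a no-good cut on its
exact assignment (such an assignment is not viable, so removing it cannot
lose a solution).

Presence variables of reactions that are individually essential on the
focal source are fixed to one, and "survivor pairs" (pairs of reactions
whose joint removal from the full network abolishes viability while neither
single removal does) are added as valid covering inequalities; both are
implied constraints that only tighten the search.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import FBASolver, ViabilityThresholds, VIABILITY_GUARD
from .model_io import Environment, Genotype, ReactionUniverse

__all__ = [
    "MinimalNetworkSet",
    "greedy_minimize",
    "enumerate_minimal",
    "minimum_size",
    "verify_complete",
    "is_antichain",
]


@dataclass
class MinimalNetworkSet:
    """All inclusion-minimal viable genotypes for one carbon source."""

    carbon_source: str
    networks: List[Genotype]
    complete: bool

    def masks(self) -> List[int]:
        return [g.bits for g in self.networks]

    def sizes(self) -> List[int]:
        return sorted(g.size for g in self.networks)

    def __len__(self) -> int:
        return len(self.networks)


def is_antichain(masks: Sequence[int]) -> bool:
    """No mask contains another (every pair incomparable)."""
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            if a & b in (a, b):
                return False
    return True


def greedy_minimize(
    solver: FBASolver,
    genotype: Genotype | int,
    env: Environment,
    thresholds: ViabilityThresholds,
    order_seed: int = 0,
    _flux_oracle: Optional[Callable[[int], Optional[int]]] = None,
    _skip: int = 0,
) -> Genotype:
    """Delete reactions one at a time (fixed order) while viability holds.

    The result is a subset of the input that is viable and inclusion-minimal.
    ``order_seed=0`` scans in universe order; any other seed shuffles the
    scan order reproducibly.  ``_skip`` is a bit mask of reactions known to
    be essential (skipping their deletion test is a pure optimization).

    A flux certificate cuts the LP count: a reaction with zero flux in the
    current optimal solution can be deleted outright, because that solution
    remains feasible for the smaller genotype.
    """
    n = solver.n_internal
    mask = genotype.bits if isinstance(genotype, Genotype) else int(genotype)
    oracle = _flux_oracle or solver.flux_oracle(env, thresholds)
    active = oracle(mask)
    if active is None:
        raise ValueError(f"input genotype is not viable on {env.name}")
    order = list(range(n))
    if order_seed:
        random.Random(order_seed).shuffle(order)
    for j in order:
        bit = 1 << j
        if not mask & bit or _skip & bit:
            continue
        if not active & bit:  # zero flux: certificate stays feasible
            mask ^= bit
            continue
        trial = oracle(mask ^ bit)
        if trial is not None:
            mask ^= bit
            active = trial
    return Genotype(mask, n)


class _GatedMILP:
    """The gated-flux MILP shared by enumeration and minimum-size search.

    Variables: fluxes v (all reactions) then binaries x (internal reactions).
    Constraints: S v = 0; a_i x_i <= v_i <= b_i x_i for internal i (with
    a_i, b_i from full-network FVA); biomass >= threshold; survivor-pair
    covers; optional blocking / no-good cuts supplied per solve.
    """

    def __init__(
        self,
        solver: FBASolver,
        env: Environment,
        thresholds: ViabilityThresholds,
        use_pair_cuts: bool = True,
    ):
        self.solver = solver
        self.env = env
        self.n = solver.n_internal
        self.nR = len(solver.reaction_ids)
        viable = solver.viability_oracle(env, thresholds)
        self.viable = viable
        full = (1 << self.n) - 1
        self.essential_mask = 0
        for j in range(self.n):
            if not viable(full ^ (1 << j)):
                self.essential_mask |= 1 << j
        free = [j for j in range(self.n) if not (self.essential_mask >> j) & 1]
        pairs: List[Tuple[int, int]] = []
        if use_pair_cuts:
            for ai in range(len(free)):
                for bi in range(ai + 1, len(free)):
                    a, b = free[ai], free[bi]
                    if not viable(full ^ (1 << a) ^ (1 << b)):
                        pairs.append((a, b))
        self.pairs = pairs

        caps = solver.flux_caps(env)
        lb, ub = solver.env_bounds(env)
        nR, n = self.nR, self.n
        m = solver.S.shape[0]
        A_eq = sp.hstack([sp.csr_matrix(solver.S), sp.csr_matrix((m, n))]).tocsr()
        nrow = 2 * n + 1 + len(pairs)
        rows = sp.lil_matrix((nrow, nR + n))
        lo = np.zeros(nrow)
        hi = np.zeros(nrow)
        for k, rid in enumerate(solver.universe.internal_ids):
            j = solver.reaction_index[rid]
            glo = min(caps[rid][0], 0.0)
            ghi = max(caps[rid][1], 0.0)
            rows[k, j] = 1.0
            rows[k, nR + k] = -glo
            lo[k], hi[k] = 0.0, np.inf          # v - a x >= 0
            rows[n + k, j] = 1.0
            rows[n + k, nR + k] = -ghi
            lo[n + k], hi[n + k] = -np.inf, 0.0  # v - b x <= 0
        rows[2 * n, solver.biomass_col] = 1.0
        lo[2 * n] = thresholds[env.name] * (1.0 + VIABILITY_GUARD)
        hi[2 * n] = np.inf
        for t, (a, b) in enumerate(pairs):
            rows[2 * n + 1 + t, nR + a] = 1.0
            rows[2 * n + 1 + t, nR + b] = 1.0
            lo[2 * n + 1 + t], hi[2 * n + 1 + t] = 1.0, np.inf
        self.base = [LinearConstraint(A_eq, 0.0, 0.0), LinearConstraint(rows.tocsr(), lo, hi)]
        lbv = np.concatenate([lb, np.zeros(n)])
        ubv = np.concatenate([ub, np.ones(n)])
        for j in range(n):
            if (self.essential_mask >> j) & 1:
                lbv[nR + j] = 1.0
        self.bounds = Bounds(lbv, ubv)
        self.integrality = np.concatenate([np.zeros(nR), np.ones(n)])
        self.extra: List[LinearConstraint] = []  # no-good cuts, persistent

    def blocking_cut(self, mask: int) -> Tuple[sp.csr_matrix, float]:
        """Exclude all supersets of ``mask``: sum of its free bits <= k-1."""
        row = sp.lil_matrix((1, self.nR + self.n))
        k = 0
        for j in range(self.n):
            if (mask >> j) & 1 and not (self.essential_mask >> j) & 1:
                row[0, self.nR + j] = 1.0
                k += 1
        return row.tocsr(), float(k - 1)

    def no_good_cut(self, mask: int) -> LinearConstraint:
        """Exclude exactly the assignment ``mask`` (used for candidates whose
        LP verification failed; such an assignment is not viable)."""
        row = sp.lil_matrix((1, self.nR + self.n))
        rhs = 1.0
        for j in range(self.n):
            if (mask >> j) & 1:
                row[0, self.nR + j] = -1.0
                rhs -= 1.0
            else:
                row[0, self.nR + j] = 1.0
        return LinearConstraint(row.tocsr(), rhs, np.inf)

    def solve(
        self,
        cuts: Tuple[List[sp.csr_matrix], List[float]],
        objective: Optional[np.ndarray] = None,
        extra_constraints: Sequence[LinearConstraint] = (),
    ) -> Tuple[int, Optional[int], float]:
        """Returns (status, presence mask, objective). status 0 = solution,
        2 = infeasible (the completeness certificate)."""
        cons = list(self.base) + self.extra + list(extra_constraints)
        rows, rhs = cuts
        if rows:
            cons.append(
                LinearConstraint(sp.vstack(rows).tocsr(), -np.inf, np.array(rhs))
            )
        obj = objective if objective is not None else np.zeros(self.nR + self.n)
        res = milp(obj, constraints=cons, integrality=self.integrality, bounds=self.bounds)
        if res.status == 2:
            return 2, None, 0.0
        if res.status != 0:
            raise RuntimeError(f"MILP solver failure: status {res.status} ({res.message})")
        x = res.x[self.nR:]
        mask = 0
        for j in range(self.n):
            if x[j] > 0.5:
                mask |= 1 << j
        leak = mask
        for j in range(self.n):
            if x[j] > 1e-7:
                leak |= 1 << j
        self._last_leak = leak
        return 0, mask, float(res.fun)


def enumerate_minimal(
    solver: FBASolver,
    env: Environment,
    thresholds: ViabilityThresholds,
    order_seed: int = 0,
    progress: Optional[Callable[[int, float], None]] = None,
    discovery_budget: int = 4000,
    discovery_patience: int = 150,
) -> MinimalNetworkSet:
    """All inclusion-minimal viable networks for one carbon source.

    Two phases.  Discovery: repeated greedy minimizations of the full
    network under random deletion orders collect minimal networks cheaply
    (each run costs a handful of warm LP solves thanks to the flux
    certificate); the phase stops after ``discovery_patience`` consecutive
    rediscoveries or ``discovery_budget`` runs.  Completion: the gated MILP
    under blocking cuts finds every region the random phase missed and its
    final infeasibility certifies completeness (``complete=True``).  The
    result is the same set in either phase split; discovery only trades
    MILP iterations for LP sweeps.
    """
    prob = _GatedMILP(solver, env, thresholds)
    oracle = solver.flux_oracle(env, thresholds)
    found: List[int] = []
    seen = set()
    cut_rows: List[sp.csr_matrix] = []
    cut_rhs: List[float] = []
    t0 = time.time()

    def record(mask: int) -> bool:
        if mask in seen:
            return False
        seen.add(mask)
        found.append(mask)
        row, rhs = prob.blocking_cut(mask)
        cut_rows.append(row)
        cut_rhs.append(rhs)
        if progress and len(found) % 50 == 0:
            progress(len(found), time.time() - t0)
        return True

    full = (1 << solver.n_internal) - 1
    rng = random.Random(order_seed + 1)
    misses = 0
    for _ in range(discovery_budget):
        if misses >= discovery_patience:
            break
        g = greedy_minimize(
            solver, full, env, thresholds, order_seed=rng.randrange(1, 2**30),
            _flux_oracle=oracle, _skip=prob.essential_mask,
        )
        misses = 0 if record(g.bits) else misses + 1

    while True:
        status, mask, _ = prob.solve((cut_rows, cut_rhs))
        if status == 2:
            break
        if prob.viable(mask):
            g = greedy_minimize(
                solver, mask, env, thresholds, order_seed,
                _flux_oracle=oracle, _skip=prob.essential_mask,
            )
            if not record(g.bits):
                raise RuntimeError("duplicate minimal network; blocking cuts inconsistent")
        else:
            # MILP tolerance artifact: try promoting fractionally-on binaries
            leak = prob._last_leak
            handled = False
            if leak != mask and prob.viable(leak):
                g = greedy_minimize(
                    solver, leak, env, thresholds, order_seed,
                    _flux_oracle=oracle, _skip=prob.essential_mask,
                )
                handled = record(g.bits)
            if not handled:
                prob.extra.append(prob.no_good_cut(mask))
    n = solver.n_internal
    return MinimalNetworkSet(
        carbon_source=env.name,
        networks=[Genotype(m, n) for m in found],
        complete=True,
    )


def minimum_size(
    solver: FBASolver,
    env: Environment,
    thresholds: ViabilityThresholds,
) -> Tuple[int, List[Genotype]]:
    """Smallest viable genotype size on a source, with all genotypes of that
    size (found by cardinality-minimizing MILP, then integer cuts)."""
    prob = _GatedMILP(solver, env, thresholds)
    obj = np.zeros(prob.nR + prob.n)
    obj[prob.nR:] = 1.0
    cut_rows: List[sp.csr_matrix] = []
    cut_rhs: List[float] = []
    best: Optional[int] = None
    nets: List[int] = []
    while True:
        extra: List[LinearConstraint] = []
        if best is not None:
            row = sp.lil_matrix((1, prob.nR + prob.n))
            for j in range(prob.n):
                row[0, prob.nR + j] = 1.0
            extra.append(LinearConstraint(row.tocsr(), -np.inf, float(best)))
        status, mask, val = prob.solve((cut_rows, cut_rhs), objective=obj, extra_constraints=extra)
        if status == 2:
            break
        if not prob.viable(mask):
            prob.extra.append(prob.no_good_cut(mask))
            continue
        size = mask.bit_count()
        if best is None:
            best = size
            if size != round(val):
                # guard against fractional objective noise
                best = min(best, int(round(val)))
        if size > best:
            break
        nets.append(mask)
        row, rhs = prob.blocking_cut(mask)
        cut_rows.append(row)
        cut_rhs.append(rhs)
    if best is None:
        raise RuntimeError(f"no viable genotype on {env.name}")
    n = solver.n_internal
    return best, [Genotype(m, n) for m in nets if m.bit_count() == best]


def verify_complete(
    solver: FBASolver,
    mns: MinimalNetworkSet,
    env: Environment,
    thresholds: ViabilityThresholds,
    n_random: int = 1000,
    seed: int = 0,
) -> bool:
    """Randomized completeness certificate.

    Draws random viable genotypes (random supersets of random minimal
    networks, and greedy-minimized random viable draws) and checks that each
    contains at least one enumerated minimal network; also checks the
    antichain property.
    """
    masks = mns.masks()
    if not is_antichain(masks):
        return False
    rng = random.Random(seed)
    n = solver.n_internal
    full = (1 << n) - 1
    viable = solver.viability_oracle(env, thresholds)

    def contains_some(g: int) -> bool:
        return any(g & m == m for m in masks)

    for _ in range(n_random // 2):
        base = rng.choice(masks)
        extra = rng.getrandbits(n)
        if not contains_some(base | extra):
            return False
    for _ in range(n_random - n_random // 2):
        g = full
        # random deletions while viability holds: a random viable genotype
        order = list(range(n))
        rng.shuffle(order)
        for j in order:
            if g & (1 << j) and viable(g ^ (1 << j)) and rng.random() < 0.8:
                g ^= 1 << j
        if not (viable(g) and contains_some(g)):
            return False
    return True
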