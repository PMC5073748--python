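"""Small synthetic reaction universes with brute-force ground truth.

The generator emulates the structure that makes the central-carbon study
tractable — linear and branched pathways from one or more carbon sources to
a biomass precursor, with optional shared segments and forced byproducts —
at sizes (N <= 16 internal reactions) where all 2^N genotypes can be
evaluated by FBA directly.  Every stage of the pipeline (viability oracle,
minimal-network enumeration, lattice counting, exaptation statistics) is
validated against :func:`brute_force_map` on these universes.

The brute-force oracle evaluates each genotype with an independent,
stateless LP (scipy/HiGHS by default, a different code path and solver
than the warm-started GLPK problems used by the pipeline), with no
monotonicity shortcuts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .fba import FBASolver, ViabilityThresholds
from .model_io import Environment, Genotype, Metabolite, Reaction, ReactionUniverse

__all__ = ["ToySpec", "make_toy_universe", "brute_force_map", "monotone_violations"]

_MAX_BRUTE_N = 16


@dataclass(frozen=True)
class ToySpec:
    """Specification of a synthetic universe; generation is a pure function
    of the spec (identical specs give identical universes)."""

    n_internal: int
    n_pathways: int
    pathway_lengths: Tuple[int, ...]
    n_carbon_sources: int = 1
    byproduct_rate: float = 0.0
    share_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_internal > _MAX_BRUTE_N:
            raise ValueError(f"toy universes are capped at {_MAX_BRUTE_N} internal reactions")
        if self.n_pathways < 1 or self.n_carbon_sources < 1:
            raise ValueError("at least one pathway and one carbon source required")
        if self.n_pathways < self.n_carbon_sources:
            raise ValueError("every carbon source needs at least one pathway")
        if len(self.pathway_lengths) != self.n_pathways:
            raise ValueError("pathway_lengths must list one length per pathway")
        if any(l < 1 for l in self.pathway_lengths):
            raise ValueError("pathway lengths must be positive")
        if sum(self.pathway_lengths) != self.n_internal:
            raise ValueError("pathway lengths must sum to n_internal")


def make_toy_universe(spec: ToySpec) -> Tuple[ReactionUniverse, Dict[str, Environment]]:
    """Build a toy universe of pathways from carbon sources to one biomass
    precursor.

    Pathway 0 of each carbon source ends at the precursor (or joins an
    earlier pathway); surplus pathways either run in parallel from their
    source or branch off a shared intermediate, creating multiple minimal
    networks.  Byproduct-forced reactions co-produce a non-precursor
    metabolite with its own excretion route.  Carbon sources carry 1-3
    carbon atoms so yield-per-carbon normalization is exercised.
    """
    rng = random.Random(spec.seed)
    mets: Dict[str, Metabolite] = {}
    internal: List[Reaction] = []
    transport: List[Reaction] = []
    exchange: List[Reaction] = []

    def add_met(mid: str, external: bool, precursor: bool = False, carbon: int = 1) -> None:
        if mid not in mets:
            mets[mid] = Metabolite(
                id=mid, name=mid, external=external,
                is_biomass_precursor=precursor, carbon_atoms=carbon,
            )

    add_met("bm_c", external=False, precursor=True)
    sources = [f"src{i}" for i in range(spec.n_carbon_sources)]
    for s in sources:
        nc = rng.randint(1, 3)
        add_met(f"{s}_e", external=True, carbon=nc)
        add_met(f"{s}_c", external=False, carbon=nc)
        transport.append(
            Reaction(
                id=f"T_{s}", stoichiometry={f"{s}_e": -1.0, f"{s}_c": 1.0},
                lower_bound=0.0, upper_bound=1000.0, kind="transport",
            )
        )
        exchange.append(
            Reaction(
                id=f"EX_{s}_e", stoichiometry={f"{s}_e": -1.0},
                lower_bound=0.0, upper_bound=1000.0, kind="exchange",
            )
        )

    # assign pathways to sources: one "primary" per source, surplus random
    owners = list(range(spec.n_carbon_sources))
    for _ in range(spec.n_pathways - spec.n_carbon_sources):
        owners.append(rng.randrange(spec.n_carbon_sources))
    intermediates: Dict[int, List[str]] = {i: [] for i in range(spec.n_carbon_sources)}
    n_mid = 0
    n_by = 0
    rxn_counter = 0
    for p, (owner, length) in enumerate(zip(owners, spec.pathway_lengths)):
        src = sources[owner]
        primary = p == owners.index(owner)
        if primary:
            start = f"{src}_c"
        else:
            pool = [f"{src}_c"] + intermediates[owner]
            start = rng.choice(pool) if rng.random() < spec.share_prob else f"{src}_c"
        if primary and p == 0:
            end = "bm_c"
        elif primary:
            # join any earlier metabolite that already flows to biomass
            pool = ["bm_c"] + [x for lst in intermediates.values() for x in lst]
            end = rng.choice(pool)
        else:
            end = "bm_c"
        chain = [start]
        for _ in range(length - 1):
            n_mid += 1
            mid = f"m{n_mid}_c"
            add_met(mid, external=False)
            chain.append(mid)
        chain.append(end)
        for a, b in zip(chain, chain[1:]):
            rxn_counter += 1
            st = {a: -1.0, b: 1.0}
            if rng.random() < spec.byproduct_rate:
                n_by += 1
                w = f"w{n_by}"
                add_met(f"{w}_c", external=False)
                add_met(f"{w}_e", external=True)
                st[f"{w}_c"] = 1.0
                transport.append(
                    Reaction(
                        id=f"T_{w}", stoichiometry={f"{w}_c": -1.0, f"{w}_e": 1.0},
                        lower_bound=0.0, upper_bound=1000.0, kind="transport",
                    )
                )
                exchange.append(
                    Reaction(
                        id=f"EX_{w}_e", stoichiometry={f"{w}_e": -1.0},
                        lower_bound=0.0, upper_bound=1000.0, kind="exchange",
                    )
                )
            internal.append(
                Reaction(
                    id=f"R{rxn_counter}", stoichiometry=st,
                    lower_bound=0.0, upper_bound=1000.0, kind="internal",
                )
            )
            if b != "bm_c":
                intermediates[owner].append(b)

    biomass = Reaction(
        id="Biomass", stoichiometry={"bm_c": -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="biomass",
    )
    universe = ReactionUniverse(
        internal_reactions=internal,
        transport_reactions=transport,
        exchange_reactions=exchange,
        biomass_reaction=biomass,
        metabolites=list(mets.values()),
    )
    envs: Dict[str, Environment] = {}
    for s in sources:
        envs[s] = Environment(
            name=s, carbon_source=f"{s}_e", fixed_nutrients=(),
            uptake_bounds={f"{s}_e": 10.0},
        )
    return universe, envs


def brute_force_map(
    universe: ReactionUniverse,
    environments: Mapping[str, Environment],
    backend: str = "scipy",
) -> pd.DataFrame:
    """Exhaustive genotype-phenotype table over all 2^N genotypes.

    Each genotype is evaluated by a fresh FBA solve per carbon source with
    no pruning or counting shortcuts.  Columns: ``bits`` (bitstring),
    ``size``, ``viable_<source>`` and ``minimal_<source>`` flags.
    """
    n = universe.n_internal
    if n > _MAX_BRUTE_N:
        raise ValueError(f"brute force is limited to N <= {_MAX_BRUTE_N} (got {n})")
    solver = FBASolver(universe, backend=backend)
    thresholds = solver.viability_thresholds(environments)
    names = list(environments)
    viable: Dict[str, List[bool]] = {}
    for name in names:
        env = environments[name]
        cut = thresholds[name]
        viable[name] = [
            solver.max_biomass(mask, env) > cut * (1.0 + 1e-6)
            for mask in range(1 << n)
        ]
    rows = []
    for mask in range(1 << n):
        row: Dict[str, object] = {
            "bits": format(mask, f"0{n}b")[::-1],
            "size": mask.bit_count(),
        }
        for name in names:
            v = viable[name][mask]
            row[f"viable_{name}"] = v
            minimal = v and all(
                not viable[name][mask ^ (1 << j)] for j in range(n) if (mask >> j) & 1
            )
            row[f"minimal_{name}"] = minimal
        rows.append(row)
    return pd.DataFrame(rows)


def monotone_violations(viable: Sequence[bool], n: int) -> List[Tuple[int, int]]:
    """Pairs (g, g + one reaction) where viability is lost by addition.

    Checking single-reaction additions over the whole lattice is exhaustive:
    monotonicity along edges implies monotonicity for all subset pairs.
    """
    bad = []
    for mask in range(1 << n):
        if viable[mask]:
            continue
        for j in range(n):
            if not (mask >> j) & 1:
                continue
            if viable[mask ^ (1 << j)]:
                bad.append((mask ^ (1 << j), mask))
    return bad
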