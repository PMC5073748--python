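"""Exaptation and preadaptation statistics over the genotype-phenotype map.

A metabolism viable on a focal carbon source C may also be viable on other
sources C_new it has never been selected on — the raw material of
exaptation.  Given the exact joint phenotype counts from
:mod:`exaptmap.lattice_count`, this module computes:

* the exaptation index ``I`` (number of non-focal sources a genotype is
  viable on) and its distribution, overall and by genotype size;
* the preadaptation matrix ``P(C_new | C)``, generally asymmetric;
* Hamming distances between 9-bit phenotype vectors and their pair-weighted
  distributions within a size class;
* UPGMA clustering of carbon sources by symmetrized preadaptation
  propensity, with Newick output;
* addition curves: how exaptation grows as tuples of non-essential
  reactions are added to each minimal network;
* biomass yield per carbon and waste-excretion summaries by exaptation
  index, from explicit enumeration of a size class or uniform sampling
  when the class is too large.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .fba import FBASolver, ViabilityThresholds
from .lattice_count import BDD, CountTable
from .minimal_enum import MinimalNetworkSet
from .model_io import Environment, Genotype

__all__ = [
    "PhenotypeVector",
    "PreadaptationMatrix",
    "AdditionCurve",
    "exaptation_index",
    "phenotype_vector",
    "fraction_exapted",
    "mean_index",
    "preadaptation_matrix",
    "phenotype_distance",
    "distance_distribution",
    "upgma_tree",
    "UPGMANode",
    "addition_curves",
    "minimal_set_phenotypes",
    "yield_waste_summary",
    "EmptyClassError",
]


class EmptyClassError(ValueError):
    """Requested statistic over an empty genotype class (e.g. size below the
    minimum viable size for the focal source)."""


@dataclass(frozen=True)
class PhenotypeVector:
    """Viability bits over the non-focal sources, in canonical source order
    with the focal source removed."""

    bits: int
    focal_source: str
    length: int = 9

    def __post_init__(self) -> None:
        if self.bits >> self.length:
            raise ValueError("phenotype bits exceed declared length")


def exaptation_index(phenotype: PhenotypeVector | int) -> int:
    """Number of non-focal sources the genotype is viable on (popcount)."""
    bits = phenotype.bits if isinstance(phenotype, PhenotypeVector) else phenotype
    return bits.bit_count()


def phenotype_vector(pmask: int, focal: str, sources: Sequence[str]) -> PhenotypeVector:
    """Conditioned phenotype vector: drop the focal bit from a joint mask."""
    fi = list(sources).index(focal)
    if not (pmask >> fi) & 1:
        raise ValueError("genotype is not viable on the focal source")
    low = pmask & ((1 << fi) - 1)
    high = pmask >> (fi + 1)
    return PhenotypeVector(low | (high << fi), focal, len(sources) - 1)


def phenotype_distance(p1: PhenotypeVector, p2: PhenotypeVector) -> int:
    """Hamming distance between two phenotype vectors with the same focal."""
    if p1.focal_source != p2.focal_source or p1.length != p2.length:
        raise ValueError("phenotype vectors are not comparable")
    return (p1.bits ^ p2.bits).bit_count()


# ---------------------------------------------------------------------------
# statistics from exact counts
# ---------------------------------------------------------------------------

def _focal_classes(counts: CountTable, focal: str, size: Optional[int]) -> Dict[int, int]:
    cls = counts.class_counts(focal, size)
    if not cls:
        where = f"size {size}" if size is not None else "any size"
        raise EmptyClassError(f"no genotypes viable on {focal} at {where}")
    return cls


def fraction_exapted(counts: CountTable, focal: str, size: Optional[int] = None) -> float:
    """Fraction of genotypes viable on ``focal`` that are viable on at least
    one other source (exaptation index I > 0)."""
    cls = _focal_classes(counts, focal, size)
    fi = counts.source_bit(focal)
    total = sum(cls.values())
    only = sum(c for p, c in cls.items() if p == (1 << fi))
    return float(Fraction(total - only, total))


def mean_index(counts: CountTable, focal: str, size: Optional[int] = None) -> float:
    """Count-weighted mean exaptation index among genotypes viable on
    ``focal``; equals the off-diagonal row sum of the preadaptation matrix."""
    cls = _focal_classes(counts, focal, size)
    total = sum(cls.values())
    weighted = sum((p.bit_count() - 1) * c for p, c in cls.items())
    return float(Fraction(weighted, total))


@dataclass
class PreadaptationMatrix:
    """P(viable on C_new | viable on C); rows = focal C, columns = C_new."""

    sources: List[str]
    values: List[List[float]]

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        focal, new = pair
        return self.values[self.sources.index(focal)][self.sources.index(new)]

    def row_sum_off_diagonal(self, focal: str) -> float:
        i = self.sources.index(focal)
        return sum(v for j, v in enumerate(self.values[i]) if j != i)

    def to_rows(self) -> List[Tuple[str, str, float]]:
        return [
            (cf, cn, self.values[i][j])
            for i, cf in enumerate(self.sources)
            for j, cn in enumerate(self.sources)
        ]


def preadaptation_matrix(counts: CountTable) -> PreadaptationMatrix:
    ns = len(counts.sources)
    totals = [0] * ns
    joint = [[0] * ns for _ in range(ns)]
    for pmask, arr in counts.counts.items():
        c = sum(arr)
        for i in range(ns):
            if (pmask >> i) & 1:
                totals[i] += c
                for j in range(ns):
                    if (pmask >> j) & 1:
                        joint[i][j] += c
    values = [
        [float(Fraction(joint[i][j], totals[i])) if totals[i] else 0.0 for j in range(ns)]
        for i in range(ns)
    ]
    return PreadaptationMatrix(sources=list(counts.sources), values=values)


def distance_distribution(
    counts: CountTable, focal: str, size: int
) -> Tuple[List[int], List[float]]:
    """Distribution of pairwise phenotype distances among genotypes of one
    size viable on ``focal``.

    Pair counts are combinatorial over phenotype classes: classes with
    counts k_u, k_v contribute k_u * k_v pairs at their Hamming distance
    (k_u choose 2 at distance zero within a class).  Returns (exact pair
    counts per distance 0..L, fractions).
    """
    cls = _focal_classes(counts, focal, size)
    fi = counts.source_bit(focal)
    items = [
        (phenotype_vector(p, focal, counts.sources).bits, c) for p, c in cls.items()
    ]
    length = len(counts.sources) - 1
    pair_counts = [0] * (length + 1)
    for i, (u, ku) in enumerate(items):
        pair_counts[0] += ku * (ku - 1) // 2
        for v, kv in items[i + 1:]:
            pair_counts[(u ^ v).bit_count()] += ku * kv
    total = sum(pair_counts)
    if total == 0:
        raise EmptyClassError(f"fewer than two genotypes viable on {focal} at size {size}")
    fractions = [float(Fraction(c, total)) for c in pair_counts]
    return pair_counts, fractions


# ---------------------------------------------------------------------------
# UPGMA clustering of carbon sources
# ---------------------------------------------------------------------------

@dataclass
class UPGMANode:
    """Rooted ultrametric tree node; leaves carry a carbon source name."""

    name: Optional[str] = None
    children: Tuple["UPGMANode", ...] = ()
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.name]
        return [x for ch in self.children for x in ch.leaves()]

    def newick(self) -> str:
        return self._newick_inner(None) + ";"

    def _newick_inner(self, parent_height: Optional[float]) -> str:
        if self.is_leaf:
            body = self.name
        else:
            body = "(" + ",".join(ch._newick_inner(self.height) for ch in self.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.6g}"

    def sibling_sets(self) -> List[frozenset]:
        """Leaf sets of every internal node (clusters of the hierarchy)."""
        if self.is_leaf:
            return []
        out = [frozenset(self.leaves())]
        for ch in self.children:
            out.extend(ch.sibling_sets())
        return out


def upgma_tree(matrix: PreadaptationMatrix) -> UPGMANode:
    """UPGMA dendrogram of carbon sources.

    The distance is one minus the symmetrized preadaptation propensity,
    d(C, C') = 1 - (P(C'|C) + P(C|C')) / 2.  Among equally distant cluster
    pairs the lexicographically first pair (by sorted leaf names) merges
    first, making the tree deterministic.
    """
    names = matrix.sources
    dist: Dict[frozenset, float] = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            d = 1.0 - 0.5 * (matrix.values[i][j] + matrix.values[j][i])
            dist[frozenset((a, b))] = d
    clusters: Dict[str, UPGMANode] = {n: UPGMANode(name=n) for n in names}
    sizes: Dict[str, int] = {n: 1 for n in names}
    cdist: Dict[Tuple[str, str], float] = {}
    keys = sorted(clusters)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            cdist[(a, b)] = dist[frozenset((a, b))]

    def pair_key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a < b else (b, a)

    while len(clusters) > 1:
        (a, b), d = min(cdist.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = clusters.pop(a), clusters.pop(b)
        sizes.pop(a), sizes.pop(b)
        new_key = min(a, b)
        node = UPGMANode(children=(na, nb), height=d / 2.0)
        for k in [k for k in cdist if a in k or b in k]:
            del cdist[k]
        clusters[new_key] = node
        sizes[new_key] = len(node.leaves())
        # distance from the merged cluster to every other one is the plain
        # arithmetic mean over member leaf pairs (the "unweighted" in UPGMA)
        for other, onode in clusters.items():
            if other == new_key:
                continue
            total = 0.0
            for x in node.leaves():
                for y in onode.leaves():
                    total += dist[frozenset((x, y))]
            cdist[pair_key(new_key, other)] = total / (len(node.leaves()) * len(onode.leaves()))
    return next(iter(clusters.values()))


# ---------------------------------------------------------------------------
# minimal networks: phenotypes and addition curves
# ---------------------------------------------------------------------------

def minimal_set_phenotypes(
    mns: MinimalNetworkSet,
    minimal_sets: Mapping[str, MinimalNetworkSet],
    n_reactions: int,
    bdd: Optional[BDD] = None,
) -> List[Tuple[Genotype, int]]:
    """Exaptation index of every minimal network of the focal source.

    By monotonicity, a genotype is viable on source s iff it contains one of
    s's minimal networks, so the index is read off the enumerated sets
    without further FBA.
    """
    bdd = bdd or BDD(n_reactions)
    roots = {
        s: bdd.from_upsets(ms.masks()) for s, ms in minimal_sets.items() if s != mns.carbon_source
    }
    out = []
    for g in mns.networks:
        idx = sum(1 for s, u in roots.items() if bdd.eval(u, g.bits))
        out.append((g, idx))
    return out


@dataclass
class AdditionCurve:
    """Exaptation statistics of minimal networks under exhaustive addition
    of n_ne-tuples of further reactions.

    All (minimal network, tuple) pairs are weighted equally; a genotype
    reachable from two different minimal networks counts once per pair.
    """

    focal_source: str
    n_ne: List[int]
    fraction_exapted: List[float]
    mean_index: List[float]
    n_pairs: List[int]


def addition_curves(
    mns: MinimalNetworkSet,
    minimal_sets: Mapping[str, MinimalNetworkSet],
    n_reactions: int,
    n_ne_values: Optional[Sequence[int]] = None,
    bdd: Optional[BDD] = None,
) -> AdditionCurve:
    """Fraction with I > 0 and mean I after adding n_ne reactions to each
    minimal network of the focal source, via exact conditioned counts."""
    focal = mns.carbon_source
    bdd = bdd or BDD(n_reactions)
    others = [s for s in minimal_sets if s != focal]
    roots = {s: bdd.from_upsets(minimal_sets[s].masks()) for s in others}
    union_others = 0
    for s in others:
        union_others = bdd.apply_or(union_others, roots[s])

    max_add = n_reactions - min(g.size for g in mns.networks)
    values = list(n_ne_values) if n_ne_values is not None else list(range(max_add + 1))
    totals = [0] * len(values)
    exapted = [0] * len(values)
    weighted_index = [0] * len(values)
    for g in mns.networks:
        s0 = g.size
        arr_union = bdd.count_by_size(union_others, forced=g.bits)
        arrs = {s: bdd.count_by_size(roots[s], forced=g.bits) for s in others}
        for t, add in enumerate(values):
            size = s0 + add
            if add < 0 or size > n_reactions:
                continue
            total = comb(n_reactions - s0, add)
            totals[t] += total
            exapted[t] += arr_union[size]
            weighted_index[t] += sum(arrs[s][size] for s in others)
    fraction = [
        float(Fraction(e, t)) if t else float("nan") for e, t in zip(exapted, totals)
    ]
    meanI = [
        float(Fraction(w, t)) if t else float("nan")
        for w, t in zip(weighted_index, totals)
    ]
    return AdditionCurve(
        focal_source=focal,
        n_ne=values,
        fraction_exapted=fraction,
        mean_index=meanI,
        n_pairs=totals,
    )


# ---------------------------------------------------------------------------
# yield and waste by exaptation index
# ---------------------------------------------------------------------------

@dataclass
class YieldWasteRow:
    index: int
    n_genotypes: int
    mean_yield: float
    mean_waste: float


def yield_waste_summary(
    solver: FBASolver,
    env: Environment,
    minimal_sets: Mapping[str, MinimalNetworkSet],
    size: int,
    thresholds: ViabilityThresholds,
    max_enumerate: int = 2000,
    sample_size: int = 500,
    seed: int = 0,
    bdd: Optional[BDD] = None,
) -> Tuple[List[YieldWasteRow], str]:
    """Mean biomass yield per carbon and mean waste count, by exaptation
    index, over genotypes of one size viable on the focal source.

    The size class is enumerated explicitly when it holds at most
    ``max_enumerate`` genotypes; otherwise ``sample_size`` genotypes are
    drawn uniformly from the class through the counting diagram.  Returns
    the per-index table and the mode used ("enumerated" or "sampled").
    """
    focal = env.name
    n = solver.n_internal
    bdd = bdd or BDD(n)
    focal_root = bdd.from_upsets(minimal_sets[focal].masks())
    others = [s for s in minimal_sets if s != focal]
    other_roots = {s: bdd.from_upsets(minimal_sets[s].masks()) for s in others}
    class_size = bdd.count_by_size(focal_root)[size]
    if class_size == 0:
        raise EmptyClassError(f"no genotypes of size {size} viable on {focal}")
    if class_size <= max_enumerate:
        masks = list(bdd.iter_masks(focal_root, size))
        mode = "enumerated"
    else:
        rng = random.Random(seed)
        masks = [bdd.sample(focal_root, size, rng) for _ in range(sample_size)]
        mode = "sampled"
    groups: Dict[int, List[int]] = {}
    for m in masks:
        idx = sum(1 for s in others if bdd.eval(other_roots[s], m))
        groups.setdefault(idx, []).append(m)
    rows: List[YieldWasteRow] = []
    for idx in sorted(groups):
        ys, ws = [], []
        for m in groups[idx]:
            ys.append(solver.yield_per_carbon(m, env))
            ws.append(solver.count_waste_metabolites(m, env))
        rows.append(
            YieldWasteRow(
                index=idx,
                n_genotypes=len(groups[idx]),
                mean_yield=sum(ys) / len(ys),
                mean_waste=sum(ws) / len(ws),
            )
        )
    return rows, mode
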