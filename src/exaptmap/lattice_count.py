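"""Exact counting over the 2^N genotype lattice.

Viability is monotone under reaction addition, so the set of genotypes
viable on a carbon source is exactly the union of the up-sets (super-set
cones) of its inclusion-minimal viable networks.  This module compiles that
monotone union into a reduced ordered binary decision diagram (BDD) over
the fixed reaction order and counts satisfying assignments exactly,
stratified by genotype size — replacing the astronomically large explicit
enumeration of the lattice by an equivalent exact computation.

Joint phenotype classes over all ten carbon sources are obtained by
intersecting per-source BDDs: for every subset ``S`` of sources the number
``A_S(n)`` of size-``n`` genotypes viable on *all* sources in ``S`` is
counted, and an inclusion–exclusion (Möbius) transform over the subset
lattice turns these into exact counts per joint phenotype class (viable on
exactly the sources of ``P``).  All counts are arbitrary-precision
integers.

An independent inclusion–exclusion backend over unions of minimal networks
is retained for small families and serves as a cross-check of the decision
diagram in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .minimal_enum import MinimalNetworkSet
from .model_io import Genotype

__all__ = [
    "BDD",
    "CountTable",
    "count_viable_by_size",
    "inclusion_exclusion_by_size",
    "joint_phenotype_counts",
    "conditioned_counts",
    "upset_union_bdd",
]


# ---------------------------------------------------------------------------
# BDD engine
# ---------------------------------------------------------------------------

class BDD:
    """Reduced ordered BDD manager over variables 0..n-1 (universe bit order).

    Nodes are integers; 0 and 1 are the terminals.  Functions are node ids
    inside a shared manager, so conjunctions across carbon sources reuse
    structure and the memo caches.
    """

    def __init__(self, n: int):
        self.n = n
        # node arrays; index 0/1 are terminals with var = n (sentinel level)
        self.var: List[int] = [n, n]
        self.lo: List[int] = [0, 1]
        self.hi: List[int] = [0, 1]
        self._unique: Dict[Tuple[int, int, int], int] = {}
        self._and_cache: Dict[Tuple[int, int], int] = {}
        self._or_cache: Dict[Tuple[int, int], int] = {}
        self._count_cache: Dict[Tuple[int, int], List[int]] = {}

    def node(self, var: int, lo: int, hi: int) -> int:
        if lo == hi:
            return lo
        key = (var, lo, hi)
        u = self._unique.get(key)
        if u is None:
            u = len(self.var)
            self.var.append(var)
            self.lo.append(lo)
            self.hi.append(hi)
            self._unique[key] = u
        return u

    def __len__(self) -> int:
        return len(self.var)

    # -- construction -------------------------------------------------------
    def from_upsets(self, masks: Iterable[int]) -> int:
        """BDD of the monotone union of super-set cones of ``masks``."""
        fam = _antichain(list(masks))
        memo: Dict[Tuple[int, Tuple[int, ...]], int] = {}

        def build(level: int, fam: Tuple[int, ...]) -> int:
            if not fam:
                return 0
            if fam[0] == 0:  # empty requirement: tautology
                return 1
            key = (level, fam)
            got = memo.get(key)
            if got is not None:
                return got
            v = min(_lowest_bit(m) for m in fam)
            bit = 1 << v
            without = tuple(m for m in fam if not m & bit)
            with_ = [m ^ bit for m in fam if m & bit]
            fam_hi = _antichain(list(without) + with_)
            u = self.node(v, build(v + 1, without), build(v + 1, fam_hi))
            memo[key] = u
            return u

        return build(0, fam)

    def cube(self, mask: int) -> int:
        """BDD of the conjunction of the positive literals in ``mask``."""
        u = 1
        for j in reversed(range(self.n)):
            if (mask >> j) & 1:
                u = self.node(j, 0, u)
        return u

    # -- boolean operations --------------------------------------------------
    def apply_and(self, u: int, v: int) -> int:
        if u == 0 or v == 0:
            return 0
        if u == 1:
            return v
        if v == 1:
            return u
        if u == v:
            return u
        key = (u, v) if u <= v else (v, u)
        got = self._and_cache.get(key)
        if got is not None:
            return got
        vu, vv = self.var[u], self.var[v]
        top = min(vu, vv)
        u0, u1 = (self.lo[u], self.hi[u]) if vu == top else (u, u)
        v0, v1 = (self.lo[v], self.hi[v]) if vv == top else (v, v)
        r = self.node(top, self.apply_and(u0, v0), self.apply_and(u1, v1))
        self._and_cache[key] = r
        return r

    def apply_or(self, u: int, v: int) -> int:
        if u == 1 or v == 1:
            return 1
        if u == 0:
            return v
        if v == 0:
            return u
        if u == v:
            return u
        key = (u, v) if u <= v else (v, u)
        got = self._or_cache.get(key)
        if got is not None:
            return got
        vu, vv = self.var[u], self.var[v]
        top = min(vu, vv)
        u0, u1 = (self.lo[u], self.hi[u]) if vu == top else (u, u)
        v0, v1 = (self.lo[v], self.hi[v]) if vv == top else (v, v)
        r = self.node(top, self.apply_or(u0, v0), self.apply_or(u1, v1))
        self._or_cache[key] = r
        return r

    def eval(self, u: int, mask: int) -> bool:
        while u > 1:
            u = self.hi[u] if (mask >> self.var[u]) & 1 else self.lo[u]
        return u == 1

    # -- counting -------------------------------------------------------------
    def _suffix_counts(self, u: int) -> List[int]:
        """Counts by popcount over variables var(u)..n-1 (terminals: var n)."""
        got = self._count_cache.get((u, 0))
        if got is not None:
            return got
        if u <= 1:
            res = [u]  # [0] for False, [1] for True; zero remaining variables
        else:
            v = self.var[u]
            lo = self._pad(self._suffix_counts(self.lo[u]), self.var[self.lo[u]] - v - 1)
            hi = self._pad(self._suffix_counts(self.hi[u]), self.var[self.hi[u]] - v - 1)
            res = [0] * (self.n - v + 1)
            for k, c in enumerate(lo):
                res[k] += c
            for k, c in enumerate(hi):
                res[k + 1] += c
        self._count_cache[(u, 0)] = res
        return res

    @staticmethod
    def _pad(arr: List[int], gap: int) -> List[int]:
        """Convolve with the binomial distribution of ``gap`` free variables."""
        if gap <= 0:
            return arr
        out = [0] * (len(arr) + gap)
        for g in range(gap + 1):
            b = comb(gap, g)
            for k, c in enumerate(arr):
                if c:
                    out[k + g] += b * c
        return out

    def count_by_size(self, u: int, forced: int = 0) -> List[int]:
        """Exact number of satisfying assignments per total popcount.

        ``forced`` is a bit mask of variables constrained to 1 (used for
        counts conditioned on a core genotype); forced bits contribute to
        the reported size.
        """
        if forced == 0:
            arr = self._pad(self._suffix_counts(u), self.var[u] if u > 1 else self.n)
            return arr + [0] * (self.n + 1 - len(arr))

        memo: Dict[int, List[int]] = {}

        def rec(u: int, level: int) -> List[int]:
            """Counts by popcount over variables level..n-1 under forcing."""
            if u <= 1:
                if u == 0:
                    return [0]
                nf = sum(1 for j in range(level, self.n) if (forced >> j) & 1)
                free = self.n - level - nf
                return _shift([comb(free, g) for g in range(free + 1)], nf)
            key = u if level == self.var[u] else (u, level)
            if key in memo:
                return memo[key]
            v = self.var[u]
            if level < v:
                nf = sum(1 for j in range(level, v) if (forced >> j) & 1)
                free = v - level - nf
                inner = rec(u, v)
                res = _shift(self._pad_list(inner, free), nf)
            else:  # level == v
                if (forced >> v) & 1:
                    res = _shift(rec(self.hi[u], v + 1), 1)
                else:
                    lo = rec(self.lo[u], v + 1)
                    hi = _shift(rec(self.hi[u], v + 1), 1)
                    res = _add(lo, hi)
            memo[key] = res
            return res

        arr = rec(u, 0)
        return arr + [0] * (self.n + 1 - len(arr))

    @staticmethod
    def _pad_list(arr: List[int], gap: int) -> List[int]:
        return BDD._pad(arr, gap)

    # -- sampling -------------------------------------------------------------
    def sample(self, u: int, size: int, rng, forced: int = 0) -> int:
        """Uniform random satisfying assignment with exactly ``size`` ones."""
        total = self.count_by_size(u, forced)[size]
        if total == 0:
            raise ValueError("empty class: no satisfying assignment of this size")
        pick = rng.randrange(total)
        mask = 0
        remaining = size
        level = 0
        while level < self.n:
            if u > 1 and self.var[u] == level:
                lo_u, hi_u = self.lo[u], self.hi[u]
                if (forced >> level) & 1:
                    u = hi_u
                    mask |= 1 << level
                    remaining -= 1
                else:
                    c_hi = self._tail_count(hi_u, level + 1, forced, remaining - 1)
                    if pick < c_hi:
                        mask |= 1 << level
                        remaining -= 1
                        u = hi_u
                    else:
                        pick -= c_hi
                        u = lo_u
            else:  # variable unconstrained at this level
                if (forced >> level) & 1:
                    mask |= 1 << level
                    remaining -= 1
                else:
                    c_one = self._tail_count(u, level + 1, forced, remaining - 1)
                    if pick < c_one:
                        mask |= 1 << level
                        remaining -= 1
                    else:
                        pick -= c_one
            level += 1
        if remaining != 0:
            raise AssertionError("sampling bookkeeping failed")
        return mask

    def iter_masks(self, u: int, size: int, forced: int = 0):
        """Yield every satisfying assignment with exactly ``size`` ones.

        Dead branches are pruned with size-resolved counts, so the cost is
        proportional to the number of solutions; use only on classes small
        enough to enumerate.
        """

        def walk(u: int, level: int, mask: int, remaining: int):
            if level == self.n:
                if u == 1 and remaining == 0:
                    yield mask
                return
            if self._tail_count(u, level, forced, remaining) == 0:
                return
            if u > 1 and self.var[u] == level:
                lo_u, hi_u = self.lo[u], self.hi[u]
            else:
                lo_u = hi_u = u
            if not (forced >> level) & 1:
                yield from walk(lo_u, level + 1, mask, remaining)
            yield from walk(hi_u, level + 1, mask | (1 << level), remaining - 1)

        yield from walk(u, 0, 0, size)

    def _tail_count(self, u: int, level: int, forced: int, ones: int) -> int:
        """Number of satisfying completions over variables level..n-1 with
        exactly ``ones`` additional ones."""
        if ones < 0:
            return 0
        sub = self.count_by_size_from(u, level, forced)
        return sub[ones] if ones < len(sub) else 0

    def count_by_size_from(self, u: int, level: int, forced: int) -> List[int]:
        key = (u, level, forced)
        got = self._count_cache.get(key)
        if got is not None:
            return got
        if u <= 1:
            if u == 0:
                res = [0]
            else:
                nf = sum(1 for j in range(level, self.n) if (forced >> j) & 1)
                free = self.n - level - nf
                res = _shift([comb(free, g) for g in range(free + 1)], nf)
        else:
            v = self.var[u]
            if level < v:
                nf = sum(1 for j in range(level, v) if (forced >> j) & 1)
                free = v - level - nf
                res = _shift(self._pad(self.count_by_size_from(u, v, forced), free), nf)
            else:
                if (forced >> v) & 1:
                    res = _shift(self.count_by_size_from(self.hi[u], v + 1, forced), 1)
                else:
                    res = _add(
                        self.count_by_size_from(self.lo[u], v + 1, forced),
                        _shift(self.count_by_size_from(self.hi[u], v + 1, forced), 1),
                    )
        self._count_cache[key] = res
        return res


def _lowest_bit(m: int) -> int:
    return (m & -m).bit_length() - 1


def _shift(arr: List[int], k: int) -> List[int]:
    return [0] * k + arr


def _add(a: List[int], b: List[int]) -> List[int]:
    if len(a) < len(b):
        a, b = b, a
    out = list(a)
    for i, c in enumerate(b):
        out[i] += c
    return out


def _antichain(masks: List[int]) -> Tuple[int, ...]:
    """Remove masks that are supersets of another mask (absorption)."""
    masks = sorted(set(masks), key=lambda m: (m.bit_count(), m))
    kept: List[int] = []
    for m in masks:
        if not any(m & k == k for k in kept):
            kept.append(m)
    return tuple(kept)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Exact genotype counts per (joint phenotype class, size).

    ``counts[pmask][n]`` is the number of genotypes of size ``n`` viable on
    exactly the sources whose bits are set in ``pmask`` (bit order =
    ``sources`` order).  When ``core`` is set, only supersets of that
    genotype are counted and sizes include the core.
    """

    sources: List[str]
    n_reactions: int
    counts: Dict[int, List[int]]
    core: Optional[Genotype] = None

    def source_bit(self, source: str) -> int:
        return self.sources.index(source)

    def total(self) -> int:
        return sum(sum(arr) for arr in self.counts.values())

    def viable_counts(self, source: str) -> List[int]:
        """Per-size counts of genotypes viable on ``source`` (marginal)."""
        b = self.source_bit(source)
        out = [0] * (self.n_reactions + 1)
        for pmask, arr in self.counts.items():
            if (pmask >> b) & 1:
                for n, c in enumerate(arr):
                    out[n] += c
        return out

    def class_counts(self, source: str, size: Optional[int] = None) -> Dict[int, int]:
        """Counts per phenotype class restricted to classes viable on
        ``source``, keyed by the class mask, optionally within one size."""
        b = self.source_bit(source)
        out: Dict[int, int] = {}
        for pmask, arr in self.counts.items():
            if (pmask >> b) & 1:
                c = arr[size] if size is not None else sum(arr)
                if c:
                    out[pmask] = out.get(pmask, 0) + c
        return out

    def to_rows(self) -> List[Tuple[str, int, int]]:
        """(phenotype bitstring, size, count) rows for serialization."""
        rows = []
        ns = len(self.sources)
        for pmask in sorted(self.counts):
            for n, c in enumerate(self.counts[pmask]):
                if c:
                    rows.append((format(pmask, f"0{ns}b")[::-1], n, c))
        return rows


def _require_complete(mns: MinimalNetworkSet) -> None:
    if not mns.complete:
        raise ValueError(
            f"minimal-network set for {mns.carbon_source} is not complete; "
            "exact counting would be wrong"
        )


def upset_union_bdd(bdd: BDD, mns: MinimalNetworkSet) -> int:
    _require_complete(mns)
    return bdd.from_upsets(mns.masks())


def count_viable_by_size(
    mns: MinimalNetworkSet,
    n_reactions: int,
    bdd: Optional[BDD] = None,
) -> Dict[int, int]:
    """Exact number of viable genotypes of each size for one source."""
    bdd = bdd or BDD(n_reactions)
    u = upset_union_bdd(bdd, mns)
    arr = bdd.count_by_size(u)
    return {n: c for n, c in enumerate(arr) if c}


def inclusion_exclusion_by_size(masks: Sequence[int], n_reactions: int) -> Dict[int, int]:
    """Per-size count of the union of up-sets by inclusion–exclusion.

    Exponential in the number of minimal networks; intended for families of
    at most ~20 networks, as an independent cross-check of the BDD backend.
    """
    masks = list(_antichain(list(masks)))
    k = len(masks)
    if k > 22:
        raise ValueError("inclusion–exclusion backend limited to 22 minimal sets")
    out = [0] * (n_reactions + 1)
    for sub in range(1, 1 << k):
        union = 0
        for i in range(k):
            if (sub >> i) & 1:
                union |= masks[i]
        sign = -1 if sub.bit_count() % 2 == 0 else 1
        fixed = union.bit_count()
        free = n_reactions - fixed
        for extra in range(free + 1):
            out[fixed + extra] += sign * comb(free, extra)
    return {n: c for n, c in enumerate(out) if c}


def _subset_counts(
    bdd: BDD,
    roots: List[int],
    n_reactions: int,
    forced: int = 0,
) -> Dict[int, List[int]]:
    """A_S(n) for every subset S of sources: counts of genotypes viable on
    all sources in S, by size, computed over incrementally cached BDD ANDs."""
    ns = len(roots)
    node_of: Dict[int, int] = {0: 1}  # S=∅: tautology
    for smask in range(1, 1 << ns):
        low = smask & -smask
        prev = node_of[smask ^ low]
        node_of[smask] = bdd.apply_and(prev, roots[low.bit_length() - 1])
    out: Dict[int, List[int]] = {}
    for smask, u in node_of.items():
        out[smask] = bdd.count_by_size(u, forced)
    return out


def _moebius(a_s: Dict[int, List[int]], ns: int, n_reactions: int) -> Dict[int, List[int]]:
    """Superset Möbius transform: counts per exact phenotype class."""
    table = [list(a_s[s]) for s in range(1 << ns)]
    for b in range(ns):
        bit = 1 << b
        for smask in range(1 << ns):
            if not smask & bit:
                row, other = table[smask], table[smask | bit]
                for n in range(len(row)):
                    row[n] -= other[n]
    return {s: table[s] for s in range(1 << ns) if any(table[s])}


def joint_phenotype_counts(
    minimal_sets: Mapping[str, MinimalNetworkSet],
    n_reactions: int,
    bdd: Optional[BDD] = None,
) -> CountTable:
    """Exact counts per (10-bit phenotype class, size) over the whole lattice."""
    sources = list(minimal_sets)
    for mns in minimal_sets.values():
        _require_complete(mns)
    bdd = bdd or BDD(n_reactions)
    roots = [bdd.from_upsets(minimal_sets[s].masks()) for s in sources]
    a_s = _subset_counts(bdd, roots, n_reactions)
    counts = _moebius(a_s, len(sources), n_reactions)
    return CountTable(sources=sources, n_reactions=n_reactions, counts=counts)


def conditioned_counts(
    core: Genotype,
    minimal_sets: Mapping[str, MinimalNetworkSet],
    n_reactions: int,
    bdd: Optional[BDD] = None,
) -> CountTable:
    """Counts per (phenotype class, size) among supersets of ``core``.

    Sizes include the core's reactions, so size - core.size is the number
    of added reactions.
    """
    sources = list(minimal_sets)
    for mns in minimal_sets.values():
        _require_complete(mns)
    bdd = bdd or BDD(n_reactions)
    roots = [bdd.from_upsets(minimal_sets[s].masks()) for s in sources]
    a_s = _subset_counts(bdd, roots, n_reactions, forced=core.bits)
    counts = _moebius(a_s, len(sources), n_reactions)
    return CountTable(
        sources=sources, n_reactions=n_reactions, counts=counts, core=core
    )
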