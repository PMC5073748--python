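import itertools
import random
from math import comb

import numpy as np
import pytest

from exaptmap import (
    FBASolver,
    addition_curves,
    brute_force_map,
    distance_distribution,
    enumerate_minimal,
    exaptation_index,
    fraction_exapted,
    joint_phenotype_counts,
    make_toy_universe,
    mean_index,
    minimal_set_phenotypes,
    phenotype_distance,
    phenotype_vector,
    preadaptation_matrix,
    upgma_tree,
    yield_waste_summary,
)
from exaptmap.exaptation_stats import EmptyClassError, PhenotypeVector, PreadaptationMatrix
from exaptmap.lattice_count import CountTable

from conftest import toy_corpus

MULTI = [s for s in toy_corpus(20) if s.n_carbon_sources >= 2]


def _setup(spec):
    universe, envs = make_toy_universe(spec)
    solver = FBASolver(universe)
    th = solver.viability_thresholds(envs)
    sets = {name: enumerate_minimal(solver, env, th) for name, env in envs.items()}
    table = joint_phenotype_counts(sets, universe.n_internal)
    df = brute_force_map(universe, envs, backend="glpk")
    return universe, envs, solver, th, sets, table, df


@pytest.fixture(scope="module")
def multi_setup():
    return _setup(MULTI[0])


class TestIndex:
    def test_popcount_boundaries(self):
        assert exaptation_index(PhenotypeVector(0, "glucose")) == 0
        assert exaptation_index(PhenotypeVector((1 << 9) - 1, "glucose")) == 9

    def test_phenotype_vector_drops_the_focal_bit(self):
        sources = ["a", "b", "c"]
        v = phenotype_vector(0b111, "b", sources)
        assert v.bits == 0b11 and v.length == 2
        with pytest.raises(ValueError):
            phenotype_vector(0b101, "b", sources)

    def test_distance_requires_matching_focal(self):
        p = PhenotypeVector(0b1, "a")
        q = PhenotypeVector(0b10, "b")
        with pytest.raises(ValueError):
            phenotype_distance(p, q)
        assert phenotype_distance(p, p) == 0
        r = PhenotypeVector(p.bits ^ ((1 << 9) - 1), "a")
        assert phenotype_distance(p, r) == 9


class TestFractionsAndMeans:
    def test_match_brute_force_on_toys(self):
        for spec in MULTI[:3]:
            universe, envs, solver, th, sets, table, df = _setup(spec)
            names = table.sources
            for focal in names:
                sub = df[df[f"viable_{focal}"]]
                idx = sum(
                    sub[f"viable_{s}"].astype(int) for s in names if s != focal
                )
                assert fraction_exapted(table, focal) == pytest.approx(
                    float((idx > 0).mean())
                )
                assert mean_index(table, focal) == pytest.approx(float(idx.mean()))
                for size in sorted(sub["size"].unique()):
                    at = idx[sub["size"] == size]
                    assert fraction_exapted(table, focal, size) == pytest.approx(
                        float((at > 0).mean())
                    )
                    assert mean_index(table, focal, size) == pytest.approx(
                        float(at.mean())
                    )

    def test_empty_size_class_is_signaled(self, multi_setup):
        universe, envs, solver, th, sets, table, df = multi_setup
        with pytest.raises(EmptyClassError):
            fraction_exapted(table, table.sources[0], size=0)

    def test_mean_index_equals_preadaptation_row_sum(self, multi_setup):
        universe, envs, solver, th, sets, table, df = multi_setup
        mat = preadaptation_matrix(table)
        for focal in table.sources:
            assert mean_index(table, focal) == pytest.approx(
                mat.row_sum_off_diagonal(focal), abs=1e-12
            )


class TestPreadaptationMatrix:
    def test_diagonal_is_one_and_entries_in_unit_interval(self, multi_setup):
        universe, envs, solver, th, sets, table, df = multi_setup
        mat = preadaptation_matrix(table)
        for i, s in enumerate(mat.sources):
            assert mat.values[i][i] == pytest.approx(1.0)
            assert all(0.0 <= v <= 1.0 for v in mat.values[i])

    def test_matches_brute_force_conditional_fractions(self):
        for spec in MULTI[1:3]:
            universe, envs, solver, th, sets, table, df = _setup(spec)
            mat = preadaptation_matrix(table)
            for focal in mat.sources:
                sub = df[df[f"viable_{focal}"]]
                for new in mat.sources:
                    assert mat[focal, new] == pytest.approx(
                        float(sub[f"viable_{new}"].mean())
                    )


class TestDistanceDistribution:
    def test_fractions_sum_to_one_and_reordering_invariance(self, multi_setup):
        universe, envs, solver, th, sets, table, df = multi_setup
        focal = table.sources[0]
        sizes = [
            s for s, c in enumerate(table.viable_counts(focal)) if c >= 2
        ]
        size = sizes[len(sizes) // 2]
        counts, fracs = distance_distribution(table, focal, size)
        assert sum(fracs) == pytest.approx(1.0)
        # permuting the non-focal sources must not change the histogram
        perm = list(reversed(list(sets)))
        table2 = joint_phenotype_counts(
            {k: sets[k] for k in perm}, universe.n_internal
        )
        counts2, fracs2 = distance_distribution(table2, focal, size)
        assert counts == counts2

    def test_single_class_means_all_pairs_at_distance_zero(self):
        # a universe with one source: every phenotype vector is empty
        for spec in [s for s in toy_corpus(20) if s.n_carbon_sources == 1]:
            universe, envs, solver, th, sets, table, df = _setup(spec)
            focal = table.sources[0]
            sizes = [s for s, c in enumerate(table.viable_counts(focal)) if c >= 2]
            if sizes:
                break
        counts, fracs = distance_distribution(table, focal, sizes[0])
        assert fracs[0] == pytest.approx(1.0)
        assert all(f == 0 for f in fracs[1:])

    def test_matches_brute_force_pair_histogram(self, multi_setup):
        universe, envs, solver, th, sets, table, df = multi_setup
        names = table.sources
        focal = names[0]
        sub = df[df[f"viable_{focal}"]]
        size = int(sub["size"].mode()[0])
        at = sub[sub["size"] == size]
        vecs = [
            tuple(bool(r[f"viable_{s}"]) for s in names if s != focal)
            for _, r in at.iterrows()
        ]
        expect = [0] * len(names)
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                d = sum(a != b for a, b in zip(vecs[i], vecs[j]))
                expect[d] += 1
        counts, _ = distance_distribution(table, focal, size)
        assert counts == expect


class TestUPGMA:
    def test_three_source_hand_computation(self):
        """d(a,b)=0.3, d(a,c)=0.7, d(b,c)=0.8: a,b merge at height 0.15 and
        c joins at (0.7+0.8)/2/2 = 0.375 (hand UPGMA arithmetic)."""
        mat = PreadaptationMatrix(
            sources=["a", "b", "c"],
            values=[
                [1.0, 0.8, 0.2],
                [0.6, 1.0, 0.1],
                [0.4, 0.3, 1.0],
            ],
        )
        tree = upgma_tree(mat)
        assert tree.height == pytest.approx(0.375)
        (left, right) = tree.children
        pair = left if not left.is_leaf else right
        leaf = right if pair is left else left
        assert sorted(pair.leaves()) == ["a", "b"]
        assert pair.height == pytest.approx(0.15)
        assert leaf.name == "c"
        assert tree.newick() == "((a:0.15,b:0.15):0.225,c:0.375);"

    def test_zero_distance_pair_merges_first(self):
        mat = PreadaptationMatrix(
            sources=["x", "y", "z"],
            values=[[1, 1, 0.1], [1, 1, 0.2], [0.1, 0.2, 1]],
        )
        tree = upgma_tree(mat)
        assert frozenset(["x", "y"]) in tree.sibling_sets()

    def test_matches_scipy_average_linkage_cophenetic_heights(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = random.Random(9)
        for _ in range(10):
            k = rng.randint(3, 8)
            names = [f"s{i}" for i in range(k)]
            vals = [[1.0] * k for _ in range(k)]
            for i in range(k):
                for j in range(i + 1, k):
                    p = rng.random()
                    q = rng.random()
                    vals[i][j], vals[j][i] = p, q
            mat = PreadaptationMatrix(sources=names, values=vals)
            tree = upgma_tree(mat)
            d = np.zeros((k, k))
            for i in range(k):
                for j in range(k):
                    if i != j:
                        d[i, j] = 1.0 - 0.5 * (vals[i][j] + vals[j][i])
            Z = linkage(squareform(d), method="average")
            coph = squareform(cophenet(Z))
            got = _cophenetic(tree, names)
            assert np.allclose(got, coph, atol=1e-9)


def _cophenetic(tree, names):
    k = len(names)
    out = np.zeros((k, k))

    def walk(node):
        if node.is_leaf:
            return [node.name]
        groups = [walk(ch) for ch in node.children]
        for gi, gj in itertools.combinations(groups, 2):
            for a in gi:
                for b in gj:
                    i, j = names.index(a), names.index(b)
                    out[i, j] = out[j, i] = 2 * node.height
        return [x for g in groups for x in g]

    walk(tree)
    return out


class TestAdditionCurves:
    def test_equals_explicit_tuple_enumeration(self):
        spec = MULTI[2]
        universe, envs, solver, th, sets, table, df = _setup(spec)
        names = list(sets)
        focal = names[0]
        n = universe.n_internal
        curve = addition_curves(sets[focal], sets, n)
        # brute force: add every tuple of absent reactions to every minimal net
        viable = {
            s: {int(b[::-1], 2) for b, v in zip(df["bits"], df[f"viable_{s}"]) if v}
            for s in names
        }
        for t, add in enumerate(curve.n_ne):
            total = 0
            exapted = 0
            isum = 0
            for g in sets[focal].networks:
                absent = [j for j in range(n) if not (g.bits >> j) & 1]
                for combo in itertools.combinations(absent, add):
                    mask = g.bits
                    for j in combo:
                        mask |= 1 << j
                    total += 1
                    idx = sum(
                        1 for s in names if s != focal and mask in viable[s]
                    )
                    exapted += idx > 0
                    isum += idx
            if total:
                assert curve.n_pairs[t] == total
                assert curve.fraction_exapted[t] == pytest.approx(exapted / total)
                assert curve.mean_index[t] == pytest.approx(isum / total)

    def test_fraction_exapted_is_monotone_in_added_reactions(self):
        for spec in MULTI[3:5]:
            universe, envs, solver, th, sets, table, df = _setup(spec)
            for focal in sets:
                curve = addition_curves(sets[focal], sets, universe.n_internal)
                vals = [f for f in curve.fraction_exapted if f == f]
                assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_zero_additions_reproduce_minimal_set_fraction(self, multi_setup):
        universe, envs, solver, th, sets, table, df = multi_setup
        focal = list(sets)[0]
        curve = addition_curves(sets[focal], sets, universe.n_internal, n_ne_values=[0])
        phen = minimal_set_phenotypes(sets[focal], sets, universe.n_internal)
        frac = sum(1 for _, i in phen if i > 0) / len(phen)
        assert curve.fraction_exapted[0] == pytest.approx(frac)


class TestYieldWaste:
    def test_single_genotype_class_equals_direct_values(self):
        spec = [s for s in toy_corpus(20) if s.n_carbon_sources == 1][1]
        universe, envs, solver, th, sets, table, df = _setup(spec)
        focal = list(envs)[0]
        # the full network is the only genotype of size N
        n = universe.n_internal
        rows, mode = yield_waste_summary(
            solver, envs[focal], sets, n, th
        )
        assert mode == "enumerated"
        assert len(rows) == 1
        assert rows[0].n_genotypes == 1
        assert rows[0].mean_yield == pytest.approx(
            solver.yield_per_carbon((1 << n) - 1, envs[focal])
        )
        assert rows[0].mean_waste == pytest.approx(
            solver.count_waste_metabolites((1 << n) - 1, envs[focal])
        )

    def test_enumerated_means_match_brute_force_grouping(self, multi_setup):
        universe, envs, solver, th, sets, table, df = multi_setup
        names = list(sets)
        focal = names[0]
        sub = df[df[f"viable_{focal}"]]
        size = int(sub["size"].mode()[0])
        rows, mode = yield_waste_summary(
            solver, envs[focal], sets, size, th, max_enumerate=5000
        )
        assert mode == "enumerated"
        at = sub[sub["size"] == size]
        groups = {}
        for _, r in at.iterrows():
            mask = int(r["bits"][::-1], 2)
            idx = sum(1 for s in names if s != focal and r[f"viable_{s}"])
            groups.setdefault(idx, []).append(mask)
        assert {r.index: r.n_genotypes for r in rows} == {
            k: len(v) for k, v in groups.items()
        }
        for r in rows:
            ys = [solver.yield_per_carbon(m, envs[focal]) for m in groups[r.index]]
            assert r.mean_yield == pytest.approx(sum(ys) / len(ys))
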