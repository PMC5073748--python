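# exaptmap

Exhaustive genotype–phenotype mapping of central carbon metabolism, and the
statistics of metabolic exaptation it supports.

## The question

A trait that evolved in one context can turn out to be useful in another —
a *pre-adaptation* or *exaptation*.  For metabolism the question becomes
quantitative: if a metabolic network is viable on a focal carbon source
*C*, how often is it also viable on other sources *C*ₙₑ𝓌 it was never
selected on?  Central carbon metabolism is small enough to answer this
exhaustively.  A metabolic *genotype* is a presence/absence vector over a
fixed universe of *N* = 51 internal reactions of the *E. coli* core network
(20 transport reactions and the biomass reaction are always present); the
genotype space holds 2⁵¹ ≈ 2·10¹⁵ variants, and each genotype's *phenotype*
is its viability on each of ten minimal aerobic environments (glucose,
fructose, pyruvate, lactate, acetate, succinate, fumarate, malate,
α-ketoglutarate, glutamate as sole carbon source).

## The method

* **Viability oracle (FBA).**  Viability on a source is decided by flux
  balance analysis: maximize biomass flux *v*\* = max *c*ᵀ*v* subject to
  *S v* = 0 and *a* ≤ *v* ≤ *b*, with absent reactions clamped to zero.  A
  genotype is viable if *v*\* exceeds 1 % of the full network's rate on the
  same source.  Deleting reactions only shrinks the flux polytope, so
  viability is **monotone** under reaction addition.
* **Minimal networks.**  For each source, all inclusion-minimal viable
  networks are enumerated by a mixed-integer program: binary presence
  variables gate the flux bounds (*aᵢxᵢ* ≤ *vᵢ* ≤ *bᵢxᵢ*), blocking cuts
  exclude the supersets of every network already found, each solution is
  LP-verified and greedily minimized, and final infeasibility certifies
  completeness.
* **Exact counting.**  By monotonicity the viable set is the union of the
  up-sets of the minimal networks.  That monotone union is compiled into a
  binary decision diagram and counted exactly (arbitrary-precision), per
  genotype size and per joint phenotype class over all ten sources — the
  2⁵¹ lattice is never enumerated.
* **Statistics.**  From the exact class counts: the exaptation index *I*
  (number of non-focal sources a genotype is viable on), fractions with
  *I* > 0 and mean *I* by source and size, the asymmetric preadaptation
  matrix *P*(*C*ₙₑ𝓌 | *C*), Hamming phenotype-distance distributions,
  UPGMA clustering of carbon sources, exhaustive reaction-addition curves,
  and biomass-yield / waste-excretion summaries.

## Worked example

```python
import exaptmap as xm

universe, envs = xm.load_bundled_model()     # 51 reactions, 10 environments
solver = xm.FBASolver(universe)
thresholds = solver.viability_thresholds(envs)

ess = solver.essential_reactions(envs, thresholds)
print(sorted(ess))
# ['ENO', 'GAPD', 'GLNS', 'PGK', 'PGM', 'RPI']   (6 universally essential)

size, nets = xm.minimum_size(solver, envs["glucose"], thresholds)
print(size, len(nets))
# 23 3    (three distinct smallest glucose metabolisms, 23 reactions each)

mns = xm.enumerate_minimal(solver, envs["glucose"], thresholds)
print(len(mns), min(mns.sizes()), max(mns.sizes()))
# 161 23 30    (all inclusion-minimal glucose metabolisms)
```

The six reactions above are lower glycolysis/gluconeogenesis (ENO, GAPD,
PGK, PGM), ribose-5-phosphate isomerase (RPI) and glutamine synthetase
(GLNS) — the steps no alternative route in the universe can replace on any
carbon source.  With the minimal networks of all ten sources enumerated,
the exact lattice statistics follow in seconds:

```python
sets = {name: xm.enumerate_minimal(solver, env, thresholds)
        for name, env in envs.items()}            # ~10 min on one core
table = xm.joint_phenotype_counts(sets, universe.n_internal)
print(round(100 * xm.fraction_exapted(table, "glucose")))
# 95    (% of glucose-viable genotypes also viable on another source)
mat = xm.preadaptation_matrix(table)
print(mat["fumarate", "malate"], round(mat["glucose", "acetate"], 4))
# 1.0 0.0023    (preadaptation is strongly asymmetric)
```

A command-line pipeline wraps the same stages with caching and logging:

```bash
exaptmap --out results all        # thresholds -> minimal -> counts -> stats
```

## Layout

| Module | Contents |
| --- | --- |
| `exaptmap.model_io` | reaction universe, genotypes, environments, TSV/JSON (optional SBML) I/O |
| `exaptmap.fba` | LP viability oracle, thresholds, essentiality, FVA caps, pFBA, yield/waste, disconnected reactions |
| `exaptmap.minimal_enum` | MILP enumeration of minimal networks, greedy minimization, minimum size, completeness certificate |
| `exaptmap.lattice_count` | decision-diagram exact counting, joint/conditioned phenotype-class tables, inclusion–exclusion cross-check |
| `exaptmap.exaptation_stats` | exaptation indices, preadaptation matrix, phenotype distances, UPGMA, addition curves, yield/waste summaries |
| `exaptmap.synthetic_data` | toy universe generator and 2^N brute-force oracle |
| `exaptmap.cli` | `exaptmap` pipeline command |

See `docs/methods.md` for the model conventions, algorithms and their
validation.
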