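# Methods

## The genotype–phenotype map

The object of study is the space of all 2^51 variants ("genotypes") of the
central carbon metabolism of *E. coli*.  A genotype is a presence/absence
vector over a fixed, ordered universe of 51 internal reactions
(glycolysis/gluconeogenesis, pentose-phosphate pathway, TCA cycle,
anaplerosis, glyoxylate shunt, oxidative phosphorylation and a few
fermentative reactions).  Twenty transport reactions, eighteen exchange
reactions and the biomass reaction are present in every genotype and are
not genotype-encoded.  The bundled model is transcribed from the published
*E. coli* core reconstruction with two edits: the ethanol-metabolism
reactions are removed (alcohol dehydrogenase, ethanol transport, and the
ethanol and acetaldehyde exchanges), and the two aconitase half-reactions
are merged into a single cit ⇌ icit conversion.  The four
proton-translocating reactions of oxidative phosphorylation count as
internal reactions, not transport.  The non-growth ATP maintenance demand
is set to zero: maintenance is a physiological calibration, not part of
the qualitative viability question asked here.

The transcription was validated against independent structural fingerprints
of this model family: exactly six universally essential internal reactions;
minimum viable network sizes of 23 (glucose) and 30 (acetate); and the full
minimal-network censuses per carbon source (161 minimal glucose networks
spanning 23–30 reactions, 76 minimal acetate networks spanning 30–36, and
so on for the other eight sources).  All of these are *outputs* of the
pipeline, recomputed by `scripts/acceptance.py` and the test suite.

## Environments and viability

Each growth environment is a minimal aerobic medium: one carbon source
(uptake bound 10 flux units), plus ammonium, phosphate, oxygen, protons and
water (bound 1000, effectively non-limiting).  Every other exchangeable
metabolite, including CO2, can only be excreted.  The ten carbon sources —
acetate, α-ketoglutarate, fructose, fumarate, glucose, glutamate, lactate,
malate, pyruvate, succinate — are kept in this fixed alphabetical order in
all phenotype vectors.  All headline statistics are invariant to a uniform
rescaling of the uptake bounds (LP homogeneity), which the tests assert.

Viability of a genotype on a source is decided by flux balance analysis:
maximize biomass flux subject to steady state (S·v = 0) and flux bounds,
with absent internal reactions clamped to zero.  A genotype is viable when
its maximal biomass rate exceeds 1 % of the rate of the *full* 51-reaction
network on the same source, with a relative guard of 10⁻⁶ on the
comparison to absorb solver round-off.  The threshold is computed per
source from the full network (the natural reading of the relative
criterion; a single cross-source reference would make the acetate census
inconsistent with the published values).  The biomass reaction drains the
13 classic biomass precursors with core-model stoichiometry, so "biomass
above threshold" operationalizes "all 13 precursors producible in the
published proportions".

Deleting a reaction restricts the feasible flux polytope, so viability is
monotone under reaction addition.  Everything downstream exploits this one
fact.

Two LP backends are used deliberately: a persistent GLPK problem per
environment, re-solved warm after flipping the bounds of absent reactions
(~0.3 ms per solve; the workhorse for the ~10⁶ viability queries of an
enumeration run), and scipy's HiGHS `linprog`, stateless and independent,
used by the brute-force oracle and as a cross-check in tests.  A failed
warm simplex is retried from a fresh advanced basis and raises if it fails
again — silently treating numerical failure as "inviable" corrupts greedy
minimization (it manufactures oversized "minimal" networks; this failure
mode is why the retry exists).

## Minimal-network enumeration

A minimal metabolism is an inclusion-minimal viable genotype.  By
monotonicity, the viable set for a source is exactly the union of the
super-set cones of its minimal networks, so the (finite, small) minimal
list is the compressed representation of the entire map.

Enumeration is MILP-driven (scipy's HiGHS branch-and-bound).  Binary
presence variables x gate the flux bounds (aᵢxᵢ ≤ vᵢ ≤ bᵢxᵢ) and biomass is
constrained above the threshold.  Each feasible solution is LP-verified,
greedily minimized (scan reactions in fixed universe order, delete while
viability holds; `order_seed` shuffles the scan for alternative minimal
representatives), and excluded by a blocking cut requiring at least one of
its reactions to be absent.  MILP infeasibility is the completeness
certificate; a randomized certificate (`verify_complete`) additionally
checks that random viable genotypes all contain an enumerated network.

Three measures keep the MILP honest and fast, none of which changes the
enumerated set:

* **Exact big-M.**  The gating bounds aᵢ, bᵢ are the flux ranges of the
  full network from FVA.  Every genotype's polytope is contained in the
  full network's, so these are valid for all genotypes, and they are tight
  enough to starve the classic leak where a binary at the integrality
  tolerance (~10⁻⁶) times a ±1000 bound smuggles enough flux to fake
  viability (without this, a spurious 22-reaction "glucose minimum"
  appears).
* **Verification with no-good repair.**  Any MILP solution whose rounded
  genotype fails LP verification is removed by a cut excluding exactly that
  assignment — sound, because the assignment is provably inviable.
* **Implied fixings and covers.**  Reactions essential for the focal source
  (single deletion from the full network abolishes viability) are fixed
  present — they belong to every minimal network.  "Survivor pairs"
  (pairs of non-essential reactions whose joint deletion from the full
  network kills the source) become covering inequalities xₐ + x_b ≥ 1,
  valid again by monotonicity.

`minimum_size` answers the smallest-size question directly: a
cardinality-minimizing MILP followed by integer cuts enumerates every
genotype at the optimum (at minimum cardinality, viable ⇒
inclusion-minimal).

## Exact lattice counting

Counting proceeds on the monotone structure, never by enumerating
genotypes.  Each source's viable set (union of up-sets of its minimal
networks) is compiled into a reduced ordered binary decision diagram over
the fixed reaction order; the compilation recurses on the minimal-network
family with absorption (antichain reduction) at every split and is
memoized on the reduced family.  Satisfying assignments are counted per
genotype size by a single pass with binomial convolution over skipped
decision levels; counts are exact Python integers throughout.

Joint phenotype classes over the ten sources are obtained from
A_S(n) — the number of size-n genotypes viable on *all* sources of a
subset S, computed by intersecting source diagrams (cached incrementally
over the subset lattice, 2¹⁰ conjunctions) — followed by a Möbius
(inclusion–exclusion) transform over subsets, yielding the exact count of
genotypes viable on *exactly* the sources of each pattern, per size.
Counts conditioned on a core genotype (used for addition curves) force the
core's variables to one inside the counting pass.  An explicit
inclusion–exclusion backend over unions of minimal networks (feasible for
≤ 22 networks) cross-checks the diagram in the tests, as does exhaustive
brute force on the synthetic universes.

The diagram also supports exact uniform sampling of a (source, size) class
and pruned enumeration of small classes.  Sampling is used only by the
yield/waste summaries when a class is too large to enumerate; all counting
outputs are exact.

## Derived statistics

With exact class counts c_P(n), every published statistic is arithmetic:

* **Exaptation index** I = number of non-focal sources a focal-viable
  genotype is viable on (popcount of the 9-bit conditioned phenotype
  vector).  `fraction_exapted` and `mean_index` are count-weighted
  aggregates, optionally within one size class; an empty class (size below
  the source's minimum) raises instead of returning a silent zero.
* **Preadaptation matrix** P(C_new | C) from pairwise joint counts; the
  identity mean_index(C) = Σ_{C'≠C} P(C'|C) is asserted exactly.
* **Phenotype distances**: Hamming distances between conditioned phenotype
  vectors; pair counts within a size class are combinatorial over classes
  (k_u·k_v between classes, k·(k−1)/2 within), never over genotype pairs.
* **UPGMA clustering** of carbon sources on the distance
  d(C,C') = 1 − (P(C'|C)+P(C|C'))/2 — the simplest symmetrization of the
  directed preadaptation propensity, chosen because the propensity itself
  is asymmetric while a dendrogram needs a metric.  Ties merge the
  lexicographically first pair, making the tree deterministic; heights are
  half-distances and the Newick output carries branch lengths.  The
  implementation is cross-checked against scipy's average-linkage
  cophenetic distances.
* **Addition curves**: for every minimal network of a focal source and
  every number n_ne of added reactions, all C(N−|m|, n_ne) tuples are
  aggregated through conditioned counts; (network, tuple) pairs are the
  unit of weighting, so a genotype reachable from two networks counts
  twice, matching the exhaustive-tuple design.  The exapted fraction uses
  one diagram for the union of the nine non-focal viable sets; the mean
  index uses one diagram per source.
* **Yield and waste**: biomass yield per mole of carbon is the biomass rate
  divided by (carbon uptake flux × carbon atoms of the source), evaluated
  at the parsimonious optimum (minimal total absolute flux at the optimal
  biomass rate) to resolve FBA degeneracy; the same designated solution
  supplies the excretion fluxes for waste counting.  A waste metabolite is
  an excreted carbon-containing molecule that is not one of the 13
  precursors (CO2 therefore counts; it is a constant offset in aerobic
  metabolisms and does not affect the reported trends).  Summaries by
  exaptation index enumerate a size class exactly when it is small and
  sample it uniformly otherwise, recording the mode.

## Synthetic universes

`make_toy_universe` builds linear/branched pathway systems (≤ 16 internal
reactions) from one to three carbon sources to a single biomass precursor,
with optional shared segments (`share_prob`) and forced byproducts with
their own excretion routes; carbon sources carry 1–3 carbon atoms so the
yield normalization is exercised with non-unit denominators.  Generation is
a pure function of the `ToySpec`.  The toys emulate the *combinatorial*
structure of the real map — monotone viability, multiple minimal networks,
nested and overlapping pathways — but not its biochemistry: no cofactors,
no energy balance, no reversibility, single precursor.  Passing the
brute-force equivalence suite on toys therefore certifies the enumeration,
counting and statistics machinery, while fidelity to the biological model
rests on the fingerprint checks against the published census.

`brute_force_map` evaluates all 2^N genotypes with fresh stateless LP
solves (scipy backend), no pruning and no monotonicity shortcuts, and is
the oracle for every DERIVED expectation in the tests.

## Problem sizes and numerical choices

The default test suite and the acceptance script enumerate all ten sources
(≈3,300 minimal networks; the blocking-cut MILP carries up to ~860 cuts for
the richest source), count the full 2^51 lattice, and cross-check on 20
synthetic universes of 6–12 internal reactions; these sizes keep a complete
run in the ten-minute range on one core while still covering every code
path.  Zero-flux tolerance is 10⁻⁹
absolute; the viability guard is 10⁻⁶ relative; pFBA holds the biomass
optimum to within 10⁻⁹ relative.  Counts are arbitrary-precision integers;
fractions are converted to floats only at the reporting boundary.

## Known limitations

* Genotypes are reaction-centered; gene–protein–reaction structure,
  regulation and enzyme kinetics are outside the framework.
* The universe covers canonical central carbon metabolism only
  (Embden–Meyerhof–Parnas glycolysis; no Entner–Doudoroff or
  phosphoketolase variants).
* The waste-metabolite count depends on the designated (parsimonious)
  optimal solution; other optima can excrete different byproduct sets.
* Analyses excluding genotypes with disconnected reactions are supported
  through the `disconnected_reactions` filter but are not part of the
  default outputs.
* In this transcription the mean biomass yield of glucose-viable genotypes
  at a fixed size is essentially flat in the exaptation index (the
  glucose-only specialists that route glucose through the oxidative
  pentose-phosphate pathway are the most efficient class); the acceptance
  script reports the measured rank correlation rather than assuming a
  direction.
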