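import pytest

from exaptmap import FBASolver, ToySpec, load_bundled_model, make_toy_universe


@pytest.fixture(scope="session")
def core_model():
    return load_bundled_model()


@pytest.fixture(scope="session")
def core_universe(core_model):
    return core_model[0]


@pytest.fixture(scope="session")
def core_envs(core_model):
    return core_model[1]


@pytest.fixture(scope="session")
def core_solver(core_universe):
    return FBASolver(core_universe)


@pytest.fixture(scope="session")
def core_thresholds(core_solver, core_envs):
    return core_solver.viability_thresholds(core_envs)


def chain_spec(length: int, seed: int = 0) -> ToySpec:
    """A single linear pathway of the given length from one carbon source."""
    return ToySpec(
        n_internal=length, n_pathways=1, pathway_lengths=(length,),
        n_carbon_sources=1, byproduct_rate=0.0, seed=seed,
    )


def parallel_spec(j: int, k: int, seed: int = 0) -> ToySpec:
    """Two disjoint parallel pathways of lengths j and k from one source."""
    return ToySpec(
        n_internal=j + k, n_pathways=2, pathway_lengths=(j, k),
        n_carbon_sources=1, byproduct_rate=0.0, share_prob=0.0, seed=seed,
    )


def toy_corpus(n: int = 20):
    """Reproducible corpus of small universes spanning shapes and sizes."""
    specs = []
    for seed in range(1, n + 1):
        import random

        rng = random.Random(1000 + seed)
        n_src = rng.randint(1, 3)
        n_path = rng.randint(n_src, n_src + 2)
        n_internal = rng.randint(max(6, n_path), 12)
        lengths = _partition(rng, n_internal, n_path)
        specs.append(
            ToySpec(
                n_internal=n_internal,
                n_pathways=n_path,
                pathway_lengths=tuple(lengths),
                n_carbon_sources=n_src,
                byproduct_rate=rng.choice([0.0, 0.2, 0.4]),
                share_prob=rng.choice([0.0, 0.5, 0.8]),
                seed=seed,
            )
        )
    return specs


def _partition(rng, total, parts):
    while True:
        cuts = sorted(rng.sample(range(1, total), parts - 1)) if parts > 1 else []
        bounds = [0] + cuts + [total]
        lengths = [b - a for a, b in zip(bounds, bounds[1:])]
        if all(l >= 1 for l in lengths):
            return lengths
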