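import numpy as np
import pytest

from wgnam.probs import FounderProbabilities
from wgnam.simulate import preset_scenario
from wgnam.types import (
    Family,
    FounderGenotypes,
    GeneticMap,
    LineGenotypes,
    NamDesign,
)


@pytest.fixture(scope="session")
def toy_map() -> GeneticMap:
    return GeneticMap(
        marker_ids=("m1", "m2", "m3", "m4"),
        linkage_groups=("1A", "1A", "1A", "2A"),
        positions=np.array([0.0, 10.0, 25.0, 5.0]),
    )


@pytest.fixture(scope="session")
def toy_founders() -> FounderGenotypes:
    # F1 is the reference; F2, F3 are donors
    calls = np.array([
        [0, 0, 2, 0],   # Ref
        [2, 0, 0, 2],   # D1
        [2, 2, 2, 0],   # D2
    ], dtype=np.int8)
    return FounderGenotypes(founder_ids=("Ref", "D1", "D2"), calls=calls)


@pytest.fixture(scope="session")
def toy_design() -> NamDesign:
    return NamDesign(
        families=(Family("famA", donor="D1", reference="Ref"),
                  Family("famB", donor="D2", reference="Ref")),
        membership={"L1": "famA", "L2": "famA", "L3": "famB", "L4": "famB"},
    )


@pytest.fixture(scope="session")
def toy_lines() -> LineGenotypes:
    calls = np.array([
        [2, 0, 0, 2],   # L1: D1 everywhere
        [0, 0, 2, 1],   # L2: Ref at m1/m3, het at m4
        [2, 2, 2, 0],   # L3: D2 everywhere
        [0, -1, 2, 0],  # L4: Ref at m1, missing at m2
    ], dtype=np.int8)
    return LineGenotypes(line_ids=("L1", "L2", "L3", "L4"), calls=calls)


@pytest.fixture(scope="session")
def null_bundle():
    """One small-but-realistic simulated bundle under the no-QTL scenario."""
    return preset_scenario("null", seed=202, n_per_family=40)


def random_prob_cube(rng: np.random.Generator, n_g: int, n_m: int,
                     n_f: int = 3) -> FounderProbabilities:
    """Fully informative 0/1 probability cube over two parents per line."""
    p = np.zeros((n_g, n_m, n_f))
    donor = rng.integers(1, n_f, size=n_g)  # founder 0 is the reference
    pick = rng.random((n_g, n_m)) < 0.5
    for i in range(n_g):
        p[i, pick[i], donor[i]] = 1.0
        p[i, ~pick[i], 0] = 1.0
    return FounderProbabilities(
        p=p,
        line_ids=tuple(f"L{i}" for i in range(n_g)),
        marker_ids=tuple(f"m{j}" for j in range(n_m)),
        founder_ids=tuple(f"F{l}" for l in range(n_f)),
    )
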