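import numpy as np
import pytest

from comdp import MutationMatrix

# hand-checkable 5-sample, 6-gene cohort used throughout:
# g1/g2 and g3/g4 form two perfectly exclusive pairs covering s1..s4 with
# identical joint coverage; g5 and g6 share the single-sample profile {s5}
F1_MUTATIONS = {
    "g1": ["s1", "s2"],
    "g2": ["s3", "s4"],
    "g3": ["s1", "s3"],
    "g4": ["s2", "s4"],
    "g5": ["s5"],
    "g6": ["s5"],
}


def make_matrix(mutations: dict, samples=None) -> MutationMatrix:
    if samples is None:
        samples = sorted({s for ss in mutations.values() for s in ss})
    genes = list(mutations)
    cells = np.zeros((len(samples), len(genes)), dtype=np.uint8)
    si = {s: i for i, s in enumerate(samples)}
    for j, g in enumerate(genes):
        for s in mutations[g]:
            cells[si[s], j] = 1
    return MutationMatrix(tuple(samples), tuple(genes), cells)


@pytest.fixture
def f1() -> MutationMatrix:
    return make_matrix(F1_MUTATIONS, samples=["s1", "s2", "s3", "s4", "s5"])


def random_matrix(rng: np.random.Generator, m: int, n: int) -> MutationMatrix:
    """Random binary matrix guaranteed to have no all-zero gene column."""
    cells = (rng.random((m, n)) < rng.uniform(0.15, 0.5)).astype(np.uint8)
    for j in range(n):
        if not cells[:, j].any():
            cells[rng.integers(0, m), j] = 1
    samples = tuple(f"s{i}" for i in range(m))
    genes = tuple(f"g{j}" for j in range(n))
    return MutationMatrix(samples, genes, cells)
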