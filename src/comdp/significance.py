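"""Permutation tests for pathway and co-occurrence significance.

The null model permutes each gene column independently across samples, so
every gene keeps its mutation count |Γ(g)| while all within-sample
structure is destroyed.  The identified gene sets are held fixed (they are
found once on the observed matrix); each permutation only re-evaluates the
statistic:

* individual significance — the Dendrix weight W of one set; large W under
  the observed matrix relative to the null indicates jointly high coverage
  and exclusivity.  A single-gene set has permutation-invariant W (its
  column sum), so its p-value is exactly 1.
* co-occurrence significance — the co-occurrence ratio c/b of the pair.

p-values use the add-one estimator p = (1 + #exceedances) / (1 + B), so
p ∈ (0, 1] and never 0.  Because the statistic of a fixed gene set depends
only on that set's columns, only those columns are permuted; the null
distribution is identical to permuting the full matrix.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .core import MutationMatrix, weight_W

__all__ = [
    "permute_matrix",
    "individual_significance",
    "cooccurrence_significance",
]


def permute_matrix(A: MutationMatrix, rng_seed: int) -> MutationMatrix:
    """Independently permute each gene column; column sums are preserved."""
    rng = np.random.default_rng(rng_seed)
    cells = rng.permuted(A.cells, axis=0)
    return MutationMatrix(A.samples, A.genes, cells)


def _permuted_columns(cols: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.permuted(cols, axis=0)


def individual_significance(
    A: MutationMatrix, S: Iterable[str], B: int, rng_seed: int
) -> float:
    """p-value for the exclusivity-and-coverage weight W of one gene set."""
    S = list(S)
    if not S:
        raise ValueError("gene set must be nonempty")
    if B < 1:
        raise ValueError(f"number of permutations B must be >= 1; got {B}")
    idx = A.gene_indices(S)
    cols = A.cells[:, idx].astype(bool)
    col_total = int(A.column_sums[idx].sum())
    observed = 2 * int(cols.any(axis=1).sum()) - col_total
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(B):
        perm = _permuted_columns(cols, rng)
        w = 2 * int(perm.any(axis=1).sum()) - col_total
        if w >= observed:
            exceed += 1
    return (1 + exceed) / (1 + B)


def cooccurrence_significance(
    A: MutationMatrix,
    S: Iterable[str],
    T: Iterable[str],
    B: int,
    rng_seed: int,
) -> float:
    """p-value for the co-occurrence ratio c/b of a disjoint pair."""
    S, T = list(S), list(T)
    if not S or not T:
        raise ValueError("both gene sets must be nonempty")
    if set(S) & set(T):
        raise ValueError("gene sets must be disjoint")
    if B < 1:
        raise ValueError(f"number of permutations B must be >= 1; got {B}")
    idx_s = A.gene_indices(S)
    idx_t = A.gene_indices(T)
    cols_s = A.cells[:, idx_s].astype(bool)
    cols_t = A.cells[:, idx_t].astype(bool)

    def ratio(cs: np.ndarray, ct: np.ndarray) -> float:
        ms = cs.any(axis=1)
        mt = ct.any(axis=1)
        b = int((ms | mt).sum())
        return int((ms & mt).sum()) / b if b else 0.0

    observed = ratio(cols_s, cols_t)
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(B):
        ps = _permuted_columns(cols_s, rng)
        pt = _permuted_columns(cols_t, rng)
        if ratio(ps, pt) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + B)
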