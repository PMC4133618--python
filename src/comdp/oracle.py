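"""Brute-force maximizer of the pairwise objective on small instances.

Ground truth for the MILP: enumerates every unordered pair of disjoint
gene sets (S, T) with |S| + |T| = k — including the degenerate pairs with
an empty T — and returns the maximum H.  Deliberately unpruned so it stays
trivially auditable; guarded against non-desk-scale inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .core import MutationMatrix, pair_stats

__all__ = ["OracleResult", "exhaustive_best_pair"]


@dataclass(frozen=True)
class OracleResult:
    best_pair: tuple[frozenset, frozenset]
    best_H: float
    n_evaluated: int


def exhaustive_best_pair(
    A: MutationMatrix,
    k: int,
    lam: float,
    eta: float,
    max_n: int = 15,
    max_k: int = 6,
) -> OracleResult:
    """Maximize H(S, T; λ, η) over all disjoint pairs with |S|+|T| = k.

    Enumeration is lexicographic over k-gene combinations, then over the
    binary S/T assignment; each unordered pair is evaluated once (the
    lexicographically first gene of the combination is pinned to S), so
    n_evaluated = C(n, k) · 2^(k−1).
    """
    if not (1 <= k <= A.n):
        raise ValueError(f"k={k} out of range [1, {A.n}]")
    if A.n > max_n or k > max_k:
        raise ValueError(
            f"instance too large for exhaustive search (n={A.n}>{max_n} or "
            f"k={k}>{max_k}); use the MILP solver instead"
        )
    best_H = None
    best_pair = (frozenset(), frozenset())
    n_eval = 0
    for combo in combinations(A.genes, k):
        # first gene pinned to S: each unordered split visited exactly once
        for mask in range(2 ** (k - 1)):
            S = [combo[0]]
            T = []
            for pos in range(1, k):
                (S if (mask >> (pos - 1)) & 1 == 0 else T).append(combo[pos])
            st = pair_stats(A, S, T, lam, eta)
            n_eval += 1
            if best_H is None or st.H > best_H:
                best_H = st.H
                best_pair = (frozenset(S), frozenset(T))
    return OracleResult(best_pair=best_pair, best_H=float(best_H), n_evaluated=n_eval)


def exhaustive_best_single(A: MutationMatrix, k: int, max_n: int = 15, max_k: int = 6):
    """Maximum Dendrix weight W over all single k-gene sets (BLP reference)."""
    from .core import weight_W

    if A.n > max_n or k > max_k:
        raise ValueError("instance too large for exhaustive search")
    best = None
    best_set = frozenset()
    for combo in combinations(A.genes, k):
        w = weight_W(A, combo)
        if best is None or w > best:
            best, best_set = w, frozenset(combo)
    return best_set, best
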