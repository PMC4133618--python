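"""Exact binary linear programs for co-occurring driver-pathway discovery.

Two programs are built over a binary mutation matrix ``A`` (m samples ×
n genes):

* ``solve_comdp`` — pick two disjoint gene sets S, T with |S|+|T| = k that
  maximize H(S, T; λ, η) = λ·c + η·d − ω(S) − ω(T).  In terms of the
  indicator variables u_j, v_j (gene j in S resp. T), x_i, y_i (sample i
  covered by S resp. T) and z_i = x_i ∧ y_i, the objective is linear:

      G = (1+η)·(Σx + Σy) + (λ−2η)·Σz − Σ_j (u_j+v_j)·|Γ(g_j)|

* ``solve_mod_comdp`` — the same objective with S frozen to a known gene
  set C; only the r-gene partner D is optimized.

The coverage indicators are tied to the gene indicators from both sides
(x_i ≥ A_ij·u_j and x_i ≤ Σ_j A_ij·u_j, likewise for y, and the standard
AND linearization for z) because the objective coefficients (1+η) and
(λ−2η) change sign across the useful (λ, η) regimes, so neither direction
can be left to the optimizer.

The backend is HiGHS branch-and-bound via ``scipy.optimize.milp``, run to
proven optimality (relative MIP gap 1e-9).  A time-limit hit or any other
non-optimal termination is reported as an error status, never as a
solution.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import MutationMatrix, PairStats, pair_stats

__all__ = ["PairResult", "solve_comdp", "solve_mod_comdp", "combine_nominal"]

_DEFAULT_TIME_LIMIT = 600.0
_MIP_GAP = 1e-9


def _solver_options(lam: float, eta: float, time_limit: float,
                    extra: Mapping | None = None) -> dict:
    """HiGHS options proving optimality as cheaply as possible.

    With integer λ and η every objective coefficient is an integer, so an
    absolute branch-and-bound gap just below 1 already certifies the
    optimum; otherwise fall back to a near-zero relative gap.  Remaining
    ``solver_options`` entries are forwarded to HiGHS verbatim.
    """
    opts = {"time_limit": time_limit, "mip_rel_gap": _MIP_GAP, "disp": False}
    if float(lam).is_integer() and float(eta).is_integer():
        opts["mip_abs_gap"] = 1.0 - 1e-6
    opts.update(extra or {})
    return opts


def _run_milp(obj: np.ndarray, constraints, nvar: int, options: dict):
    """Maximize obj over binary vectors; silences the verbatim-option warning."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*passed to HiGHS verbatim.*")
        return milp(
            c=-obj,
            constraints=constraints,
            integrality=np.ones(nvar),
            bounds=Bounds(0, 1),
            options=options,
        )


@dataclass(frozen=True)
class PairResult:
    """Outcome of one CoMDP / mod_CoMDP solve."""

    set1: frozenset
    set2: frozenset
    stats: PairStats | None
    objective: float | None
    solver_status: str  # "optimal" | "infeasible" | "error"
    runtime_seconds: float
    mode: str = "comdp"

    def to_record(self, **extra) -> dict:
        rec = {
            "mode": self.mode,
            "set1": sorted(self.set1),
            "set2": sorted(self.set2),
            "solver_status": self.solver_status,
            "runtime_seconds": self.runtime_seconds,
        }
        if self.stats is not None:
            s = asdict(self.stats)
            rec.update(
                n1=s["n1"], n2=s["n2"], c=s["c"], b=s["b"], d=s["d"],
                ratio=s["ratio"], W1=s["w1"], W2=s["w2"], H=s["H"],
                **{"lambda": s["lam"], "eta": s["eta"]},
            )
        rec.update(extra)
        return rec


def _canonical_pair(genes1: set, genes2: set) -> tuple[frozenset, frozenset]:
    """set1 holds the lexicographically smallest gene of the union."""
    if not genes1 and not genes2:
        return frozenset(), frozenset()
    all_genes = genes1 | genes2
    lead = min(all_genes)
    if lead in genes2:
        genes1, genes2 = genes2, genes1
    return frozenset(genes1), frozenset(genes2)


def _coupling_rows(A_csc: sparse.csc_matrix, n: int, m: int, u_off: int, x_off: int,
                   nvar: int) -> list[LinearConstraint]:
    """x_i ≥ A_ij·u_j for every nonzero, and x_i ≤ Σ_j A_ij·u_j."""
    rows_lo = []  # u_j − x_i ≤ 0 per nonzero entry
    coo = A_csc.tocoo()
    k = coo.nnz
    data = np.concatenate([np.ones(k), -np.ones(k)])
    r = np.concatenate([np.arange(k), np.arange(k)])
    c = np.concatenate([u_off + coo.col, x_off + coo.row])
    lo = sparse.csr_matrix((data, (r, c)), shape=(k, nvar))
    rows_lo.append(LinearConstraint(lo, -np.inf, 0.0))
    # x_i − Σ_j A_ij u_j ≤ 0, one row per sample
    up = sparse.hstack(
        [
            sparse.csr_matrix((m, u_off)),
            -A_csc,
            sparse.csr_matrix((m, x_off - u_off - n)),
            sparse.eye(m, format="csr"),
            sparse.csr_matrix((m, nvar - x_off - m)),
        ],
        format="csr",
    )
    rows_lo.append(LinearConstraint(up, -np.inf, 0.0))
    return rows_lo


def _solve_single_set(A: MutationMatrix, k: int, time_limit: float,
                      extra: Mapping | None = None):
    """Exact max-W over k-gene sets (the Dendrix/BLP program) via MILP."""
    m, n = A.m, A.n
    nvar = n + m  # u (gene picked) | x (sample covered)
    obj = np.zeros(nvar)
    obj[:n] = -A.column_sums.astype(float)
    obj[n:] = 2.0
    A_csc = sparse.csc_matrix(A.cells.astype(float))
    card = np.zeros(nvar)
    card[:n] = 1.0
    constraints = [LinearConstraint(sparse.csr_matrix(card), k, k)]
    constraints += _coupling_rows(A_csc, n, m, 0, n, nvar)
    res = _run_milp(obj, constraints, nvar, _solver_options(0, 0, time_limit, extra))
    if res.status != 0:
        return None, res.status
    u = np.round(res.x[:n]).astype(bool)
    return {A.genes[j] for j in np.flatnonzero(u)}, 0


def solve_comdp(
    A: MutationMatrix,
    k: int,
    lam: float = 10.0,
    eta: float = -2.0,
    solver_options: Mapping | None = None,
) -> PairResult:
    """Solve the two-set program to proven optimality.

    Either returned set may be empty: for strongly exclusivity-driven
    regimes (λ<0, η=1) the optimum often places all k genes in one set,
    which is exactly the single-set maximum-weight submatrix solution.

    For η=1 the objective collapses algebraically: using b = |Γ(S)|+|Γ(T)|−c
    and ω(S)+ω(T) = Σ_{S∪T}|Γ(g)| − (b+c),

        H = λ·c + b − ω(S) − ω(T) = W(S∪T) + λ·c,

    so when additionally λ < 0 an optimal solution is (argmax_U W(U), ∅)
    with c = 0: the pair program is solved exactly through the much smaller
    single-set maximum-weight program.
    """
    if not (2 <= k <= A.n):
        raise ValueError(f"k={k} out of range [2, {A.n}]")
    opts = dict(solver_options or {})
    time_limit = float(opts.pop("time_limit", _DEFAULT_TIME_LIMIT))

    if eta == 1.0 and lam < 0:
        t0 = time.perf_counter()
        best, status = _solve_single_set(A, k, time_limit, opts)
        runtime = time.perf_counter() - t0
        if best is None:
            label = "infeasible" if status == 2 else "error"
            return PairResult(frozenset(), frozenset(), None, None, label,
                              runtime, "comdp")
        set1, set2 = _canonical_pair(best, set())
        stats = pair_stats(A, set1, set2, lam, eta)
        return PairResult(set1, set2, stats, float(stats.H), "optimal",
                          runtime, "comdp")

    m, n = A.m, A.n
    # variable layout: u (n) | v (n) | x (m) | y (m) | z (m); the z block is
    # omitted when its objective coefficient λ−2η vanishes (it is then
    # unconstrained in effect and only inflates the program)
    with_z = (lam - 2.0 * eta) != 0.0
    nvar = 2 * n + (3 if with_z else 2) * m
    u_off, v_off, x_off, y_off, z_off = 0, n, 2 * n, 2 * n + m, 2 * n + 2 * m

    col_sums = A.column_sums.astype(float)
    obj = np.zeros(nvar)
    obj[u_off:u_off + n] = -col_sums
    obj[v_off:v_off + n] = -col_sums
    obj[x_off:x_off + m] = 1.0 + eta
    obj[y_off:y_off + m] = 1.0 + eta
    if with_z:
        obj[z_off:z_off + m] = lam - 2.0 * eta

    A_csc = sparse.csc_matrix(A.cells.astype(float))  # float: uint8 would overflow under negation
    constraints = []
    # Σ_j (u_j + v_j) = k
    card = np.zeros(nvar)
    card[:2 * n] = 1.0
    constraints.append(LinearConstraint(sparse.csr_matrix(card), k, k))
    # u_j + v_j ≤ 1 (disjoint sets)
    disj = sparse.hstack(
        [sparse.eye(n), sparse.eye(n), sparse.csr_matrix((n, nvar - 2 * n))],
        format="csr",
    )
    constraints.append(LinearConstraint(disj, -np.inf, 1.0))
    constraints += _coupling_rows(A_csc, n, m, u_off, x_off, nvar)
    constraints += _coupling_rows(A_csc, n, m, v_off, y_off, nvar)
    if with_z:
        # z_i ≤ x_i, z_i ≤ y_i, z_i ≥ x_i + y_i − 1
        I = sparse.eye(m, format="csr")
        Zn = sparse.csr_matrix((m, n))
        Zm = sparse.csr_matrix((m, m))
        constraints.append(
            LinearConstraint(sparse.hstack([Zn, Zn, -I, Zm, I], format="csr"),
                             -np.inf, 0.0)
        )
        constraints.append(
            LinearConstraint(sparse.hstack([Zn, Zn, Zm, -I, I], format="csr"),
                             -np.inf, 0.0)
        )
        constraints.append(
            LinearConstraint(sparse.hstack([Zn, Zn, I, I, -I], format="csr"),
                             -np.inf, 1.0)
        )
    t0 = time.perf_counter()
    res = _run_milp(obj, constraints, nvar, _solver_options(lam, eta, time_limit, opts))
    runtime = time.perf_counter() - t0
    if res.status != 0:
        status = "infeasible" if res.status == 2 else "error"
        return PairResult(frozenset(), frozenset(), None, None, status, runtime, "comdp")

    u = np.round(res.x[u_off:u_off + n]).astype(bool)
    v = np.round(res.x[v_off:v_off + n]).astype(bool)
    S = {A.genes[j] for j in np.flatnonzero(u)}
    T = {A.genes[j] for j in np.flatnonzero(v)}
    set1, set2 = _canonical_pair(S, T)
    stats = pair_stats(A, set1, set2, lam, eta)
    return PairResult(set1, set2, stats, float(stats.H), "optimal", runtime, "comdp")


def solve_mod_comdp(
    A: MutationMatrix,
    C: Iterable[str],
    r: int,
    lam: float = 10.0,
    eta: float = -2.0,
    solver_options: Mapping | None = None,
) -> PairResult:
    """Find the r-gene set D that best co-occurs with a fixed known set C.

    With the C-side coverage fixed, the AND indicator z_i reduces to y_i on
    the rows Γ(C) and to 0 elsewhere, so the program only carries the v and
    y variables.
    """
    C = list(dict.fromkeys(C))
    if not C:
        raise ValueError("known gene set C must be nonempty")
    c_idx = A.gene_indices(C)  # raises on unknown genes
    free = [g for g in A.genes if g not in set(C)]
    if not (1 <= r <= len(free)):
        raise ValueError(f"r={r} out of range [1, {len(free)}]")
    opts = dict(solver_options or {})
    time_limit = float(opts.pop("time_limit", _DEFAULT_TIME_LIMIT))

    sub = A.subset_genes(free)
    m, n = sub.m, sub.n
    x_fixed = A.cells[:, c_idx].any(axis=1)  # Γ(C) indicator

    # variable layout: v (n) | y (m)
    nvar = n + m
    obj = np.zeros(nvar)
    obj[:n] = -sub.column_sums.astype(float)
    obj[n:] = (1.0 + eta) + (lam - 2.0 * eta) * x_fixed

    A_csc = sparse.csc_matrix(sub.cells.astype(float))
    constraints = []
    card = np.zeros(nvar)
    card[:n] = 1.0
    constraints.append(LinearConstraint(sparse.csr_matrix(card), r, r))
    constraints += _coupling_rows(A_csc, n, m, 0, n, nvar)

    t0 = time.perf_counter()
    res = _run_milp(obj, constraints, nvar, _solver_options(lam, eta, time_limit, opts))
    runtime = time.perf_counter() - t0
    if res.status != 0:
        status = "infeasible" if res.status == 2 else "error"
        return PairResult(frozenset(C), frozenset(), None, None, status, runtime, "mod_comdp")

    v = np.round(res.x[:n]).astype(bool)
    D = frozenset(sub.genes[j] for j in np.flatnonzero(v))
    stats = pair_stats(A, C, D, lam, eta)
    return PairResult(frozenset(C), D, stats, float(stats.H), "optimal", runtime, "mod_comdp")


def combine_nominal(
    A: MutationMatrix, sets: list[Iterable[str]], name: str
) -> MutationMatrix:
    """Append a nominal gene mutated where *all* given sets are mutated.

    The nominal column's support is the intersection of the sets'
    coverages; it represents the joint disruption of several pathways and
    lets the pairwise program chain to a third (and further) pathway.
    """
    sets = [list(s) for s in sets]
    if not sets or any(not s for s in sets):
        raise ValueError("combine_nominal requires a nonempty list of nonempty gene sets")
    if name in A.genes:
        raise ValueError(f"duplicate gene identifier: {name!r}")
    mask = np.ones(A.m, dtype=bool)
    for s in sets:
        idx = A.gene_indices(s)
        mask &= A.cells[:, idx].any(axis=1)
    if not mask.any():
        warnings.warn(
            f"nominal gene {name!r} has empty support (sets never co-occur)",
            stacklevel=2,
        )
    cells = np.column_stack([A.cells, mask.astype(np.uint8)])
    return MutationMatrix(A.samples, A.genes + (name,), cells)
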