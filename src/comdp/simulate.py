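"""Synthetic mutation-matrix generators with ground-truth bookkeeping.

Three generators emulate cohorts with planted driver pathways:

* ``sim_data1`` — m×n matrix (default 500×1000) with I=10 disjoint 10-gene
  sets M_i.  For each sample, set M_i is "covered" with probability
  p_i = 1 − i·Δ (Δ=0.05): one uniformly chosen driver gene of M_i is
  mutated, and each other member is additionally mutated with the noise
  probability p0 (default 0.04).  Genes outside every M_i are passengers,
  mutated in at most three samples each.
* ``sim_data2`` — a Sim_data1-style dataset per point of a p0 grid
  (default 0.04 … 0.24 in steps of 0.02), to probe how exclusivity decays
  with noise.
* ``sim_data3`` — r×s matrix (default 600×1000) with J=9 planted 5-gene
  sets N_i that are active only on the sample prefix 1..m_i,
  m_i = ⌊r/2⌋ + 2^(i−1); the nested prefixes make (N_1, N_2) the maximally
  co-occurring pair, which is what the pairwise program should find.

The generators model neither copy-number vs point-mutation event types,
tumor subtypes, nor inter-tumor heterogeneity: every sample follows the
same per-set Bernoulli law.

Also here: recovery scoring against the planted truth and the iterative
discovery loop (solve, remove the found genes, repeat) used to collect
multiple pathways.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import MutationMatrix
from .ilp import PairResult, solve_comdp

__all__ = [
    "SimulationTruth",
    "sim_data1",
    "sim_data2",
    "sim_data3",
    "recovery_score",
    "iterative_discovery",
]


@dataclass(frozen=True)
class EmbeddedSet:
    genes: tuple[str, ...]
    p: float  # per-sample coverage probability p_i
    rows: tuple[int, int]  # active sample range [start, stop) (0-based)


@dataclass(frozen=True)
class SimulationTruth:
    embedded_sets: tuple[EmbeddedSet, ...]
    params: dict
    seed: int

    def gene_sets(self) -> list[frozenset]:
        return [frozenset(s.genes) for s in self.embedded_sets]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sets": [asdict(s) for s in self.embedded_sets],
            "params": self.params,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        sets = tuple(
            EmbeddedSet(tuple(s["genes"]), s["p"], tuple(s["rows"]))
            for s in payload["sets"]
        )
        return cls(sets, payload["params"], payload["seed"])


def _fill_embedded_block(
    cells: np.ndarray,
    rng: np.random.Generator,
    cols: np.ndarray,
    n_rows: int,
    p: float,
    p0: float,
) -> None:
    """Plant one driver set on rows 0..n_rows−1 over the given columns."""
    size = len(cols)
    covered = rng.random(n_rows) < p
    drivers = rng.integers(0, size, size=n_rows)
    extra = rng.random((n_rows, size)) < p0
    block = extra
    block[np.arange(n_rows), drivers] = True
    block &= covered[:, None]
    cells[:n_rows, cols] |= block


def _fill_passengers(
    cells: np.ndarray, rng: np.random.Generator, cols: Iterable[int], m: int
) -> None:
    """Each passenger gene mutated in U ~ Uniform{1,2,3} distinct samples."""
    for j in cols:
        u = int(rng.integers(1, 4))
        rows = rng.choice(m, size=u, replace=False)
        cells[rows, j] = True


def _ids(prefix: str, count: int) -> tuple[str, ...]:
    width = len(str(count))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(count))


def sim_data1(
    m: int = 500,
    n: int = 1000,
    I: int = 10,
    delta: float = 0.05,
    p0: float = 0.04,
    seed: int = 0,
) -> tuple[MutationMatrix, SimulationTruth]:
    """Cohort with I planted 10-gene driver sets of decaying coverage."""
    set_size = 10
    if I * set_size > n:
        raise ValueError(f"I·10 = {I * set_size} exceeds gene count n = {n}")
    if not 0 < delta * I < 1:
        raise ValueError(f"need 0 < I·delta < 1; got {I * delta}")
    if not 0 <= p0 < 1:
        raise ValueError(f"noise probability p0 must be in [0, 1); got {p0}")
    rng = np.random.default_rng(seed)
    cells = np.zeros((m, n), dtype=bool)
    genes = _ids("g", n)
    samples = _ids("s", m)
    sets = []
    for i in range(1, I + 1):
        cols = np.arange((i - 1) * set_size, i * set_size)
        p_i = 1.0 - i * delta
        _fill_embedded_block(cells, rng, cols, m, p_i, p0)
        sets.append(EmbeddedSet(tuple(genes[j] for j in cols), p_i, (0, m)))
    _fill_passengers(cells, rng, range(I * set_size, n), m)
    truth = SimulationTruth(
        tuple(sets),
        {"m": m, "n": n, "I": I, "delta": delta, "p0": p0, "kind": "sim_data1"},
        seed,
    )
    return MutationMatrix(samples, genes, cells.astype(np.uint8)), truth


_DEFAULT_P0_GRID = tuple(np.round(np.arange(0.04, 0.2401, 0.02), 2))


def sim_data2(
    p0_grid: Sequence[float] = _DEFAULT_P0_GRID,
    m: int = 500,
    n: int = 1000,
    I: int = 10,
    delta: float = 0.05,
    seed: int = 0,
) -> list[tuple[MutationMatrix, SimulationTruth]]:
    """One Sim_data1-style dataset per noise level, fresh sub-seed each."""
    if len(p0_grid) == 0:
        raise ValueError("p0 grid must be nonempty")
    children = np.random.SeedSequence(seed).spawn(len(p0_grid))
    out = []
    for p0, child in zip(p0_grid, children):
        sub_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        out.append(sim_data1(m=m, n=n, I=I, delta=delta, p0=float(p0), seed=sub_seed))
    return out


def sim_data3(
    r: int = 600,
    s: int = 1000,
    J: int = 9,
    n0: int = 5,
    delta: float = 0.05,
    p0: float = 0.04,
    seed: int = 0,
) -> tuple[MutationMatrix, SimulationTruth]:
    """Cohort with J sample-nested planted sets for co-occurrence benchmarks.

    Set N_i (n0 genes) is active on samples 1..m_i with
    m_i = ⌊r/2⌋ + 2^(i−1) — (301, 302, 304, ..., 556) at the defaults — and
    follows the sim_data1 coverage rule with p_i = 1 − i·δ on those rows.
    """
    if J * n0 > s:
        raise ValueError(f"J·n0 = {J * n0} exceeds gene count s = {s}")
    if not 0 < delta * J < 1:
        raise ValueError(f"need 0 < J·delta < 1; got {J * delta}")
    rng = np.random.default_rng(seed)
    cells = np.zeros((r, s), dtype=bool)
    genes = _ids("g", s)
    samples = _ids("s", r)
    sets = []
    for i in range(1, J + 1):
        m_i = r // 2 + 2 ** (i - 1)
        if m_i > r:
            raise ValueError(f"active prefix m_{i} = {m_i} exceeds sample count {r}")
        cols = np.arange((i - 1) * n0, i * n0)
        p_i = 1.0 - i * delta
        _fill_embedded_block(cells, rng, cols, m_i, p_i, p0)
        sets.append(EmbeddedSet(tuple(genes[j] for j in cols), p_i, (0, m_i)))
    _fill_passengers(cells, rng, range(J * n0, s), r)
    truth = SimulationTruth(
        tuple(sets),
        {"r": r, "s": s, "J": J, "n0": n0, "delta": delta, "p0": p0,
         "kind": "sim_data3"},
        seed,
    )
    return MutationMatrix(samples, genes, cells.astype(np.uint8)), truth


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def recovery_score(
    found: Sequence, truth: SimulationTruth
) -> tuple[int, list[float]]:
    """Score discovered sets against the planted truth.

    ``found`` may mix plain gene sets and (set1, set2) pairs / PairResults.
    A truth set counts as exactly matched when it equals a found set, either
    half of a found pair, or the union of a pair (the solver may split one
    planted set across both sides with zero common coverage).  The second
    return value is the best Jaccard index per truth set.
    """
    candidates: list[frozenset] = []
    for item in found:
        if isinstance(item, PairResult):
            parts = [item.set1, item.set2]
        elif isinstance(item, tuple) and len(item) == 2 and not isinstance(item, str):
            parts = [frozenset(item[0]), frozenset(item[1])]
        else:
            parts = [frozenset(item)]
        parts = [p for p in parts if p]
        candidates.extend(parts)
        if len(parts) == 2:
            candidates.append(parts[0] | parts[1])
    exact = 0
    jaccards = []
    for true_set in truth.gene_sets():
        best = max((_jaccard(true_set, c) for c in candidates), default=0.0)
        jaccards.append(best)
        if any(c == true_set for c in candidates):
            exact += 1
    return exact, jaccards


def iterative_discovery(
    A: MutationMatrix,
    k: int,
    lam: float,
    eta: float,
    rounds: int,
    solver_options=None,
) -> list[PairResult]:
    """Repeatedly solve, strip the found genes, and re-solve.

    Stops early when fewer than k genes remain or a solve fails (partial
    results are returned; the failed round's error result is appended so
    callers can see the flag).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    results: list[PairResult] = []
    current = A
    for _ in range(rounds):
        if current.n < k:
            break
        res = solve_comdp(current, k, lam, eta, solver_options=solver_options)
        results.append(res)
        if res.solver_status != "optimal":
            break
        found = res.set1 | res.set2
        remaining = [g for g in current.genes if g not in found]
        if not remaining:
            break
        current = current.subset_genes(remaining)
    return results
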