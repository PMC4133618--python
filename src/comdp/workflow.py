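"""High-level experiment drivers: k-sweeps, the nominal-gene multi-pathway
loop, and the simulation-study protocols.

Every reported row recomputes its statistics from the raw matrix through
:mod:`comdp.core` rather than trusting solver-side values, and carries the
seeds and permutation counts used, so report tables are reproducible
bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MutationMatrix, collapse_metagenes, pair_stats
from .ilp import PairResult, combine_nominal, solve_comdp, solve_mod_comdp
from .significance import cooccurrence_significance, individual_significance
from .simulate import iterative_discovery, recovery_score, sim_data2, sim_data3

__all__ = ["RunConfig", "run_sweep", "run_multi_pathway", "run_simulation_study"]

logger = logging.getLogger("comdp")

SWEEP_COLUMNS = ["k", "gene_set_1", "gene_set_2", "p1", "p2", "n1", "n2", "r12", "p12"]


@dataclass
class RunConfig:
    """Shared knobs for a sweep / multi-pathway / simulation-study run."""

    k_min: int = 4
    k_max: int = 10
    r: int = 5
    lam: float = 10.0
    eta: float = -2.0
    permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05
    time_limit: float = 600.0

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError(f"invalid k range ({self.k_min}, {self.k_max})")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1]; got {self.alpha}")

    @property
    def solver_options(self) -> dict:
        return {"time_limit": self.time_limit}


def _fmt_set(genes: Iterable[str]) -> str:
    return ",".join(sorted(genes))


def run_sweep(A: MutationMatrix, config: RunConfig) -> pd.DataFrame:
    """Solve for each k in the configured range and report the table layout
    (k, gene sets, individual p-values, coverages, co-occurrence ratio and
    its p-value) used for cohort results.

    Metagenes are collapsed once before the sweep; a per-k solver error is
    recorded in its row and the sweep continues.
    """
    collapsed, metagenes = collapse_metagenes(A)
    if metagenes:
        logger.info("collapsed %d metagenes", len(metagenes))
    if config.k_max > collapsed.n:
        raise ValueError(
            f"k_max={config.k_max} exceeds {collapsed.n} gene columns after collapse"
        )
    rows = []
    for k in range(config.k_min, config.k_max + 1):
        res = solve_comdp(
            collapsed, k, config.lam, config.eta, solver_options=config.solver_options
        )
        logger.info(
            "k=%d lambda=%g eta=%g -> status=%s H=%s runtime=%.2fs",
            k, config.lam, config.eta, res.solver_status, res.objective,
            res.runtime_seconds,
        )
        if res.solver_status != "optimal":
            rows.append({"k": k, "gene_set_1": f"<{res.solver_status}>",
                         "gene_set_2": "", "p1": np.nan, "p2": np.nan,
                         "n1": np.nan, "n2": np.nan, "r12": np.nan, "p12": np.nan})
            continue
        st = pair_stats(collapsed, res.set1, res.set2, config.lam, config.eta)
        B = config.permutations
        p1 = individual_significance(collapsed, res.set1, B, config.seed) \
            if res.set1 else np.nan
        p2 = individual_significance(collapsed, res.set2, B, config.seed + 1) \
            if res.set2 else np.nan
        p12 = (
            cooccurrence_significance(collapsed, res.set1, res.set2, B, config.seed + 2)
            if res.set1 and res.set2 else np.nan
        )
        rows.append({
            "k": k,
            "gene_set_1": _fmt_set(res.set1),
            "gene_set_2": _fmt_set(res.set2),
            "p1": round(p1, 4), "p2": round(p2, 4),
            "n1": st.n1, "n2": st.n2,
            "r12": round(st.ratio, 4),
            "p12": round(p12, 4) if not np.isnan(p12) else np.nan,
        })
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def run_multi_pathway(
    A: MutationMatrix,
    config: RunConfig,
    seed_set: Iterable[str] | str = "auto",
    max_rounds: int = 5,
) -> list[dict]:
    """Chain pathway discovery through nominal genes.

    Round 1 fixes the seed set (or set1 of an initial solve when "auto")
    and finds its best r-gene partner.  Each later round combines all
    accepted sets into one nominal gene — mutated only where every accepted
    set is mutated — and finds the best partner of the nominal gene.  A
    partner is accepted when its co-occurrence p-value is ≤ alpha.
    """
    if seed_set == "auto":
        init = solve_comdp(
            A, config.k_min, config.lam, config.eta,
            solver_options=config.solver_options,
        )
        if init.solver_status != "optimal" or not init.set1:
            raise RuntimeError(f"initial solve failed: {init.solver_status}")
        current_sets = [sorted(init.set1)]
    else:
        seed_set = list(seed_set)
        A.gene_indices(seed_set)  # raises naming unknown genes
        current_sets = [seed_set]

    reports: list[dict] = []
    matrix = A
    anchor_genes = list(current_sets[0])
    for round_no in range(1, max_rounds + 1):
        if round_no > 1:
            nominal = f"NOMINAL_{round_no}"
            matrix = combine_nominal(matrix, current_sets, nominal)
            if matrix.column_sums[matrix.gene_indices([nominal])[0]] == 0:
                logger.warning("nominal gene has empty support; stopping")
                break
            anchor_genes = [nominal]
        exclude = {g for s in current_sets for g in s} | set(anchor_genes)
        free = [g for g in matrix.genes if g not in exclude]
        if len(free) < config.r:
            break
        res = solve_mod_comdp(
            matrix, anchor_genes, config.r, config.lam, config.eta,
            solver_options=config.solver_options,
        )
        if res.solver_status != "optimal":
            reports.append({"round": round_no, "status": res.solver_status})
            break
        p12 = cooccurrence_significance(
            matrix, anchor_genes, res.set2, config.permutations,
            config.seed + round_no,
        )
        accepted = bool(p12 <= config.alpha)
        reports.append({
            "round": round_no,
            "anchor": _fmt_set(anchor_genes),
            "partner": _fmt_set(res.set2),
            "ratio": round(res.stats.ratio, 4),
            "p12": round(p12, 4),
            "accepted": accepted,
            "status": "optimal",
        })
        if not accepted:
            break
        current_sets.append(sorted(res.set2))
    return reports


def run_simulation_study(
    protocol: str,
    config: RunConfig,
    p0_grid: Sequence[float] | None = None,
    eta_grid: Sequence[float] | None = None,
    replicates: int = 1,
    sim_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run one of the two simulation protocols.

    ``protocol="sim2"``: per noise level p0, generate a cohort, run the
    iterative discovery loop, and report the number of planted sets
    recovered exactly.  ``protocol="sim3"``: on one nested-prefix cohort,
    solve once per η grid point (λ fixed) and report coverages, common
    coverage, and co-occurrence ratio.
    """
    sim_kwargs = dict(sim_kwargs or {})
    if protocol == "sim2":
        grid = list(p0_grid if p0_grid is not None else
                    np.round(np.arange(0.04, 0.2401, 0.02), 2))
        rows = []
        for rep in range(replicates):
            datasets = sim_data2(p0_grid=grid, seed=config.seed + rep, **sim_kwargs)
            for (A, truth), p0 in zip(datasets, grid):
                results = iterative_discovery(
                    A, k=config.k_min, lam=config.lam, eta=config.eta,
                    rounds=len(truth.embedded_sets),
                    solver_options=config.solver_options,
                )
                exact, jac = recovery_score(results, truth)
                rows.append({"replicate": rep, "p0": p0, "exact_matches": exact,
                             "mean_jaccard": float(np.mean(jac))})
        df = pd.DataFrame(rows)
        return df
    if protocol == "sim3":
        etas = list(eta_grid if eta_grid is not None else [config.eta])
        A, truth = sim_data3(seed=config.seed, **sim_kwargs)
        rows = []
        for eta in etas:
            res = solve_comdp(
                A, config.k_min, config.lam, eta,
                solver_options=config.solver_options,
            )
            if res.solver_status != "optimal":
                rows.append({"lambda": config.lam, "eta": eta,
                             "status": res.solver_status})
                continue
            st = res.stats
            rows.append({
                "lambda": config.lam, "eta": eta, "status": "optimal",
                "n1": st.n1, "n2": st.n2, "c": st.c, "b": st.b,
                "ratio": round(st.ratio, 4), "H": st.H,
            })
        return pd.DataFrame(rows)
    raise ValueError(f"unknown protocol {protocol!r}; expected 'sim2' or 'sim3'")
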