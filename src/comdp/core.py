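"""Mutation-matrix data model and coverage/exclusivity statistics.

A study cohort is represented as a binary matrix ``A`` with ``m`` sample rows
and ``n`` gene columns; ``A[i, j] = 1`` means gene ``j`` carries a somatic
alteration (point mutation or CNA, pre-binarized upstream) in sample ``i``.
All pathway scores used by the optimizers are derived from two set-valued
primitives on this matrix:

* the coverage ``Γ(S)`` of a gene set ``S`` — the samples in which at least
  one member is altered, and
* the coverage overlap ``ω(S) = Σ_{g∈S}|Γ(g)| − |Γ(S)|`` — the excess of
  per-gene mutation counts over the coverage, zero iff the members are
  perfectly mutually exclusive.

The single-set Dendrix weight is ``W(S) = |Γ(S)| − ω(S)``, and the pairwise
objective for two disjoint sets is

    H(S, T; λ, η) = λ·c + η·d − ω(S) − ω(T)

where ``c`` is the common coverage (samples hit by both sets), ``b`` the
union coverage, and ``d = b − c`` the non-shared coverage.  ``λ>0, η<0``
rewards co-occurring pairs; ``λ=2, η=1`` collapses to ``W(S)+W(T)``
(the Multi-Dendrix objective); ``λ<0, η=1`` degenerates to single-set
weight maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationMatrix",
    "Metagene",
    "PairStats",
    "load_matrix",
    "collapse_metagenes",
    "coverage",
    "weight_W",
    "pair_stats",
]

GeneSet = frozenset  # gene sets are plain frozensets of gene identifiers


@dataclass(frozen=True)
class MutationMatrix:
    """Binary sample × gene incidence matrix with identifier-based addressing."""

    samples: tuple[str, ...]
    genes: tuple[str, ...]
    cells: np.ndarray  # uint8, shape (m, n), values in {0, 1}

    def __post_init__(self) -> None:
        cells = np.ascontiguousarray(self.cells, dtype=np.uint8)
        object.__setattr__(self, "cells", cells)
        m, n = cells.shape
        if m < 1 or n < 1:
            raise ValueError("mutation matrix must have at least one sample and one gene")
        if len(self.samples) != m or len(self.genes) != n:
            raise ValueError("identifier lists do not match matrix shape")
        _check_unique(self.samples, "sample")
        _check_unique(self.genes, "gene")
        if cells.max(initial=0) > 1:
            i, j = np.argwhere(cells > 1)[0]
            raise ValueError(
                f"non-binary cell at sample {self.samples[i]!r}, gene {self.genes[j]!r}"
            )

    @property
    def m(self) -> int:
        return self.cells.shape[0]

    @property
    def n(self) -> int:
        return self.cells.shape[1]

    @property
    def column_sums(self) -> np.ndarray:
        """Per-gene mutation counts |Γ(g)|."""
        return self.cells.sum(axis=0, dtype=np.int64)

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: j for j, g in enumerate(self.genes)}
        idx = []
        for g in genes:
            if g not in lookup:
                raise KeyError(f"unknown gene identifier: {g!r}")
            idx.append(lookup[g])
        return np.asarray(sorted(idx), dtype=np.intp)

    def subset_genes(self, genes: Sequence[str]) -> "MutationMatrix":
        """Matrix restricted to the given gene columns (order preserved from input)."""
        lookup = {g: j for j, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene identifier: {missing[0]!r}")
        idx = np.asarray([lookup[g] for g in genes], dtype=np.intp)
        return MutationMatrix(self.samples, tuple(genes), self.cells[:, idx])

    def drop_genes(self, genes: Iterable[str]) -> "MutationMatrix":
        drop = set(genes)
        keep = [g for g in self.genes if g not in drop]
        return self.subset_genes(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.samples), columns=list(self.genes))

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample"
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class Metagene:
    """Genes with bitwise-identical mutation profiles merged into one column."""

    name: str
    members: tuple[str, ...]

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


@dataclass(frozen=True)
class PairStats:
    """All scalar statistics of a disjoint gene-set pair at given (λ, η)."""

    c: int  # common coverage |Γ(S) ∩ Γ(T)|
    b: int  # union coverage  |Γ(S) ∪ Γ(T)|
    d: int  # non-shared coverage b − c
    ratio: float  # co-occurrence ratio c/b (0 when b = 0)
    n1: int  # |Γ(S)|
    n2: int  # |Γ(T)|
    w1: int  # Dendrix weight W(S)
    w2: int  # Dendrix weight W(T)
    H: float  # λ·c + η·d − ω(S) − ω(T)
    lam: float = field(default=10.0)
    eta: float = field(default=-2.0)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


def load_matrix(path: str | Path, format: str = "matrix") -> MutationMatrix:
    """Read a mutation matrix from disk.

    ``format="matrix"``: TSV with a header line ``sample<TAB>gene1<TAB>...``
    and one 0/1 row per sample.  ``format="pairs"``: two-column TSV of
    ``sample<TAB>gene`` events (no header); a cell is 1 iff the pair occurs
    at least once.
    """
    path = Path(path)
    if format == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"empty mutation matrix in {path}")
        samples = tuple(str(s) for s in df.index)
        genes = tuple(str(g) for g in df.columns)
        _check_unique(samples, "sample")
        _check_unique(genes, "gene")
        cells = np.zeros(df.shape, dtype=np.uint8)
        for i in range(df.shape[0]):
            for j, v in enumerate(df.iloc[i]):
                v = str(v).strip()
                if v not in ("0", "1"):
                    # 1-based coordinates counting the header row and sample column
                    raise ValueError(
                        f"non-binary cell {v!r} at file row {i + 2}, column {j + 2} "
                        f"(sample {samples[i]!r}, gene {genes[j]!r})"
                    )
                cells[i, j] = int(v)
        return MutationMatrix(samples, genes, cells)
    if format == "pairs":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[0] == 0:
            raise ValueError(f"empty event list in {path}")
        if df.shape[1] < 2:
            raise ValueError("pairs format requires two columns: sample<TAB>gene")
        samples = tuple(dict.fromkeys(str(s) for s in df[0]))
        genes = tuple(dict.fromkeys(str(g) for g in df[1]))
        si = {s: i for i, s in enumerate(samples)}
        gi = {g: j for j, g in enumerate(genes)}
        cells = np.zeros((len(samples), len(genes)), dtype=np.uint8)
        for s, g in zip(df[0], df[1]):
            cells[si[str(s)], gi[str(g)]] = 1
        return MutationMatrix(samples, genes, cells)
    raise ValueError(f"unknown format {format!r}; expected 'matrix' or 'pairs'")


def collapse_metagenes(A: MutationMatrix) -> tuple[MutationMatrix, list[Metagene]]:
    """Merge genes with identical mutation profiles into metagenes.

    Genes sharing a bitwise-identical column are replaced by a single column
    named ``g1|g2|...`` (members joined in input order).  All-zero columns
    cannot enter any optimal solution and are dropped.  Singleton genes pass
    through unchanged and do not appear in the returned metagene list.
    """
    groups: dict[bytes, list[int]] = {}
    for j in range(A.n):
        col = A.cells[:, j]
        if not col.any():
            continue
        groups.setdefault(col.tobytes(), []).append(j)
    if not groups:
        raise ValueError("matrix has no mutated gene after dropping all-zero columns")
    names: list[str] = []
    cols: list[np.ndarray] = []
    metagenes: list[Metagene] = []
    for key, idx in groups.items():
        members = tuple(A.genes[j] for j in idx)
        name = "|".join(members)
        names.append(name)
        cols.append(A.cells[:, idx[0]])
        if len(members) >= 2:
            metagenes.append(Metagene(name=name, members=members))
    out = MutationMatrix(A.samples, tuple(names), np.column_stack(cols))
    return out, metagenes


def write_metagene_map(metagenes: Iterable[Metagene], path: str | Path) -> None:
    """Write the metagene → member mapping as two-column TSV."""
    with open(path, "w") as fh:
        fh.write("metagene\tmember\n")
        for mg in metagenes:
            for member in mg.members:
                fh.write(f"{mg.name}\t{member}\n")


def _coverage_mask(A: MutationMatrix, S: Iterable[str]) -> np.ndarray:
    genes = list(S)
    if not genes:
        return np.zeros(A.m, dtype=bool)
    idx = A.gene_indices(genes)
    return A.cells[:, idx].any(axis=1)


def coverage(A: MutationMatrix, S: Iterable[str]) -> frozenset:
    """Γ(S): the set of samples in which at least one gene of S is mutated."""
    mask = _coverage_mask(A, S)
    return frozenset(A.samples[i] for i in np.flatnonzero(mask))


def weight_W(A: MutationMatrix, S: Iterable[str]) -> int:
    """Dendrix weight W(S) = |Γ(S)| − ω(S) = 2|Γ(S)| − Σ_{g∈S}|Γ(g)|."""
    genes = list(S)
    if not genes:
        return 0
    idx = A.gene_indices(genes)
    cov = int(A.cells[:, idx].any(axis=1).sum())
    total = int(A.column_sums[idx].sum())
    return 2 * cov - total


def _omega(A: MutationMatrix, genes: list[str]) -> int:
    if not genes:
        return 0
    idx = A.gene_indices(genes)
    cov = int(A.cells[:, idx].any(axis=1).sum())
    return int(A.column_sums[idx].sum()) - cov


def pair_stats(
    A: MutationMatrix,
    S: Iterable[str],
    T: Iterable[str],
    lam: float = 10.0,
    eta: float = -2.0,
) -> PairStats:
    """Coverage statistics and objective H for a disjoint pair of gene sets."""
    S, T = list(S), list(T)
    if set(S) & set(T):
        overlap = sorted(set(S) & set(T))
        raise ValueError(f"gene sets must be disjoint; shared: {overlap}")
    mask_s = _coverage_mask(A, S)
    mask_t = _coverage_mask(A, T)
    c = int((mask_s & mask_t).sum())
    b = int((mask_s | mask_t).sum())
    d = b - c
    ratio = c / b if b > 0 else 0.0
    w1 = weight_W(A, S)
    w2 = weight_W(A, T)
    H = lam * c + eta * d - _omega(A, S) - _omega(A, T)
    return PairStats(
        c=c, b=b, d=d, ratio=ratio,
        n1=int(mask_s.sum()), n2=int(mask_t.sum()),
        w1=w1, w2=w2, H=float(H), lam=lam, eta=eta,
    )
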