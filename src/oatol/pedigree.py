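"""Pedigree containers and additive-relationship algebra.

A :class:`Pedigree` records parent links for founders (wild-caught,
strip-spawned adults, assumed unrelated and non-inbred) and their
offspring.  The expected additive relationship between two individuals —
1 for self, 0.5 for full sibs and parent/offspring, 0.25 for half sibs —
is what lets an animal model translate phenotypic similarity of relatives
into an additive genetic (co)variance estimate.

The numerator relationship matrix A is built with the tabular method, its
inverse with Henderson's rules (exact for non-inbred pedigrees), and a
Monte-Carlo gene-dropping estimator is provided as an independent oracle.
"""

from __future__ import annotations

import warnings
from collections import deque
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse


class PedigreeError(ValueError):
    """Malformed pedigree: unresolved parents, cycles, duplicates."""


def _clean(v) -> str | None:
    if v is None:
        return None
    if isinstance(v, float) and np.isnan(v):
        return None
    s = str(v).strip()
    return s if s else None


class Pedigree:
    """An ordered pedigree with optional sire/dam links.

    Individuals are stored in topological order (parents before
    offspring); input order is arbitrary.  Founders have both parents
    unknown.  Self-ancestry (a cycle in the parent graph) is an error.
    """

    def __init__(self, ids: Sequence, sires: Sequence, dams: Sequence):
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        if not (len(ids) == len(sires) == len(dams)):
            raise PedigreeError("ids, sires, dams must have equal length")
        raw_index = {v: k for k, v in enumerate(ids)}
        parents = []
        for s, d in zip(sires, dams):
            s, d = _clean(s), _clean(d)
            for p in (s, d):
                if p is not None and p not in raw_index:
                    raise PedigreeError(f"unknown parent id {p!r}")
            parents.append((s, d))

        order = self._toposort(ids, parents, raw_index)
        self.ids: list[str] = [ids[k] for k in order]
        self._index = {v: k for k, v in enumerate(self.ids)}
        self.sire = np.array(
            [-1 if parents[k][0] is None else self._index[parents[k][0]] for k in order],
            dtype=np.int64,
        )
        self.dam = np.array(
            [-1 if parents[k][1] is None else self._index[parents[k][1]] for k in order],
            dtype=np.int64,
        )

    @staticmethod
    def _toposort(ids, parents, raw_index):
        n = len(ids)
        children = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for k, (s, d) in enumerate(parents):
            for p in (s, d):
                if p is not None:
                    children[raw_index[p]].append(k)
                    indeg[k] += 1
        queue = deque(k for k in range(n) if indeg[k] == 0)
        order = []
        while queue:
            k = queue.popleft()
            order.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            raise PedigreeError("cyclic pedigree: an individual is its own ancestor")
        return order

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def index(self, individual) -> int:
        return self._index[str(individual)]

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(df["id"], df["sire"], df["dam"])

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": ["" if s < 0 else self.ids[s] for s in self.sire],
                "dam": ["" if d < 0 else self.ids[d] for d in self.dam],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def additive_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method.

    ``A[i, j] = 0.5 * (A[i, sire(j)] + A[i, dam(j)])`` with founders
    unrelated and non-inbred; the diagonal is ``1 + 0.5 * A[sire, dam]``.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[s, :j]
        if d >= 0:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """F = diag(A) - 1; zero throughout for a single-generation cross."""
    return np.diag(additive_relationship_matrix(ped)) - 1.0


def a_inverse(ped: Pedigree, as_dense: bool = False):
    """Sparse inverse of A via Henderson's rules (non-inbred pedigrees).

    The Mendelian-sampling variance of individual *j* is 1, 3/4 or 1/2
    according to whether 0, 1 or 2 parents are known; its reciprocal is
    scattered over (j, sire, dam).  If inbreeding is detected the rules
    are no longer exact and we fall back to dense inversion of the
    tabular A, with a warning.
    """
    F = inbreeding_coefficients(ped)
    if np.any(F > 1e-12):
        warnings.warn(
            "inbred pedigree: Henderson's non-inbred rules are inexact; "
            "falling back to dense inversion",
            stacklevel=2,
        )
        Ainv = np.linalg.inv(additive_relationship_matrix(ped))
        return Ainv if as_dense else sparse.csr_matrix(Ainv)

    n = len(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        known = [p for p in (s, d) if p >= 0]
        alpha = {0: 1.0, 1: 4.0 / 3.0, 2: 2.0}[len(known)]
        add(j, j, alpha)
        for p in known:
            add(j, p, -alpha / 2.0)
            add(p, j, -alpha / 2.0)
            add(p, p, alpha / 4.0)
        if len(known) == 2:
            add(s, d, alpha / 4.0)
            add(d, s, alpha / 4.0)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv.toarray() if as_dense else Ainv


def gene_drop_kinship(ped: Pedigree, n_reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo estimate of A by gene dropping.

    Each founder receives two uniquely labelled alleles; every offspring
    inherits one random allele from each parent.  Averaging the
    identity-by-descent indicator over the four allele pairings of a pair
    of individuals estimates their kinship, and twice that estimates the
    additive relationship.  Standard error scales as 1/sqrt(n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ped)
    alleles = np.empty((n_reps, n, 2), dtype=np.int32)
    rep_idx = np.arange(n_reps)
    next_label = 0
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        for slot, p in enumerate((s, d)):
            if p < 0:
                alleles[:, j, slot] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_reps)
                alleles[:, j, slot] = alleles[rep_idx, p, pick]
    est = np.empty((n, n))
    for i in range(n):
        ai = alleles[:, i, :]
        for j in range(i, n):
            aj = alleles[:, j, :]
            ibd = (ai[:, :, None] == aj[:, None, :]).mean(axis=(1, 2))
            # kinship = mean IBD over the four allele pairings; A = 2*kinship
            # (the two guaranteed self-pairings give the diagonal its 1)
            est[i, j] = est[j, i] = 2.0 * ibd.mean()
    return est
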