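"""Pedigree handling and the inverse numerator relationship matrix.

The additive genetic prior of the animal model is MVN(0, G ⊗ A), where A is
the numerator relationship matrix implied by the pedigree.  Only A⁻¹ is ever
needed by the sampler; it is sparse and is assembled directly from pedigree
rules (Henderson's rules with inbreeding; Quaas–Westell phantom-parent rows
when genetic groups are present).  A dense tabular-method construction of A
itself is provided purely as a test oracle.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .model import PedigreeError


@dataclass
class PedigreeTable:
    """Recoded pedigree: codes 1..N, parent 0 = unknown, negative = group.

    Rows are stored in the user's order; ``order`` is a topological
    permutation (parents before offspring) used by downstream algorithms, so
    input files need not be pre-sorted.
    """

    sire: np.ndarray
    dam: np.ndarray
    order: np.ndarray = field(init=False)
    group_codes: np.ndarray = field(init=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = self.sire.shape[0]
        if self.dam.shape[0] != n:
            raise PedigreeError("sire and dam vectors differ in length")
        for arr in (self.sire, self.dam):
            bad = arr[arr > n]
            if bad.size:
                raise PedigreeError(
                    f"parent code {int(bad[0])} exceeds the number of "
                    f"individuals ({n}) and is not a genetic group"
                )
        groups = np.unique(np.concatenate([self.sire, self.dam]))
        self.group_codes = groups[groups < 0]
        self.order = _topological_order(self.sire, self.dam)

    @property
    def n_individuals(self) -> int:
        return self.sire.shape[0]

    @property
    def n_groups(self) -> int:
        return self.group_codes.shape[0]

    def group_column(self, code: int) -> int:
        """0-based column of a (negative) group code in the augmented matrix."""
        j = np.searchsorted(self.group_codes, code)
        if j >= self.n_groups or self.group_codes[j] != code:
            raise PedigreeError(f"unknown group code {code}")
        return self.n_individuals + int(j)


def _topological_order(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Kahn's algorithm on parent->offspring edges; detects cycles."""
    n = sire.shape[0]
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p > 0:
                if p == i + 1:
                    raise PedigreeError(f"individual {i + 1} is its own parent")
                children[p - 1].append(i)
                indeg[i] += 1
    stack = [i for i in range(n) if indeg[i] == 0]
    out = np.empty(n, dtype=np.int64)
    k = 0
    while stack:
        i = stack.pop()
        out[k] = i
        k += 1
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if k != n:
        raise PedigreeError("pedigree contains a cycle (an individual is its own ancestor)")
    return out


def compute_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients F_i = A_ii - 1.

    F_i is the kinship of the parents, computed by the recursive kinship
    definition with memoisation (exact; group and unknown parents contribute
    zero kinship).  Cost is proportional to the number of distinct ancestor
    pairs visited, which is small for livestock-shaped pedigrees.
    """
    sire, dam = ped.sire, ped.dam
    rank = np.empty(ped.n_individuals, dtype=np.int64)
    rank[ped.order] = np.arange(ped.n_individuals)
    cache: dict[tuple[int, int], float] = {}

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * ped.n_individuals + 1000))

    def kin(i: int, j: int) -> float:
        # codes are 1-based; 0 / negative -> unrelated
        if i <= 0 or j <= 0:
            return 0.0
        if rank[i - 1] > rank[j - 1]:
            i, j = j, i
        key = (i, j)
        v = cache.get(key)
        if v is not None:
            return v
        if i == j:
            v = 0.5 * (1.0 + kin(sire[i - 1], dam[i - 1]))
        else:
            # j is the younger: recurse on j's parents
            v = 0.5 * (kin(i, sire[j - 1]) + kin(i, dam[j - 1]))
        cache[key] = v
        return v

    F = np.empty(ped.n_individuals)
    for i in ped.order:
        F[i] = kin(sire[i], dam[i])
    return F


@dataclass
class AInverse:
    """Sparse A⁻¹ (augmented with group rows/columns when groups exist)."""

    matrix: sparse.csr_matrix
    inbreeding: np.ndarray
    n_individuals: int
    n_groups: int

    @property
    def size(self) -> int:
        return self.n_individuals + self.n_groups


def build_a_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> AInverse:
    """Assemble sparse A⁻¹ by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of individual i is
    d_i = 0.5 - 0.25 (F_s + F_d) with both real parents known,
    d_i = 0.75 - 0.25 F_p with one, and 1 with none.  Genetic-group
    (phantom-parent) codes enter the rule contributions like parents but are
    treated as unknown when computing d_i (Quaas–Westell).
    """
    if F is None:
        F = compute_inbreeding(ped)
    n, g = ped.n_individuals, ped.n_groups
    size = n + g
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        contrib = [(i, 1.0)]
        d = 1.0
        for p in (ped.sire[i], ped.dam[i]):
            if p > 0:
                contrib.append((p - 1, -0.5))
                d -= 0.25 * (1.0 + F[p - 1])
            elif p < 0:
                contrib.append((ped.group_column(p), -0.5))
        b = 1.0 / d
        for u, cu in contrib:
            for v, cv in contrib:
                rows.append(u)
                cols.append(v)
                vals.append(b * cu * cv)
    m = sparse.coo_matrix((vals, (rows, cols)), shape=(size, size)).tocsr()
    return AInverse(matrix=m, inbreeding=F, n_individuals=n, n_groups=g)


def build_a_tabular(ped: PedigreeTable) -> np.ndarray:
    """Dense A by the recursive tabular method — test oracle only."""
    if ped.n_groups:
        raise PedigreeError("tabular A is not defined with genetic groups")
    n = ped.n_individuals
    A = np.zeros((n, n))
    for i in ped.order:
        s, d = ped.sire[i] - 1, ped.dam[i] - 1  # -1 -> unknown
        for j in ped.order:
            if j == i:
                break
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A
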