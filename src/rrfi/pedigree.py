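"""Pedigree bookkeeping and the numerator relationship matrix.

The additive-genetic covariance of an animal model is ``G0 (x) A``, where
``A`` is the numerator relationship matrix over all animals in the pedigree.
This module validates and topologically sorts raw pedigrees, builds ``A``
by the tabular method, computes inbreeding coefficients with the
Meuwissen-Luo recursion, and assembles the sparse inverse of ``A`` directly
from pedigree rules (Henderson's method, inbreeding-corrected).

Unknown parents are treated as unrelated founders; no genetic-group
structure is fitted.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = 0  # sentinel for an unknown parent in raw input files

__all__ = [
    "PedigreeTable",
    "RelationshipStructure",
    "validate_and_sort_pedigree",
    "relationship_matrix",
    "relationship_inverse",
    "inbreeding",
    "read_pedigree",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates)."""


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree.

    ``sire`` and ``dam`` hold positional indices into ``ids`` (or -1 for an
    unknown parent), so every parent index is smaller than its offspring's
    position.
    """

    ids: np.ndarray            # original labels, in sorted order
    sire: np.ndarray           # int positions, -1 = unknown
    dam: np.ndarray            # int positions, -1 = unknown
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._pos:
            self._pos = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def position(self, animal_id) -> int:
        return self._pos[animal_id]

    def positions(self, animal_ids) -> np.ndarray:
        return np.array([self._pos[a] for a in animal_ids], dtype=np.int64)


@dataclass
class RelationshipStructure:
    """Additive relationships derived from a pedigree.

    diag(a_matrix) = 1 + F, and a_matrix @ a_inverse = I to numerical
    tolerance whenever both are filled.
    """

    pedigree: PedigreeTable
    a_matrix: np.ndarray | None = None
    a_inverse: sparse.csr_matrix | None = None
    inbreeding: np.ndarray | None = None


def validate_and_sort_pedigree(raw) -> PedigreeTable:
    """Validate animal/sire/dam triples and sort parents before offspring.

    Parameters
    ----------
    raw : iterable of (animal, sire, dam)
        Unknown parents coded as ``0`` or ``None``. A parent appearing only
        in a parent column is added as a founder.

    Raises
    ------
    PedigreeError
        On duplicate animal ids or a pedigree loop (an animal among its own
        ancestors), naming the offending id.
    """
    rows = [(a, s, d) for a, s, d in raw]
    seen = set()
    for a, _, _ in rows:
        if a in seen:
            raise PedigreeError(f"duplicate animal id: {a!r}")
        seen.add(a)

    def known(x):
        return x is not None and x != UNKNOWN

    parents: dict = {}
    order = []  # stable: founders implied by parent columns first
    for a, s, d in rows:
        for p in (s, d):
            if known(p) and p not in seen and p not in parents:
                parents[p] = (None, None)
                order.append(p)
        parents[a] = (s if known(s) else None, d if known(d) else None)
        order.append(a)

    # Kahn topological sort, preserving input order among ready animals.
    children: dict = {a: [] for a in order}
    indeg = {a: 0 for a in order}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    ready = [a for a in order if indeg[a] == 0]
    sorted_ids = []
    head = 0
    while head < len(ready):
        a = ready[head]
        head += 1
        sorted_ids.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(sorted_ids) != len(order):
        bad = [a for a in order if indeg[a] > 0]
        raise PedigreeError(f"pedigree loop involving id {bad[0]!r}")

    pos = {a: i for i, a in enumerate(sorted_ids)}
    sire = np.full(len(sorted_ids), -1, dtype=np.int64)
    dam = np.full(len(sorted_ids), -1, dtype=np.int64)
    for a, (s, d) in parents.items():
        i = pos[a]
        if s is not None:
            sire[i] = pos[s]
        if d is not None:
            dam[i] = pos[d]
    return PedigreeTable(ids=np.asarray(sorted_ids), sire=sire, dam=dam, _pos=pos)


def _check_sorted(ped: PedigreeTable) -> None:
    idx = np.arange(ped.n)
    if np.any(ped.sire >= idx) or np.any(ped.dam >= idx):
        raise PedigreeError("pedigree is not sorted: a parent follows its offspring")


def relationship_matrix(ped: PedigreeTable) -> RelationshipStructure:
    """Dense numerator relationship matrix A by the tabular method.

    a(i,j) = 0.5 (a(j, s_i) + a(j, d_i)) for j < i and
    a(i,i) = 1 + 0.5 a(s_i, d_i); unknown parents contribute 0.
    """
    _check_sorted(ped)
    n = ped.n
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipStructure(pedigree=ped, a_matrix=a, inbreeding=np.diag(a) - 1.0)


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo recursion.

    Computes diag(A) - 1 without forming A, traversing each animal's
    ancestor list; O(n * ancestors^2) but cheap on desk-scale pedigrees.
    """
    _check_sorted(ped)
    n = ped.n
    F = np.empty(n)
    dvar = np.empty(n)  # Mendelian (within-family) variance scale d_i
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            dvar[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            dvar[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            dvar[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # a_ii = sum_j L_ij^2 d_j over ancestors j of i (including i).
        coeff = {i: 1.0}
        aii = 0.0
        # process ancestors in decreasing index order
        heap = [-i]
        inheap = {i}
        while heap:
            j = -heapq.heappop(heap)
            inheap.discard(j)
            c = coeff.pop(j)
            aii += c * c * dvar[j]
            for p in (ped.sire[j], ped.dam[j]):
                if p >= 0:
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * c
                    if p not in inheap:
                        heapq.heappush(heap, -p)
                        inheap.add(p)
        F[i] = aii - 1.0
    return F


def relationship_inverse(
    ped: PedigreeTable, f: np.ndarray | None = None
) -> RelationshipStructure:
    """Sparse inverse of A assembled directly from pedigree rules.

    Uses the inbreeding-corrected rules: for each animal i the Mendelian
    variance b_i = 0.5 - 0.25 (F_s + F_d) (with the obvious adjustment for
    unknown parents) contributes 1/b_i to (i,i), -1/(2 b_i) to the
    animal-parent cells and 1/(4 b_i) to the parent-parent cells.
    """
    _check_sorted(ped)
    if f is None:
        f = inbreeding(ped)
    n = ped.n
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            b = 0.5 - 0.25 * (f[s] + f[d])
        elif s >= 0 or d >= 0:
            b = 0.75 - 0.25 * f[max(s, d)]
        else:
            b = 1.0
        alpha = 1.0 / b
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        ps = [p for p in (s, d) if p >= 0]
        for p in ps:
            for q in ps:
                add(p, q, 0.25 * alpha)
    ainv = sparse.csr_matrix(
        (np.array(vals), (np.array(rows), np.array(cols))), shape=(n, n)
    )
    ainv.sum_duplicates()
    return RelationshipStructure(pedigree=ped, a_inverse=ainv, inbreeding=f)


def read_pedigree(path) -> PedigreeTable:
    """Read a 3-column delimited pedigree file (animal, sire, dam; 0 = unknown).

    A header row is detected and skipped if the first field is not numeric.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    first = str(df.iloc[0, 0])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    trip = df.iloc[:, :3].astype(np.int64)
    return validate_and_sort_pedigree(trip.itertuples(index=False, name=None))
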