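"""Pedigree relationships.

The numerator relationship matrix ``A`` holds the additive genetic
relationship between every pair of animals; its diagonal is ``1 + F`` with
``F`` the inbreeding coefficient.  The genomic models downstream only need
the genotyped-animal submatrix ``A22`` and its lower Cholesky factor ``L``
(``A22 = L L'``), which is how the pedigree enters the residual polygenic
part of the blended relationship matrix.

Unknown parents are treated as unrelated, non-inbred base animals; an
animal with at least one unknown parent has ``F = 0``.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: codes in input files that mean "parent unknown"
UNKNOWN_CODES = {"", "0", ".", "na", "nan", "none", "unknown"}

#: successively larger diagonal boosts tried when a Cholesky attempt fails
JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6)

_HEADER_WORDS = {"animal", "id", "sire", "dam", "father", "mother", "progeny"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class Pedigree:
    """A topologically sorted pedigree.

    ``records`` is an ordered tuple of ``(animal, sire, dam)`` triples with
    ``None`` for an unknown parent.  Every known parent appears as an animal
    earlier in the order, which also rules out cycles.
    """

    records: tuple[tuple[str, str | None, str | None], ...]

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for i, (animal, sire, dam) in enumerate(self.records):
            if animal in seen:
                raise PedigreeError(f"duplicate animal ID {animal!r}")
            for parent in (sire, dam):
                if parent is None:
                    continue
                if parent == animal:
                    raise PedigreeError(f"animal {animal!r} is its own parent")
                if parent not in seen:
                    raise PedigreeError(
                        f"parent {parent!r} of {animal!r} does not precede it; "
                        "pedigree is not topologically sorted"
                    )
            seen[animal] = i

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec[0] for rec in self.records)

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of sire/dam positions, -1 for unknown."""
        pos = {a: i for i, a in enumerate(self.ids)}
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, (_, sire, dam) in enumerate(self.records):
            if sire is not None:
                out[i, 0] = pos[sire]
            if dam is not None:
                out[i, 1] = pos[dam]
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric additive relationship matrix with its animal ordering."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CholeskyFactor:
    """Lower-triangular factor ``L`` with ``L L'`` equal to its source matrix."""

    ids: tuple[str, ...]
    values: np.ndarray
    jitter: float = 0.0


@dataclass(frozen=True)
class InbreedingVector:
    ids: tuple[str, ...]
    F: np.ndarray


def _normalise_parent(token: str) -> str | None:
    token = token.strip()
    return None if token.lower() in UNKNOWN_CODES else token


def _toposort(raw: list[tuple[str, str | None, str | None]]) -> list[tuple[str, str | None, str | None]]:
    """Stable Kahn sort: parents before offspring, file order breaking ties."""
    order = {a: i for i, (a, _, _) in enumerate(raw)}
    record = {a: (a, s, d) for a, s, d in raw}
    pending = {a: sum(p is not None for p in (s, d)) for a, s, d in raw}
    children: dict[str, list[str]] = defaultdict(list)
    for a, s, d in raw:
        for p in (s, d):
            if p is not None:
                children[p].append(a)
    heap = [(order[a], a) for a, k in pending.items() if k == 0]
    heapq.heapify(heap)
    out: list[tuple[str, str | None, str | None]] = []
    while heap:
        _, a = heapq.heappop(heap)
        out.append(record[a])
        for child in children[a]:
            pending[child] -= 1
            if pending[child] == 0:
                heapq.heappush(heap, (order[child], child))
    if len(out) < len(raw):
        emitted = {a for a, _, _ in out}
        start = next(a for a in order if a not in emitted)
        cycle, node = [start], start
        while True:
            _, s, d = record[node]
            node = s if (s is not None and s not in emitted) else d
            if node in cycle:
                cycle.append(node)
                break
            cycle.append(node)
        raise PedigreeError(f"pedigree contains a parent cycle: {' -> '.join(cycle)}")
    return out


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (animal, sire, dam) and topologically sort it.

    Unknown parents are coded ``0`` or empty.  Parents that never appear as
    animals are implicitly added as founders with a warning.  The header row
    is optional.
    """
    df = pd.read_csv(path, header=None, dtype=str, sep=None, engine="python",
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError(f"{path}: expected 3 columns (animal, sire, dam)")
    df = df.iloc[:, :3].fillna("")
    first = [str(c).strip().lower() for c in df.iloc[0]]
    if any(tok in _HEADER_WORDS for tok in first):
        df = df.iloc[1:]
    raw: list[tuple[str, str | None, str | None]] = []
    seen: set[str] = set()
    for animal, sire, dam in df.itertuples(index=False):
        animal = str(animal).strip()
        if not animal:
            continue
        if animal in seen:
            raise PedigreeError(f"duplicate animal ID {animal!r} in {path}")
        seen.add(animal)
        raw.append((animal, _normalise_parent(str(sire)), _normalise_parent(str(dam))))
    phantoms = []
    for _, sire, dam in raw:
        for p in (sire, dam):
            if p is not None and p not in seen:
                seen.add(p)
                phantoms.append(p)
    if phantoms:
        warnings.warn(
            f"{len(phantoms)} parent(s) never defined as animals; added as founders: "
            f"{', '.join(phantoms[:5])}{'...' if len(phantoms) > 5 else ''}",
            stacklevel=2,
        )
        raw = [(p, None, None) for p in phantoms] + raw
    return Pedigree(tuple(_toposort(raw)))


def numerator_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix ``A``.

    Founders get ``A_jj = 1``; with both parents known ``A_jj = 1 + 0.5
    A(s,d)``; off-diagonals are ``A_kj = 0.5 (A_ks + A_kd)`` for earlier
    animals ``k``, unknown parents contributing zero.
    """
    n = len(ped)
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for j in range(n):
        s, d = par[j]
        if j:
            row = np.zeros(j)
            if s >= 0:
                row += A[:j, s]
            if d >= 0:
                row += A[:j, d]
            A[:j, j] = A[j, :j] = 0.5 * row
        A[j, j] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(ped.ids, A)


def _meuwissen_luo_inbreeding(par: np.ndarray) -> np.ndarray:
    # Per-animal ancestor trace of the self-relationship A_ii = sum L^2 D,
    # using the within-family variances D of all ancestors; O(total ancestors)
    # and independent of the dense tabular recursion.
    n = par.shape[0]
    F = np.zeros(n)

    def within_family_variance(j: int) -> float:
        s, d = par[j]
        if s >= 0 and d >= 0:
            return 0.5 - 0.25 * (F[s] + F[d])
        if s >= 0 or d >= 0:
            return 0.75 - 0.25 * F[max(s, d)]
        return 1.0

    for i in range(n):
        s, d = par[i]
        if s < 0 or d < 0:
            continue  # unknown-parent convention: F = 0
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        acc = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            acc += lj * lj * within_family_variance(j)
            for p in par[j]:
                if p >= 0:
                    if p not in L:
                        heapq.heappush(heap, -int(p))
                        L[p] = 0.0
                    L[p] += 0.5 * lj
        F[i] = acc - 1.0
    return F


def inbreeding_coefficients(ped: Pedigree, method: str = "meuwissen-luo") -> InbreedingVector:
    """Per-animal inbreeding coefficients ``F_j = diag(A)_j - 1``.

    ``method="meuwissen-luo"`` traces each animal's ancestors directly;
    ``method="tabular"`` takes the diagonal of the tabular ``A``.  The two
    agree to machine precision.
    """
    if method == "tabular":
        F = np.diag(numerator_relationship_matrix(ped).values) - 1.0
    elif method == "meuwissen-luo":
        F = _meuwissen_luo_inbreeding(ped.parent_indices())
    else:
        raise ValueError(f"unknown inbreeding method {method!r}")
    return InbreedingVector(ped.ids, F)


def subset_A22(A: RelationshipMatrix, genotyped_ids: Sequence[str]) -> RelationshipMatrix:
    """Extract the genotyped-animal block of ``A`` in the given order."""
    genotyped_ids = list(genotyped_ids)
    if not genotyped_ids:
        raise ValueError("genotyped_ids is empty")
    pos = {a: i for i, a in enumerate(A.ids)}
    try:
        idx = np.array([pos[g] for g in genotyped_ids])
    except KeyError as exc:
        raise KeyError(f"genotyped animal {exc.args[0]!r} not in relationship matrix") from None
    return RelationshipMatrix(tuple(genotyped_ids), A.values[np.ix_(idx, idx)])


def cholesky_factor(A22: RelationshipMatrix, jitter: Sequence[float] = JITTER_LADDER) -> CholeskyFactor:
    """Lower Cholesky factor of ``A22``, with a small jitter ladder.

    A pedigree ``A22`` is positive definite in exact arithmetic; the jitter
    only absorbs floating-point noise.  The jitter actually used is logged
    and recorded on the returned factor.
    """
    M = np.asarray(A22.values, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    for jit in jitter:
        try:
            L = np.linalg.cholesky(M + jit * np.eye(M.shape[0]))
        except np.linalg.LinAlgError:
            continue
        if jit > 0:
            logger.info("Cholesky required jitter %.1e on the diagonal", jit)
        return CholeskyFactor(A22.ids, L, jitter=jit)
    raise np.linalg.LinAlgError(
        f"matrix not positive definite even with jitter up to {max(jitter):.1e}"
    )
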