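"""Pedigree handling: validation, inbreeding, and the inverse numerator
relationship matrix.

The additive genetic covariance structure of an animal model is
``Var(u) = A sigma_u^2`` where ``A`` is the numerator relationship matrix of
the pedigree.  The mixed-model equations only ever need ``A^{-1}``, which is
sparse (at most nine contributions per individual) and can be written down
directly from the pedigree with Henderson's rules once every parent's
inbreeding coefficient is known.  This module provides:

* :func:`validate_and_order` -- parse raw rows into a topologically ordered
  pedigree, materialising referenced-but-unlisted parents as founders;
* :func:`inbreeding` -- exact inbreeding coefficients via the
  Meuwissen–Luo recursion;
* :func:`a_inverse` -- sparse ``A^{-1}`` with inbreeding-corrected
  Mendelian-sampling variances;
* :func:`numerator_relationship` -- the dense tabular ``A`` (small pedigrees
  only; useful for cross-checks and teaching);
* :func:`completeness` -- equivalent generations and per-generation ancestor
  completeness.

Unknown parents are treated as unrelated, non-inbred founders throughout
(no genetic-group modelling).  The file sentinel for an unknown parent is
``"0"`` by convention of milk-recording pedigree files; it is configurable
on the I/O helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = ""  # internal sentinel for an unknown parent


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass(frozen=True)
class PedigreeEntry:
    """One individual with parent links and its topological rank."""

    individual_id: str
    sire_id: str  # UNKNOWN if not known
    dam_id: str
    birth_order: int


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree.

    ``entries[i].birth_order == i`` and every known parent precedes its
    offspring.  Dense arrays ``sire`` / ``dam`` hold parent ranks with ``-1``
    for unknown, which is the representation every numeric routine consumes.
    """

    entries: list[PedigreeEntry]
    sire: np.ndarray  # int64, -1 = unknown
    dam: np.ndarray
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.individual_id for e in self.entries]

    def rank(self, individual_id: str) -> int:
        return self.index[individual_id]

    def is_founder(self, i: int) -> bool:
        return self.sire[i] < 0 and self.dam[i] < 0


def validate_and_order(
    rows: Iterable[tuple[str, str, str]], unknown: str = "0"
) -> Pedigree:
    """Validate raw ``(id, sire, dam)`` rows and return an ordered pedigree.

    Parents that are referenced but never listed are materialised as
    founders.  Raises :class:`PedigreeError` on duplicate ids or on a cycle
    in the parent graph (naming one individual on the cycle).
    """
    raw: dict[str, tuple[str, str]] = {}
    for ind, sire, dam in rows:
        ind, sire, dam = str(ind), str(sire), str(dam)
        if ind == unknown:
            raise PedigreeError(f"individual id equals the unknown sentinel {unknown!r}")
        if ind in raw:
            raise PedigreeError(f"duplicate individual id {ind!r}")
        raw[ind] = (
            UNKNOWN if sire == unknown else sire,
            UNKNOWN if dam == unknown else dam,
        )
    # materialise referenced-but-unlisted parents as founders
    for sire, dam in list(raw.values()):
        for p in (sire, dam):
            if p != UNKNOWN and p not in raw:
                raw[p] = (UNKNOWN, UNKNOWN)

    # Kahn's algorithm; ties broken by input order for determinism
    import heapq

    order_hint = {k: i for i, k in enumerate(raw)}
    pending = {k: len({s, d} - {UNKNOWN}) for k, (s, d) in raw.items()}
    children: dict[str, list[str]] = {k: [] for k in raw}
    for k, (s, d) in raw.items():
        for p in {s, d} - {UNKNOWN}:
            children[p].append(k)
    heap = [(order_hint[k], k) for k, npend in pending.items() if npend == 0]
    heapq.heapify(heap)
    ordered: list[str] = []
    while heap:
        _, k = heapq.heappop(heap)
        ordered.append(k)
        for c in children[k]:
            pending[c] -= 1
            if pending[c] == 0:
                heapq.heappush(heap, (order_hint[c], c))
    if len(ordered) < len(raw):
        on_cycle = next(k for k in raw if k not in ordered)
        raise PedigreeError(
            f"cycle in pedigree: individual {on_cycle!r} is its own ancestor"
        )

    index = {k: i for i, k in enumerate(ordered)}
    n = len(ordered)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    entries = []
    for i, k in enumerate(ordered):
        s, d = raw[k]
        if s != UNKNOWN:
            sire[i] = index[s]
        if d != UNKNOWN:
            dam[i] = index[d]
        entries.append(PedigreeEntry(k, s, d, i))
    return Pedigree(entries=entries, sire=sire, dam=dam, index=index)


# ---------------------------------------------------------------------------
# inbreeding (Meuwissen & Luo style exact recursion)
# ---------------------------------------------------------------------------

def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F for every individual, in pedigree order.

    Exact Meuwissen–Luo recursion: for each animal the ancestor list is
    traced, accumulating the coefficients ``L`` of the decomposition
    ``A = L D L'``; then ``1 + F_i = sum_j L_ij^2 d_jj``.  Cost is quadratic
    in the number of ancestors per animal, which is small for the shallow
    pedigrees generated here and acceptable for a few hundred deep ones.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    # Mendelian-sampling d_jj depends on parent F values, filled in order
    d = np.ones(n)
    L = np.zeros(n)  # scratch, indexed by rank
    for i in range(n):
        s, dm = sire[i], dam[i]
        d[i] = _mendelian_d(F, s, dm)
        if s < 0 or dm < 0:
            F[i] = 0.0
            continue
        # trace ancestors of i via parent average coefficients
        L[:] = 0.0
        L[s] += 0.5
        L[dm] += 0.5
        acc = 0.0
        for j in range(max(s, dm), -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
            acc += lj * lj * d[j]
        # 1 + F_i = d_i + sum_{j<i} L_ij^2 d_j, so:
        F[i] = d[i] + acc - 1.0  # equals a(sire,dam)/2
    return F


def _mendelian_d(F: np.ndarray, s: int, d: int) -> float:
    """Mendelian-sampling variance ratio d_ii given parent ranks."""
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s >= 0:
        return 0.75 - 0.25 * F[s]
    if d >= 0:
        return 0.75 - 0.25 * F[d]
    return 1.0


# ---------------------------------------------------------------------------
# A^{-1} by Henderson's rules
# ---------------------------------------------------------------------------

def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse inverse numerator relationship matrix.

    Henderson's rules with inbreeding-corrected Mendelian-sampling
    variances: for individual ``i`` with parents ``s, d`` and
    ``alpha_i = 1/d_ii``, add ``alpha_i`` at (i,i), ``-alpha_i/2`` at (i,s),
    (s,i), (i,d), (d,i), and ``alpha_i/4`` at the four parent blocks —
    at most nine contributions per individual.
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    i_all = np.arange(n)
    dvec = np.array([_mendelian_d(F, sire[i], dam[i]) for i in range(n)])
    if np.any(dvec <= 0):
        bad = int(np.argmax(dvec <= 0))
        raise PedigreeError(
            f"non-positive Mendelian-sampling variance for {ped.ids[bad]!r}; "
            "inbreeding table is corrupt"
        )
    alpha = 1.0 / dvec
    add(i_all, i_all, alpha)
    for parent in (sire, dam):
        m = parent >= 0
        add(i_all[m], parent[m], -0.5 * alpha[m])
        add(parent[m], i_all[m], -0.5 * alpha[m])
        add(parent[m], parent[m], 0.25 * alpha[m])
    both = (sire >= 0) & (dam >= 0)
    add(sire[both], dam[both], 0.25 * alpha[both])
    add(dam[both], sire[both], 0.25 * alpha[both])
    A_inv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    A_inv.sum_duplicates()
    return A_inv


def numerator_relationship(ped: Pedigree) -> np.ndarray:
    """Dense tabular A (use only for small pedigrees; O(n^2) memory)."""
    n = len(ped)
    if n > 5000:
        raise PedigreeError("dense A requested for a pedigree of >5000 individuals")
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return A


# ---------------------------------------------------------------------------
# completeness statistics
# ---------------------------------------------------------------------------

@dataclass
class CompletenessReport:
    equivalent_generations: np.ndarray  # per individual, pedigree order
    generation_completeness: np.ndarray  # fraction known per ancestor generation
    mean_equivalent_generations: float


def completeness(ped: Pedigree, max_gen: int = 14) -> CompletenessReport:
    """Equivalent generations and per-generation ancestor completeness.

    ``eq_gen(i) = sum over known ancestors (1/2)^g``; a founder scores 0.
    ``generation_completeness[g-1]`` is the population mean of
    (known ancestors at generation g) / 2^g for g = 1..max_gen.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    # counts[i, g] = number of known ancestors of i at generation g+1
    counts = np.zeros((n, max_gen), dtype=np.float64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                counts[i, 0] += 1.0
                counts[i, 1:] += counts[p, :-1]
    weights = 0.5 ** np.arange(1, max_gen + 1)
    eq = counts @ weights
    frac = counts / (2.0 ** np.arange(1, max_gen + 1))
    return CompletenessReport(
        equivalent_generations=eq,
        generation_completeness=frac.mean(axis=0),
        mean_equivalent_generations=float(eq.mean()),
    )


# ---------------------------------------------------------------------------
# file I/O (headered CSV, "0" = unknown)
# ---------------------------------------------------------------------------

def read_pedigree(path, unknown: str = "0") -> Pedigree:
    df = pd.read_csv(path, dtype=str, comment="#")
    need = {"id", "sire", "dam"}
    if not need <= set(df.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(need)}")
    return validate_and_order(
        df[["id", "sire", "dam"]].itertuples(index=False, name=None),
        unknown=unknown,
    )


def write_pedigree(ped: Pedigree, path, unknown: str = "0") -> None:
    df = pd.DataFrame(
        {
            "id": ped.ids,
            "sire": [e.sire_id or unknown for e in ped.entries],
            "dam": [e.dam_id or unknown for e in ped.entries],
        }
    )
    df.to_csv(path, index=False)
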