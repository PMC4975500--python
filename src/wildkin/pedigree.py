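"""Pedigree-based expectations for inbreeding, kinship and dominance.

Marker-based estimates of inbreeding (f), coancestry (f_jk) and dominance
(fraternity, d_jk) coefficients are interpreted against their pedigree
expectations: a parent-offspring pair has kinship 1/4 and fraternity 0, full
sibs have kinship 1/4 and fraternity 1/4, half sibs kinship 1/8 and
fraternity 0, and double first cousins fraternity 1/16.  This module computes
those expectations exactly:

* :meth:`Pedigree.kinship` runs the classical recursive (tabular) kinship
  algorithm, with founders assumed unrelated and non-inbred;
* :func:`dominance_expectation` enumerates every Mendelian transmission
  pattern of founder alleles (deterministic gene dropping over all
  ``2^meioses`` outcomes) to obtain the probability that a pair shares both
  allele pairs identical by descent, falling back to seeded Monte Carlo when
  the pedigree is too deep to enumerate;
* :func:`mating_trajectory` builds the explicit pedigree of a regular mating
  system (repeated full-sib, parent-offspring backcross, or rotational
  half-sib mating) generation by generation and reads inbreeding off the
  kinship recursion, rather than trusting textbook recurrences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATING_SYSTEMS = ("full_sib", "parent_offspring", "half_sib_3", "half_sib_4")


class PedigreeError(ValueError):
    """Raised for cyclic, incomplete or otherwise invalid pedigrees."""


class Pedigree:
    """A sire/dam graph over named individuals.

    Parameters
    ----------
    parents
        Mapping from individual id to a ``(sire, dam)`` tuple.  ``None``
        entries mark unknown parents; an individual with both parents unknown
        is a founder.  Parents referenced but not listed as keys are added as
        founders.
    """

    def __init__(self, parents: Mapping[str, tuple[str | None, str | None]]):
        self._parents: dict[str, tuple[str | None, str | None]] = {}
        for ind, (sire, dam) in parents.items():
            self._parents[str(ind)] = (
                None if sire in (None, "", "0") else str(sire),
                None if dam in (None, "", "0") else str(dam),
            )
        # implicit founders
        for sire, dam in list(self._parents.values()):
            for par in (sire, dam):
                if par is not None and par not in self._parents:
                    self._parents[par] = (None, None)
        self.members: list[str] = self._toposort()
        self._index = {m: i for i, m in enumerate(self.members)}

    def _toposort(self) -> list[str]:
        ts = TopologicalSorter(
            {m: [p for p in ps if p is not None] for m, ps in self._parents.items()}
        )
        try:
            return list(ts.static_order())
        except CycleError as exc:
            raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc

    @property
    def founders(self) -> list[str]:
        return [m for m in self.members if self._parents[m] == (None, None)]

    def parents_of(self, ind: str) -> tuple[str | None, str | None]:
        return self._parents[ind]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, ind: str) -> bool:
        return ind in self._parents

    @classmethod
    def from_tuples(cls, trios: Iterable[tuple[str, str | None, str | None]]) -> "Pedigree":
        """Build from ``(individual, sire, dam)`` triples."""
        return cls({ind: (sire, dam) for ind, sire, dam in trios})

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        """Read a tab-separated pedigree with columns id, sire, dam.

        ``0`` or an empty field marks an unknown parent.
        """
        tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cols = [c.lower() for c in tab.columns]
        try:
            i_id = cols.index("id")
            i_s = cols.index("sire")
            i_d = cols.index("dam")
        except ValueError as exc:
            raise PedigreeError("pedigree TSV needs columns id, sire, dam") from exc
        return cls.from_tuples(
            (row.iloc[i_id], row.iloc[i_s] or None, row.iloc[i_d] or None)
            for _, row in tab.iterrows()
        )

    def kinship(self) -> pd.DataFrame:
        """Pairwise kinship (coancestry) matrix by the tabular recursion.

        Founders are unrelated and non-inbred: self-kinship 1/2 and zero with
        everyone earlier.  For a non-founder j and any earlier k,
        ``phi(j,k) = (phi(sire_j,k) + phi(dam_j,k)) / 2`` (an absent parent
        contributes 0), and ``phi(j,j) = (1 + phi(sire_j,dam_j)) / 2``.
        """
        n = len(self.members)
        phi = np.zeros((n, n))
        for j, ind in enumerate(self.members):
            sire, dam = self._parents[ind]
            si = self._index[sire] if sire is not None else None
            di = self._index[dam] if dam is not None else None
            for k in range(j):
                v = 0.0
                if si is not None:
                    v += 0.5 * phi[si, k]
                if di is not None:
                    v += 0.5 * phi[di, k]
                phi[j, k] = phi[k, j] = v
            f = phi[si, di] if (si is not None and di is not None) else 0.0
            phi[j, j] = 0.5 * (1.0 + f)
        return pd.DataFrame(phi, index=self.members, columns=self.members)

    def inbreeding(self) -> pd.Series:
        """Per-individual inbreeding coefficient, f = kinship(sire, dam)."""
        phi = self.kinship()
        f = 2.0 * pd.Series(np.diag(phi.values), index=self.members) - 1.0
        return f


# ---------------------------------------------------------------------------
# Dominance (fraternity) expectation by exhaustive gene dropping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DominanceResult:
    """Expected dominance relationship with provenance of the computation."""

    value: float
    se: float | None  # None for exact enumeration
    method: str  # "enumeration" | "monte_carlo"
    n_meioses: int


def _drop_alleles(
    ped: Pedigree, bits: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Propagate founder allele labels down the pedigree.

    ``bits`` has one column per meiosis (two per non-founder) and one row per
    transmission pattern; returns for each member the (paternal, maternal)
    founder-allele label arrays across patterns.
    """
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    npat = bits.shape[0]
    label = 0
    col = 0
    for ind in ped.members:
        sire, dam = ped.parents_of(ind)
        if sire is None and dam is None:
            a = np.full(npat, label)
            b = np.full(npat, label + 1)
            label += 2
            alleles[ind] = (a, b)
            continue
        if sire is None or dam is None:
            raise PedigreeError(f"{ind!r} has exactly one known parent")
        pa, pb = alleles[sire]
        ma, mb = alleles[dam]
        from_sire = np.where(bits[:, col], pa, pb)
        from_dam = np.where(bits[:, col + 1], ma, mb)
        col += 2
        alleles[ind] = (from_sire, from_dam)
    return alleles


def _both_pairs_ibd(
    alleles: dict[str, tuple[np.ndarray, np.ndarray]], j: str, k: str
) -> np.ndarray:
    """Pattern-wise indicator that j and k share both alleles IBD."""
    ja, jb = alleles[j]
    ka, kb = alleles[k]
    straight = (ja == ka) & (jb == kb)
    crossed = (ja == kb) & (jb == ka)
    return straight | crossed


def dominance_expectation(
    ped: Pedigree,
    pair: tuple[str, str],
    *,
    max_meioses: int = 20,
    n_monte_carlo: int = 100_000,
    seed: int | None = None,
) -> DominanceResult:
    """Probability that a pair shares both allele pairs identical by descent.

    For non-inbred individuals this is the fraternity coefficient, the
    pedigree expectation of the genomic dominance relationship: 1/4 for full
    sibs, 1/16 for double first cousins, 0 for parent-offspring and half sibs.

    Computed by exact enumeration of all ``2^M`` founder-allele transmission
    patterns (M = two meioses per non-founder).  Pedigrees with
    ``M > max_meioses`` fall back to seeded Monte Carlo gene dropping and the
    result carries a binomial standard error.
    """
    j, k = pair
    for ind in (j, k):
        if ind not in ped:
            raise PedigreeError(f"{ind!r} not in pedigree")
    n_nonfounders = len(ped) - len(ped.founders)
    m = 2 * n_nonfounders
    if m <= max_meioses:
        if m == 0:
            bits = np.zeros((1, 0), dtype=bool)
        else:
            grid = np.arange(2**m, dtype=np.int64)
            bits = (grid[:, None] >> np.arange(m)) & 1
            bits = bits.astype(bool)
        hit = _both_pairs_ibd(_drop_alleles(ped, bits), j, k)
        return DominanceResult(float(hit.mean()), None, "enumeration", m)
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(n_monte_carlo, m), dtype=np.int64).astype(bool)
    hit = _both_pairs_ibd(_drop_alleles(ped, bits), j, k)
    p = float(hit.mean())
    se = float(np.sqrt(p * (1.0 - p) / n_monte_carlo))
    logger.info(
        "dominance_expectation: %d meioses > budget %d, Monte Carlo with %d replicates",
        m, max_meioses, n_monte_carlo,
    )
    return DominanceResult(p, se, "monte_carlo", m)


# ---------------------------------------------------------------------------
# Canonical small pedigrees
# ---------------------------------------------------------------------------


def full_sib_pair() -> tuple[Pedigree, tuple[str, str]]:
    """Two full sibs from unrelated non-inbred parents."""
    ped = Pedigree.from_tuples(
        [("P1", None, None), ("P2", None, None), ("S1", "P1", "P2"), ("S2", "P1", "P2")]
    )
    return ped, ("S1", "S2")


def half_sib_pair() -> tuple[Pedigree, tuple[str, str]]:
    """Two half sibs sharing a sire, with three unrelated founders."""
    ped = Pedigree.from_tuples(
        [
            ("P1", None, None),
            ("P2", None, None),
            ("P3", None, None),
            ("H1", "P1", "P2"),
            ("H2", "P1", "P3"),
        ]
    )
    return ped, ("H1", "H2")


def parent_offspring_pair() -> tuple[Pedigree, tuple[str, str]]:
    """A founder parent and its offspring."""
    ped = Pedigree.from_tuples(
        [("P1", None, None), ("P2", None, None), ("C", "P1", "P2")]
    )
    return ped, ("P1", "C")


def full_sib_mating_offspring() -> tuple[Pedigree, str]:
    """Offspring of a full-sib mating; its inbreeding is 1/4."""
    ped, (s1, s2) = full_sib_pair()
    ped = Pedigree.from_tuples(
        [(m, *ped.parents_of(m)) for m in ped.members] + [("C", s1, s2)]
    )
    return ped, "C"


def half_sib_mating_offspring() -> tuple[Pedigree, str]:
    """Offspring of a half-sib mating; its inbreeding is 1/8."""
    ped, (h1, h2) = half_sib_pair()
    ped = Pedigree.from_tuples(
        [(m, *ped.parents_of(m)) for m in ped.members] + [("C", h1, h2)]
    )
    return ped, "C"


def double_first_cousin_pair() -> tuple[Pedigree, tuple[str, str]]:
    """Double first cousins: two sib pairs cross-mated between two families."""
    ped = Pedigree.from_tuples(
        [
            ("A1", None, None),
            ("A2", None, None),
            ("B1", None, None),
            ("B2", None, None),
            ("S1", "A1", "A2"),
            ("S2", "A1", "A2"),
            ("T1", "B1", "B2"),
            ("T2", "B1", "B2"),
            ("C1", "S1", "T1"),
            ("C2", "S2", "T2"),
        ]
    )
    return ped, ("C1", "C2")


# ---------------------------------------------------------------------------
# Regular mating systems
# ---------------------------------------------------------------------------


def _trajectory_full_sib(T: int) -> tuple[list[float], Pedigree]:
    trios: list[tuple[str, str | None, str | None]] = [("P1", None, None), ("P2", None, None)]
    sires, dams = "P1", "P2"
    pair = ("G0_A", "G0_B")
    trios += [(pair[0], sires, dams), (pair[1], sires, dams)]
    children: list[str] = []
    for t in range(1, T + 1):
        nxt = (f"G{t}_A", f"G{t}_B")
        trios += [(nxt[0], *pair), (nxt[1], *pair)]
        children.append(nxt[0])
        pair = nxt
    ped = Pedigree.from_tuples(trios)
    f = ped.inbreeding()
    return [float(f[c]) for c in children], ped

def _trajectory_parent_offspring(T: int) -> tuple[list[float], Pedigree]:
    trios: list[tuple[str, str | None, str | None]] = [("P1", None, None), ("P2", None, None)]
    trios.append(("C0", "P1", "P2"))
    prev = "C0"
    children = []
    for t in range(1, T + 1):
        child = f"C{t}"
        trios.append((child, "P1", prev))
        children.append(child)
        prev = child
    ped = Pedigree.from_tuples(trios)
    f = ped.inbreeding()
    return [float(f[c]) for c in children], ped

def _trajectory_half_sib(T: int, n_sibs: int) -> tuple[list[float], Pedigree]:
    # Generation 0: one founder sire, n distinct founder dams -> n half sibs.
    # Each later generation: sib 0 is the common sire, the remaining n-1 sibs
    # are dams assigned round-robin to the n offspring.  With fewer dams than
    # offspring some offspring share a dam; this rotational scheme is one
    # concrete realisation of "half-sib mating with n sibs".
    trios: list[tuple[str, str | None, str | None]] = [("F", None, None)]
    trios += [(f"M{i}", None, None) for i in range(n_sibs)]
    sibs = [f"G0_{i}" for i in range(n_sibs)]
    trios += [(s, "F", f"M{i}") for i, s in enumerate(sibs)]
    per_gen_children: list[list[str]] = []
    for t in range(1, T + 1):
        sire = sibs[0]
        dams = sibs[1:]
        nxt = [f"G{t}_{i}" for i in range(n_sibs)]
        trios += [(c, sire, dams[i % len(dams)]) for i, c in enumerate(nxt)]
        per_gen_children.append(nxt)
        sibs = nxt
    ped = Pedigree.from_tuples(trios)
    f = ped.inbreeding()
    # all matings of a round pair the common sire with a half-sib dam; report
    # the mean inbreeding of that round's offspring
    return [float(np.mean([f[c] for c in gen])) for gen in per_gen_children], ped


def mating_trajectory(system: str, T: int, *, return_pedigree: bool = False):
    """Inbreeding per generation of a regular mating system.

    ``system`` is one of ``full_sib`` (repeated sib mating),
    ``parent_offspring`` (repeated backcross to the same parent), or
    ``half_sib_3`` / ``half_sib_4`` (rotational half-sib mating with 3 or 4
    sibs per generation).  The explicit pedigree is built generation by
    generation and inbreeding evaluated by the kinship recursion, so
    ``full_sib`` gives 0.25, 0.375, 0.5, ... and ``parent_offspring`` gives
    0.25, 0.375, 0.4375, ...

    Returns a list of length ``T`` (generation 1 is the first inbred
    offspring generation); with ``return_pedigree=True`` also returns the
    constructed :class:`Pedigree`.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if system == "full_sib":
        fs, ped = _trajectory_full_sib(T)
    elif system == "parent_offspring":
        fs, ped = _trajectory_parent_offspring(T)
    elif system == "half_sib_3":
        fs, ped = _trajectory_half_sib(T, 3)
    elif system == "half_sib_4":
        fs, ped = _trajectory_half_sib(T, 4)
    else:
        raise ValueError(f"unknown mating system {system!r}; choose from {MATING_SYSTEMS}")
    return (fs, ped) if return_pedigree else fs
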