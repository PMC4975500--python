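"""Genomic additive and dominance relationship matrices and coefficients.

Three definitions of the genomic relationship matrix are supported.  With
``x_ij`` the counted-allele dosage of individual j at SNP i, ``p_i`` the
counted-allele frequency, ``q_i = 1 - p_i`` and ``z_ij = x_ij - 2 p_i``:

* Definition I (across-SNP standardization):
  ``A = Z Z' / sum_i 2 p_i q_i``.
* Definition IV (within-SNP standardization):
  ``A_jk = (1/m) sum_i z_ij z_ik / (2 p_i q_i)``.
* Definition IVb: off-diagonals as IV; the diagonal ignores heterozygous
  genotypes, scoring each SNP only through its homozygosity indicator
  ``h_ij``: ``A_jj = 1 + (1/m) sum_i (h_ij - (1 - 2 p_i q_i)) / (2 p_i q_i)``.
  Under HWE the per-SNP term has expectation 0, and a fully homozygous
  individual gets ``A_jj = 2``.

Dominance uses the coding ``w = -2q^2, 2pq, -2p^2`` for dosages 2, 1, 0,
with Definition I ``D = W W' / sum_i (2 p_i q_i)^2`` and Definition IV
``D_jk = (1/m) sum_i w_ij w_ik / (2 p_i q_i)^2``.  The scalar summaries are
the genomic inbreeding coefficient ``f_j = A_jj - 1``, the coancestry
coefficient ``f_jk = A_jk / 2``, and the dominance (fraternity) coefficient
``d_jk = D_jk``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFINITIONS = ("I", "IV", "IVb")


class RelationshipError(ValueError):
    """Raised for degenerate SNPs or mismatched matrix kinds."""


@dataclass
class RelationshipMatrix:
    """A symmetric genomic relationship matrix tagged with its definition."""

    kind: str  # "additive" | "dominance"
    definition: str  # "I" | "IV" | "IVb"
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise RelationshipError("matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise RelationshipError("matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        """Square TSV with sample ids as header row and column."""
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    def write_grm_text(self, path) -> None:
        """Lower-triangle text layout: i, j (1-based), and the value."""
        with open(path, "w") as fh:
            for j in range(len(self.sample_ids)):
                for k in range(j + 1):
                    fh.write(f"{j + 1}\t{k + 1}\t{self.values[j, k]:.10g}\n")


def _validate(G: GenotypeMatrix, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (G.n_snps,):
        raise RelationshipError(
            f"frequency vector length {p.shape} does not match {G.n_snps} SNPs"
        )
    if G.has_missing:
        raise RelationshipError("relationship matrices require a complete matrix")
    degenerate = (p <= 0.0) | (p >= 1.0)
    if degenerate.any():
        i = int(np.flatnonzero(degenerate)[0])
        snp = G.snps.iloc[i]
        raise RelationshipError(
            f"degenerate SNP {snp.chrom}:{snp.pos} has frequency {p[i]}; "
            "remove monomorphic SNPs before standardization"
        )
    return p


def additive_matrix(
    G: GenotypeMatrix, p: np.ndarray, definition: str = "IV"
) -> RelationshipMatrix:
    """Genomic additive relationship matrix under Definition I, IV or IVb."""
    if definition not in DEFINITIONS:
        raise RelationshipError(f"unknown definition {definition!r}")
    p = _validate(G, p)
    x = G.codes.astype(float)
    z = x - 2.0 * p
    two_pq = 2.0 * p * (1.0 - p)
    if definition == "I":
        a = (z @ z.T) / two_pq.sum()
    else:
        zs = z / np.sqrt(two_pq)
        a = (zs @ zs.T) / G.n_snps
        if definition == "IVb":
            h = (x != 1.0).astype(float)  # homozygosity indicator
            diag = 1.0 + ((h - (1.0 - two_pq)) / two_pq).mean(axis=1)
            np.fill_diagonal(a, diag)
    a = (a + a.T) / 2.0  # enforce exact symmetry
    return RelationshipMatrix("additive", definition, a, list(G.samples))


def dominance_matrix(
    G: GenotypeMatrix, p: np.ndarray, definition: str = "IV"
) -> RelationshipMatrix:
    """Genomic dominance relationship matrix under Definition I or IV.

    Definition IVb has no dominance formulation of its own; requesting it
    reuses Definition IV (logged).
    """
    if definition not in DEFINITIONS:
        raise RelationshipError(f"unknown definition {definition!r}")
    if definition == "IVb":
        logger.info("dominance Definition IVb not defined; using Definition IV")
        definition = "IV"
    p = _validate(G, p)
    q = 1.0 - p
    x = G.codes
    w = np.where(x == 2, -2.0 * q**2, np.where(x == 1, 2.0 * p * q, -2.0 * p**2))
    two_pq = 2.0 * p * q
    if definition == "I":
        d = (w @ w.T) / (two_pq**2).sum()
    else:
        ws = w / two_pq
        d = (ws @ ws.T) / G.n_snps
    d = (d + d.T) / 2.0
    return RelationshipMatrix("dominance", definition, d, list(G.samples))


def inbreeding_from_diagonal(A: RelationshipMatrix) -> pd.Series:
    """Genomic inbreeding coefficient per individual, f_j = A_jj - 1."""
    if A.kind != "additive":
        raise RelationshipError("inbreeding requires an additive matrix")
    return pd.Series(np.diag(A.values) - 1.0, index=A.sample_ids, name="f")


def coancestry_from_offdiagonal(A: RelationshipMatrix) -> pd.DataFrame:
    """Coancestry coefficient per unordered pair, f_jk = A_jk / 2.

    Returns a long-format frame with columns id1, id2, f_jk (j < k in input
    order).
    """
    if A.kind != "additive":
        raise RelationshipError("coancestry requires an additive matrix")
    ids = A.sample_ids
    pairs = list(itertools.combinations(range(len(ids)), 2))
    return pd.DataFrame(
        {
            "id1": [ids[j] for j, _ in pairs],
            "id2": [ids[k] for _, k in pairs],
            "f_jk": [0.5 * A.values[j, k] for j, k in pairs],
        }
    )


def dominance_from_offdiagonal(D: RelationshipMatrix) -> pd.DataFrame:
    """Dominance (fraternity) coefficient per unordered pair, d_jk = D_jk."""
    if D.kind != "dominance":
        raise RelationshipError("dominance coefficients require a dominance matrix")
    ids = D.sample_ids
    pairs = list(itertools.combinations(range(len(ids)), 2))
    return pd.DataFrame(
        {
            "id1": [ids[j] for j, _ in pairs],
            "id2": [ids[k] for _, k in pairs],
            "d_jk": [D.values[j, k] for j, k in pairs],
        }
    )


def mean_coancestry(pairs) -> float:
    """Group mean coancestry: the arithmetic mean of pairwise f_jk values."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_coancestry needs at least one pair")
    return float(arr.mean())
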