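"""Genotype-sharing measures, their HWE expectations, IBD and exclusion power.

Per unordered pair of individuals, over bi-allelic SNPs:

* **IBS** — mean proportion of shared alleles: 1 for identical homozygotes or
  two heterozygotes, 1/2 for a heterozygote against a homozygote, 0 for
  opposing homozygotes;
* **IBG** — proportion of SNPs with identical genotypes;
* **NSG** — proportion of SNPs with opposing homozygotes (AA vs aa), the
  Mendelian-impossible configuration for a true parent-offspring pair and
  hence the per-SNP parentage exclusion probability;
* **IBD** — method-of-moments identity-by-descent state probabilities
  (Z0, Z1, Z2) and relatedness ``pi_hat = Z2 + Z1/2``.

Under HWE at counted-allele frequency p (q = 1 - p) the per-SNP expectations
are ``IBS_E = (p^2 + q^2)^2 + 2pq(1 - pq)``, ``IBG_E = (p^2+q^2)^2 + 2p^2q^2``
and ``NSG_E = 2 p^2 q^2``; with inbreeding f the opposing-homozygote
probability becomes ``NSG_Ef = 2 (p^2 + f p q)(q^2 + f p q)``, which grows
with f at every interior frequency.  A panel of n SNPs excludes a false
parent-offspring claim with probability ``Q = 1 - prod_i (1 - Q_i)`` where
``Q_i`` is SNP i's NSG value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    """Raised for degenerate input to similarity estimators."""


def _pair_index(ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    j, k = np.triu_indices(len(ids), k=1)
    return j, k


def _ibs_state_counts(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts of IBS states 0/1/2 for every pair (condensed upper triangle)."""
    x = G.codes
    g0 = (x == 0).astype(np.float64)
    g1 = (x == 1).astype(np.float64)
    g2 = (x == 2).astype(np.float64)
    n0 = g0 @ g2.T
    n0 = n0 + n0.T  # opposing homozygotes
    n2 = g0 @ g0.T + g1 @ g1.T + g2 @ g2.T  # identical genotypes
    j, k = _pair_index(G.samples)
    c0 = n0[j, k]
    c2 = n2[j, k]
    c1 = G.n_snps - c0 - c2
    return c0, c1, c2


def pairwise_similarity(G: GenotypeMatrix) -> pd.DataFrame:
    """IBS, IBG and NSG for every unordered pair.

    Returns a long-format frame (id1, id2, ibs, ibg, nsg).  By construction
    ``ibs = ibg + (het-vs-hom fraction) / 2`` and ``nsg <= 1 - ibg``.
    """
    if G.n_samples < 2:
        raise SimilarityError("pairwise measures need at least 2 samples")
    if G.has_missing:
        raise SimilarityError("pairwise measures require a complete matrix")
    c0, c1, c2 = _ibs_state_counts(G)
    m = float(G.n_snps)
    j, k = _pair_index(G.samples)
    return pd.DataFrame(
        {
            "id1": np.asarray(G.samples)[j],
            "id2": np.asarray(G.samples)[k],
            "ibs": (2.0 * c2 + c1) / (2.0 * m),
            "ibg": c2 / m,
            "nsg": c0 / m,
        }
    )


@dataclass(frozen=True)
class ExpectedSimilarity:
    """Per-SNP expected sharing probabilities at one allele frequency."""

    ibs_e: float
    ibg_e: float
    nsg_e: float
    nsg_ef: float  # opposing-homozygote probability with inbreeding f


def expected_similarity(p: float, f: float = 0.0) -> ExpectedSimilarity:
    """HWE expectations of IBS/IBG/NSG, plus NSG under inbreeding f.

    ``p`` must be an interior frequency; ``f`` an inbreeding coefficient in
    [0, 1].  ``nsg_ef`` reduces to ``nsg_e`` at f = 0.
    """
    if not 0.0 < p < 1.0:
        raise SimilarityError(f"allele frequency must be in (0, 1), got {p}")
    if not 0.0 <= f <= 1.0:
        raise SimilarityError(f"inbreeding coefficient must be in [0, 1], got {f}")
    q = 1.0 - p
    ibs_e = (p**2 + q**2) ** 2 + 2 * p * q * (1 - p * q)
    ibg_e = (p**2 + q**2) ** 2 + 2 * p**2 * q**2
    nsg_e = 2 * p**2 * q**2
    nsg_ef = 2 * (p**2 + f * p * q) * (q**2 + f * p * q)
    return ExpectedSimilarity(ibs_e, ibg_e, nsg_e, nsg_ef)


def mom_ibd(G: GenotypeMatrix, p: np.ndarray) -> pd.DataFrame:
    """Method-of-moments IBD state probabilities per unordered pair.

    Observed counts of IBS states 0/1/2 are equated to their expectations
    conditional on sharing 0, 1 or 2 alleles IBD (frequencies from ``p``),
    the triangular system is solved pair by pair, and the estimates are
    clamped to [0, 1] and renormalized.  No finite-sample allele-frequency
    correction is applied.  Returns columns id1, id2, z0, z1, z2, pi_hat.
    """
    if G.n_samples < 2:
        raise SimilarityError("IBD estimation needs at least 2 samples")
    if G.has_missing:
        raise SimilarityError("IBD estimation requires a complete matrix")
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        i = int(np.flatnonzero((p <= 0) | (p >= 1))[0])
        snp = G.snps.iloc[i]
        raise SimilarityError(f"degenerate SNP {snp.chrom}:{snp.pos} (p={p[i]})")
    q = 1.0 - p
    # expected counts of each IBS state given the IBD state, summed over SNPs
    e00 = (2 * p**2 * q**2).sum()
    e10 = (4 * p**3 * q + 4 * p * q**3).sum()
    e20 = (p**4 + q**4 + 4 * p**2 * q**2).sum()
    e11 = (2 * p**2 * q + 2 * p * q**2).sum()
    e21 = (p**3 + q**3 + p**2 * q + p * q**2).sum()
    e22 = float(len(p))
    c0, c1, c2 = _ibs_state_counts(G)
    z0 = c0 / e00
    z1 = (c1 - z0 * e10) / e11
    z2 = (c2 - z0 * e20 - z1 * e21) / e22
    z = np.clip(np.stack([z0, z1, z2], axis=1), 0.0, 1.0)
    total = z.sum(axis=1, keepdims=True)
    z = np.where(total > 0, z / np.where(total > 0, total, 1.0), [[1.0, 0.0, 0.0]])
    j, k = _pair_index(G.samples)
    return pd.DataFrame(
        {
            "id1": np.asarray(G.samples)[j],
            "id2": np.asarray(G.samples)[k],
            "z0": z[:, 0],
            "z1": z[:, 1],
            "z2": z[:, 2],
            "pi_hat": z[:, 2] + 0.5 * z[:, 1],
        }
    )


def exclusion_survival(per_snp_q) -> float:
    """``prod_i (1 - Q_i)``, evaluated in the log domain.

    The probability that a panel reveals no opposing-homozygote locus; its
    complement is the exclusion probability.  Kept separate because the
    product underflows long before double precision can represent
    ``1 - Q``.
    """
    qs = np.asarray(list(per_snp_q), dtype=float)
    if qs.size == 0:
        raise SimilarityError("exclusion probability needs at least one SNP")
    if ((qs < 0) | (qs > 1)).any():
        raise SimilarityError("per-SNP exclusion values must be in [0, 1]")
    if (qs == 1.0).any():
        return 0.0
    return float(np.exp(np.log1p(-qs).sum()))


def exclusion_probability(per_snp_q) -> float:
    """Overall parentage exclusion probability ``Q = 1 - prod_i (1 - Q_i)``."""
    return 1.0 - exclusion_survival(per_snp_q)


def nsg_snp_count(m: int, nsg_rate: float) -> int:
    """Number of opposing-homozygote SNPs implied by an observed NSG rate.

    ``floor(m * rate)`` — e.g. 150,025 SNPs at rate 0.047 give 7,051.
    """
    if m < 0:
        raise ValueError("SNP count must be >= 0")
    if not 0.0 <= nsg_rate <= 1.0:
        raise ValueError("NSG rate must be in [0, 1]")
    return int(np.floor(m * nsg_rate))


def flag_outliers(
    observed: pd.DataFrame, p: np.ndarray, *, margin_sd: float = 3.0
) -> pd.DataFrame:
    """Screen observed pairwise measures against their HWE expectations.

    The dataset-level expectation of each measure is the mean of the per-SNP
    HWE expectation over the frequency spectrum ``p`` (for unrelated pairs
    IBS and IBG cannot fall systematically below it, nor NSG above it).  A
    pair is flagged when an observed value deviates from the expectation by
    more than ``margin_sd`` standard deviations of the across-pair
    distribution of that measure.  Returns the flagged rows with a ``reason``
    column naming the offending measures.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    exp = {
        "ibs": ((p**2 + q**2) ** 2 + 2 * p * q * (1 - p * q)).mean(),
        "ibg": ((p**2 + q**2) ** 2 + 2 * p**2 * q**2).mean(),
        "nsg": (2 * p**2 * q**2).mean(),
    }
    reasons = []
    flags = np.zeros(len(observed), dtype=bool)
    for measure, e in exp.items():
        sd = observed[measure].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        dev = (observed[measure] - e).abs() > margin_sd * sd
        flags |= dev.values
        reasons.append(np.where(dev.values, measure, ""))
    reason = [
        "+".join(r for r in parts if r) for parts in zip(*reasons)
    ] if reasons else [""] * len(observed)
    out = observed.loc[flags].copy()
    out["reason"] = np.asarray(reason, dtype=object)[flags]
    return out.reset_index(drop=True)


def classical_mds(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    ``n x k`` coordinates from the top-k non-negative eigenvalues ordered by
    eigenvalue.  If fewer than ``k`` positive eigenvalues exist, the extra
    axes are returned as zeros (with a warning).  Axis signs are fixed so the
    first nonzero loading of each axis is positive, making runs reproducible.
    The conventional input here is ``1 - IBS``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise SimilarityError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise SimilarityError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise SimilarityError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    jmat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * jmat @ (d**2) @ jmat
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    positive = vals > max(1e-12, 1e-12 * abs(vals[0]) if n else 0)
    n_pos = int(positive.sum())
    if n_pos < k:
        logger.warning(
            "requested %d MDS dimensions but only %d positive eigenvalues", k, n_pos
        )
    coords = np.zeros((n, k))
    use = min(k, n_pos)
    coords[:, :use] = vecs[:, :use] * np.sqrt(vals[:use])
    for axis in range(use):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords


def ibs_distance_matrix(G: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric ``1 - IBS`` distance matrix over all samples."""
    sim = pairwise_similarity(G)
    n = G.n_samples
    d = np.zeros((n, n))
    j, k = _pair_index(G.samples)
    d[j, k] = d[k, j] = 1.0 - sim.ibs.values
    return pd.DataFrame(d, index=G.samples, columns=G.samples)
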