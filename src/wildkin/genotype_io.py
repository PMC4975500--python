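"""Genotype containers, readers and the SNP selection cascade.

Genotypes are held as an individuals x SNPs matrix of counted-allele dosages
(0/1/2, with -1 marking a missing call before filtering).  The counted allele
is the VCF ALT allele; every estimator downstream is invariant to which
allele is counted.  SNP selection applies, in order: completeness (every
individual genotyped), minor-allele-frequency, a chi-square Hardy-Weinberg
equilibrium test, and greedy physical spacing thinning per chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1

#: columns of the per-SNP table carried by :class:`GenotypeMatrix`
SNP_COLUMNS = ["chrom", "pos", "ref", "alt"]


class GenotypeError(ValueError):
    """Raised for malformed or degenerate genotype input."""


@dataclass
class GenotypeMatrix:
    """Allele-count codes for a cohort of individuals at bi-allelic SNPs.

    Attributes
    ----------
    samples
        Ordered sample identifiers (rows of ``codes``).
    snps
        Per-SNP table with columns ``chrom, pos, ref, alt`` (1-based bp
        positions) plus any computed columns (``p``, ``hwe_p``).
    codes
        ``(n_samples, n_snps)`` int8 matrix, entries in {0, 1, 2} counting
        ALT alleles, or -1 for a missing call.
    """

    samples: list[str]
    snps: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.snps)):
            raise GenotypeError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError("genotype codes must be 0, 1, 2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the SNP positions in ``index``."""
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[index].reset_index(drop=True),
            codes=self.codes[:, index],
        )


def read_vcf(path) -> GenotypeMatrix:
    """Read bi-allelic SNP genotypes from a plain or bgzipped VCF.

    Multi-allelic records and indels are skipped (a count is logged); missing
    GT calls become -1.  Raises :class:`GenotypeError` if no bi-allelic SNP
    records remain.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except OSError as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, chroms, poss, refs, alts = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = rec.genotype.array()[:, :2]
        codes = np.where((gts < 0).any(axis=1), MISSING, (gts > 0).sum(axis=1))
        rows.append(codes.astype(np.int8))
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel records", n_skipped)
    if not rows:
        raise GenotypeError(f"no bi-allelic SNP records in {path}")
    snps = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    return GenotypeMatrix(samples, snps, np.column_stack(rows))


def read_plink_text(prefix) -> GenotypeMatrix:
    """Read PLINK text genotypes from ``prefix``.ped / ``prefix``.map.

    The counted allele is the first ALT-like allele encountered per SNP (the
    non-majority allele of the first fully typed genotype); as everywhere
    else, estimators are invariant to the choice.  ``0`` marks missing
    alleles.
    """
    map_tab = pd.read_csv(
        f"{prefix}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str},
    )
    m = len(map_tab)
    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise GenotypeError(
                    f"ped line for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields) - 6} allele fields, expected {2 * m}"
                )
            samples.append(fields[1])
            allele_rows.append(np.array(fields[6:], dtype="U1").reshape(m, 2))
    if not samples:
        raise GenotypeError(f"empty ped file {prefix}.ped")
    alleles = np.stack(allele_rows)  # (n, m, 2)
    codes = np.zeros((len(samples), m), dtype=np.int8)
    refs, alts = [], []
    for i in range(m):
        col = alleles[:, i, :]
        obs = np.unique(col[col != "0"])
        if len(obs) > 2:
            raise GenotypeError(f"SNP {map_tab.snp_id[i]} has >2 alleles")
        ref = obs[0] if len(obs) else "A"
        alt = obs[1] if len(obs) > 1 else "N"
        missing = (col == "0").any(axis=1)
        codes[:, i] = np.where(missing, MISSING, (col == alt).sum(axis=1))
        refs.append(ref)
        alts.append(alt)
    snps = pd.DataFrame(
        {"chrom": map_tab.chrom, "pos": map_tab.pos, "ref": refs, "alt": alts}
    )
    return GenotypeMatrix(samples, snps, codes)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (id, habitat, latitude, longitude, origin).

    Coordinates are validated to lie in [-90, 90] x [-180, 180].
    """
    meta = pd.read_csv(path, sep="\t", dtype={"id": str, "habitat": str, "origin": str})
    required = {"id", "habitat", "latitude", "longitude", "origin"}
    missing = required - set(meta.columns)
    if missing:
        raise GenotypeError(f"metadata missing columns: {sorted(missing)}")
    if ((meta.latitude.abs() > 90) | (meta.longitude.abs() > 180)).any():
        raise GenotypeError("metadata has out-of-range coordinates")
    return meta


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per SNP, pooled over the whole cohort.

    Frequencies are always estimated on the full analyzed sample (including
    individuals of unknown or crossbred origin), never per subgroup; all
    standardizations downstream use these pooled estimates.  Requires a
    complete matrix.
    """
    if G.has_missing:
        raise GenotypeError("allele_frequencies requires a complete matrix; filter first")
    return G.codes.sum(axis=0, dtype=np.int64) / (2.0 * G.n_samples)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df, no continuity correction) Hardy-Weinberg test.

    Genotype counts are tested against the p^2 / 2pq / q^2 proportions at the
    sample allele frequency; returns the upper-tail p-value.  A monomorphic
    column has nothing to test and returns 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    stat = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=1))


def _hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    """Vectorized chi-square HWE p-value per SNP (complete matrix)."""
    n = G.n_samples
    n_aa = (G.codes == 0).sum(axis=0)
    n_Aa = (G.codes == 1).sum(axis=0)
    n_AA = (G.codes == 2).sum(axis=0)
    p = (2 * n_AA + n_Aa) / (2.0 * n)
    poly = (p > 0) & (p < 1)
    pvals = np.ones(G.n_snps)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = n * np.stack([p**2, 2 * p * (1 - p), (1 - p) ** 2])
        o = np.stack([n_AA, n_Aa, n_aa])
        stat = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0).sum(axis=0)
    pvals[poly] = stats.chi2.sf(stat[poly], df=1)
    return pvals


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the SNP selection cascade.

    ``maf_min`` is a frequency in [0, 0.5]; ``hwe_p_min`` the smallest
    acceptable HWE p-value; ``spacing_min_bp`` the minimum distance (bp) kept
    between consecutive SNPs on a chromosome (0 disables thinning).
    """

    require_complete: bool = True
    maf_min: float = 0.10
    hwe_p_min: float = 0.01
    spacing_min_bp: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be in [0, 1]")
        if self.spacing_min_bp < 0:
            raise ValueError("spacing_min_bp must be >= 0")


@dataclass
class FilterReport:
    """Per-criterion removal counts from one cascade run."""

    n_input: int = 0
    removed_incomplete: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_spacing: int = 0
    n_output: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def filter_snps(
    G: GenotypeMatrix, criteria: FilterCriteria
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP selection cascade and report removals per criterion.

    Order: completeness -> MAF -> HWE -> spacing.  Spacing thinning is greedy
    per chromosome in coordinate order: keep the first surviving SNP, then
    each next SNP at least ``spacing_min_bp`` away from the last kept one.
    Input SNPs must be sorted by (chrom, pos).  The returned matrix carries
    computed ``p`` and ``hwe_p`` columns in its SNP table.
    """
    snps = G.snps
    order_ok = snps.groupby("chrom", sort=False)["pos"].apply(
        lambda s: bool(s.is_monotonic_increasing)
    )
    if not order_ok.all():
        chrom = order_ok[~order_ok].index[0]
        pos = snps.loc[snps.chrom == chrom, "pos"]
        first_bad = pos.index[np.flatnonzero(np.diff(pos.values) < 0)[0] + 1]
        raise GenotypeError(
            f"SNPs not sorted by position: {chrom}:{snps.pos[first_bad]} "
            f"(row {first_bad}) is out of order"
        )

    report = FilterReport(n_input=G.n_snps)
    keep = np.ones(G.n_snps, dtype=bool)

    if criteria.require_complete:
        complete = ~(G.codes == MISSING).any(axis=0)
        report.removed_incomplete = int((~complete & keep).sum())
        keep &= complete
    elif G.has_missing:
        raise GenotypeError(
            "matrix has missing calls; MAF/HWE filtering requires completeness"
        )

    sub = G.take_snps(np.flatnonzero(keep))
    p = allele_frequencies(sub)
    maf_ok = np.minimum(p, 1 - p) >= criteria.maf_min
    report.removed_maf = int((~maf_ok).sum())

    hwe_p = _hwe_pvalues(sub)
    hwe_ok = hwe_p >= criteria.hwe_p_min
    report.removed_hwe = int((maf_ok & ~hwe_ok).sum())

    ok = maf_ok & hwe_ok
    sub = sub.take_snps(np.flatnonzero(ok))
    sub.snps["p"] = p[ok]
    sub.snps["hwe_p"] = hwe_p[ok]

    if criteria.spacing_min_bp > 0 and sub.n_snps:
        keep_sp = np.zeros(sub.n_snps, dtype=bool)
        for _, idx in sub.snps.groupby("chrom", sort=False).indices.items():
            last = None
            for i in idx:
                pos = sub.snps.pos.iloc[i]
                if last is None or pos - last >= criteria.spacing_min_bp:
                    keep_sp[i] = True
                    last = pos
        report.removed_spacing = int((~keep_sp).sum())
        sub = sub.take_snps(np.flatnonzero(keep_sp))

    report.n_output = sub.n_snps
    logger.info(
        "filter: %d -> %d SNPs (incomplete %d, MAF %d, HWE %d, spacing %d)",
        report.n_input, report.n_output, report.removed_incomplete,
        report.removed_maf, report.removed_hwe, report.removed_spacing,
    )
    return sub, report


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_genotype_tsv(G: GenotypeMatrix, path) -> None:
    """Write codes as samples x SNPs TSV with chrom:pos column headers."""
    cols = G.snps.chrom.astype(str) + ":" + G.snps.pos.astype(str)
    pd.DataFrame(G.codes, index=G.samples, columns=cols).to_csv(
        path, sep="\t", index_label="sample"
    )


def write_snp_table(G: GenotypeMatrix, path) -> None:
    """Write the per-SNP table (coordinates, alleles, computed columns)."""
    G.snps.to_csv(path, sep="\t", index=False)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with GT fields (plain text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in G.snps.chrom.unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples) + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i, snp in enumerate(G.snps.itertuples(index=False)):
            gts = "\t".join(gt_map[int(c)] for c in G.codes[:, i])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t.\t{snp.ref}\t{snp.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
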