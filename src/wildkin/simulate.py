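"""Synthetic genotype cohorts with known population structure and pedigrees.

The generator emulates the structure of a fragmented wild population
sampled across several habitats: a handful of subpopulations that diverged
from a common ancestral gene pool (Balding-Nichols Beta model, one Fst knob
per subpopulation), founders with habitat-specific inbreeding levels
(inbreeding-adjusted genotype frequencies ``p^2 + fpq / 2pq(1-f) /
q^2 + fpq``), crossbred individuals whose parents come from two different
habitats, and small families with known pedigree relationships (full sibs,
half sibs, parent-offspring, offspring of a full-sib mating, double first
cousins) realised by Mendelian gene dropping.  SNPs are unlinked; there is
no mutation, no LD and no genotyping error — see the methods note for what
that implies about tests built on this generator.

Every dataset carries a :class:`SyntheticTruth` with the realised allele
frequencies, each individual's pedigree-level inbreeding and the analytic
expectation of its genomic (pooled-frequency) inbreeding coefficient, and
each planted pair's relationship class, pedigree kinship and dominance
expectation — enough to predict the value of every estimator in the
package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, write_vcf
from .pedigree import (
    Pedigree,
    dominance_expectation,
    double_first_cousin_pair,
    full_sib_mating_offspring,
    full_sib_pair,
    half_sib_pair,
    parent_offspring_pair,
)

logger = logging.getLogger(__name__)

RELATIONSHIP_TYPES = (
    "parent_offspring",
    "full_sibs",
    "half_sibs",
    "full_sib_mating_offspring",
    "double_first_cousins",
)


class ScenarioError(ValueError):
    """Raised for inconsistent scenario configurations."""


@dataclass
class SubpopConfig:
    """One subpopulation: sampled founders and divergence from the ancestor.

    ``founder_f`` is the mean within-subpopulation inbreeding of sampled
    founders; ``founder_f_sd`` spreads individual levels around it (draws are
    clipped to [0, 0.95]).  ``fst`` parameterises Balding-Nichols divergence
    of the subpopulation's allele frequencies from the ancestral ones.
    """

    name: str
    n_founders: int
    founder_f: float = 0.0
    fst: float = 0.05
    founder_f_sd: float = 0.0
    center: tuple[float, float] | None = None  # (lat, lon) decimal degrees

    def __post_init__(self) -> None:
        if self.n_founders < 0:
            raise ScenarioError("n_founders must be >= 0")
        if not 0.0 <= self.founder_f < 1.0:
            raise ScenarioError("founder_f must be in [0, 1)")
        if not 0.0 < self.fst < 1.0:
            raise ScenarioError("fst must be in (0, 1)")
        if self.founder_f_sd < 0:
            raise ScenarioError("founder_f_sd must be >= 0")


@dataclass
class RelationshipSpec:
    """Planted families of a known relationship type within a subpopulation."""

    type: str
    subpop: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.type not in RELATIONSHIP_TYPES:
            raise ScenarioError(
                f"unknown relationship type {self.type!r}; choose from {RELATIONSHIP_TYPES}"
            )
        if self.count < 0:
            raise ScenarioError("count must be >= 0")


@dataclass
class CrossbredSpec:
    """Crossbred individuals with one (unsampled) parent from each habitat."""

    parents: tuple[str, str]
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ScenarioError("count must be >= 0")


@dataclass
class ScenarioConfig:
    """Full description of a synthetic cohort."""

    n_snps: int = 10_000
    maf_range: tuple[float, float] = (0.10, 0.50)
    subpops: list[SubpopConfig] = field(default_factory=list)
    relationships: list[RelationshipSpec] = field(default_factory=list)
    crossbreds: list[CrossbredSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ScenarioError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_snps <= 0:
            raise ScenarioError("n_snps must be positive")
        names = [s.name for s in self.subpops]
        if len(set(names)) != len(names):
            raise ScenarioError("duplicate subpopulation names")
        for rel in self.relationships:
            if rel.subpop not in names:
                raise ScenarioError(f"relationship references unknown subpop {rel.subpop!r}")
        for cb in self.crossbreds:
            for par in cb.parents:
                if par not in names:
                    raise ScenarioError(f"crossbred references unknown subpop {par!r}")

    def subpop(self, name: str) -> SubpopConfig:
        return next(s for s in self.subpops if s.name == name)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset.

    ``individuals`` columns: id, subpop, habitat, origin, f_pedigree (the
    inbreeding level the genotypes were drawn at), f_expected (analytic
    expectation of the Definition-IV genomic inbreeding coefficient under
    pooled-frequency standardization, given the realised subpopulation
    frequencies; O(1/n) finite-sample standardization terms are neglected).
    ``pairs`` columns: id1, id2, relation, kinship, dominance (pedigree
    expectations).
    """

    individuals: pd.DataFrame
    pairs: pd.DataFrame
    ancestral_p: np.ndarray
    subpop_p: dict[str, np.ndarray]
    pooled_p: np.ndarray
    seed: int
    pedigree_rows: list[tuple[str, str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary draws
# ---------------------------------------------------------------------------


def sample_subpop_frequencies(
    p0: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols draw of subpopulation frequencies.

    ``Beta(p0 (1-fst)/fst, (1-p0)(1-fst)/fst)`` — mean ``p0`` and variance
    ``fst p0 (1 - p0)``.
    """
    p0 = np.asarray(p0, dtype=float)
    if ((p0 <= 0) | (p0 >= 1)).any():
        raise ScenarioError("ancestral frequencies must be in (0, 1)")
    if not 0.0 < fst < 1.0:
        raise ScenarioError("fst must be in (0, 1)")
    scale = (1.0 - fst) / fst
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def _founder_haplotypes(
    freqs: np.ndarray, f: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two allele vectors for one founder at inbreeding level f.

    With probability f a locus is autozygous (both alleles copies of one
    draw), else the two alleles are independent — giving genotype
    frequencies ``p^2 + fpq, 2pq(1-f), q^2 + fpq``.
    """
    autozygous = rng.random(freqs.size) < f
    a = rng.random(freqs.size) < freqs
    b = np.where(autozygous, a, rng.random(freqs.size) < freqs)
    return a.astype(np.int8), b.astype(np.int8)


def simulate_founder(freqs: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Genotype codes (0/1/2) for one founder at inbreeding level f."""
    if not 0.0 <= f <= 1.0:
        raise ScenarioError("f must be in [0, 1]")
    a, b = _founder_haplotypes(np.asarray(freqs, dtype=float), f, rng)
    return (a + b).astype(np.int8)


def gene_drop(
    ped: Pedigree,
    founder_haplotypes: dict[str, tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mendelian transmission of founder alleles down a pedigree.

    Each non-founder receives one uniformly chosen allele from each parent
    per SNP, independently across SNPs.  Returns haplotype pairs for every
    member; sum the pair for genotype codes.
    """
    missing = [fo for fo in ped.founders if fo not in founder_haplotypes]
    if missing:
        raise ScenarioError(f"missing founder genotypes for {missing}")
    haps = dict(founder_haplotypes)
    m = next(iter(haps.values()))[0].size
    for ind in ped.members:
        sire, dam = ped.parents_of(ind)
        if sire is None and dam is None:
            continue
        out = []
        for parent in (sire, dam):
            pa, pb = haps[parent]
            pick = rng.integers(0, 2, size=m, dtype=np.int8)
            out.append(np.where(pick == 1, pa, pb))
        haps[ind] = (out[0], out[1])
    return haps


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

_FAMILY_BUILDERS = {
    "full_sibs": lambda: full_sib_pair(),
    "half_sibs": lambda: half_sib_pair(),
    "parent_offspring": lambda: parent_offspring_pair(),
    "double_first_cousins": lambda: double_first_cousin_pair(),
}

# roughly where the six real habitats sit (mountain ranges in Sichuan/Shaanxi);
# only the inter-habitat distance scale (~150-500 km) matters downstream
DEFAULT_CENTERS = {
    "Qinling": (33.7, 107.6),
    "Minshan": (32.6, 104.1),
    "Qionglai": (30.9, 103.0),
    "Liangshan": (28.9, 103.0),
    "Daxiangling": (29.6, 102.8),
    "Xiaoxiangling": (28.9, 102.3),
}


def default_scenario(n_snps: int = 10_000, seed: int = 0) -> ScenarioConfig:
    """The default cohort: six habitats, crossbreds, and a calibration kindred.

    Habitat sizes (15/8/7/2/1/1), mean founder inbreeding levels and their
    spreads mirror the observed structure of a fragmented wild population
    with two small, highly inbred habitats and two large, outbred ones.
    Each habitat diverges from the ancestral pool at fst = 0.02 — enough to
    make habitats genetically unrelated (negative mean between-habitat
    coancestry) under pooled standardization while keeping each habitat's
    pooled-base inbreeding within ~0.03 of its configured within-habitat
    level; see the methods note for this trade-off.  The
    known-relationship families live in a separate low-divergence
    (fst = 0.01) "Kindred" cohort so their genomic estimates can be compared
    against pedigree expectations without a Wahlund offset.
    """
    subpops = [
        SubpopConfig("Qionglai", 15, 0.07, 0.02, 0.043),
        SubpopConfig("Qinling", 8, 0.20, 0.02, 0.056),
        SubpopConfig("Minshan", 7, 0.09, 0.02, 0.024),
        SubpopConfig("Liangshan", 2, 0.25, 0.02, 0.024),
        SubpopConfig("Daxiangling", 1, 0.13, 0.02, 0.0),
        SubpopConfig("Xiaoxiangling", 1, 0.0, 0.02, 0.0),
        SubpopConfig("Kindred", 0, 0.0, 0.01, 0.0, center=(31.8, 105.3)),
    ]
    for sp in subpops:
        if sp.center is None:
            sp.center = DEFAULT_CENTERS[sp.name]
    relationships = [
        RelationshipSpec("full_sibs", "Kindred", 6),
        RelationshipSpec("half_sibs", "Kindred", 4),
        RelationshipSpec("parent_offspring", "Kindred", 4),
        RelationshipSpec("full_sib_mating_offspring", "Kindred", 3),
        RelationshipSpec("double_first_cousins", "Kindred", 2),
    ]
    crossbreds = [
        CrossbredSpec(("Qionglai", "Liangshan"), 3),
        CrossbredSpec(("Qionglai", "Minshan"), 4),
        CrossbredSpec(("Qionglai", "Qinling"), 3),
        CrossbredSpec(("Minshan", "Liangshan"), 4),
    ]
    return ScenarioConfig(
        n_snps=n_snps,
        maf_range=(0.10, 0.50),
        subpops=subpops,
        relationships=relationships,
        crossbreds=crossbreds,
        seed=seed,
    )


def _habitat_coords(
    cfg: ScenarioConfig, name: str, rng: np.random.Generator, grid_slot: int
) -> tuple[float, float]:
    sp = cfg.subpop(name)
    if sp.center is not None:
        lat0, lon0 = sp.center
    else:
        # spread unnamed habitats on a coarse grid near 31N so inter-habitat
        # distances land in the few-hundred-km range
        lat0 = 29.0 + 1.5 * (grid_slot % 4)
        lon0 = 102.0 + 1.8 * (grid_slot // 4)
    return lat0 + rng.normal(0, 0.08), lon0 + rng.normal(0, 0.08)


def make_dataset(
    config: ScenarioConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a cohort: genotypes, sample metadata and ground truth.

    Fully reproducible from ``config.seed``.  Sample order: per-subpop
    founders (config order), then relationship-family members, then
    crossbreds.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps

    maf = rng.uniform(*config.maf_range, size=m)
    flip = rng.random(m) < 0.5
    p0 = np.where(flip, maf, 1.0 - maf)  # counted-allele frequency
    subpop_p = {
        sp.name: sample_subpop_frequencies(p0, sp.fst, rng) for sp in config.subpops
    }

    codes_rows: list[np.ndarray] = []
    ind_rows: list[dict] = []
    pair_rows: list[dict] = []
    ped_rows: list[tuple[str, str, str]] = []  # (id, sire, dam) for emitted members
    mus: list[np.ndarray] = []  # per-individual expected allele frequency
    grid = {sp.name: i for i, sp in enumerate(config.subpops)}

    def emit(ind_id, codes, mu, subpop, habitat, origin, f_ped, center_of):
        lat, lon = _habitat_coords(config, center_of, rng, grid[center_of])
        codes_rows.append(codes)
        mus.append(mu)
        ind_rows.append(
            {
                "id": ind_id,
                "subpop": subpop,
                "habitat": habitat,
                "origin": origin,
                "f_pedigree": f_ped,
                "latitude": round(lat, 5),
                "longitude": round(lon, 5),
            }
        )

    # --- standing founders per habitat
    for sp in config.subpops:
        ps = subpop_p[sp.name]
        for i in range(sp.n_founders):
            if sp.founder_f_sd > 0:
                f_i = float(np.clip(rng.normal(sp.founder_f, sp.founder_f_sd), 0.0, 0.95))
            else:
                f_i = sp.founder_f
            emit(
                f"{sp.name}_{i + 1}",
                simulate_founder(ps, f_i, rng),
                ps,
                sp.name,
                sp.name,
                "wild",
                f_i,
                sp.name,
            )

    # --- planted relationship families (founders non-inbred)
    fam_counter = 0
    for rel in config.relationships:
        ps = subpop_p[rel.subpop]
        for _ in range(rel.count):
            fam_counter += 1
            tag = f"F{fam_counter}"
            if rel.type == "full_sib_mating_offspring":
                ped, child = full_sib_mating_offspring()
                focal: tuple[str, ...] = (child,)
            else:
                ped, pair = _FAMILY_BUILDERS[rel.type]()
                focal = pair
            founder_haps = {
                fo: _founder_haplotypes(ps, 0.0, rng) for fo in ped.founders
            }
            haps = gene_drop(ped, founder_haps, rng)
            fped = ped.inbreeding()
            phi = ped.kinship()
            names = {mem: f"{tag}_{mem}" for mem in ped.members}
            for mem in focal:
                emit(
                    names[mem],
                    (haps[mem][0] + haps[mem][1]).astype(np.int8),
                    ps,
                    rel.subpop,
                    rel.subpop,
                    "wild",
                    float(fped[mem]),
                    rel.subpop,
                )
                sire, dam = ped.parents_of(mem)
                ped_rows.append(
                    (
                        names[mem],
                        names.get(sire, "0") if sire else "0",
                        names.get(dam, "0") if dam else "0",
                    )
                )
            if len(focal) == 2:
                a, b = focal
                dom = dominance_expectation(ped, (a, b))
                pair_rows.append(
                    {
                        "id1": names[a],
                        "id2": names[b],
                        "relation": rel.type,
                        "kinship": float(phi.loc[a, b]),
                        "dominance": dom.value,
                    }
                )

    # --- crossbreds: one allele from each parental habitat's gene pool
    # (equivalent to gene-dropping from two hidden unrelated founders)
    cb_counter = 0
    for cb in config.crossbreds:
        a_name, b_name = cb.parents
        pa, pb = subpop_p[a_name], subpop_p[b_name]
        for _ in range(cb.count):
            cb_counter += 1
            allele_a = (rng.random(m) < pa).astype(np.int8)
            allele_b = (rng.random(m) < pb).astype(np.int8)
            emit(
                f"CB{cb_counter}_{a_name}x{b_name}",
                allele_a + allele_b,
                (pa + pb) / 2.0,
                f"{a_name} × {b_name}",
                f"{a_name} × {b_name}",
                "crossbred",
                0.0,
                a_name,  # reared near a parental habitat; location is cosmetic
            )

    if not codes_rows:
        raise ScenarioError("scenario emits no individuals")

    codes = np.vstack(codes_rows)
    individuals = pd.DataFrame(ind_rows)
    pooled_p = np.mean(np.vstack(mus), axis=0)
    qbar = 1.0 - pooled_p
    denom = 2.0 * pooled_p * qbar

    # analytic expectation of the Definition-IV diagonal given realised
    # frequencies: E[(x - 2*pbar)^2] = Var(x) + (mu - 2*pbar)^2 per SNP
    f_expected = []
    for row, mu in zip(ind_rows, mus):
        name = row["subpop"]
        if row["origin"] == "crossbred":
            a_name, b_name = name.split(" × ")
            pa, pb = subpop_p[a_name], subpop_p[b_name]
            var = pa * (1 - pa) + pb * (1 - pb)
        else:
            ps = subpop_p[name]
            var = 2.0 * ps * (1.0 - ps) * (1.0 + row["f_pedigree"])
        delta = 2.0 * (mu - pooled_p)
        f_expected.append(float(np.mean((var + delta**2) / denom) - 1.0))
    individuals["f_expected"] = f_expected

    # positions: SNPs spread over 20 scaffolds at irregular spacing
    n_chrom = 20
    chrom_ids = np.sort(rng.integers(1, n_chrom + 1, size=m))
    gaps = rng.integers(1_000, 25_000, size=m)
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, n_chrom + 1):
        idx = np.flatnonzero(chrom_ids == c)
        pos[idx] = np.cumsum(gaps[idx]) + 1
    bases = np.array(["A", "C", "G", "T"])
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    snps = pd.DataFrame(
        {
            "chrom": [f"scaffold{c}" for c in chrom_ids],
            "pos": pos,
            "ref": bases[ref_i],
            "alt": bases[alt_i],
        }
    )
    G = GenotypeMatrix(individuals["id"].tolist(), snps, codes)

    meta = individuals[["id", "habitat", "latitude", "longitude", "origin"]].copy()
    truth = SyntheticTruth(
        individuals=individuals.drop(columns=["latitude", "longitude"]),
        pairs=pd.DataFrame(
            pair_rows, columns=["id1", "id2", "relation", "kinship", "dominance"]
        ),
        ancestral_p=p0,
        subpop_p=subpop_p,
        pooled_p=pooled_p,
        seed=config.seed,
        pedigree_rows=ped_rows,
    )
    logger.info(
        "generated %d individuals x %d SNPs (%d planted pairs)",
        G.n_samples, G.n_snps, len(truth.pairs),
    )
    return G, meta, truth


def write_dataset(prefix: str, G: GenotypeMatrix, meta: pd.DataFrame, truth: SyntheticTruth) -> None:
    """Write VCF, metadata TSV, pedigree TSV and truth TSVs under ``prefix``."""
    write_vcf(G, f"{prefix}.vcf")
    meta.to_csv(f"{prefix}.meta.tsv", sep="\t", index=False)
    pd.DataFrame(truth.pedigree_rows, columns=["id", "sire", "dam"]).to_csv(
        f"{prefix}.ped.tsv", sep="\t", index=False
    )
    truth.individuals.to_csv(f"{prefix}.truth_individuals.tsv", sep="\t", index=False)
    truth.pairs.to_csv(f"{prefix}.truth_pairs.tsv", sep="\t", index=False)
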