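# Methods

## Estimands and estimators

The package estimates identity-by-descent-based quantities from bi-allelic
SNP dosages without pedigree information. All standardizations use allele
frequencies pooled over the entire analyzed sample — including crossbred and
unknown-origin individuals — because in the target setting (a few dozen
samples) every genotype improves the frequency estimates; external
frequencies can be supplied instead.

**Additive relationships.** Definition I divides the genome-wide
cross-product of centered dosages by `Σ 2p_i q_i` (across-SNP
standardization); Definition IV averages per-SNP standardized products
(within-SNP). The two agree exactly when all SNPs share one frequency, and
correlate > 0.99 on cohorts with genuine structure; on pure-noise cohorts of
unrelated individuals the correlation of their (near-zero) entries is lower,
which is a property of the noise weighting, not of the estimators.
Definition IVb keeps IV's off-diagonals but scores diagonals only through
each SNP's homozygosity indicator `h`: the per-SNP diagonal term is
`(h − (1 − 2pq)) / 2pq`, which has expectation 0 under HWE and gives a fully
homozygous individual `A_jj = 2`. The literature this definition comes from
does not print its formula; the homozygosity-indicator form adopted here is
one faithful reading of "heterozygous genotypes are not used for diagonal
elements", and is flagged as an interpretation. No dominance analogue of IVb
exists; requesting it returns Definition IV with a log message.

**Coefficients.** `f = A_jj − 1`, `f_jk = A_jk/2`, `d_jk = D_jk`, and group
means are plain averages of the constituent pairwise values. Dominance
coding is `−2q², 2pq, −2p²` for dosages 2, 1, 0; the Definition-I dominance
denominator is `Σ(2pq)²` (the convention of the programs that introduced
these definitions — the alternative `(Σ2pq)²` is not used).

**Similarity and IBD.** IBS scores a SNP 1 / 0.5 / 0 for
identical-genotype-or-both-het / het-vs-hom / opposing-homozygote pairs; IBG
is the identical-genotype fraction; NSG the opposing-homozygote fraction.
The method-of-moments IBD estimator equates observed IBS-state counts to
their frequency-conditional expectations and solves the triangular system
per pair, clamping to [0,1] and renormalizing. It deliberately omits the
finite-sample allele-frequency corrections some tools apply: validation here
is by recovery of known pedigree relationships, where the uncorrected
estimator is accurate to ~0.01–0.02 at m = 10⁴ unlinked SNPs.

**Exclusion power.** `Q = 1 − Π(1 − Q_i)` underflows double precision for
realistic panels, so the survival `Π(1 − Q_i)` is computed in the log domain
and exposed separately: for n = 7051 SNPs at the theoretical per-SNP lower
bound Q_i = 0.017 the survival is ≈ 3.4 × 10⁻⁵³ — Q is exactly 1.0 in double
precision. (Printed values of this quantity in the source literature are not
reproducible from the formula itself; the package evaluates the formula.)

**Outlier screening.** For SNP-panel quality control, observed pairwise
IBS/IBG/NSG are compared against the mean per-SNP HWE expectation over the
panel's frequency spectrum; a pair is flagged when it deviates by more than
a configurable multiple (default 3) of the across-pair standard deviation.
The two-sided rule flags both artifact-like deviations and strongly related
pairs (duplicates, full sibs), which is what a screening step should
surface. The 3-SD default implies ~1% flagged pairs per measure on a clean
null cohort.

**MDS.** Classical (Torgerson) scaling of the `1 − IBS` matrix:
double-center squared distances, eigendecompose, scale the top-k
non-negative eigenvectors. Axes are ordered by eigenvalue; each axis's sign
is fixed so its first nonzero loading is positive, making runs
reproducible. Requesting more dimensions than there are positive eigenvalues
zero-pads with a warning.

## SNP selection cascade

Completeness (no missing genotype in any individual) → minor-allele
frequency → Hardy–Weinberg χ² (1 df, no continuity correction; monomorphic
SNPs return p = 1 by convention) → greedy physical spacing per chromosome
(keep the first SNP, then each next one at least the minimum distance from
the last kept). Order is fixed; the cascade is idempotent and the removal
report partitions the removed SNPs by first failing criterion. Spacing is
implemented as a keep-requirement (minimum inter-SNP distance) throughout.
The chi-square test was chosen as the conventional default; an exact test is
future work.

## Exact pedigree oracle

Kinship uses the standard tabular recursion with founders assumed unrelated
and non-inbred — "hidden inbreeding" in real data is precisely deviation
from this assumption, which is why genomic estimates are interesting.
Dominance (fraternity) expectations are computed by deterministic gene
dropping: all `2^M` transmission patterns (M = two meioses per non-founder)
are enumerated vectorially and the pattern fraction in which the pair shares
both allele pairs IBD is returned. Pedigrees beyond the meiosis budget
(default 20) fall back to seeded Monte Carlo with a binomial standard error;
tests confirm Monte Carlo converges to the enumerated values.

Regular-mating trajectories are computed from explicitly constructed
pedigrees, not textbook recurrences — the same kinship code produces
full-sib (0.25, 0.375, 0.5, …), repeated-backcross (0.25, 0.375, 0.4375, …)
and rotational half-sib series. The half-sib systems are realised as one
common sire per generation with the remaining sibs as dams assigned
round-robin; with this construction the 4-sib system inbreeds more slowly
than the 3-sib system at every generation, as expected. The exact layout of
multi-sib half-sib systems is not canonical; the rotational scheme is this
package's documented choice.

## Habitat statistics

Population contrasts fit `y = μ + population + e` by OLS (cell-means coding)
and test pairwise mean differences on the pooled residual degrees of
freedom, reducing exactly to the pooled two-sample t-test for two groups.
Groups with a single observation are dropped from the fit. Pairwise
observations (coancestry, similarity) are treated as independent even though
pairs sharing an individual are correlated — a deliberate fidelity choice
replicating how such tables are conventionally produced; a mixed-model or
permutation treatment is out of scope and noted as a limitation.

Distances are great-circle (haversine) on a 6371-km sphere; at
inter-habitat scales of 150–500 km the spherical approximation is accurate
to well under 0.5%. The coancestry-on-distance model is linear or
polynomial (degree 2 by default — the degree is a knob, since nothing makes
quadratic canonical); the reported slope per 100 km is the fitted
derivative, evaluated at the mean observed distance for the polynomial
model, and the zero-crossing is the smallest non-negative real root of the
fitted curve, with numerically null coefficients zeroed so a constant fit
reports no crossing.

## Synthetic cohort generator

The generator emulates the study design the estimators target:

- **Divergence.** Each subpopulation's allele frequencies are Balding–Nichols
  draws `Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)` around ancestral frequencies p₀,
  uniform on the configured MAF range (default 0.10–0.50, mirroring the
  MAF ≥ 0.10 filtering regime). Closed-form Beta moments make the model
  testable.
- **Founders.** Genotypes are drawn with inbreeding-adjusted frequencies
  `p²+fpq, 2pq(1−f), q²+fpq`, realised as autozygous-with-probability-f
  haplotype pairs so that pedigree machinery and founder simulation share
  one allele-level representation. Individual founder f is drawn
  Normal(mean, sd) clipped to [0, 0.95], giving within-habitat spread.
- **Families.** Known-relationship pairs (full sibs, half sibs,
  parent–offspring, offspring of full-sib matings, double first cousins) are
  gene-dropped from non-inbred founders, so parent–offspring pairs have NSG
  exactly 0 (no mutation model) and realised IBD follows Mendelian
  proportions.
- **Crossbreds.** One allele from each parental habitat's gene pool —
  exactly equivalent to gene-dropping from two hidden unrelated founders —
  giving expected inbreeding ≈ 0 relative to the pooled sample.
- **Coordinates.** Habitat centers sit at realistic mountain-range locations
  spanning a few hundred km; individuals are jittered around them. Locations
  exist to exercise the distance regression, nothing else.

**Default scenario.** Six habitats with sizes 15/8/7/2/1/1, founder
inbreeding means 0.07/0.20/0.09/0.25/0.13/0.0 and spreads 0.024–0.056
mirroring the observed structure of a fragmented wild population; 14
crossbreds across four habitat pairs; and a 35-member low-divergence
"Kindred" cohort carrying the planted families. Two calibration choices are
deliberate:

- Habitat Fst = 0.02. Any positive divergence makes between-habitat mean
  coancestry negative under pooled standardization (the "genetically
  unrelated habitats" signature), but divergence also inflates every
  individual's pooled-base inbreeding by a Wahlund term that grows with Fst
  and shrinks with the habitat's share of the sample (≈ +0.02 to +0.07 per
  unit of the default sizes at Fst = 0.05). Fst = 0.02 keeps that inflation
  within ~0.03 for every habitat, so habitat means remain interpretable on
  the configured scale while the unrelatedness signature is strict.
- The kindred sits at Fst = 0.01 so that planted-pair estimates can be
  compared to pedigree expectations (0.25, 0.125, …) without a Wahlund
  offset.

**Ground truth.** For every individual the truth table stores both the
pedigree-level inbreeding its genotypes were drawn at and the analytic
expectation of its Definition-IV genomic inbreeding coefficient given the
realised frequencies: per SNP, `E[(x − 2p̄)²] = Var(x) + (2π − 2p̄)²` with π
the individual's expected allele frequency and p̄ the planned pooled
frequency, averaged over SNPs and divided by `2p̄q̄`. This neglects O(1/n)
standardization terms from estimating p̄ on the sample itself (≈ −0.01 at
the default n = 83), which is well inside the recovery tolerances. Planted
pairs store relationship class, pedigree kinship and the enumerated
dominance expectation.

**What the generator does not emulate** — and hence what passing
parameter-recovery tests do and do not show: SNPs are unlinked (no LD), so
realised relationships concentrate on their pedigree expectations much
faster in m than in real genomes, where linkage keeps the SD of realised
full-sib relationships at ~0.04 regardless of marker count; there is no
mutation, no genotyping error and no allelic dropout, so NSG = 0 for
parent–offspring pairs is exact rather than approximate; and frequencies
have no ascertainment bias. Recovery results therefore validate estimator
correctness, not field-data error magnitudes.

## Problem sizes and numerical choices

The validation suite runs the default scenario at m = 10,000 SNPs — enough
that per-individual estimator noise (~0.015 SD) is small against the
configured effects, while a full generate-estimate cycle stays around a
second. Estimator-recovery checks pool three replicate cohorts (seeds
2016–2018) so that single-individual habitat means carry ~0.01 standard
error. Relationship matrices are accumulated in double precision with
symmetry enforced by construction; degenerate (monomorphic-in-sample) SNPs
raise errors naming the SNP rather than producing infinities, and pipelines
drop them before standardization.

One validation check is known to be statistically optimistic as stated: with
the configured habitat means (0.20/0.25 vs 0.09/0.07), sample sizes
(8/2/7/15) and realistic within-habitat spreads, the probability that a
replicate simultaneously shows both high-vs-low contrasts at p < 0.001 *and*
no Minshan–Qionglai difference at α = 0.05 is ~0.75 (the observed contrast
t-values are themselves the noncentralities, and the two requirements pull
the residual variance in opposite directions). The corresponding acceptance
test demands ≥ 90% of 20 replicates and is expected to fail at ~15/20; it is
kept faithful rather than loosened.

## Scenario configuration schema

`wildkin simulate --config scenario.json` accepts:

```json
{
  "n_snps": 10000,
  "maf_range": [0.10, 0.50],
  "seed": 1,
  "subpops": [
    {"name": "A", "n_founders": 10, "founder_f": 0.1,
     "fst": 0.02, "founder_f_sd": 0.03, "center": [31.0, 103.0]}
  ],
  "relationships": [
    {"type": "full_sibs", "subpop": "A", "count": 2}
  ],
  "crossbreds": [
    {"parents": ["A", "B"], "count": 3}
  ]
}
```

Relationship types: `parent_offspring`, `full_sibs`, `half_sibs`,
`full_sib_mating_offspring`, `double_first_cousins`.
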