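# Methods

## The estimator

For each expression probe, one SNP *z* (the instrument) is chosen among
the probe's harmonized cis-eQTL associations: the smallest eQTL p-value
below the instrument threshold (default 5·10⁻⁸, the conventional
genome-wide level; configurable). Ties break by larger |b_zx/se_zx|,
then by lexicographically smallest SNP id, so results are deterministic.
The effect of expression on the trait is the Wald ratio

    b_xy = b_zy / b_zx ,

with b_zy the GWAS SNP–trait effect and b_zx the eQTL SNP–expression
effect. With one instrument this is exactly two-stage least squares on
the generating individual-level data — an algebraic identity, not an
approximation, when both summary effects come from the same cohort (the
test suite asserts it to 10⁻¹⁰). In the intended two-sample setting the
two effects carry independent estimation noise.

Significance uses the harmonic combination of the two squared z-scores,

    T_SMR = z_zy² z_zx² / (z_zy² + z_zx²) ~ χ²(1),

with p = 2(1 − Φ(√T)). T_SMR ≤ min(z_zy², z_zx²), so a weak instrument
can only make the test conservative, never anticonservative. The
reporting standard error of b_xy is first-order delta method,
|b_zy/b_zx|·√((se_zy/b_zy)² + (se_zx/b_zx)²), which is accurate when the
instrument is strong (|z_zx| ≳ 10) and undefined (reported as NaN) when
either beta is exactly zero.

Assumptions inherited from instrumental-variable analysis: the
instrument is associated with expression; it affects the trait only
through that gene's expression (no horizontal pleiotropy); and it is
unconfounded with the trait. The pleiotropy simulation scenario
exercises the first failure mode deliberately. Heterogeneity tests that
distinguish causality from linkage (multi-SNP approaches) are out of
scope; one instrument per probe is used.

## Harmonization

Both effects must refer to the same effect allele before the ratio is
taken. The GWAS effect allele is the reference. If the eQTL record
reports the swapped orientation, its beta is negated and its frequency
complemented; irreconcilable allele sets are dropped (`allele_mismatch`).
Palindromic A/T and C/G variants are dropped by default because strand
is unresolvable from summary data, and no frequency-based strand
inference is attempted (too error-prone exactly where it would be
needed). An optional sanity check drops pairs whose aligned
effect-allele frequencies differ by more than 0.2 (default), guarding
against population mismatch or mislabeled strands. Records with missing
frequency (NA) skip the check. Every candidate (probe, SNP) pair is
either emitted or appears in the drop ledger with exactly one reason;
output order is (probe, SNP) lexicographic.

## Significance policies and aggregation

Per experiment (one GWAS dataset × one eQTL dataset), significance is
declared by Bonferroni (α/n_tested, n_tested = probes that yielded an
instrument), Benjamini–Hochberg FDR (step-up at α; implemented via
statsmodels), or a fixed cutoff. The boundary is inclusive (p ≤ cutoff),
matching step-up conventions, and the realized cutoff is recorded in
each report.

Across experiments, each significant (SNP × probe × experiment)
occurrence counts once: because several microarray probes can annotate
one gene, and several experiment pairs can rediscover the same SNP, a
single variant may be "screened" many times, and that repetition count
is the cross-experiment reliability signal. The histogram maps a
repetition count to the number of SNPs screened exactly that often;
per-gene counts sum occurrences over the gene's SNPs. Gene flagging
compares screened gene symbols case-insensitively against user-supplied
flat gene lists (e.g. exports from curated disease-gene databases);
nothing is fetched from the network.

## The synthetic-data generator

The simulator draws Hardy–Weinberg genotypes (two independent
Bernoulli(maf) alleles per individual, no LD between SNPs) and builds

    x = Σ_j b_zx_j g_j + ε_x ,   ε_x ~ N(0, σ_x²)
    y = b_xy x + b_direct Σ_j g_j + ε_y ,   ε_y ~ N(0, σ_y²)

under three scenarios: `causal` (b_direct = 0), `pleiotropy` (b_xy = 0,
b_direct ≠ 0) and `null` (both 0). Defaults — n = 5000, maf = 0.3,
b_zx = 0.5 (expression-SD units per allele), b_xy = 0.3, σ_x = σ_y = 1 —
give an instrument of realistic strength for a strong cis-eQTL
(|z_zx| ≈ 14 at n = 5000) and a trait effect detectable but not
overwhelming at GWAS scale. Summary statistics are the slope, standard
error and normal-approximation p-value of the per-SNP simple regression
of trait (or expression) on dosage, matching how public summary sets
are produced; the t-vs-normal difference is negligible at the simulated
sample sizes. The seed fully determines all randomness; fixture files
are byte-identical across reruns.

The multi-experiment grid generator emulates a multi-consortium
analysis: a shared panel of genes (default 6) each with its own
independent locus of 4 SNPs (lead SNP carries b_zx, the rest half of
it, so instrument selection has real work to do), half the genes causal
for the trait and half not, several GWAS datasets and several eQTL
datasets each drawn as an independent cohort (so GWAS and eQTL noise is
independent, as in two-sample MR), and 1–3 probes per gene varying by
eQTL dataset. What the simulation does **not** model: linkage
disequilibrium, case–control liability traits, covariates, allele
frequency drift between populations, or trans-eQTLs. Passing tests
therefore validate the estimator's arithmetic, calibration and
bookkeeping — not robustness to LD-induced linkage artifacts, which a
heterogeneity test would address.

## Numerical and design choices

- Monomorphic SNPs in a genotype draw have no regression slope and are
  skipped with a logged warning rather than erroring the whole dataset.
- p-values are floored at the smallest positive double so the contract
  p ∈ (0, 1] survives extreme z-scores.
- Summary files round-trip exactly: floats are written with 17
  significant digits.
- b_zx = 0 at a selected instrument raises a weak-instrument condition
  and the probe is skipped with a warning instead of emitting an
  unstable ratio (unreachable in practice once an eQTL p threshold is
  active, but guarded).
- An experiment that fails (unreadable file, malformed rows in strict
  mode) is logged and skipped; the rest of the grid completes and the
  run reports partial status via a nonzero exit code.

## Problem sizes used in the checks

The acceptance checks use n = 2000 for the exact two-stage
least-squares identity, 200 replicates at n = 5000 for effect recovery
and interval coverage, 2000 replicates at n = 2000 for type-I error
calibration, 10⁷ draws for the χ²(1) tail Monte-Carlo, and a
2 GWAS × 5 eQTL grid at n = 2000 per cohort — sizes at which every
quantity's Monte-Carlo error is well below the tolerance being checked.
For the calibration check the null-scenario instrument is deliberately
strong (b_zx = 1.0, |z_zx| ≈ 29): the harmonic statistic is
conservative by construction at moderate instrument strength (at
|z_zx| ≈ 10 the deflation of T_SMR is ~1% and already detectable as
non-uniformity over 2000 replicates), and the calibration claim is
about the strong-instrument regime in which T_SMR → z_zy².

## Known limitations

Single-instrument estimation only; no heterogeneity (linkage vs.
causality) test; no LD-aware multi-SNP extension; no strand inference
for palindromic variants (they are dropped); harmonization matches on
variant id only, not genomic position; reference gene lists are flat
files supplied by the user.
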