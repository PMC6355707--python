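# smrpipe

Summary-data Mendelian randomization (SMR) for integrating GWAS and eQTL
summary statistics, aimed at prioritizing genes whose expression level
causally influences a complex trait.

## The problem

Genome-wide association studies report thousands of SNP–trait
associations, but linkage disequilibrium makes it hard to tell which
association reflects a causal gene. If a SNP *z* affects the expression
*x* of a nearby gene (an eQTL effect, b_zx) and also associates with the
trait *y* (a GWAS effect, b_zy), the SNP can serve as an instrumental
variable: random allele assortment at conception shields the ratio

    b_xy = b_zy / b_zx

from the confounding that plagues observational expression–trait
correlations. With a single instrument this Wald ratio is algebraically
identical to two-stage least squares on individual-level data — but it
needs only published summary statistics from two independent studies.
Significance combines the two z-scores into

    T_SMR = z_zy² · z_zx² / (z_zy² + z_zx²),   z = b / se,

referred to a χ²(1) distribution. `smrpipe` implements this estimator,
the allele harmonization it requires, a config-driven pipeline that runs
every configured GWAS × eQTL dataset pair, and the cross-experiment
bookkeeping (significant-SNP counts per experiment, SNP/gene repetition
histograms across probes and experiments, known-vs-novel gene flagging
against reference gene lists). Because consortium-scale input data are
not redistributable, the package ships a synthetic-data generator that
simulates individual-level cohorts under a known causal model and
reduces them to the same summary-statistic dialects, so the whole
pipeline is testable end to end with known ground truth.

## Worked example

```python
from smrpipe import (simulate_cohort, cohort_to_gwas_summary,
                     cohort_to_eqtl_summary, run_smr)
from smrpipe.synthetic_data import causal_scenario

# one gene, one strong cis-eQTL SNP, true effect of expression on trait = 0.3
scenario = causal_scenario(n_individuals=5000, maf=0.3, b_zx=0.5,
                           b_xy=0.3, seed=42)
cohort = simulate_cohort(scenario)
gwas = cohort_to_gwas_summary(cohort, "sim_gwas")
eqtl = cohort_to_eqtl_summary(cohort, {"probe1": ("GENE1", ["rs1"])}, "sim_eqtl")

r = run_smr(gwas, eqtl)[0]
print(f"instrument={r.snp_id}  b_zx={r.b_zx:.4f}  b_zy={r.b_zy:.4f}")
print(f"b_xy={r.b_xy:.4f}  se_xy={r.se_xy:.4f}  T_smr={r.t_smr:.2f}  p_smr={r.p_smr:.3e}")
```

prints

```
instrument=rs1  b_zx=0.5207  b_zy=0.1476
b_xy=0.2835  se_xy=0.0455  T_smr=38.79  p_smr=4.722e-10
```

The eQTL effect (0.52 per allele) and the GWAS effect (0.15 per allele)
combine into an estimated expression→trait effect of 0.28 — within one
standard error (0.046) of the simulated truth 0.3 — and the χ²(1)
statistic 38.8 rejects the null of no effect at p ≈ 5·10⁻¹⁰.

## Command line

```sh
smrpipe simulate -o fixtures/ --scenario causal --seed 1   # GWAS+eQTL TSVs + provenance
smrpipe run -c config.yaml                                 # full experiment grid
smrpipe report -d output/                                  # re-aggregate existing results
```

`config.yaml` lists the GWAS × eQTL experiment pairs, the instrument
p-value threshold (default 5·10⁻⁸), the significance policy (Bonferroni,
Benjamini–Hochberg FDR, or a fixed cutoff) and harmonization options;
see `smrpipe.pipeline.load_config` for the layout. Outputs are TSV
tables (per-experiment results, drop ledger, combined significant table
sorted by p, repetition histogram, gene counts/flags) plus a plain-text
manifest; reruns are byte-identical.

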