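"""Simulation of individual-level cohorts and their reduction to summaries.

The generator instantiates the linear mediation model the Wald-ratio
estimator assumes: genotype z affects gene expression x, and x affects the
trait y, with an optional direct (pleiotropic) genotype-to-trait path:

    x_i = sum_j b_zx_j * g_ij + eps_x,   eps_x ~ N(0, sigma_x^2)
    y_i = b_xy * x_i + sum_j b_direct * g_ij + eps_y,  eps_y ~ N(0, sigma_y^2)

Genotypes are Hardy-Weinberg draws (two independent alleles at frequency
``maf``) with no linkage disequilibrium between SNPs.  Reducing a cohort to
summary statistics uses the same simple per-SNP regressions a GWAS or eQTL
consortium would run, with p-values from the large-sample normal
approximation z = beta/se, matching how public summary data are produced.

Three named scenarios pin the causal structure:

``causal``      b_direct = 0: the ratio b_zy/b_zx recovers b_xy.
``pleiotropy``  b_xy = 0, b_direct != 0: the estimator's failure mode.
``null``        b_xy = b_direct = 0: no genotype-trait association at all.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from smrpipe.sumstats_io import (
    EqtlDataset,
    EqtlRecord,
    GwasDataset,
    GwasRecord,
    write_eqtl_summary,
    write_gwas_summary,
)

import logging

logger = logging.getLogger(__name__)

SCENARIOS = ("causal", "pleiotropy", "null")

# non-palindromic allele pairs cycled over simulated SNPs
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True, slots=True)
class SnpSpec:
    """One simulated SNP: identifier, allele frequency, effect on expression."""

    snp_id: str
    maf: float
    b_zx: float
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must lie in (0, 0.5], got {self.maf}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass(frozen=True, slots=True)
class SimScenario:
    """Generative parameters for one simulated cohort."""

    n_individuals: int
    snps: tuple[SnpSpec, ...]
    b_xy: float
    b_direct: float
    sigma_x: float
    sigma_y: float
    scenario: str
    seed: int

    def __post_init__(self) -> None:
        if self.n_individuals < 10:
            raise ValueError("n_individuals must be at least 10")
        if not self.snps:
            raise ValueError("at least one SNP is required")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("noise SDs must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario == "causal" and self.b_direct != 0:
            raise ValueError("causal scenario requires b_direct = 0")
        if self.scenario == "pleiotropy" and not (self.b_xy == 0 and self.b_direct != 0):
            raise ValueError("pleiotropy scenario requires b_xy = 0 and b_direct != 0")
        if self.scenario == "null" and not (self.b_xy == 0 and self.b_direct == 0):
            raise ValueError("null scenario requires b_xy = 0 and b_direct = 0")


def causal_scenario(*, n_individuals: int = 5000, maf: float = 0.3,
                    b_zx: float = 0.5, b_xy: float = 0.3,
                    sigma_x: float = 1.0, sigma_y: float = 1.0,
                    seed: int = 0, snp_id: str = "rs1") -> SimScenario:
    """Single-SNP causal scenario with conventional defaults."""
    return SimScenario(
        n_individuals=n_individuals,
        snps=(SnpSpec(snp_id, maf, b_zx),),
        b_xy=b_xy, b_direct=0.0,
        sigma_x=sigma_x, sigma_y=sigma_y,
        scenario="causal", seed=seed,
    )


def null_scenario(*, n_individuals: int = 5000, maf: float = 0.3,
                  b_zx: float = 0.5, sigma_x: float = 1.0, sigma_y: float = 1.0,
                  seed: int = 0, snp_id: str = "rs1") -> SimScenario:
    """Single-SNP null scenario: expression heritable, trait independent."""
    return SimScenario(
        n_individuals=n_individuals,
        snps=(SnpSpec(snp_id, maf, b_zx),),
        b_xy=0.0, b_direct=0.0,
        sigma_x=sigma_x, sigma_y=sigma_y,
        scenario="null", seed=seed,
    )


@dataclass(slots=True)
class Cohort:
    """Individual-level realization of (genotype, expression, trait)."""

    genotypes: np.ndarray  # (n, n_snps) int8, entries in {0,1,2}
    expression: np.ndarray  # (n,)
    phenotype: np.ndarray  # (n,)
    scenario: SimScenario

    def __post_init__(self) -> None:
        n = self.scenario.n_individuals
        if self.genotypes.shape != (n, len(self.scenario.snps)):
            raise ValueError("genotype matrix shape inconsistent with scenario")
        if self.expression.shape != (n,) or self.phenotype.shape != (n,):
            raise ValueError("trait vector length inconsistent with scenario")


def simulate_cohort(scenario: SimScenario) -> Cohort:
    """Draw one cohort under the scenario's mediation model.

    Genotype counts are two independent Bernoulli(maf) allele draws per
    individual; identical seeds give bit-identical cohorts.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_individuals
    mafs = np.array([s.maf for s in scenario.snps])
    g = (rng.random((n, len(mafs))) < mafs).astype(np.int8)
    g += (rng.random((n, len(mafs))) < mafs).astype(np.int8)
    b_zx = np.array([s.b_zx for s in scenario.snps])
    x = g @ b_zx + rng.normal(0.0, scenario.sigma_x, size=n)
    y = (scenario.b_xy * x
         + scenario.b_direct * g.sum(axis=1)
         + rng.normal(0.0, scenario.sigma_y, size=n))
    return Cohort(genotypes=g, expression=x, phenotype=y, scenario=scenario)


def _simple_regression(g: np.ndarray, trait: np.ndarray) -> tuple[float, float, float]:
    """Slope, SE and normal-approximation p of trait on genotype dosage."""
    n = g.shape[0]
    gc = g - g.mean()
    tc = trait - trait.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        raise ZeroDivisionError("monomorphic genotype")
    sxy = float(gc @ tc)
    beta = sxy / sxx
    sse = float(tc @ tc) - beta * sxy
    sigma2 = max(sse, 0.0) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        return beta, se, 1.0 if beta == 0.0 else 0.0
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = max(p, np.nextafter(0.0, 1.0))  # keep p in (0, 1]
    return beta, se, p


def cohort_to_gwas_summary(cohort: Cohort, dataset_name: str) -> GwasDataset:
    """Per-SNP regression of the trait on dosage, reported GWAS-style.

    Monomorphic SNPs (zero genotype variance in the draw) are skipped with
    a logged warning.  ``eaf`` is the sample effect-allele frequency.
    """
    records: list[GwasRecord] = []
    for j, spec in enumerate(cohort.scenario.snps):
        g = cohort.genotypes[:, j].astype(float)
        try:
            beta, se, p = _simple_regression(g, cohort.phenotype)
        except ZeroDivisionError:
            logger.warning("%s: SNP %s monomorphic in draw; skipped",
                           dataset_name, spec.snp_id)
            continue
        records.append(GwasRecord(
            snp_id=spec.snp_id,
            effect_allele=spec.effect_allele,
            other_allele=spec.other_allele,
            eaf=float(g.mean() / 2.0),
            beta=beta, se=se, pvalue=p,
            n=cohort.scenario.n_individuals,
        ))
    return GwasDataset(name=dataset_name, records=records)


def cohort_to_eqtl_summary(cohort: Cohort,
                           probe_map: Mapping[str, tuple[str, Sequence[str]]],
                           dataset_name: str) -> EqtlDataset:
    """Per-(probe, SNP) regression of expression on dosage, eQTL-style.

    ``probe_map`` maps probe_id -> (gene_symbol, SNP ids covered by the
    probe).  Probes sharing a SNP produce distinct records with identical
    effect estimates, mirroring how one SNP can be labeled by several
    expression probes.
    """
    snp_index = {s.snp_id: j for j, s in enumerate(cohort.scenario.snps)}
    records: list[EqtlRecord] = []
    for probe_id in sorted(probe_map):
        gene_symbol, snp_ids = probe_map[probe_id]
        for snp_id in snp_ids:
            if snp_id not in snp_index:
                raise ValueError(f"probe {probe_id}: unknown snp_id {snp_id!r}")
            j = snp_index[snp_id]
            spec = cohort.scenario.snps[j]
            g = cohort.genotypes[:, j].astype(float)
            try:
                beta, se, p = _simple_regression(g, cohort.expression)
            except ZeroDivisionError:
                logger.warning("%s: SNP %s monomorphic in draw; skipped",
                               dataset_name, snp_id)
                continue
            records.append(EqtlRecord(
                probe_id=probe_id, gene_symbol=gene_symbol,
                snp_id=snp_id,
                effect_allele=spec.effect_allele,
                other_allele=spec.other_allele,
                eaf=float(g.mean() / 2.0),
                beta=beta, se=se, pvalue=p,
                n=cohort.scenario.n_individuals,
            ))
    return EqtlDataset(name=dataset_name, records=records)


def generate_fixture_files(scenario: SimScenario,
                           probe_map: Mapping[str, tuple[str, Sequence[str]]],
                           out_dir: str | Path) -> list[Path]:
    """Write one GWAS TSV, one eQTL TSV and a provenance record.

    Identical scenarios produce byte-identical files.  Returns the manifest
    of written paths (always three files).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(scenario)
    gwas = cohort_to_gwas_summary(cohort, "sim_gwas")
    eqtl = cohort_to_eqtl_summary(cohort, probe_map, "sim_eqtl")
    gwas_path = out_dir / "gwas.tsv"
    eqtl_path = out_dir / "eqtl.tsv"
    prov_path = out_dir / "provenance.txt"
    write_gwas_summary(gwas, gwas_path)
    write_eqtl_summary(eqtl, eqtl_path)
    with prov_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"scenario={scenario.scenario}\n")
        fh.write(f"seed={scenario.seed}\n")
        fh.write(f"n_individuals={scenario.n_individuals}\n")
        fh.write(f"true_b_xy={scenario.b_xy!r}\n")
        fh.write(f"b_direct={scenario.b_direct!r}\n")
        fh.write(f"sigma_x={scenario.sigma_x!r}\n")
        fh.write(f"sigma_y={scenario.sigma_y!r}\n")
        for s in scenario.snps:
            fh.write(f"snp={s.snp_id},maf={s.maf!r},b_zx={s.b_zx!r},"
                     f"a1={s.effect_allele},a2={s.other_allele}\n")
    return [gwas_path, eqtl_path, prov_path]


def _derive_seed(master_seed: int, label: str) -> int:
    """Stable per-dataset seed below 2**31 derived from a master seed."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass(slots=True)
class GridFixture:
    """Paths and ground truth for a multi-experiment synthetic fixture."""

    gwas_paths: list[Path]
    eqtl_paths: list[Path]
    true_effects: dict[str, float]  # gene_symbol -> true b_xy
    probe_maps: dict[str, dict] = field(default_factory=dict)


def generate_experiment_grid(out_dir: str | Path, *, seed: int = 0,
                             n_gwas: int = 2, n_eqtl: int = 5,
                             n_genes: int = 6, snps_per_gene: int = 4,
                             n_individuals: int = 3000,
                             b_zx: float = 0.5, b_xy: float = 0.3,
                             causal_fraction: float = 0.5) -> GridFixture:
    """Build a grid of GWAS and eQTL summary files over a shared SNP panel.

    Emulates the structure of a multi-consortium analysis: several GWAS
    sets and several eQTL sets over overlapping SNP content, multiple
    probes per gene, some genes causal for the trait and some not.  Each
    gene occupies its own independent locus; within a gene the lead SNP
    carries the expression effect ``b_zx`` and the remaining SNPs carry
    half of it, so instrument selection has real work to do.

    Every dataset is an independent cohort draw (seeded deterministically
    from ``seed``), so GWAS and eQTL effects at a SNP are estimated with
    independent noise, as in real two-sample summary-data MR.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_derive_seed(seed, "panel"))

    genes = [f"GENE{k + 1}" for k in range(n_genes)]
    n_causal = int(round(causal_fraction * n_genes))
    true_effects = {g: (b_xy if k < n_causal else 0.0) for k, g in enumerate(genes)}

    # Shared per-gene SNP panel: ids, mafs and alleles fixed across datasets.
    panels: dict[str, tuple[SnpSpec, ...]] = {}
    snp_counter = 0
    for gene in genes:
        specs = []
        for j in range(snps_per_gene):
            snp_counter += 1
            maf = float(rng.uniform(0.1, 0.5))
            a1, a2 = _ALLELE_PAIRS[snp_counter % len(_ALLELE_PAIRS)]
            effect = b_zx if j == 0 else 0.5 * b_zx
            specs.append(SnpSpec(f"rs{10000 + snp_counter}", maf, effect, a1, a2))
        panels[gene] = tuple(specs)

    def gene_scenario(gene: str, label: str, n: int) -> SimScenario:
        effect = true_effects[gene]
        return SimScenario(
            n_individuals=n, snps=panels[gene],
            b_xy=effect, b_direct=0.0,
            sigma_x=1.0, sigma_y=1.0,
            scenario="causal" if effect != 0 else "null",
            seed=_derive_seed(seed, f"{label}:{gene}"),
        )

    gwas_paths: list[Path] = []
    for i in range(n_gwas):
        label = f"gwas{i + 1}"
        records: list[GwasRecord] = []
        for gene in genes:
            cohort = simulate_cohort(gene_scenario(gene, label, n_individuals))
            records.extend(cohort_to_gwas_summary(cohort, label).records)
        path = out_dir / f"{label}.tsv"
        write_gwas_summary(GwasDataset(name=label, records=records), path)
        gwas_paths.append(path)

    eqtl_paths: list[Path] = []
    probe_maps: dict[str, dict] = {}
    for i in range(n_eqtl):
        label = f"eqtl{i + 1}"
        n_probes = 1 + (i % 3)  # 1..3 probes per gene, varies by dataset
        records: list[EqtlRecord] = []
        probe_map_all: dict[str, tuple[str, list[str]]] = {}
        for gene in genes:
            cohort = simulate_cohort(gene_scenario(gene, label, n_individuals))
            probe_map = {
                f"{label}_{gene}_p{k + 1}": (gene, [s.snp_id for s in panels[gene]])
                for k in range(n_probes)
            }
            probe_map_all.update(probe_map)
            records.extend(
                cohort_to_eqtl_summary(cohort, probe_map, label).records)
        path = out_dir / f"{label}.tsv"
        write_eqtl_summary(EqtlDataset(name=label, records=records), path)
        eqtl_paths.append(path)
        probe_maps[label] = probe_map_all

    return GridFixture(gwas_paths=gwas_paths, eqtl_paths=eqtl_paths,
                       true_effects=true_effects, probe_maps=probe_maps)
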