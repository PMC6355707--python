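"""Config-driven orchestration of the full GWAS x eQTL analysis grid.

Runs every configured experiment pair through harmonization, SMR and the
significance policy, then aggregates repetition counts and gene flags
across experiments.  All outputs are TSV plus a plain-text manifest; the
run is end-to-end deterministic for fixed inputs and configuration.  A
failing experiment (e.g. an unreadable file) is logged and skipped; the
pipeline completes the rest and reports partial status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from smrpipe.aggregation import (
    ExperimentReport,
    apply_significance,
    count_repetitions,
    flag_known_genes,
)
from smrpipe.harmonization import HarmonizeOptions, harmonize_datasets, write_drop_ledger
from smrpipe.smr_core import SignificancePolicy, SmrConfig, select_instrument, smr_from_pair
from smrpipe.sumstats_io import read_eqtl_summary, read_gwas_summary, write_results_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class ExperimentSpec:
    gwas_path: Path
    eqtl_path: Path
    label: str


@dataclass(slots=True)
class PipelineConfig:
    experiments: list[ExperimentSpec]
    smr: SmrConfig = field(default_factory=SmrConfig)
    harmonize: HarmonizeOptions = field(default_factory=HarmonizeOptions)
    reference_lists: dict[str, Path] = field(default_factory=dict)
    output_dir: Path = Path("smr_output")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        labels = [e.label for e in self.experiments]
        if len(labels) != len(set(labels)):
            raise ValueError("experiment labels must be unique")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML file.

    Layout::

        output_dir: out
        seed: 1
        smr:
          p_eqtl_instrument: 5.0e-8
          significance: {method: bonferroni, alpha: 0.05}
        harmonize:
          drop_palindromic: true
          freq_check: true
          max_freq_diff: 0.2
        reference_lists:
          listA: path/to/genes.txt
        experiments:
          - {gwas: g1.tsv, eqtl: e1.tsv, label: g1_x_e1}
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    experiments = [
        ExperimentSpec(Path(e["gwas"]), Path(e["eqtl"]), str(e["label"]))
        for e in raw.get("experiments", [])
    ]
    smr_raw = dict(raw.get("smr", {}))
    sig_raw = dict(smr_raw.pop("significance", {}))
    smr = SmrConfig(
        p_eqtl_instrument=float(smr_raw.get("p_eqtl_instrument", 5e-8)),
        significance=SignificancePolicy(
            method=str(sig_raw.get("method", "bonferroni")),
            alpha=float(sig_raw.get("alpha", 0.05)),
            cutoff=(float(sig_raw["cutoff"]) if "cutoff" in sig_raw else None),
        ),
    )
    harm_raw = dict(raw.get("harmonize", {}))
    harmonize = HarmonizeOptions(
        drop_palindromic=bool(harm_raw.get("drop_palindromic", True)),
        freq_check=bool(harm_raw.get("freq_check", True)),
        max_freq_diff=float(harm_raw.get("max_freq_diff", 0.2)),
    )
    return PipelineConfig(
        experiments=experiments,
        smr=smr,
        harmonize=harmonize,
        reference_lists={k: Path(v) for k, v in (raw.get("reference_lists") or {}).items()},
        output_dir=Path(raw.get("output_dir", "smr_output")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


@dataclass(slots=True)
class RunManifest:
    """Outcome of a pipeline run: written files and per-experiment status."""

    files: dict[str, int]  # relative path -> row count (data rows)
    completed: list[str]
    failed: dict[str, str]  # label -> error message
    reports: list[ExperimentReport]

    @property
    def ok(self) -> bool:
        return not self.failed


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> int:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return len(rows)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every experiment, aggregate across them, write all outputs.

    Per experiment: ``<label>.drops.tsv`` (harmonization ledger),
    ``<label>.smr.tsv`` (all tested probes), ``<label>.significant.tsv``.
    Cross-experiment: ``experiment_counts.tsv`` (one row per experiment
    with its significant count), ``combined_significant.tsv`` (all
    significant results sorted by p), ``snp_repetitions.tsv``,
    ``repetition_histogram.tsv``, ``gene_counts.tsv`` and, when reference
    lists are configured, ``gene_flags.tsv``.  ``manifest.txt`` lists every
    written file with its data row count.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, int] = {}
    completed: list[str] = []
    failed: dict[str, str] = {}
    reports: list[ExperimentReport] = []

    for exp in config.experiments:
        try:
            gwas = read_gwas_summary(exp.gwas_path)
            eqtl = read_eqtl_summary(exp.eqtl_path)
            pairs, drops = harmonize_datasets(gwas, eqtl, config.harmonize)
            by_probe: dict[str, list] = {}
            for p in pairs:
                by_probe.setdefault(p.probe_id, []).append(p)
            results = []
            for probe_id in sorted(by_probe):
                instrument = select_instrument(by_probe[probe_id],
                                               config.smr.p_eqtl_instrument)
                if instrument is not None:
                    results.append(smr_from_pair(instrument))
            n_tested = len(results)
            report = apply_significance(results, config.smr.significance,
                                        n_tested=n_tested,
                                        experiment_label=exp.label)
        except Exception as exc:  # crash isolation: one bad experiment
            logger.error("experiment %s failed: %s", exp.label, exc)
            failed[exp.label] = str(exc)
            continue

        drop_path = out / f"{exp.label}.drops.tsv"
        write_drop_ledger(drops, drop_path)
        files[drop_path.name] = len(drops)
        smr_path = out / f"{exp.label}.smr.tsv"
        write_results_table(results, smr_path)
        files[smr_path.name] = len(results)
        sig_path = out / f"{exp.label}.significant.tsv"
        write_results_table(report.significant, sig_path)
        files[sig_path.name] = len(report.significant)
        logger.info(
            "experiment %s: read %d GWAS / %d eQTL records, %d pairs, "
            "%d dropped, %d tested, %d significant (cutoff %.4g)",
            exp.label, len(gwas), len(eqtl), len(pairs), len(drops),
            n_tested, len(report.significant), report.cutoff_used)
        completed.append(exp.label)
        reports.append(report)

    # Cross-experiment aggregation.
    counts_rows = [
        [r.experiment_label, r.n_tested, len(r.significant), f"{r.cutoff_used:.6e}"]
        for r in reports
    ]
    files["experiment_counts.tsv"] = _write_tsv(
        out / "experiment_counts.tsv",
        ["experiment", "n_tested", "n_significant", "cutoff"], counts_rows)

    combined = [r for rep in reports for r in rep.significant]
    write_results_table(combined, out / "combined_significant.tsv")
    files["combined_significant.tsv"] = len(combined)

    summary = count_repetitions(reports)
    files["snp_repetitions.tsv"] = _write_tsv(
        out / "snp_repetitions.tsv", ["SNP", "occurrences"],
        [[s, c] for s, c in summary.snp_counts.items()])
    files["repetition_histogram.tsv"] = _write_tsv(
        out / "repetition_histogram.tsv", ["repetitions", "n_snps"],
        [[k, v] for k, v in summary.histogram.items()])
    files["gene_counts.tsv"] = _write_tsv(
        out / "gene_counts.tsv", ["gene", "occurrences"],
        [[g, c] for g, c in summary.gene_counts.items()])

    if config.reference_lists:
        flags = flag_known_genes(summary, config.reference_lists)
        flags_path = out / "gene_flags.tsv"
        flags.to_csv(flags_path, sep="\t")
        files["gene_flags.tsv"] = len(flags)

    manifest = RunManifest(files=files, completed=completed,
                           failed=failed, reports=reports)
    with (out / "manifest.txt").open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"completed={len(completed)}\nfailed={len(failed)}\n")
        for label, msg in failed.items():
            fh.write(f"failed_experiment={label}: {msg}\n")
        for name in sorted(files):
            fh.write(f"file={name}\trows={files[name]}\n")
    return manifest
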