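"""Cross-experiment bookkeeping: significance, repetition counts, gene flags.

A multi-consortium analysis runs every GWAS set against every eQTL set.
Because one SNP can be labeled by several expression probes, and several
experiment pairs can rediscover the same SNP, the same variant may be
"screened" many times; the repetition histogram over (SNP x probe x
experiment) occurrences is the cross-experiment reliability signal, and
gene-level counts aggregate it per annotated gene symbol.  Finally, the
genes can be flagged known/novel against user-supplied reference gene
lists (flat one-symbol-per-line files, e.g. exports from curated
disease-gene databases).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from smrpipe.smr_core import SignificancePolicy, SmrResult


@dataclass(slots=True)
class ExperimentReport:
    """Significant results of one GWAS x eQTL experiment."""

    experiment_label: str
    significant: list[SmrResult]
    n_tested: int
    cutoff_used: float

    def __post_init__(self) -> None:
        for r in self.significant:
            if r.p_smr > self.cutoff_used:
                raise ValueError(
                    f"{self.experiment_label}: result {r.snp_id} has "
                    f"p_smr {r.p_smr} above the realized cutoff {self.cutoff_used}")


@dataclass(slots=True)
class RepetitionSummary:
    """Occurrence counts of SNPs and genes among significant results."""

    snp_counts: dict[str, int] = field(default_factory=dict)
    gene_counts: dict[str, int] = field(default_factory=dict)
    histogram: dict[int, int] = field(default_factory=dict)

    @property
    def n_distinct_snps(self) -> int:
        return len(self.snp_counts)

    @property
    def n_occurrences(self) -> int:
        return sum(self.snp_counts.values())


def apply_significance(results: Sequence[SmrResult],
                       policy: SignificancePolicy,
                       n_tested: int,
                       experiment_label: str = "experiment") -> ExperimentReport:
    """Declare significant results under the configured policy.

    bonferroni: cutoff = alpha / n_tested (n_tested = probes tested, which
    may exceed len(results) when probes lacked instruments).  fdr:
    Benjamini-Hochberg step-up at alpha over the result p-values; the
    realized cutoff is the largest rejected p (0 if none).  fixed: the
    given cutoff.  The boundary is inclusive: p <= cutoff is significant.
    """
    if n_tested < len(results):
        raise ValueError("n_tested cannot be smaller than the number of results")
    pvals = [r.p_smr for r in results]
    if policy.method == "bonferroni":
        cutoff = policy.alpha / n_tested if n_tested > 0 else policy.alpha
    elif policy.method == "fixed":
        cutoff = float(policy.cutoff)  # validated at construction
    else:  # fdr
        if pvals:
            reject, _, _, _ = multipletests(pvals, alpha=policy.alpha, method="fdr_bh")
            rejected = [p for p, r in zip(pvals, reject) if r]
            cutoff = max(rejected) if rejected else 0.0
        else:
            cutoff = 0.0
    significant = [r for r in results if r.p_smr <= cutoff]
    significant.sort(key=lambda r: (r.p_smr, r.probe_id, r.snp_id))
    return ExperimentReport(
        experiment_label=experiment_label,
        significant=significant,
        n_tested=n_tested,
        cutoff_used=cutoff,
    )


def count_repetitions(reports: Sequence[ExperimentReport]) -> RepetitionSummary:
    """Count how often each SNP and gene recurs among significant results.

    Each significant (SNP, probe, experiment) occurrence contributes one
    count; the histogram maps a repetition count to the number of SNPs
    screened exactly that many times.  Invariant to report order.
    """
    snp_counts: Counter[str] = Counter()
    gene_counts: Counter[str] = Counter()
    for report in reports:
        for r in report.significant:
            snp_counts[r.snp_id] += 1
            gene_counts[r.gene_symbol] += 1
    histogram = Counter(snp_counts.values())
    return RepetitionSummary(
        snp_counts=dict(sorted(snp_counts.items())),
        gene_counts=dict(sorted(gene_counts.items())),
        histogram=dict(sorted(histogram.items())),
    )


def flag_known_genes(summary: RepetitionSummary,
                     reference_lists: Mapping[str, str | Path]) -> pd.DataFrame:
    """Flag each screened gene known/novel against named reference lists.

    Each reference list is a plain text file, one gene symbol per line
    (blank lines and lines starting with '#' ignored); matching is
    case-insensitive.  Returns a DataFrame indexed by gene symbol with one
    boolean ``known_<list>`` column per list.
    """
    known: dict[str, set[str]] = {}
    for list_name, path in reference_lists.items():
        path = Path(path)
        symbols = set()
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                s = line.strip()
                if s and not s.startswith("#"):
                    symbols.add(s.upper())
        known[list_name] = symbols
    genes = sorted(summary.gene_counts)
    data = {
        f"known_{name}": [g.upper() in syms for g in genes]
        for name, syms in known.items()
    }
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    df.insert(0, "occurrences", [summary.gene_counts[g] for g in genes])
    return df
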