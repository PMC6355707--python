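"""The SMR estimator: instrument selection, Wald ratio, chi-square test.

For a probe with instrument SNP z, exposure x (expression) and outcome y
(trait), the effect of expression on the trait is estimated as the ratio

    b_xy = b_zy / b_zx

of the SNP-trait effect (from GWAS) over the SNP-expression effect (from
eQTL).  With one instrument this is the Wald ratio, algebraically
identical to two-stage least squares on the individual-level data.
Significance combines the two z-scores z_zy = b_zy/se_zy and
z_zx = b_zx/se_zx into

    T_SMR = z_zy^2 * z_zx^2 / (z_zy^2 + z_zx^2)

referred to a chi-square distribution with one degree of freedom.  T_SMR
is bounded by the smaller squared z-score, which keeps the test
conservative when the instrument is weak.  The reporting standard error
of b_xy comes from the first-order delta method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from smrpipe.harmonization import HarmonizedPair, HarmonizeOptions, harmonize_datasets
from smrpipe.sumstats_io import EqtlDataset, GwasDataset

logger = logging.getLogger(__name__)


class WeakInstrumentError(ValueError):
    """Raised when b_zx = 0 makes the Wald ratio undefined."""


@dataclass(frozen=True, slots=True)
class SignificancePolicy:
    """How per-experiment significance is declared.

    method: "bonferroni" (cutoff alpha/n_tested), "fdr" (Benjamini-
    Hochberg step-up at alpha), or "fixed" (use ``cutoff`` as given).
    """

    method: str = "bonferroni"
    alpha: float = 0.05
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in {"bonferroni", "fdr", "fixed"}:
            raise ValueError(f"unknown significance method {self.method!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.method == "fixed":
            if self.cutoff is None or not (0.0 < self.cutoff < 1.0):
                raise ValueError("fixed policy requires a cutoff in (0, 1)")


@dataclass(frozen=True, slots=True)
class SmrConfig:
    p_eqtl_instrument: float = 5e-8
    significance: SignificancePolicy = field(default_factory=SignificancePolicy)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_eqtl_instrument < 1.0):
            raise ValueError("p_eqtl_instrument must lie in (0, 1)")


@dataclass(frozen=True, slots=True)
class SmrResult:
    """One probe's instrument and the SMR estimate built on it."""

    probe_id: str
    gene_symbol: str
    snp_id: str
    b_zx: float
    se_zx: float
    p_eqtl: float
    b_zy: float
    se_zy: float
    p_gwas: float
    b_xy: float
    se_xy: float  # NaN when the delta-method SE is undefined (b_zy = 0)
    t_smr: float
    p_smr: float


def select_instrument(pairs_for_probe: Sequence[HarmonizedPair],
                      p_threshold: float) -> Optional[HarmonizedPair]:
    """Pick the probe's instrument: smallest p_eqtl below the threshold.

    Ties break by larger |b_zx/se_zx|, then lexicographically smallest
    snp_id.  Returns None when no pair qualifies.
    """
    probes = {p.probe_id for p in pairs_for_probe}
    if len(probes) > 1:
        raise ValueError(f"mixed probe_ids in instrument selection: {sorted(probes)}")
    qualifying = [p for p in pairs_for_probe if p.p_eqtl < p_threshold]
    if not qualifying:
        return None
    return min(qualifying,
               key=lambda p: (p.p_eqtl, -abs(p.b_zx / p.se_zx), p.snp_id))


def estimate_bxy(b_zy: float, b_zx: float) -> float:
    """Wald-ratio estimate b_xy = b_zy / b_zx."""
    if b_zx == 0.0:
        raise WeakInstrumentError("b_zx = 0: ratio undefined")
    return b_zy / b_zx


def delta_se_bxy(b_zy: float, se_zy: float, b_zx: float, se_zx: float) -> float:
    """First-order delta-method SE of the ratio b_zy/b_zx.

    |b_zy/b_zx| * sqrt((se_zy/b_zy)^2 + (se_zx/b_zx)^2); NaN when either
    beta is zero (relative error undefined).
    """
    if se_zy <= 0 or se_zx <= 0:
        raise ValueError("standard errors must be positive")
    if b_zy == 0.0 or b_zx == 0.0:
        return math.nan
    return abs(b_zy / b_zx) * math.sqrt((se_zy / b_zy) ** 2 + (se_zx / b_zx) ** 2)


def smr_statistic(b_zy: float, se_zy: float, b_zx: float, se_zx: float) -> float:
    """Chi-square(1) statistic combining the GWAS and eQTL z-scores.

    t = z_zy^2 z_zx^2 / (z_zy^2 + z_zx^2); 0 when both z-scores are 0.
    """
    if se_zy <= 0 or se_zx <= 0:
        raise ValueError("standard errors must be positive")
    z2_zy = (b_zy / se_zy) ** 2
    z2_zx = (b_zx / se_zx) ** 2
    denom = z2_zy + z2_zx
    if denom == 0.0:
        return 0.0
    return (z2_zy * z2_zx) / denom


def smr_pvalue(t: float) -> float:
    """Upper-tail chi-square(1) probability at t, i.e. 2*(1 - Phi(sqrt(t)))."""
    if t < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    return float(stats.chi2.sf(t, df=1))


def smr_from_pair(pair: HarmonizedPair) -> SmrResult:
    """Compute the full SMR result for one harmonized instrument pair."""
    b_xy = estimate_bxy(pair.b_zy, pair.b_zx)
    se_xy = delta_se_bxy(pair.b_zy, pair.se_zy, pair.b_zx, pair.se_zx)
    t = smr_statistic(pair.b_zy, pair.se_zy, pair.b_zx, pair.se_zx)
    return SmrResult(
        probe_id=pair.probe_id, gene_symbol=pair.gene_symbol,
        snp_id=pair.snp_id,
        b_zx=pair.b_zx, se_zx=pair.se_zx, p_eqtl=pair.p_eqtl,
        b_zy=pair.b_zy, se_zy=pair.se_zy, p_gwas=pair.p_gwas,
        b_xy=b_xy, se_xy=se_xy, t_smr=t, p_smr=smr_pvalue(t),
    )


def run_smr(gwas: GwasDataset, eqtl: EqtlDataset,
            config: SmrConfig = SmrConfig(),
            harmonize_opts: HarmonizeOptions = HarmonizeOptions(),
            ) -> list[SmrResult]:
    """Harmonize, select one instrument per probe, estimate and test.

    Probes with no qualifying instrument are logged and omitted; a probe
    whose instrument has b_zx exactly 0 (impossible once the eQTL p
    threshold is finite, but guarded anyway) is skipped with a warning.
    Deterministic for fixed inputs and config; results come out in
    (probe_id) lexicographic order.
    """
    pairs, _drops = harmonize_datasets(gwas, eqtl, harmonize_opts)
    by_probe: dict[str, list[HarmonizedPair]] = {}
    for p in pairs:
        by_probe.setdefault(p.probe_id, []).append(p)
    results: list[SmrResult] = []
    for probe_id in sorted(by_probe):
        instrument = select_instrument(by_probe[probe_id], config.p_eqtl_instrument)
        if instrument is None:
            logger.info("probe %s: no instrument at p < %g",
                        probe_id, config.p_eqtl_instrument)
            continue
        try:
            results.append(smr_from_pair(instrument))
        except WeakInstrumentError:
            logger.warning("probe %s: instrument %s has b_zx = 0; skipped",
                           probe_id, instrument.snp_id)
    return results
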