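"""Readers and writers for tab-delimited GWAS and eQTL summary statistics.

Both dialects are header-bound TSV: columns are located by name, never by
position.  The GWAS dialect carries {SNP, A1, A2, freq, b, se, p, n} where
A1 is the effect allele; the eQTL dialect adds {probe, gene} in front.
Files are UTF-8 with "." as the decimal separator; scientific notation is
accepted everywhere a number is.  A missing effect-allele frequency may be
encoded as "NA", in which case downstream frequency checks are skipped for
that SNP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ("SNP", "A1", "A2", "freq", "b", "se", "p", "n")
EQTL_COLUMNS = ("probe", "gene") + GWAS_COLUMNS

RESULT_COLUMNS = (
    "index", "SNP", "GENE", "probe",
    "b_zx", "se_zx", "p_eqtl",
    "b_zy", "se_zy", "p_gwas",
    "b_xy", "se_xy", "T_smr", "p_smr",
)


class SumstatsFormatError(ValueError):
    """The file as a whole is malformed (e.g. a required column is missing)."""


class SumstatsValidationError(ValueError):
    """A data row violates a record invariant (strict mode only)."""


@dataclass(frozen=True, slots=True)
class GwasRecord:
    """One SNP's summary association with the trait (houses b_zy)."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: Optional[float]  # None when the source file reports NA
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> None:
        if self.effect_allele == self.other_allele:
            raise SumstatsValidationError(
                f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0) or math.isnan(self.se):
            raise SumstatsValidationError(f"{self.snp_id}: se must be > 0")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SumstatsValidationError(f"{self.snp_id}: eaf outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise SumstatsValidationError(f"{self.snp_id}: p outside (0, 1]")
        if math.isnan(self.beta):
            raise SumstatsValidationError(f"{self.snp_id}: beta is NaN")
        if self.n <= 0:
            raise SumstatsValidationError(f"{self.snp_id}: n must be positive")


@dataclass(frozen=True, slots=True)
class EqtlRecord:
    """One SNP's summary association with a probe's expression (houses b_zx)."""

    probe_id: str
    gene_symbol: str
    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> None:
        GwasRecord.validate(self)  # type: ignore[arg-type]  # same numeric invariants
        if not self.probe_id:
            raise SumstatsValidationError(f"{self.snp_id}: empty probe_id")


@dataclass(slots=True)
class GwasDataset:
    name: str
    records: list[GwasRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("dataset name must be nonempty")
        seen: set[str] = set()
        for r in self.records:
            if r.snp_id in seen:
                raise SumstatsValidationError(
                    f"duplicate snp_id {r.snp_id!r} in GWAS dataset {self.name!r}")
            seen.add(r.snp_id)

    def __len__(self) -> int:
        return len(self.records)

    def by_snp(self) -> dict[str, GwasRecord]:
        return {r.snp_id: r for r in self.records}


@dataclass(slots=True)
class EqtlDataset:
    name: str
    records: list[EqtlRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("dataset name must be nonempty")
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.probe_id, r.snp_id)
            if key in seen:
                raise SumstatsValidationError(
                    f"duplicate (probe, SNP) {key} in eQTL dataset {self.name!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def probes(self) -> dict[str, list[EqtlRecord]]:
        out: dict[str, list[EqtlRecord]] = {}
        for r in self.records:
            out.setdefault(r.probe_id, []).append(r)
        return out


def _parse_float(value: str, what: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SumstatsValidationError(
            f"line {line}: non-numeric {what} {value!r}") from None


def _parse_eaf(value, line: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s.upper() in {"NA", "NAN", ""}:
        return None
    return _parse_float(s, "freq", line)


def _read_table(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_gwas_summary(path: str | Path, *, name: Optional[str] = None,
                      mode: str = "strict") -> GwasDataset:
    """Read a GWAS summary-statistic TSV into a :class:`GwasDataset`.

    Parameters
    ----------
    path
        TSV file with header columns ``SNP A1 A2 freq b se p n`` in any order.
    name
        Dataset label; defaults to the file stem.
    mode
        ``"strict"`` aborts on the first invalid row; ``"lenient"`` skips
        invalid rows and logs how many were dropped.
    """
    if mode not in {"strict", "lenient"}:
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    df = _read_table(path, GWAS_COLUMNS)
    records: list[GwasRecord] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            rec = GwasRecord(
                snp_id=str(getattr(row, "SNP")),
                effect_allele=str(getattr(row, "A1")).upper(),
                other_allele=str(getattr(row, "A2")).upper(),
                eaf=_parse_eaf(getattr(row, "freq"), line),
                beta=_parse_float(getattr(row, "b"), "b", line),
                se=_parse_float(getattr(row, "se"), "se", line),
                pvalue=_parse_float(getattr(row, "p"), "p", line),
                n=int(float(getattr(row, "n"))),
            )
            rec.validate()
        except (SumstatsValidationError, ValueError) as exc:
            if mode == "strict":
                if isinstance(exc, SumstatsValidationError):
                    raise SumstatsValidationError(f"{path} line {line}: {exc}") from None
                raise SumstatsValidationError(f"{path} line {line}: {exc}") from exc
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.warning("%s: dropped %d invalid row(s) in lenient mode", path, dropped)
    if not records:
        logger.warning("%s: no data rows parsed", path)
    return GwasDataset(name=name or path.stem, records=records)


def read_eqtl_summary(path: str | Path, *, name: Optional[str] = None,
                      mode: str = "strict") -> EqtlDataset:
    """Read an eQTL summary-statistic TSV into an :class:`EqtlDataset`.

    Same dialect as :func:`read_gwas_summary` plus leading ``probe`` and
    ``gene`` columns.  Duplicate (probe, SNP) pairs are a validation error.
    """
    if mode not in {"strict", "lenient"}:
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    df = _read_table(path, EQTL_COLUMNS)
    records: list[EqtlRecord] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            rec = EqtlRecord(
                probe_id=str(getattr(row, "probe")),
                gene_symbol=str(getattr(row, "gene")),
                snp_id=str(getattr(row, "SNP")),
                effect_allele=str(getattr(row, "A1")).upper(),
                other_allele=str(getattr(row, "A2")).upper(),
                eaf=_parse_eaf(getattr(row, "freq"), line),
                beta=_parse_float(getattr(row, "b"), "b", line),
                se=_parse_float(getattr(row, "se"), "se", line),
                pvalue=_parse_float(getattr(row, "p"), "p", line),
                n=int(float(getattr(row, "n"))),
            )
            rec.validate()
        except (SumstatsValidationError, ValueError) as exc:
            if mode == "strict":
                raise SumstatsValidationError(f"{path} line {line}: {exc}") from None
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.warning("%s: dropped %d invalid row(s) in lenient mode", path, dropped)
    if not records:
        logger.warning("%s: no data rows parsed", path)
    return EqtlDataset(name=name or path.stem, records=records)


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return format(x, ".17g")  # round-trips float64 exactly


def _fmt_p(p: float, digits: int = 6) -> str:
    return format(p, f".{digits}e")


def write_gwas_summary(dataset: GwasDataset, path: str | Path) -> None:
    """Write a GWAS dataset in the dialect :func:`read_gwas_summary` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(GWAS_COLUMNS) + "\n")
        for r in dataset.records:
            fh.write("\t".join([
                r.snp_id, r.effect_allele, r.other_allele, _fmt(r.eaf),
                _fmt(r.beta), _fmt(r.se), _fmt_p(r.pvalue, 17), str(r.n),
            ]) + "\n")


def write_eqtl_summary(dataset: EqtlDataset, path: str | Path) -> None:
    """Write an eQTL dataset in the dialect :func:`read_eqtl_summary` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EQTL_COLUMNS) + "\n")
        for r in dataset.records:
            fh.write("\t".join([
                r.probe_id, r.gene_symbol,
                r.snp_id, r.effect_allele, r.other_allele, _fmt(r.eaf),
                _fmt(r.beta), _fmt(r.se), _fmt_p(r.pvalue, 17), str(r.n),
            ]) + "\n")


def write_results_table(results, path: str | Path) -> None:
    """Write SMR results as TSV, rows ordered by ascending p_smr.

    Columns: index, SNP, GENE, probe, b_zx, se_zx, p_eqtl, b_zy, se_zy,
    p_gwas, b_xy, se_xy, T_smr, p_smr.  P-values are rendered in scientific
    notation with 7 significant digits; an empty result list produces a
    header-only file.
    """
    path = Path(path)
    ordered = sorted(results, key=lambda r: (r.p_smr, r.probe_id, r.snp_id))
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for i, r in enumerate(ordered, start=1):
            fh.write("\t".join([
                str(i), r.snp_id, r.gene_symbol, r.probe_id,
                _fmt(r.b_zx), _fmt(r.se_zx), _fmt_p(r.p_eqtl),
                _fmt(r.b_zy), _fmt(r.se_zy), _fmt_p(r.p_gwas),
                _fmt(r.b_xy), _fmt(r.se_xy), _fmt(r.t_smr), _fmt_p(r.p_smr),
            ]) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results_table`."""
    df = _read_table(path, RESULT_COLUMNS)
    numeric = [c for c in RESULT_COLUMNS if c not in {"SNP", "GENE", "probe"}]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df
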