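"""Allele harmonization of GWAS and eQTL summary records.

Before taking the ratio b_zy/b_zx the two effects must refer to the same
effect allele.  The GWAS effect allele is adopted as the reference: when
the eQTL record reports the complementary orientation its beta is negated
and its frequency complemented.  Palindromic variants (A/T, C/G) are
dropped by default because strand cannot be resolved from allele labels in
summary data, and an optional allele-frequency sanity check guards against
mislabeled strands or population mismatch.  Mismatches are dropped, never
guessed; every candidate pair is either emitted or lands in the drop
ledger with exactly one reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from smrpipe.sumstats_io import EqtlDataset, EqtlRecord, GwasDataset, GwasRecord

DROP_REASONS = ("allele_mismatch", "palindromic", "freq_mismatch")

_SINGLE_BASES = {"A", "C", "G", "T"}
_PALINDROMIC_SETS = (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True, slots=True)
class HarmonizedPair:
    """A SNP with GWAS and eQTL effects expressed on the same effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    probe_id: str
    gene_symbol: str
    b_zy: float
    se_zy: float
    p_gwas: float
    b_zx: float
    se_zx: float
    p_eqtl: float
    eaf_gwas: Optional[float]
    eaf_eqtl: Optional[float]


@dataclass(frozen=True, slots=True)
class HarmonizeOptions:
    drop_palindromic: bool = True
    freq_check: bool = True
    max_freq_diff: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_freq_diff <= 1.0):
            raise ValueError("max_freq_diff must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class DropRecord:
    probe_id: str
    snp_id: str
    reason: str


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff {a1, a2} is {A, T} or {C, G} (strand-ambiguous pair)."""
    if a1 not in _SINGLE_BASES or a2 not in _SINGLE_BASES:
        return False
    return frozenset((a1, a2)) in _PALINDROMIC_SETS


def align_alleles(g: GwasRecord, e: EqtlRecord,
                  opts: HarmonizeOptions = HarmonizeOptions(),
                  ) -> Union[HarmonizedPair, DropRecord]:
    """Express the eQTL effect on the GWAS effect allele, or drop.

    Returns a :class:`HarmonizedPair`, or a :class:`DropRecord` carrying
    one of the reasons ``allele_mismatch``, ``palindromic``,
    ``freq_mismatch``.
    """
    if g.snp_id != e.snp_id:
        raise ValueError(f"snp_id mismatch: {g.snp_id} vs {e.snp_id}")

    if (g.effect_allele, g.other_allele) == (e.effect_allele, e.other_allele):
        b_zx, eaf_eqtl = e.beta, e.eaf
    elif (g.effect_allele, g.other_allele) == (e.other_allele, e.effect_allele):
        b_zx = -e.beta
        eaf_eqtl = None if e.eaf is None else 1.0 - e.eaf
    else:
        return DropRecord(e.probe_id, g.snp_id, "allele_mismatch")

    if opts.drop_palindromic and is_palindromic(g.effect_allele, g.other_allele):
        return DropRecord(e.probe_id, g.snp_id, "palindromic")

    if (opts.freq_check and g.eaf is not None and eaf_eqtl is not None
            and abs(g.eaf - eaf_eqtl) > opts.max_freq_diff):
        return DropRecord(e.probe_id, g.snp_id, "freq_mismatch")

    return HarmonizedPair(
        snp_id=g.snp_id,
        effect_allele=g.effect_allele,
        other_allele=g.other_allele,
        probe_id=e.probe_id,
        gene_symbol=e.gene_symbol,
        b_zy=g.beta, se_zy=g.se, p_gwas=g.pvalue,
        b_zx=b_zx, se_zx=e.se, p_eqtl=e.pvalue,
        eaf_gwas=g.eaf, eaf_eqtl=eaf_eqtl,
    )


def harmonize_datasets(gwas: GwasDataset, eqtl: EqtlDataset,
                       opts: HarmonizeOptions = HarmonizeOptions(),
                       ) -> tuple[list[HarmonizedPair], list[DropRecord]]:
    """Inner join on snp_id per probe; conserve every candidate pair.

    Output order is deterministic: (probe_id, snp_id) lexicographic.
    Returns (pairs, drop ledger); candidates = emitted + dropped.
    """
    gwas_by_snp = gwas.by_snp()
    pairs: list[HarmonizedPair] = []
    drops: list[DropRecord] = []
    for e in sorted(eqtl.records, key=lambda r: (r.probe_id, r.snp_id)):
        g = gwas_by_snp.get(e.snp_id)
        if g is None:
            continue  # not a candidate: SNP absent from GWAS
        out = align_alleles(g, e, opts)
        if isinstance(out, DropRecord):
            drops.append(out)
        else:
            pairs.append(out)
    return pairs, drops


def write_drop_ledger(drops: list[DropRecord], path: str | Path) -> None:
    """Write the drop ledger as TSV: probe, SNP, reason."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe\tSNP\treason\n")
        for d in drops:
            fh.write(f"{d.probe_id}\t{d.snp_id}\t{d.reason}\n")
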