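import pytest

from smrpipe.smr_core import SmrResult, smr_pvalue, smr_statistic
from smrpipe.sumstats_io import EqtlDataset, EqtlRecord, GwasDataset, GwasRecord
from smrpipe.synthetic_data import causal_scenario, simulate_cohort


def make_gwas_record(snp_id="rs1", a1="A", a2="G", eaf=0.3, beta=0.1,
                     se=0.02, pvalue=1e-6, n=10000):
    return GwasRecord(snp_id=snp_id, effect_allele=a1, other_allele=a2,
                      eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n)


def make_eqtl_record(probe_id="probe1", gene="GENE1", snp_id="rs1", a1="A",
                     a2="G", eaf=0.3, beta=0.5, se=0.03, pvalue=1e-12, n=5000):
    return EqtlRecord(probe_id=probe_id, gene_symbol=gene, snp_id=snp_id,
                      effect_allele=a1, other_allele=a2, eaf=eaf, beta=beta,
                      se=se, pvalue=pvalue, n=n)


def make_result(snp_id="rs1", gene="GENE1", probe_id="probe1",
                b_zx=0.5, se_zx=0.03, p_eqtl=1e-12,
                b_zy=0.15, se_zy=0.02, p_gwas=1e-8, p_smr=None):
    t = smr_statistic(b_zy, se_zy, b_zx, se_zx)
    return SmrResult(
        probe_id=probe_id, gene_symbol=gene, snp_id=snp_id,
        b_zx=b_zx, se_zx=se_zx, p_eqtl=p_eqtl,
        b_zy=b_zy, se_zy=se_zy, p_gwas=p_gwas,
        b_xy=b_zy / b_zx, se_xy=abs(b_zy / b_zx) * ((se_zy / b_zy) ** 2
                                                    + (se_zx / b_zx) ** 2) ** 0.5,
        t_smr=t, p_smr=smr_pvalue(t) if p_smr is None else p_smr,
    )


@pytest.fixture
def causal_cohort():
    """One strong-instrument causal cohort: b_zx=0.5, b_xy=0.3, n=2000."""
    return simulate_cohort(causal_scenario(n_individuals=2000, seed=7))


@pytest.fixture
def small_gwas():
    return GwasDataset(name="gwas_fix", records=[
        make_gwas_record("rs1", "A", "G", 0.30, 0.15, 0.02, 1e-8),
        make_gwas_record("rs2", "C", "T", 0.40, -0.05, 0.02, 1e-2),
        make_gwas_record("rs3", "G", "A", 0.20, 0.08, 0.03, 1e-3),
    ])


@pytest.fixture
def small_eqtl():
    return EqtlDataset(name="eqtl_fix", records=[
        make_eqtl_record("probe1", "GENE1", "rs1", "A", "G", 0.30, 0.5, 0.03, 1e-12),
        make_eqtl_record("probe1", "GENE1", "rs2", "C", "T", 0.40, 0.2, 0.03, 1e-9),
        make_eqtl_record("probe2", "GENE1", "rs1", "A", "G", 0.30, 0.45, 0.04, 1e-10),
        make_eqtl_record("probe3", "GENE2", "rs3", "G", "A", 0.20, 0.6, 0.05, 1e-11),
    ])
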