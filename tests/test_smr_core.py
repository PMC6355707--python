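"""The Wald-ratio estimator, its delta-method SE, and the chi-square test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smrpipe.harmonization import HarmonizeOptions
from smrpipe.smr_core import (
    SmrConfig,
    WeakInstrumentError,
    delta_se_bxy,
    estimate_bxy,
    run_smr,
    select_instrument,
    smr_pvalue,
    smr_statistic,
)
from smrpipe.sumstats_io import GwasDataset, GwasRecord
from smrpipe.synthetic_data import (
    causal_scenario,
    cohort_to_eqtl_summary,
    cohort_to_gwas_summary,
    simulate_cohort,
)

from conftest import make_eqtl_record, make_gwas_record

PROBES = {"p1": ("GENE1", ["rs1"])}


def make_pair(**kw):
    from smrpipe.harmonization import align_alleles
    g = make_gwas_record(beta=kw.get("b_zy", 0.15), se=kw.get("se_zy", 0.02),
                         pvalue=kw.get("p_gwas", 1e-8),
                         snp_id=kw.get("snp_id", "rs1"))
    e = make_eqtl_record(beta=kw.get("b_zx", 0.5), se=kw.get("se_zx", 0.03),
                         pvalue=kw.get("p_eqtl", 1e-12),
                         snp_id=kw.get("snp_id", "rs1"),
                         probe_id=kw.get("probe_id", "probe1"))
    return align_alleles(g, e)


class TestEstimateBxy:
    @pytest.mark.parametrize("b_zy,b_zx,expected", [
        (0.2, 0.5, 0.4), (0.0, 0.5, 0.0), (-0.2, 0.5, -0.4), (0.3, -0.6, -0.5),
    ])
    def test_ratio(self, b_zy, b_zx, expected):
        assert estimate_bxy(b_zy, b_zx) == pytest.approx(expected)

    def test_zero_denominator_flagged(self):
        with pytest.raises(WeakInstrumentError):
            estimate_bxy(0.2, 0.0)


class TestDeltaSe:
    def test_frozen_value(self):
        # 0.4 * sqrt(0.0625 + 0.01) = 0.4 * sqrt(0.0725)
        assert delta_se_bxy(0.2, 0.05, 0.5, 0.05) == pytest.approx(
            0.4 * math.sqrt(0.0725), rel=1e-12)

    def test_against_parametric_bootstrap(self):
        # Well-conditioned regime: sampling SD of the ratio from 1e6 draws.
        rng = np.random.default_rng(42)
        b_zy, se_zy, b_zx, se_zx = 0.2, 0.01, 0.5, 0.01
        draws = (rng.normal(b_zy, se_zy, 1_000_000)
                 / rng.normal(b_zx, se_zx, 1_000_000))
        mc_sd = draws.std(ddof=1)
        assert delta_se_bxy(b_zy, se_zy, b_zx, se_zx) == pytest.approx(mc_sd, rel=0.02)

    def test_homogeneity_in_gwas_scale(self):
        base = delta_se_bxy(0.2, 0.05, 0.5, 0.05)
        assert delta_se_bxy(0.6, 0.15, 0.5, 0.05) == pytest.approx(3 * base, rel=1e-12)

    def test_single_source_limit(self):
        assert delta_se_bxy(0.2, 0.05, 0.5, 1e-15) == pytest.approx(
            0.05 / 0.5, rel=1e-6)

    def test_zero_beta_yields_nan(self):
        assert math.isnan(delta_se_bxy(0.0, 0.05, 0.5, 0.05))


class TestSmrStatistic:
    def test_frozen_harmonic_combination(self):
        # z_zy = 4, z_zx = 10: t = 1600/116
        t = smr_statistic(4.0, 1.0, 10.0, 1.0)
        assert t == pytest.approx(1600 / 116, rel=1e-12)

    def test_null_gwas_signal_gives_zero(self):
        assert smr_statistic(0.0, 1.0, 10.0, 1.0) == 0.0

    def test_both_zero_gives_zero(self):
        assert smr_statistic(0.0, 1.0, 0.0, 1.0) == 0.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(b_zy=st.floats(-5, 5), se_zy=st.floats(0.01, 2),
           b_zx=st.floats(-5, 5), se_zx=st.floats(0.01, 2))
    def test_bounded_by_smaller_squared_zscore(self, b_zy, se_zy, b_zx, se_zx):
        t = smr_statistic(b_zy, se_zy, b_zx, se_zx)
        assert 0.0 <= t <= min((b_zy / se_zy) ** 2, (b_zx / se_zx) ** 2) + 1e-12


class TestSmrPvalue:
    def test_boundary(self):
        assert smr_pvalue(0.0) == 1.0

    def test_conventional_quantile(self):
        assert smr_pvalue(3.841459) == pytest.approx(0.05, abs=1e-5)

    def test_matches_normal_tail_closed_form(self):
        from scipy.stats import norm
        for t in (0.5, 1600 / 116, 30.0):
            assert smr_pvalue(t) == pytest.approx(
                2 * norm.sf(math.sqrt(t)), rel=1e-10)

    def test_strictly_decreasing(self):
        ts = np.linspace(0, 40, 200)
        ps = [smr_pvalue(t) for t in ts]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            smr_pvalue(-1.0)


class TestSelectInstrument:
    def test_smallest_qualifying_p_wins(self):
        pairs = [make_pair(snp_id=s, p_eqtl=p)
                 for s, p in [("rs1", 1e-9), ("rs2", 1e-6), ("rs3", 2e-9)]]
        assert select_instrument(pairs, 5e-8).snp_id == "rs1"

    def test_none_when_no_pair_qualifies(self):
        pairs = [make_pair(snp_id=s, p_eqtl=1e-6) for s in ("rs1", "rs2")]
        assert select_instrument(pairs, 5e-8) is None

    def test_p_tie_breaks_on_instrument_strength(self):
        strong = make_pair(snp_id="rs2", p_eqtl=1e-9, b_zx=0.9, se_zx=0.03)
        weak = make_pair(snp_id="rs1", p_eqtl=1e-9, b_zx=0.3, se_zx=0.03)
        assert select_instrument([weak, strong], 5e-8).snp_id == "rs2"

    def test_full_tie_breaks_lexicographically(self):
        a = make_pair(snp_id="rs10", p_eqtl=1e-9)
        b = make_pair(snp_id="rs2", p_eqtl=1e-9)
        assert select_instrument([a, b], 5e-8).snp_id == "rs10"

    def test_mixed_probes_rejected(self):
        pairs = [make_pair(probe_id="p1"), make_pair(probe_id="p2")]
        with pytest.raises(ValueError, match="mixed"):
            select_instrument(pairs, 5e-8)


class TestRunSmr:
    def test_recovers_causal_effect(self):
        sc = causal_scenario(n_individuals=5000, seed=3)
        c = simulate_cohort(sc)
        res = run_smr(cohort_to_gwas_summary(c, "g"),
                      cohort_to_eqtl_summary(c, PROBES, "e"))
        assert len(res) == 1
        r = res[0]
        assert abs(r.b_xy - 0.3) < 3 * r.se_xy

    def test_wald_ratio_equals_two_stage_least_squares(self, causal_cohort):
        res = run_smr(cohort_to_gwas_summary(causal_cohort, "g"),
                      cohort_to_eqtl_summary(causal_cohort, PROBES, "e"))
        g = causal_cohort.genotypes[:, 0].astype(float)
        tsls = (np.cov(g, causal_cohort.phenotype)[0, 1]
                / np.cov(g, causal_cohort.expression)[0, 1])
        assert abs(res[0].b_xy - tsls) < 1e-10

    def test_no_qualifying_probe_gives_empty_list(self, causal_cohort):
        res = run_smr(cohort_to_gwas_summary(causal_cohort, "g"),
                      cohort_to_eqtl_summary(causal_cohort, PROBES, "e"),
                      SmrConfig(p_eqtl_instrument=1e-300))
        assert res == []

    def test_gwas_scale_invariance(self, causal_cohort):
        gwas = cohort_to_gwas_summary(causal_cohort, "g")
        eqtl = cohort_to_eqtl_summary(causal_cohort, PROBES, "e")
        scaled = GwasDataset(name="g", records=[
            GwasRecord(snp_id=r.snp_id, effect_allele=r.effect_allele,
                       other_allele=r.other_allele, eaf=r.eaf,
                       beta=3 * r.beta, se=3 * r.se, pvalue=r.pvalue, n=r.n)
            for r in gwas.records])
        a, b = run_smr(gwas, eqtl)[0], run_smr(scaled, eqtl)[0]
        assert b.b_xy == pytest.approx(3 * a.b_xy, rel=1e-12)
        assert b.t_smr == pytest.approx(a.t_smr, rel=1e-12)
        assert b.p_smr == pytest.approx(a.p_smr, rel=1e-12)

    def test_sign_coherence_under_gwas_negation(self, causal_cohort):
        gwas = cohort_to_gwas_summary(causal_cohort, "g")
        eqtl = cohort_to_eqtl_summary(causal_cohort, PROBES, "e")
        negated = GwasDataset(name="g", records=[
            GwasRecord(snp_id=r.snp_id, effect_allele=r.effect_allele,
                       other_allele=r.other_allele, eaf=r.eaf,
                       beta=-r.beta, se=r.se, pvalue=r.pvalue, n=r.n)
            for r in gwas.records])
        a, b = run_smr(gwas, eqtl)[0], run_smr(negated, eqtl)[0]
        assert b.b_xy == pytest.approx(-a.b_xy, rel=1e-12)
        assert b.p_smr == pytest.approx(a.p_smr, rel=1e-12)

    def test_result_sign_follows_component_signs(self, causal_cohort):
        res = run_smr(cohort_to_gwas_summary(causal_cohort, "g"),
                      cohort_to_eqtl_summary(causal_cohort, PROBES, "e"))[0]
        assert math.copysign(1, res.b_xy) == (
            math.copysign(1, res.b_zy) * math.copysign(1, res.b_zx))
        assert res.t_smr >= 0
        assert 0 < res.p_smr <= 1
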