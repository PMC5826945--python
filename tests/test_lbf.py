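import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sczprio.config import PipelineConfig
from sczprio.errors import ParameterError, ValidationError
from sczprio.lbf import (
    bonferroni,
    esnp_lbf,
    find_esnps,
    gene_lbf,
    lbf_empirical_p,
    lbf_scan,
    lbf_sign_change_z2,
    lbf_to_bayes_factor,
    null_total_lbfs,
)
from sczprio.types import EqtlAssociation, p_from_z


def eqtl_rec(snp, gene, z, cis="cis"):
    return EqtlAssociation(snp_id=snp, gene_id=gene, z_score=z,
                           p_value=float(p_from_z(z)), cis_trans=cis)


class TestEsnpLbf:
    def test_closed_form_value(self):
        # 0.5*ln(0.5) + 4.5*0.5 at z=3, W=1
        assert esnp_lbf(3.0, 1.0) == pytest.approx(1.9034, abs=5e-5)

    def test_null_z_is_negative_half_log(self):
        for w in (0.05, 0.15, 1.0, 4.0):
            assert esnp_lbf(0.0, w) == pytest.approx(0.5 * math.log(1 / (1 + w)))
            assert esnp_lbf(0.0, w) < 0

    def test_vanishing_prior_kills_evidence(self):
        for z in (0.0, 1.0, 5.0):
            assert abs(esnp_lbf(z, 1e-12)) < 1e-10

    @given(z=st.floats(0, 10), dz=st.floats(1e-3, 2.0), w=st.floats(0.01, 5.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strictly_increasing_in_z_squared(self, z, dz, w):
        assert esnp_lbf(z + dz, w) > esnp_lbf(z, w)

    def test_sign_change_at_documented_z2(self):
        for w in (0.15, 1.0):
            z2 = lbf_sign_change_z2(w)
            assert esnp_lbf(math.sqrt(z2), w) == pytest.approx(0.0, abs=1e-12)
            assert esnp_lbf(math.sqrt(z2) - 0.01, w) < 0
            assert esnp_lbf(math.sqrt(z2) + 0.01, w) > 0

    def test_nonfinite_z_rejected(self):
        with pytest.raises(ValidationError):
            esnp_lbf(float("nan"), 0.15)
        with pytest.raises(ParameterError):
            esnp_lbf(1.0, 0.0)


class TestBayesFactorInterpretation:
    def test_printed_odds_example(self):
        assert round(lbf_to_bayes_factor(5.64)) == 281

    def test_identities(self):
        assert lbf_to_bayes_factor(0.0) == 1.0
        assert lbf_to_bayes_factor(math.log(10)) == pytest.approx(10.0)


class TestBonferroni:
    def test_threshold_form_matches_printed_value(self):
        thr = 0.05 / 8998
        # two significant figures
        assert float(f"{thr:.1e}") == 5.6e-6

    def test_identity_and_cap(self):
        assert bonferroni(0.5, 1) == 0.5
        assert bonferroni(0.1, 100) == 1.0

    def test_bad_n(self):
        with pytest.raises(ParameterError):
            bonferroni(0.1, 0)


class TestFindEsnps:
    def test_threshold_filters(self):
        table = [eqtl_rec("rs1", "G", 5.5), eqtl_rec("rs2", "G", 3.0)]
        # rs1 p ~ 4e-8 passes 1e-5; rs2 p ~ 2.7e-3 does not
        assert find_esnps(table, "G", 1e-5) == [("rs1", 5.5)]

    def test_near_one_threshold_returns_all_sorted(self):
        table = [eqtl_rec("rs2", "G", 1.0), eqtl_rec("rs1", "G", 2.0)]
        out = find_esnps(table, "G", 1 - 1e-12)
        assert [s for s, _ in out] == ["rs1", "rs2"]  # ascending p

    def test_absent_gene_gives_empty(self):
        assert find_esnps([eqtl_rec("rs1", "G", 5.0)], "other", 1e-5) == []

    def test_tie_breaks_lexicographic(self):
        table = [eqtl_rec("rsB", "G", 4.0), eqtl_rec("rsA", "G", 4.0)]
        assert [s for s, _ in find_esnps(table, "G", 0.5)] == ["rsA", "rsB"]

    def test_matches_bruteforce_on_random_tables(self, rng):
        genes = ["G1", "G2", "G3"]
        for _ in range(25):
            table = [
                eqtl_rec(f"rs{i}", genes[rng.integers(3)],
                         float(rng.uniform(0, 6)))
                for i in range(12)
            ]
            thr = float(rng.uniform(1e-6, 0.5))
            for g in genes:
                expected = sorted(
                    [(r.p_value, r.snp_id, r.z_score) for r in table
                     if r.gene_id == g and r.p_value < thr]
                )
                assert find_esnps(table, g, thr) == [
                    (s, z) for _, s, z in expected
                ]


class TestGeneLbf:
    def test_sum_matches_bruteforce(self, rng):
        w = 0.15
        esnps = [(f"rs{i}", 1.0) for i in range(5)]
        gwas = {f"rs{i}": float(rng.normal(0, 3)) for i in range(5)}
        res = gene_lbf(esnps, gwas, w, gene_id="G")
        expected = sum(esnp_lbf(gwas[s], w) for s, _ in esnps)
        assert res.total_lbf == pytest.approx(expected, abs=1e-12)
        assert res.total_lbf == pytest.approx(sum(res.esnp_lbfs), abs=1e-12)
        assert res.top_esnp == max(gwas, key=lambda s: abs(gwas[s]))

    def test_missing_gwas_record_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            res = gene_lbf([("rs1", 1.0), ("rsX", 1.0)], {"rs1": 2.0}, 0.15, "G")
        assert res.esnp_ids == ["rs1"]
        assert "rsX" in caplog.text

    def test_empty_list_not_testable(self):
        with pytest.raises(ValidationError, match="not testable"):
            gene_lbf([], {}, 0.15, "G")

    def test_all_null_esnps_give_negative_total(self):
        esnps = [(f"rs{i}", 1.0) for i in range(4)]
        gwas = {f"rs{i}": 0.0 for i in range(4)}
        assert gene_lbf(esnps, gwas, 0.15, "G").total_lbf < 0

    @given(st.integers(0, 4), st.floats(0.1, 4.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_increasing_abs_z_never_decreases_total(self, which, bump):
        gwas = {f"rs{i}": [0.5, -1.0, 2.0, -0.2, 1.3][i] for i in range(5)}
        esnps = [(f"rs{i}", 1.0) for i in range(5)]
        base = gene_lbf(esnps, gwas, 0.15, "G").total_lbf
        key = f"rs{which}"
        gwas[key] = math.copysign(abs(gwas[key]) + bump, gwas[key])
        assert gene_lbf(esnps, gwas, 0.15, "G").total_lbf >= base


class TestEmpiricalP:
    def test_extremes(self):
        assert lbf_empirical_p(1e6, 3, 0.15, 1000, seed=0) == 1 / 1001
        assert lbf_empirical_p(-1e6, 3, 0.15, 1000, seed=0) == 1.0

    def test_too_few_esnps_or_draws(self):
        with pytest.raises(ParameterError):
            lbf_empirical_p(0.0, 0, 0.15, 1000, seed=0)
        with pytest.raises(ParameterError):
            lbf_empirical_p(0.0, 1, 0.15, 50, seed=0)

    def test_null_totals_reusable(self, rng):
        nulls = null_total_lbfs(3, 0.15, 500, rng)
        p1 = lbf_empirical_p(0.1, 3, 0.15, 500, seed=None, null_totals=nulls)
        p2 = lbf_empirical_p(0.1, 3, 0.15, 500, seed=None, null_totals=nulls)
        assert p1 == p2


class TestLbfScan:
    def test_scan_is_deterministic_and_order_invariant(self):
        from sczprio.simulate import gen_gwas_eqtl
        gwas, eqtl, _ = gen_gwas_eqtl(200, 20, 2, 3, 4.0, 7.0, seed=5)
        cfg = PipelineConfig(rng_seed=9, n_null_draws_lbf=500)
        a = lbf_scan(gwas, eqtl, cfg)
        b = lbf_scan(list(reversed(gwas)), list(reversed(eqtl)), cfg)
        assert [(r.gene_id, r.total_lbf, r.empirical_p) for r in a] == [
            (r.gene_id, r.total_lbf, r.empirical_p) for r in b
        ]

    def test_corrected_p_scales_with_genes_tested(self):
        from sczprio.simulate import gen_gwas_eqtl
        gwas, eqtl, _ = gen_gwas_eqtl(200, 20, 2, 3, 4.0, 7.0, seed=5)
        cfg = PipelineConfig(rng_seed=9, n_null_draws_lbf=500)
        results = lbf_scan(gwas, eqtl, cfg)
        n = len(results)
        for r in results:
            assert r.corrected_p == pytest.approx(min(1.0, r.empirical_p * n))
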