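"""Founder statistics: carrier accounting, odds-ratio model (checked
against statsmodels), hypergeometric model (checked against exhaustive
enumeration), Bonferroni, and the combined founder prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderscan.cohort import HET, HOM_ALT, AnnotatedVariant, VariantCall, VariantKey
from founderscan.simulate import make_index_pedigree, sample_enrichment_panel
from founderscan.stats import (
    CarrierCounts,
    EnrichmentConfig,
    HypergeomParams,
    allele_frequency_percent,
    bonferroni,
    carrier_counts,
    hypergeometric_model,
    odds_ratio_model,
    predict_founders,
)


def hypergeom_tail_by_enumeration(N, K, n, x):
    """Independent oracle: direct combinatorial sum of the upper tail."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(x, min(n, K) + 1)
    ) / total


class TestCarrierCounts:
    def test_hand_count(self):
        """1 hom + 4 het case carriers of 225; 2 het controls of 649."""
        ped = make_index_pedigree(225, 649)
        calls = {}
        case_ids = sorted(p.sample_id for p in ped.cases())
        control_ids = sorted(p.sample_id for p in ped.controls())
        calls[case_ids[0]] = VariantCall(case_ids[0], HOM_ALT)
        for sid in case_ids[1:5]:
            calls[sid] = VariantCall(sid, HET)
        for sid in control_ids[:2]:
            calls[sid] = VariantCall(sid, HET)
        v = AnnotatedVariant(key=VariantKey("chr1", 1, "G", "A"), calls=calls)
        counts = carrier_counts(v, ped, set(ped.individuals))
        assert (counts.x_cases, counts.a_cases) == (5, 6)
        assert (counts.x_controls, counts.a_controls) == (2, 2)
        assert (counts.n_cases, counts.n_controls) == (225, 649)

    def test_no_calls_all_zero(self):
        ped = make_index_pedigree(3, 3)
        v = AnnotatedVariant(key=VariantKey("chr1", 1, "G", "A"))
        counts = carrier_counts(v, ped, set(ped.individuals))
        assert (counts.x_cases, counts.x_controls, counts.a_cases) == (0, 0, 0)

    def test_all_hom_cases(self):
        ped = make_index_pedigree(4, 2)
        calls = {
            p.sample_id: VariantCall(p.sample_id, HOM_ALT) for p in ped.cases()
        }
        v = AnnotatedVariant(key=VariantKey("chr1", 1, "G", "A"), calls=calls)
        counts = carrier_counts(v, ped, set(ped.individuals))
        assert counts.a_cases == 2 * counts.n_cases

    def test_unknown_sample_rejected(self):
        ped = make_index_pedigree(2, 2)
        v = AnnotatedVariant(
            key=VariantKey("chr1", 1, "G", "A"),
            calls={"GHOST": VariantCall("GHOST", HET)},
        )
        with pytest.raises(KeyError):
            carrier_counts(v, ped, set(ped.individuals))


class TestAlleleFrequencyPercent:
    @pytest.mark.parametrize("count,n,decimals,expect", [
        (12, 225, 2, 2.67),
        (2, 649, 2, 0.15),
        (7, 677, 2, 0.52),
        (8, 1016, 2, 0.39),
        (50, 677, 1, 3.7),
        (105, 1016, 2, 5.17),
        (6, 6, 0, 50.0),
        (0, 100, 2, 0.0),
    ])
    def test_printed_percentages(self, count, n, decimals, expect):
        assert allele_frequency_percent(count, n, decimals) == expect

    def test_half_away_from_zero(self):
        # 25/1000 alleles = 1.25%: banker's rounding would give 1.2
        assert allele_frequency_percent(25, 1000, 1) == 1.3

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            allele_frequency_percent(0, 0)


class TestOddsRatioModel:
    def test_symmetric_table(self):
        counts = CarrierCounts(1, 2, 1, 2)
        or_value, lo, hi, p, flag = odds_ratio_model(counts)
        assert or_value == pytest.approx(1.0)
        assert lo < 1 < hi and not flag

    def test_hand_cross_product_and_statsmodels(self):
        """11/225 vs 2/649: OR = (11*647)/(214*2); CI and p match an
        independent implementation (statsmodels Table2x2)."""
        from statsmodels.stats.contingency_tables import Table2x2

        counts = CarrierCounts(11, 225, 2, 649)
        or_value, lo, hi, p, flag = odds_ratio_model(counts)
        assert or_value == pytest.approx((11 * 647) / (214 * 2))
        assert or_value == pytest.approx(16.63, abs=0.01)
        table = Table2x2([[11, 214], [2, 647]])
        sm_lo, sm_hi = table.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-6)
        assert hi == pytest.approx(sm_hi, rel=1e-6)
        assert p == pytest.approx(table.oddsratio_pvalue(), rel=1e-6)
        assert flag

    def test_zero_cell_haldane(self):
        counts = CarrierCounts(11, 225, 0, 649)
        or_value, lo, hi, p, flag = odds_ratio_model(counts)
        expect = (11.5 * 649.5) / (214.5 * 0.5)
        assert or_value == pytest.approx(expect)
        assert np.isfinite([lo, hi, p]).all()

    def test_empty_table_undefined(self):
        counts = CarrierCounts(0, 0, 0, 0)
        or_value, lo, hi, p, flag = odds_ratio_model(counts)
        assert math.isnan(or_value) and not flag

    @given(
        a=st.integers(1, 50), b=st.integers(1, 200),
        c=st.integers(1, 50), d=st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_reciprocal_symmetry(self, a, b, c, d):
        """Swapping the cohort rows maps OR to 1/OR and mirrors the CI
        (exact on tables without zero cells)."""
        fwd = odds_ratio_model(CarrierCounts(a, a + b, c, c + d))
        rev = odds_ratio_model(CarrierCounts(c, c + d, a, a + b))
        assert rev[0] == pytest.approx(1 / fwd[0])
        assert rev[1] == pytest.approx(1 / fwd[2])
        assert rev[2] == pytest.approx(1 / fwd[1])
        assert rev[3] == pytest.approx(fwd[3])


class TestHypergeometricModel:
    def test_enumerated_example(self):
        """N=10, K=3, n=5: P(X>=2) = 1 - 21/252 - 105/252 = 0.5."""
        p = hypergeometric_model(HypergeomParams(10, 3, 5, 2))
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_zero_observed(self):
        assert hypergeometric_model(HypergeomParams(10, 3, 5, 0)) == 1.0

    def test_no_carriers_in_population(self):
        assert hypergeometric_model(HypergeomParams(10, 0, 5, 1)) == 0.0

    def test_x_exceeding_draw_rejected(self):
        with pytest.raises(ValueError):
            HypergeomParams(10, 3, 5, 6)

    @pytest.mark.parametrize("N", [6, 9, 12])
    def test_matches_enumeration_small_urns(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for x in range(n + 2):
                    if x > n:
                        continue
                    got = hypergeometric_model(HypergeomParams(N, K, n, x))
                    want = hypergeom_tail_by_enumeration(N, K, n, x)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_binomial_limit(self):
        """As N_pop grows with q fixed, the tail approaches the binomial."""
        from scipy.stats import binom

        q = 2 / 649
        for x_obs in (1, 3, 6):
            K = round(q * 10**8)
            hyper = hypergeometric_model(HypergeomParams(10**8, K, 225, x_obs))
            bino = float(binom.sf(x_obs - 1, 225, K / 10**8))
            assert abs(hyper - bino) / bino < 1e-4

    def test_monotone_in_x_and_q(self):
        N = 10_000_000
        tails = [
            hypergeometric_model(HypergeomParams(N, 30_000, 225, x))
            for x in range(0, 12)
        ]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        by_q = [
            hypergeometric_model(HypergeomParams(N, K, 225, 5))
            for K in (10_000, 30_000, 100_000, 300_000)
        ]
        assert all(a <= b for a, b in zip(by_q, by_q[1:]))


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expect", [
        (0.001, 35, 0.035),
        (0.5, 3, 1.0),
        (0.123, 1, 0.123),
    ])
    def test_values(self, p, m, expect):
        assert bonferroni(p, m) == pytest.approx(expect)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestPredictFounders:
    def test_planted_founder_top_ranked(self):
        ped = make_index_pedigree()
        rng = np.random.default_rng(42)
        variants, planted = sample_enrichment_panel(ped, rng)
        results = predict_founders(variants, ped)
        assert results[0].key == planted
        assert results[0].founder
        assert results[0].p_hyper_bonf >= results[0].p_hyper_raw

    def test_null_panel_no_founder(self):
        ped = make_index_pedigree()
        rng = np.random.default_rng(7)
        variants, _ = sample_enrichment_panel(ped, rng, planted=None)
        results = predict_founders(variants, ped)
        assert not any(r.founder for r in results)

    def test_single_variant_bonf_equals_raw(self):
        ped = make_index_pedigree(10, 10)
        calls = {
            p.sample_id: VariantCall(p.sample_id, HET)
            for p in list(ped.cases())[:3]
        }
        v = AnnotatedVariant(key=VariantKey("chr1", 5, "G", "A"), calls=calls)
        (r,) = predict_founders([v], ped)
        assert r.p_hyper_bonf == r.p_hyper_raw
        assert r.p_or_bonf == r.p_or_raw

    def test_empty_call_set(self):
        assert predict_founders([], make_index_pedigree(2, 2)) == []

    def test_founder_requires_both_flags(self):
        ped = make_index_pedigree()
        rng = np.random.default_rng(3)
        variants, _ = sample_enrichment_panel(ped, rng)
        for r in predict_founders(variants, ped):
            assert r.founder == (r.flag_or and r.flag_hyper)
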