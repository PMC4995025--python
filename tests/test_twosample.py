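"""Wald ratios, delta-method SEs, IVW combination, Egger regression."""

import math

import numpy as np
import pytest

from scoremr import (
    DomainError,
    HarmonizedPair,
    InsufficientDataError,
    OutcomeAssociation,
    SnpRecord,
    egger_regression,
    funnel_data,
    ivw_combine,
    wald_ratio,
)
from scoremr.twosample import WaldEstimate
from scoremr.validation import delta_se_check


def _pair(rsid="rs1", bxg=0.1, sxg=0.01, byg=-0.02, syg=0.01, action="unchanged"):
    snp = SnpRecord(rsid, "A", "G", 0.3, bxg, sxg, 1e-9)
    out = OutcomeAssociation(rsid, "A", "G", 0.3, byg, syg, 0.5)
    return HarmonizedPair(snp, out, action)


class TestWaldRatio:
    def test_null_numerator(self):
        est = wald_ratio(_pair(byg=0.0, syg=0.02, bxg=0.05))
        assert est.beta_causal == 0.0
        assert est.se_causal == pytest.approx(0.02 / 0.05)

    def test_deterministic_instrument_limit(self):
        # zero exposure uncertainty collapses the delta SE to S_YG/|b_XG|
        snp = SnpRecord("rs1", "A", "G", 0.3, -0.05, 1e-300, 1e-9)
        out = OutcomeAssociation("rs1", "A", "G", 0.3, -0.02, 0.01, 0.5)
        est = wald_ratio(HarmonizedPair(snp, out, "unchanged"))
        assert est.se_causal == pytest.approx(0.01 / 0.05)

    def test_delta_se_matches_monte_carlo_ratio_sd(self):
        res = delta_se_check(n_draws=200_000, seed=5)
        assert res["ratio"] == pytest.approx(1.0, abs=0.05)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DomainError):
            wald_ratio(_pair(bxg=0.0))

    def test_dropped_pair_rejected(self):
        with pytest.raises(DomainError):
            wald_ratio(_pair(action="dropped_palindromic"))

    def test_weak_instrument_flagged(self):
        assert wald_ratio(_pair(bxg=0.01, sxg=0.01)).weak
        assert not wald_ratio(_pair(bxg=0.1, sxg=0.01)).weak


class TestIvw:
    def test_single_estimate_unchanged(self):
        est = WaldEstimate("rs1", -0.08, 0.03)
        res = ivw_combine([est])
        assert (res.beta, res.se) == (-0.08, 0.03)

    def test_k_copies_shrink_se(self):
        ests = [WaldEstimate(f"rs{i}", -0.08, 0.03) for i in range(4)]
        res = ivw_combine(ests)
        assert res.beta == pytest.approx(-0.08)
        assert res.se == pytest.approx(0.03 / 2)

    def test_equals_wls_through_origin(self, rng):
        # first-order IVW == weighted regression of b_YG on b_XG with no intercept
        pairs = [
            _pair(f"rs{i}", bxg=b, sxg=0.01, byg=y, syg=s)
            for i, (b, y, s) in enumerate(
                zip(
                    rng.uniform(0.05, 0.2, 5),
                    rng.normal(-0.01, 0.01, 5),
                    rng.uniform(0.005, 0.02, 5),
                )
            )
        ]
        ests = [wald_ratio(p, se_mode="first_order") for p in pairs]
        res = ivw_combine(ests)
        x = np.array([p.snp.beta_exposure for p in pairs])
        y = np.array([p.outcome.beta_outcome for p in pairs])
        w = x**2 / np.array([p.outcome.se_outcome for p in pairs]) ** 2
        wls = np.sum(w * (y / x)) / np.sum(w)
        assert res.beta == pytest.approx(wls, abs=1e-10)

    def test_classic_ivw_identity_without_exposure_noise(self, rng):
        x = rng.uniform(0.05, 0.2, 8)
        y = rng.normal(-0.01, 0.01, 8)
        s = rng.uniform(0.005, 0.02, 8)
        pairs = []
        for i in range(8):
            snp = SnpRecord(f"rs{i}", "A", "G", 0.3, float(x[i]), 1e-300, 1e-9)
            out = OutcomeAssociation(f"rs{i}", "A", "G", 0.3, float(y[i]), float(s[i]), 0.5)
            pairs.append(HarmonizedPair(snp, out, "unchanged"))
        res = ivw_combine([wald_ratio(p) for p in pairs])
        classic = np.sum(x * y / s**2) / np.sum(x**2 / s**2)
        assert res.beta == pytest.approx(classic, abs=1e-10)

    def test_exposure_rescaling_invariance(self):
        pairs = [_pair(f"rs{i}", bxg=0.05 + 0.01 * i, byg=-0.02, syg=0.01) for i in range(5)]
        res = ivw_combine([wald_ratio(p) for p in pairs])
        scaled = [
            _pair(f"rs{i}", bxg=2 * (0.05 + 0.01 * i), sxg=2 * 0.01, byg=-0.02, syg=0.01)
            for i in range(5)
        ]
        res2 = ivw_combine([wald_ratio(p) for p in scaled])
        assert res2.beta == pytest.approx(res.beta / 2)
        assert res2.beta / res2.se == pytest.approx(res.beta / res.se, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            ivw_combine([])


class TestEgger:
    def _pairs(self, rng, n=20, intercept=0.0, slope=-0.1):
        pairs = []
        for i in range(n):
            bxg = rng.uniform(0.05, 0.2)
            syg = rng.uniform(0.005, 0.02)
            byg = intercept + slope * bxg + rng.normal(0, syg)
            pairs.append(_pair(f"rs{i}", bxg=bxg, syg=syg, byg=byg))
        return pairs

    def test_two_instruments_rejected(self):
        with pytest.raises(InsufficientDataError):
            egger_regression([_pair("rs1"), _pair("rs2")])

    def test_constrained_slope_equals_first_order_ivw(self, rng):
        pairs = self._pairs(rng)
        constrained = egger_regression(pairs, constrain_intercept=True)
        ivw = ivw_combine([wald_ratio(p, se_mode="first_order") for p in pairs])
        assert constrained.slope == pytest.approx(ivw.beta, abs=1e-10)

    def test_orientation_invariance(self, rng):
        pairs = self._pairs(rng)
        flipped = []
        for i, p in enumerate(pairs):
            if i % 2 == 0:
                flipped.append(p)
            else:
                snp = SnpRecord(
                    p.snp.rsid, p.snp.other_allele, p.snp.effect_allele,
                    1 - p.snp.eaf, -p.snp.beta_exposure, p.snp.se_exposure, p.snp.p_exposure,
                )
                out = OutcomeAssociation(
                    p.outcome.rsid, p.outcome.other_allele, p.outcome.effect_allele,
                    1 - p.outcome.eaf, -p.outcome.beta_outcome, p.outcome.se_outcome,
                )
                flipped.append(HarmonizedPair(snp, out, "unchanged"))
        a = egger_regression(pairs)
        b = egger_regression(flipped)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_recovers_generative_line(self, rng):
        pairs = self._pairs(rng, n=200, intercept=0.02, slope=-0.15)
        res = egger_regression(pairs)
        assert res.intercept == pytest.approx(0.02, abs=0.005)
        assert res.slope == pytest.approx(-0.15, abs=0.05)


class TestFunnel:
    def test_single_estimate_row(self):
        df = funnel_data([WaldEstimate("rs1", -0.08, 0.04)])
        assert df.shape == (1, 3)
        assert df.loc[0, "precision"] == pytest.approx(25.0)

    def test_conservation_and_positive_precision(self, rng):
        ests = [
            WaldEstimate(f"rs{i}", float(rng.normal()), float(rng.uniform(0.01, 1)))
            for i in range(50)
        ]
        df = funnel_data(ests)
        assert len(df) == 50
        assert (df["precision"] > 0).all()

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            funnel_data([])
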