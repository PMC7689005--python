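"""Wald ratio, IVW, weighted median and MR-Egger against independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrkit import (
    InsufficientInstrumentsError,
    SingularDesignError,
    ValidationError,
    estimate_all,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
)

from conftest import make_instruments, random_instruments


def meta_analysis_of_wald_ratios(insts):
    """Fixed-effect inverse-variance meta-analysis of the per-SNP ratios —
    an algebraically different route to the IVW estimate."""
    r = np.array([i.beta_outcome / i.beta_exposure for i in insts])
    w = np.array([(i.beta_exposure / i.se_outcome) ** 2 for i in insts])
    return np.sum(w * r) / np.sum(w), np.sqrt(1 / np.sum(w))


class TestWaldRatio:
    def test_direct_substitution(self):
        (inst,) = make_instruments([0.05], [0.01], [0.005])
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_negative_exposure_beta_uses_absolute_value_for_se(self):
        (inst,) = make_instruments([-0.05], [0.01], [0.005])
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_beta_rejected(self):
        (inst,) = make_instruments([0.0], [0.01], [0.005])
        with pytest.raises(ValidationError, match="undefined"):
            wald_ratio(inst)

    def test_singleton_ivw_equals_wald_ratio(self, rng):
        for _ in range(20):
            insts = random_instruments(rng, k=1)
            w = wald_ratio(insts[0])
            f = ivw(insts, "fixed")
            assert f.beta == pytest.approx(w.beta)
            assert f.se == pytest.approx(w.se)


class TestIvw:
    def test_matches_wls_through_origin(self, rng):
        for _ in range(50):
            insts = random_instruments(rng)
            bx = np.array([i.beta_exposure for i in insts])
            by = np.array([i.beta_outcome for i in insts])
            sy = np.array([i.se_outcome for i in insts])
            fit = sm.WLS(by, bx[:, None], weights=sy**-2.0).fit()
            est = ivw(insts, "fixed")
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_matches_meta_analysis_of_wald_ratios(self):
        insts = make_instruments(
            [0.1, 0.2, 0.15], [0.02, 0.05, 0.03], [0.01, 0.01, 0.02]
        )
        beta, se = meta_analysis_of_wald_ratios(insts)
        est = ivw(insts, "fixed")
        assert est.beta == pytest.approx(beta, rel=1e-12)
        assert est.se == pytest.approx(se, rel=1e-12)

    def test_identical_ratios_give_exact_estimate_and_equal_ses(self):
        bx = np.array([0.05, 0.1, 0.2])
        insts = make_instruments(bx, 0.3 * bx, [0.01, 0.02, 0.01])
        fixed = ivw(insts, "fixed")
        rand = ivw(insts, "random")
        assert fixed.beta == pytest.approx(0.3)
        assert rand.se == pytest.approx(fixed.se)  # Q = 0 -> no inflation

    def test_random_se_at_least_fixed_se(self, rng):
        for _ in range(20):
            insts = random_instruments(rng)
            assert ivw(insts, "random").se >= ivw(insts, "fixed").se

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([], "fixed")
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_instruments([0.1], [0.02], [0.01]), "random")

    def test_order_and_joint_sign_flip_invariance(self, rng):
        insts = random_instruments(rng, k=10)
        base = ivw(insts, "fixed")
        shuffled = [insts[i] for i in rng.permutation(10)]
        assert ivw(shuffled, "fixed").beta == pytest.approx(base.beta)
        import dataclasses

        flipped = [
            dataclasses.replace(
                i, beta_exposure=-i.beta_exposure, beta_outcome=-i.beta_outcome
            )
            for i in insts
        ]
        assert ivw(flipped, "fixed").beta == pytest.approx(base.beta)
        assert ivw(flipped, "fixed").se == pytest.approx(base.se)

    def test_outcome_rescaling_scales_beta_and_se(self, rng):
        import dataclasses

        insts = random_instruments(rng, k=8)
        c = 454.0  # e.g. SD of birth weight in grams
        scaled = [
            dataclasses.replace(
                i, beta_outcome=c * i.beta_outcome, se_outcome=c * i.se_outcome
            )
            for i in insts
        ]
        for model in ("fixed", "random"):
            a, b = ivw(insts, model), ivw(scaled, model)
            assert b.beta == pytest.approx(c * a.beta)
            assert b.se == pytest.approx(c * a.se)


class TestWeightedMedian:
    def test_equal_weights_interpolated_median(self):
        # ratios 0.1, 0.2, 0.9 with equal weights -> middle ratio
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.02, 0.09])
        insts = make_instruments(bx, by, [0.01] * 3)
        est = weighted_median(insts, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_all_ratios_identical_degenerate(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        insts = make_instruments(bx, 0.4 * bx, [0.01] * 4, sx=[1e-9] * 4)
        est = weighted_median(insts, n_boot=200, seed=2)
        assert est.beta == pytest.approx(0.4)
        assert est.se < 0.1  # small relative to the ratio, and stable
        assert est == weighted_median(insts, n_boot=200, seed=2)

    def test_reduces_to_plain_interpolated_median_with_equal_weights(self, rng):
        k = 7
        bx = np.full(k, 0.1)
        by = rng.normal(0.02, 0.005, size=k)
        insts = make_instruments(bx, by, [0.01] * k)
        ratios = np.sort(by / bx)
        w = np.full(k, 1 / k)
        s = np.cumsum(w) - w / 2
        expected = np.interp(0.5, s, ratios)
        est = weighted_median(insts, n_boot=50, seed=3)
        assert est.beta == pytest.approx(expected)

    def test_seed_required_and_reproducible(self, rng):
        insts = random_instruments(rng, k=6)
        with pytest.raises(ValidationError, match="seed"):
            weighted_median(insts, n_boot=50)
        a = weighted_median(insts, n_boot=200, seed=7)
        b = weighted_median(insts, n_boot=200, seed=7)
        assert a == b

    def test_too_few_instruments(self):
        insts = make_instruments([0.1, 0.2], [0.02, 0.04], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(insts, n_boot=50, seed=1)

    def test_robust_to_minority_invalid_instruments(self):
        # 9 of 20 instruments shifted by +0.5: median unaffected, IVW biased
        rng = np.random.default_rng(2024)
        k, truth = 20, 0.1
        # invalid instruments get smaller exposure effects, guaranteeing the
        # valid majority carries more than half of the weight
        bx = np.concatenate([rng.uniform(0.05, 0.1, 9), rng.uniform(0.12, 0.2, 11)])
        sy = np.full(k, 1e-4)
        by = truth * bx
        by[:9] += 0.5 * bx[:9]  # pleiotropic minority
        insts = make_instruments(bx, by, sy)
        wm = weighted_median(insts, n_boot=200, seed=5)
        assert wm.beta == pytest.approx(truth, abs=0.01)
        assert ivw(insts, "fixed").beta > truth + 0.05


class TestMrEgger:
    def test_exact_fit_recovery(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.003 + 0.2 * bx
        slope, intercept = mr_egger(make_instruments(bx, by, [0.01] * 4))
        assert slope.beta == pytest.approx(0.2)
        assert intercept.beta == pytest.approx(0.003)
        assert slope.se > 0 and intercept.se > 0  # floor keeps SEs positive

    def test_orientation_invariance(self, rng):
        import dataclasses

        insts = random_instruments(rng, k=12)
        slope, intercept = mr_egger(insts)
        flipped = [
            dataclasses.replace(
                i, beta_exposure=-i.beta_exposure, beta_outcome=-i.beta_outcome
            )
            for i in insts
        ]
        slope2, intercept2 = mr_egger(flipped)
        assert slope2.beta == pytest.approx(slope.beta)
        assert intercept2.beta == pytest.approx(intercept.beta)

    def test_pvalues_use_t_distribution(self):
        rng = np.random.default_rng(5)
        insts = random_instruments(rng, k=5)
        slope, intercept = mr_egger(insts)
        for est in (slope, intercept):
            expected = 2 * stats.t.sf(abs(est.beta / est.se), 3)
            assert est.pval == pytest.approx(expected)

    def test_singular_design_rejected(self):
        insts = make_instruments([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], [0.01] * 3)
        with pytest.raises(SingularDesignError):
            mr_egger(insts)

    def test_too_few_instruments(self):
        insts = make_instruments([0.1, 0.2], [0.02, 0.04], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(insts)


def test_estimate_all_runs_each_method_once(rng):
    insts = random_instruments(rng, k=10)
    ests = estimate_all(insts, seed=3, n_boot=50)
    assert [e.method for e in ests] == [
        "ivw_fixed", "ivw_random", "weighted_median", "egger_slope", "egger_intercept"
    ]
    assert all(e.n_snps == 10 for e in ests)
    assert all(e.ci_low < e.beta < e.ci_high for e in ests)
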