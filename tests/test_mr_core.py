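"""Estimators vs independent weighted-least-squares oracles and worked examples."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrmediate.harmonize import HarmonizedPair
from mrmediate.mr_core import (
    EstimatorError,
    beta_to_or,
    ivw,
    mr_egger,
    or_ci_to_beta_se,
    wald_ratio,
    weighted_median,
)
from mrmediate.synthetic import SimulationConfig, simulate_tripartite
from mrmediate.harmonize import harmonize, usable_pairs

from conftest import make_pairs


def wls_origin_oracle(bx, by, sy):
    """Independent IVW oracle: WLS of beta_out on beta_exp through the
    origin with weights 1/se_out² (statsmodels)."""
    fit = sm.WLS(by, np.asarray(bx)[:, None], weights=1.0 / np.asarray(sy) ** 2).fit()
    return float(fit.params[0])


def wls_intercept_oracle(bx, by, sy):
    """Egger oracle: weighted regression with intercept, bx oriented > 0."""
    sign = np.sign(bx)
    x = sm.add_constant(np.asarray(bx) * sign)
    fit = sm.WLS(np.asarray(by) * sign, x, weights=1.0 / np.asarray(sy) ** 2).fit()
    return float(fit.params[0]), float(fit.params[1])


class TestWald:
    def test_hand_arithmetic(self):
        pair = make_pairs([0.2], [0.04], [0.1])[0]
        est = wald_ratio(pair)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.5)

    def test_null_outcome(self):
        assert wald_ratio(make_pairs([0.2], [0.0], [0.1])[0]).beta == 0.0

    def test_orientation_symmetry(self):
        a = wald_ratio(make_pairs([0.2], [0.04], [0.1])[0])
        b = wald_ratio(make_pairs([-0.2], [-0.04], [0.1])[0])
        assert b.beta == pytest.approx(a.beta)
        assert b.se == pytest.approx(a.se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(EstimatorError):
            wald_ratio(make_pairs([0.0], [0.04], [0.1])[0])


class TestIVW:
    def test_single_instrument_equals_wald(self):
        pairs = make_pairs([0.2], [0.04], [0.1])
        est = ivw(pairs)
        wald = wald_ratio(pairs[0])
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_weighted_mean_by_hand(self):
        # ratios 0.1 (weight 1) and 0.3 (weight 3) -> 0.25
        pairs = make_pairs([1.0, np.sqrt(3)], [0.1, 0.3 * np.sqrt(3)], [1.0, 1.0])
        assert ivw(pairs, model="fixed").beta == pytest.approx(0.25)

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_equals_origin_wls_oracle(self, data):
        k = data.draw(st.integers(2, 20))
        bx = np.array(data.draw(st.lists(st.floats(0.02, 1), min_size=k, max_size=k)))
        by = np.array(data.draw(st.lists(st.floats(-1, 1), min_size=k, max_size=k)))
        sy = np.array(data.draw(st.lists(st.floats(0.01, 1), min_size=k, max_size=k)))
        est = ivw(make_pairs(bx, by, sy), model="fixed")
        assert est.beta == pytest.approx(wls_origin_oracle(bx, by, sy), abs=1e-10)

    def test_random_effects_never_narrower_than_fixed(self, rng):
        bx = rng.uniform(0.05, 0.3, 15)
        by = 0.2 * bx + rng.normal(0, 0.05, 15)
        pairs = make_pairs(bx, by, 0.02)
        assert ivw(pairs, model="random").se >= ivw(pairs, model="fixed").se

    def test_empty_rejected(self):
        with pytest.raises(EstimatorError):
            ivw([])

    def test_orientation_equivariance(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.2 * bx + rng.normal(0, 0.02, 10)
        pairs = make_pairs(bx, by, 0.02)
        flipped = make_pairs(-bx, -by, 0.02)
        assert ivw(flipped).beta == pytest.approx(ivw(pairs).beta, rel=1e-12)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        pairs = make_pairs(bx, 0.02 + 0.3 * bx, 0.05)
        fit = mr_egger(pairs)
        assert fit.intercept == pytest.approx(0.02, abs=1e-10)
        assert fit.slope.beta == pytest.approx(0.3, abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(EstimatorError):
            mr_egger(make_pairs([0.1, 0.2], [0.03, 0.06], [0.05, 0.05]))

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_equals_weighted_regression_oracle(self, data):
        k = data.draw(st.integers(3, 20))
        bx = np.array(
            data.draw(st.lists(st.floats(0.02, 1), min_size=k, max_size=k, unique=True))
        )
        sign = np.array(data.draw(st.lists(st.sampled_from([-1.0, 1.0]), min_size=k, max_size=k)))
        by = np.array(data.draw(st.lists(st.floats(-1, 1), min_size=k, max_size=k)))
        sy = np.array(data.draw(st.lists(st.floats(0.01, 1), min_size=k, max_size=k)))
        fit = mr_egger(make_pairs(bx * sign, by * sign, sy))
        b0, b1 = wls_intercept_oracle(bx * sign, by * sign, sy)
        assert fit.intercept == pytest.approx(b0, abs=1e-9)
        assert fit.slope.beta == pytest.approx(b1, abs=1e-9)

    def test_balanced_pleiotropy_intercept_shrinks_with_k(self, rng):
        """Balanced (mean-zero) pleiotropy: the intercept estimate
        concentrates near 0 as instrument count grows."""
        def mean_abs_intercept(k, reps=30):
            vals = []
            for _ in range(reps):
                bx = rng.uniform(0.1, 0.5, k)
                by = 0.3 * bx + rng.normal(0, 0.05, k)  # balanced pleiotropy
                vals.append(abs(mr_egger(make_pairs(bx, by, 0.01)).intercept))
            return np.mean(vals)

        assert mean_abs_intercept(100) < mean_abs_intercept(8)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], [1.0, 1.0, 1.0])
        est = weighted_median(pairs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_degenerate_weight_concentration(self):
        # middle instrument carries ~all the weight (w ratio 1e8 : 1)
        pairs = make_pairs([1.0, 1e4, 1.0], [0.1, 0.5 * 1e4, 0.9], [1.0, 1.0, 1.0])
        est = weighted_median(pairs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_insufficient_instruments(self):
        with pytest.raises(EstimatorError):
            weighted_median(make_pairs([0.1, 0.2], [0.03, 0.06], [0.05, 0.05]))

    def test_seeded_bootstrap_reproducible(self):
        pairs = make_pairs(
            [0.1, 0.2, 0.3, 0.4], [0.02, 0.05, 0.05, 0.09], [0.03] * 4, sx=[0.01] * 4
        )
        a = weighted_median(pairs, n_boot=200, seed=7)
        b = weighted_median(pairs, n_boot=200, seed=7)
        assert a == b

    def test_beats_ivw_under_directional_invalidity(self):
        """10 instruments, 4 with a large directional pleiotropic offset:
        the weighted median lands closer to the truth than IVW in >= 90%
        of seeded replicates."""
        wins = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            bx = rng.uniform(0.1, 0.3, 10)
            by = 0.2 * bx + rng.normal(0, 0.01, 10)
            by[:4] += 0.08  # invalid instruments, strongly biased upward
            pairs = make_pairs(bx, by, 0.01)
            wm = weighted_median(pairs, n_boot=2, seed=rep).beta
            iv = ivw(pairs, model="fixed").beta
            wins += abs(wm - 0.2) < abs(iv - 0.2)
        assert wins / reps >= 0.90


class TestORConversion:
    def test_null(self):
        or_, lo, hi, p = beta_to_or(0.0, 1.0)
        assert or_ == 1.0
        assert p == pytest.approx(1.0)

    def test_ci_boundary_construction(self):
        or_, lo, hi, p = beta_to_or(np.log(2), np.log(2) / 1.96)
        assert lo == pytest.approx(1.0, rel=1e-12)

    def test_reconstructs_published_triplet(self):
        beta, se, p = or_ci_to_beta_se(0.65, 0.441, 0.959)
        assert beta == pytest.approx(-0.4308, abs=5e-4)
        assert se == pytest.approx(0.1982, abs=5e-4)
        or_, lo, hi, _ = beta_to_or(beta, se)
        assert or_ == pytest.approx(0.65, abs=5e-3)
        assert lo == pytest.approx(0.441, abs=5e-3)
        assert hi == pytest.approx(0.959, abs=5e-3)

    @pytest.mark.parametrize(
        "or_,lo,hi,printed_p",
        [
            (0.45, 0.280, 0.731, 0.001),  # Ruminococcus torques group -> CD
            (0.77, 0.623, 0.951, 0.015),  # Eisenbergiella -> CD
        ],
    )
    def test_published_p_recovered_from_or_ci(self, or_, lo, hi, printed_p):
        _, _, p = or_ci_to_beta_se(or_, lo, hi)
        assert round(p, 3) == printed_p

    def test_symmetric_null_interval(self):
        beta, se, p = or_ci_to_beta_se(1.0, 1 / 1.7, 1.7)
        assert beta == 0.0
        assert p == pytest.approx(1.0)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            or_ci_to_beta_se(0.5, 0.6, 0.9)

    @settings(max_examples=50, deadline=None)
    @given(beta=st.floats(-2, 2), se=st.floats(1e-3, 2))
    def test_roundtrip_identity(self, beta, se):
        or_, lo, hi, _ = beta_to_or(beta, se)
        beta2, se2, _ = or_ci_to_beta_se(or_, lo, hi)
        assert beta2 == pytest.approx(beta, rel=1e-6, abs=1e-9)
        assert se2 == pytest.approx(se, rel=1e-6)


class TestParameterRecovery:
    def test_ivw_unbiased_and_calibrated_under_no_pleiotropy(self):
        """Default no-pleiotropy simulation: mean IVW over 200 replicates
        sits within first-order attenuation + Monte-Carlo error of the true
        total effect, and the nominal 95% CI covers in [91%, 99%]."""
        est, cov = [], 0
        reps = 200
        for s in range(reps):
            exposure, _, outcome, truth, _ = simulate_tripartite(
                SimulationConfig(seed=s)
            )
            instruments = exposure.subset(truth.exposure_snps)
            pairs = usable_pairs(harmonize(instruments, outcome))
            e = ivw(pairs)
            est.append(e.beta)
            cov += e.beta - 1.96 * e.se <= truth.c_true <= e.beta + 1.96 * e.se
        assert abs(np.mean(est) - 0.16) < 0.003
        assert 0.91 <= cov / reps <= 0.99
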