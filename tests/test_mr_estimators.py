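"""MR estimators against closed forms and independent regression oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from targetmr.errors import DomainError, EstimationError
from targetmr.mr_estimators import (
    cochran_q,
    ivw,
    mr_egger,
    run_sensitivity_suite,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from targetmr.sumstats import HarmonisedPair, HarmonisedSet
from targetmr.synthetic import simulate_two_sample

from conftest import BINARY_META, CONTINUOUS_META


def pair(bx, sx, by, sy, vid="rs1"):
    return HarmonisedPair(
        variant_id=vid, effect_allele="A", beta_exposure=bx, se_exposure=sx,
        beta_outcome=by, se_outcome=sy, p_exposure=1e-5, p_outcome=0.1,
    )


def pair_set(bxs, sxs, bys, sys_):
    hs = HarmonisedSet(CONTINUOUS_META, BINARY_META)
    for i, (bx, sx, by, sy) in enumerate(zip(bxs, sxs, bys, sys_)):
        hs.pairs.append(pair(bx, sx, by, sy, vid=f"rs{i + 1}"))
    return hs


def ratio_set(ratios, weights, sy=0.1):
    """Pairs with the requested per-SNP ratios and ratio weights."""
    bxs, sys_, bys = [], [], []
    for theta, w in zip(ratios, weights):
        # w = 1/(sy/|bx|)^2  =>  bx = sy * sqrt(w)
        bx = sy * np.sqrt(w)
        bxs.append(bx)
        bys.append(theta * bx)
        sys_.append(sy)
    return pair_set(bxs, [0.01] * len(bxs), bys, sys_)


def random_set(rng, j=20):
    bx = rng.normal(0.2, 0.08, j)
    bx[np.abs(bx) < 0.02] = 0.05
    sx = rng.uniform(0.005, 0.02, j)
    by = rng.normal(0.0, 0.05, j)
    sy = rng.uniform(0.01, 0.08, j)
    return pair_set(bx, sx, by, sy)


class TestWaldRatio:
    def test_definition(self):
        res = wald_ratio(pair(0.5, 0.05, -0.15, 0.05))
        assert res.beta == pytest.approx(-0.3)
        assert res.se == pytest.approx(0.1)
        assert res.ci_low == pytest.approx(-0.3 - 1.959964 * 0.1)

    def test_null_case(self):
        res = wald_ratio(pair(1.0, 0.05, 0.0, 0.2))
        assert res.beta == 0.0
        assert res.se == pytest.approx(0.2)
        assert res.pvalue == 1.0

    def test_second_order_se_closed_form(self):
        bx, sx, by, sy = 0.5, 0.05, -0.15, 0.05
        res = wald_ratio(pair(bx, sx, by, sy), second_order_se=True)
        expected = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        assert res.se == pytest.approx(expected, rel=1e-12)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(DomainError):
            wald_ratio(pair(0.0, 0.05, 0.1, 0.05))


class TestIVW:
    def test_equal_weight_symmetry(self):
        hs = pair_set([0.2, 0.2], [0.01, 0.01], [0.02, 0.06], [0.05, 0.05])
        res, _ = ivw(hs)
        assert res.beta == pytest.approx(0.2)  # mean of ratios 0.1 and 0.3

    def test_identical_copies_degenerate(self):
        hs = pair_set([0.2] * 5, [0.01] * 5, [0.05] * 5, [0.03] * 5)
        res, het = ivw(hs)
        assert res.beta == pytest.approx(0.25)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.multiplier == 1.0

    def test_single_pair_rejected(self):
        with pytest.raises(EstimationError, match="wald_ratio"):
            ivw(pair_set([0.2], [0.01], [0.05], [0.03]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_wls_through_origin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hs = random_set(rng)
        bx, _, by, sy = hs.arrays()
        res, het = ivw(hs, random_effects=True)
        fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        assert res.beta == pytest.approx(fit.params[0], abs=1e-10)
        se_fixed = fit.bse[0] / np.sqrt(fit.scale)
        q = fit.scale * (len(bx) - 1)
        assert het.q == pytest.approx(q, abs=1e-8)
        assert res.se == pytest.approx(se_fixed * max(1, np.sqrt(q / (len(bx) - 1))),
                                       abs=1e-10)

    def test_fixed_effects_equals_weighted_mean_of_ratios(self):
        rng = np.random.default_rng(77)
        hs = random_set(rng, j=25)
        bx, _, by, sy = hs.arrays()
        res, _ = ivw(hs, random_effects=False)
        theta = by / bx
        w = bx**2 / sy**2
        assert res.beta == pytest.approx(np.sum(w * theta) / np.sum(w), abs=1e-10)


class TestEgger:
    def test_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.05 + 0.4 * bx
        hs = pair_set(bx, [0.01] * 3, by, [0.05] * 3)
        res = mr_egger(hs)
        assert res.beta == pytest.approx(0.4, abs=1e-12)
        assert res.extra["egger_intercept"] == pytest.approx(0.05, abs=1e-12)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(2)
        hs = random_set(rng)
        base = mr_egger(hs)
        flipped = HarmonisedSet(hs.exposure_meta, hs.outcome_meta)
        for i, p in enumerate(hs.pairs):
            s = -1.0 if i % 3 == 0 else 1.0
            flipped.pairs.append(
                pair(s * p.beta_exposure, p.se_exposure, s * p.beta_outcome,
                     p.se_outcome, vid=p.variant_id)
            )
        res = mr_egger(flipped)
        assert res.beta == pytest.approx(base.beta, abs=1e-12)
        assert res.extra["egger_intercept"] == pytest.approx(
            base.extra["egger_intercept"], abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_wls_with_intercept_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        hs = random_set(rng)
        bx, _, by, sy = hs.arrays()
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        res = mr_egger(hs)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.extra["egger_intercept"] == pytest.approx(fit.params[0], abs=1e-10)
        infl = max(1.0, np.sqrt(fit.scale))
        assert res.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * infl,
                                       abs=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            mr_egger(pair_set([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.05] * 2))

    def test_degenerate_design(self):
        with pytest.raises(EstimationError, match="degenerate"):
            mr_egger(pair_set([0.2] * 4, [0.01] * 4, [0.04] * 4, [0.05] * 4))


class TestWeightedMedian:
    def test_middle_value_equal_weights(self):
        hs = ratio_set([0.1, 0.2, 0.3], [1, 1, 1])
        assert weighted_median(hs, n_boot=0).beta == pytest.approx(0.2)

    def test_majority_weight_ratio_wins(self):
        hs = ratio_set([0.1, 0.2, 0.3], [0.2, 0.6, 0.2])
        assert weighted_median(hs, n_boot=0).beta == pytest.approx(0.2)

    def test_interpolation_formula(self):
        # cumulative fractions (cum - w/2)/W = .05, .20, .45, .80
        # 0.5 interpolates between theta=0.3 and 0.4: 0.3 + 0.1*(0.05/0.35)
        hs = ratio_set([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        assert weighted_median(hs, n_boot=0).beta == pytest.approx(
            0.3 + 0.1 * (0.05 / 0.35), abs=1e-12
        )

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(9)
        hs = random_set(rng, j=10)
        a = weighted_median(hs, n_boot=200, seed=5)
        b = weighted_median(hs, n_boot=200, seed=5)
        c = weighted_median(hs, n_boot=200, seed=6)
        assert a.se == b.se
        assert a.se != c.se

    def test_seed_required_for_bootstrap(self):
        hs = ratio_set([0.1, 0.2, 0.3], [1, 1, 1])
        with pytest.raises(EstimationError, match="seed"):
            weighted_median(hs, n_boot=100, seed=None)


def kde_argmax_oracle(theta, w, phi=1.0, grid_n=200_001):
    """Dense-grid weighted normal-KDE argmax, independent of the package."""
    sd = np.std(theta, ddof=1)
    iqr = np.percentile(theta, 75) - np.percentile(theta, 25)
    h = phi * 0.9 * min(s for s in (sd, iqr / 1.34) if s > 0) * len(theta) ** -0.2
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_n)
    dens = np.zeros_like(grid)
    for t, wj in zip(theta, w):
        dens += wj * np.exp(-0.5 * ((grid - t) / h) ** 2)
    return grid[np.argmax(dens)]


class TestWeightedMode:
    def test_identical_ratios_any_bandwidth(self):
        for phi in (0.25, 1.0, 4.0):
            hs = ratio_set([0.2, 0.2, 0.2], [1, 2, 3])
            assert weighted_mode(hs, phi=phi, n_boot=0).beta == pytest.approx(0.2)

    def test_cluster_beats_outlier(self):
        theta = np.array([0.199, 0.200, 0.201, 1.0])
        w = np.ones(4)
        hs = ratio_set(theta, w)
        est = weighted_mode(hs, n_boot=0).beta
        assert abs(est - 0.2) < 0.01
        assert est == pytest.approx(kde_argmax_oracle(theta, w), abs=2e-3)

    def test_heavier_cluster_wins(self):
        theta = np.array([-0.3, -0.29, -0.31, 0.3, 0.29, 0.31])
        w = np.array([1, 1, 1, 2, 2, 2], dtype=float)
        hs = ratio_set(theta, w)
        est = weighted_mode(hs, n_boot=0).beta
        oracle = kde_argmax_oracle(theta, w)
        assert est > 0
        assert est == pytest.approx(oracle, abs=5e-3)

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(10)
        hs = random_set(rng, j=10)
        a = weighted_mode(hs, n_boot=100, seed=5)
        b = weighted_mode(hs, n_boot=100, seed=5)
        assert a.se == b.se


class TestCochranQ:
    def test_identical_ratios_zero(self):
        hs = ratio_set([0.2, 0.2, 0.2], [1, 2, 3])
        het = cochran_q(hs, 0.2)
        assert het.q == pytest.approx(0.0, abs=1e-18)
        assert het.q_pvalue == 1.0

    def test_two_ratio_closed_form(self):
        theta1, theta2, w = 0.1, 0.5, 4.0
        hs = ratio_set([theta1, theta2], [w, w])
        het = cochran_q(hs, (theta1 + theta2) / 2)
        assert het.q == pytest.approx(w * (theta1 - theta2) ** 2 / 2, rel=1e-10)
        assert het.q_df == 1


class TestSuite:
    def test_single_instrument_wald_only(self):
        hs = pair_set([0.2], [0.01], [0.05], [0.03])
        suite = run_sensitivity_suite(hs, n_boot=0)
        assert [r.method for r in suite] == ["wald_ratio"]

    def test_two_instruments_wald_per_snp_plus_ivw(self):
        hs = pair_set([0.2, 0.25], [0.01] * 2, [0.05, 0.04], [0.03] * 2)
        suite = run_sensitivity_suite(hs, n_boot=0)
        assert [r.method for r in suite] == ["wald_ratio", "wald_ratio", "ivw_mre"]

    def test_many_instruments_full_suite(self):
        d = simulate_two_sample(0.1, 50, seed=3)
        suite = run_sensitivity_suite(d.pairs, n_boot=50, seed=1)
        assert [r.method for r in suite] == [
            "ivw_mre", "egger", "weighted_median", "weighted_mode"
        ]
        assert "q_pvalue" in suite[0].extra
        assert "egger_intercept_p" in suite[1].extra


class TestScaleEquivariance:
    def test_estimates_scale_inversely_with_exposure(self):
        rng = np.random.default_rng(21)
        hs = random_set(rng, j=15)
        c = 2.5
        scaled = HarmonisedSet(hs.exposure_meta, hs.outcome_meta)
        for p in hs.pairs:
            scaled.pairs.append(
                pair(c * p.beta_exposure, c * p.se_exposure, p.beta_outcome,
                     p.se_outcome, vid=p.variant_id)
            )
        for fn in (
            lambda h: ivw(h)[0].beta,
            lambda h: mr_egger(h).beta,
            lambda h: weighted_median(h, n_boot=0).beta,
        ):
            assert fn(scaled) == pytest.approx(fn(hs) / c, rel=1e-9)
        # the mode is grid-based: equivariance holds to grid resolution
        m1 = weighted_mode(hs, n_boot=0).beta
        m2 = weighted_mode(scaled, n_boot=0).beta
        assert m2 == pytest.approx(m1 / c, abs=5e-3)
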