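"""Monte Carlo engine: variant sampling, iteration allocation,
convergence along the iteration grid, and Spearman sensitivity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pahrisk.fitting import LogNormalParams, PowerLawModel
from pahrisk.mcs import (
    AGE_STRATIFIED,
    CONCENTRATION_ADJUSTED,
    CORRELATED,
    TRADITIONAL,
    ConfigError,
    MCSConfig,
    StratumParams,
    allocate_iterations,
    convergence_check,
    run_mcs,
    sensitivity_spearman,
)
from pahrisk.risk_core import ExposureConstants

CONC = LogNormalParams(2.21, 1.01)
BW = LogNormalParams(4.169, 0.218)
IR = LogNormalParams(2.788, 0.195)
POWER_LAW = PowerLawModel(slope=0.679, intercept=-0.0428)


def make_config(variant=TRADITIONAL, **kwargs):
    defaults = dict(concentration=CONC, iterations=2000, seed=7)
    if variant in (TRADITIONAL, CONCENTRATION_ADJUSTED):
        defaults.update(bw=BW, ir=IR)
    elif variant == AGE_STRATIFIED:
        defaults.update(
            strata=(
                StratumParams("18-44", 19379 / 30000,
                              LogNormalParams(4.169, 0.225),
                              LogNormalParams(2.823, 0.175)),
                StratumParams("45-59", 8172 / 30000,
                              LogNormalParams(4.192, 0.204),
                              LogNormalParams(2.816, 0.150)),
                StratumParams("60-70", 2449 / 30000,
                              LogNormalParams(4.142, 0.216),
                              LogNormalParams(2.660, 0.157)),
            )
        )
    elif variant == CORRELATED:
        defaults.update(bw=BW, ir_model=POWER_LAW)
    defaults.update(kwargs)
    return MCSConfig(variant=variant, **defaults)


def zero_variance(config):
    import dataclasses

    flat = {"concentration": LogNormalParams(config.concentration.a, 0.0)}
    if config.bw is not None:
        flat["bw"] = LogNormalParams(config.bw.a, 0.0)
    if config.ir is not None:
        flat["ir"] = LogNormalParams(config.ir.a, 0.0)
    if config.strata is not None:
        flat["strata"] = tuple(
            StratumParams(s.label, s.weight,
                          LogNormalParams(s.bw.a, 0.0),
                          LogNormalParams(s.ir.a, 0.0))
            for s in config.strata
        )
    return dataclasses.replace(config, **flat)


class TestAllocateIterations:
    def test_equal_thirds(self):
        np.testing.assert_array_equal(
            allocate_iterations(30_000, [1 / 3] * 3), [10_000] * 3
        )

    def test_largest_remainder_by_hand(self):
        # quotas 4.5/2.7/1.8 -> floors 4/2/1, remainders .5/.7/.8
        np.testing.assert_array_equal(
            allocate_iterations(9, [0.5, 0.3, 0.2]), [4, 3, 2]
        )

    def test_census_weights_reproduce_published_counts(self):
        counts = allocate_iterations(
            30_000, [19379 / 30000, 8172 / 30000, 2449 / 30000]
        )
        np.testing.assert_array_equal(counts, [19379, 8172, 2449])

    @given(st.lists(st.floats(0.01, 10), min_size=1, max_size=8),
           st.integers(8, 100_000))
    def test_conservation(self, weights, total):
        assert allocate_iterations(total, weights).sum() == total

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            allocate_iterations(100, [0.5, 0.0, 0.5])


class TestRunMCS:
    @pytest.mark.parametrize(
        "variant", [TRADITIONAL, CONCENTRATION_ADJUSTED, AGE_STRATIFIED, CORRELATED]
    )
    def test_zero_variance_collapses_to_point_estimate(self, variant):
        config = zero_variance(make_config(variant, iterations=50))
        result = run_mcs(config)
        k = ExposureConstants().dose_factor
        if variant == CORRELATED:
            ir_med = POWER_LAW.predict(math.exp(BW.a))
            expected = math.exp(CONC.a) * ir_med / math.exp(BW.a) * k
            np.testing.assert_allclose(result.ilcr, expected, rtol=1e-12)
        elif variant == AGE_STRATIFIED:
            for s in config.strata:
                mask = result.stratum == s.label
                expected = (math.exp(config.concentration.a)
                            * math.exp(s.ir.a) / math.exp(s.bw.a) * k)
                np.testing.assert_allclose(result.ilcr[mask], expected, rtol=1e-12)
        else:
            expected = (math.exp(CONC.a) * math.exp(IR.a) / math.exp(BW.a) * k)
            np.testing.assert_allclose(result.ilcr, expected, rtol=1e-12)

    def test_traditional_matches_product_lognormal_closed_form(self):
        result = run_mcs(make_config(iterations=30_000))
        # independent lognormals: ln ILCR ~ N(ln k + a_C + a_IR - a_BW, sum b^2)
        k = ExposureConstants().dose_factor
        mu = math.log(k) + CONC.a + IR.a - BW.a
        sigma2 = CONC.b**2 + IR.b**2 + BW.b**2
        logs = np.log(result.ilcr)
        n = logs.size
        assert abs(logs.mean() - mu) < 3 * math.sqrt(sigma2 / n)
        assert abs(logs.std(ddof=1) - math.sqrt(sigma2)) < 3 * math.sqrt(
            sigma2 / (2 * n)
        )
        mean_exact = math.exp(mu + sigma2 / 2)
        assert abs(result.ilcr.mean() - mean_exact) < 3 * result.ilcr.std(
            ddof=1
        ) / math.sqrt(n)

    def test_correlated_ir_is_exact_model_prediction(self):
        result = run_mcs(make_config(CORRELATED))
        np.testing.assert_array_equal(result.ir, POWER_LAW.predict(result.bw))

    def test_correlated_effective_bw_exponent_is_slope_minus_one(self):
        config = make_config(
            CORRELATED, concentration=LogNormalParams(2.21, 0.0), iterations=5000
        )
        result = run_mcs(config)
        slope = stats.linregress(np.log(result.bw), np.log(result.ilcr)).slope
        assert slope == pytest.approx(POWER_LAW.slope - 1.0, abs=1e-10)

    def test_bit_reproducible_under_seed(self):
        a, b = run_mcs(make_config(seed=11)), run_mcs(make_config(seed=11))
        np.testing.assert_array_equal(a.ilcr, b.ilcr)
        c = run_mcs(make_config(seed=12))
        assert not np.array_equal(a.ilcr, c.ilcr)

    def test_stratified_with_identical_strata_matches_traditional(self):
        strata = tuple(
            StratumParams(label, w, BW, IR)
            for label, w in (("a", 0.5), ("b", 0.3), ("c", 0.2))
        )
        pooled = run_mcs(make_config(AGE_STRATIFIED, strata=strata,
                                     iterations=4000, seed=3))
        plain = run_mcs(make_config(TRADITIONAL, iterations=4000, seed=4))
        assert stats.ks_2samp(pooled.ilcr, plain.ilcr).pvalue > 0.01

    def test_stratum_substreams_stable_under_reallocation(self):
        # changing one stratum's weight must not reshuffle the others' draws
        strata = make_config(AGE_STRATIFIED).strata
        base = run_mcs(make_config(AGE_STRATIFIED, iterations=3000, seed=5))
        rew = tuple(
            StratumParams(s.label, w, s.bw, s.ir)
            for s, w in zip(strata, (0.70, 0.20, 0.10))
        )
        moved = run_mcs(make_config(AGE_STRATIFIED, strata=rew,
                                    iterations=3000, seed=5))
        label = strata[1].label
        a = base.ilcr[base.stratum == label]
        b = moved.ilcr[moved.stratum == label]
        m = min(a.size, b.size)
        np.testing.assert_array_equal(a[:m], b[:m])

    @pytest.mark.parametrize(
        "variant, drop",
        [
            (TRADITIONAL, "ir"),
            (AGE_STRATIFIED, "strata"),
            (CORRELATED, "ir_model"),
        ],
    )
    def test_missing_distribution_is_config_error(self, variant, drop):
        with pytest.raises(ConfigError):
            make_config(variant, **{drop: None})


class TestConvergence:
    def test_zero_variance_converges_at_first_grid_point(self):
        report = convergence_check(
            zero_variance(make_config()), grid=(100, 200, 300)
        )
        assert report.converged
        assert report.converged_at == 100

    def test_zero_tolerance_never_converges(self):
        report = convergence_check(
            make_config(), grid=(200, 400, 600), tolerance=0.0
        )
        assert not report.converged
        assert report.converged_at is None

    def test_fluctuation_shrinks_like_root_n(self):
        # across seeds, the SD of the simulated mean should scale ~ n^(-1/2)
        n_lo, n_hi = 1000, 16_000
        means_lo, means_hi = [], []
        for seed in range(30):
            r = run_mcs(make_config(iterations=n_hi, seed=seed))
            means_lo.append(r.ilcr[:n_lo].mean())
            means_hi.append(r.ilcr.mean())
        ratio = np.std(means_lo, ddof=1) / np.std(means_hi, ddof=1)
        expected = math.sqrt(n_hi / n_lo)
        assert expected / 2 < ratio < expected * 2

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            convergence_check(make_config(), grid=(500,))
        with pytest.raises(ValueError):
            convergence_check(make_config(), grid=(500, 400))


class TestSensitivity:
    def test_perfect_monotone_input(self):
        config = make_config(
            bw=LogNormalParams(BW.a, 0.0), ir=LogNormalParams(IR.a, 0.0)
        )
        sens = sensitivity_spearman(run_mcs(config))
        assert sens.correlations["concentration"] == pytest.approx(1.0)
        assert math.isnan(sens.correlations["bw"])
        assert sens.top == "concentration"

    @pytest.mark.parametrize(
        "variant", [TRADITIONAL, CONCENTRATION_ADJUSTED, AGE_STRATIFIED]
    )
    def test_bw_negative_ir_positive(self, variant):
        sens = sensitivity_spearman(run_mcs(make_config(variant, iterations=5000)))
        assert sens.correlations["bw"] < 0
        assert sens.correlations["ir"] > 0
        assert sens.top == "concentration"

    def test_correlated_variant_ir_shares_bw_ranks(self):
        # IR is a monotone-increasing function of BW here, so its rank
        # correlation with ILCR is identical to BW's (and negative, since
        # ILCR ~ BW^(slope-1) at fixed concentration)
        sens = sensitivity_spearman(run_mcs(make_config(CORRELATED,
                                                        iterations=5000)))
        assert sens.correlations["ir"] == pytest.approx(sens.correlations["bw"])
        assert sens.correlations["bw"] < 0
        assert sens.top == "concentration"

    def test_ranking_consistent_with_absolute_values(self):
        sens = sensitivity_spearman(run_mcs(make_config(iterations=3000)))
        magnitudes = [abs(sens.correlations[name]) for name in sens.ranking]
        assert magnitudes == sorted(magnitudes, reverse=True)
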