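"""Trophic position estimators: closed forms, error propagation, Bayesian."""

import math

import numpy as np
import pytest

from isotroph.isoscape import RegionBaseline
from isotroph.records import AminoAcidTDF, AnalyticalPrecision, ConsumerRecord, TEF
from isotroph.trophic import (
    BayesianTPConfig,
    TwoBaselineTPModel,
    tp_bulk,
    tp_bulk_propagated_sd,
    tp_csia,
    tp_csia_propagated_sd,
    tp_size_relationship,
)

TEF_MUSCLE = TEF(tissue="muscle", dC_mean=1.8, dC_sd=0.0, dN_mean=1.9, dN_sd=0.4)
TDF_TUNA = AminoAcidTDF(tdf_mean=6.3, tdf_sd=0.4, beta_mean=3.4, beta_sd=0.9)
PRECISION = AnalyticalPrecision()


def _baseline(mean, sd, region="north"):
    return RegionBaseline(
        region=region, n=28, d13C_mean=-21.3, d13C_sd=0.9,
        d15N_mean=mean, d15N_sd=sd,
    )


class TestBulkTP:
    def test_published_muscle_vs_north_baseline(self):
        # pooled n-weighted muscle mean 10.081 permil; baseline 6.0; TEF 1.9
        est = tp_bulk(10.081, _baseline(6.0, 3.1), TEF_MUSCLE)
        assert round(est.tp, 1) == 4.1

    def test_published_muscle_vs_south_baseline(self):
        est = tp_bulk(10.081, _baseline(2.8, 1.0, "central_south"), TEF_MUSCLE)
        assert round(est.tp, 1) == 5.8

    def test_consumer_at_baseline_sits_at_baseline_tp(self):
        est = tp_bulk(6.0, _baseline(6.0, 3.1), TEF_MUSCLE)
        assert est.tp == pytest.approx(2.0)

    def test_one_tef_of_enrichment_is_one_level(self):
        b = _baseline(6.0, 3.1)
        low = tp_bulk(8.0, b, TEF_MUSCLE).tp
        high = tp_bulk(8.0 + TEF_MUSCLE.dN_mean, b, TEF_MUSCLE).tp
        assert high - low == pytest.approx(1.0)

    def test_zero_tef_rejected(self):
        with pytest.raises(ValueError):
            tp_bulk(10.0, _baseline(6.0, 3.1),
                    TEF(tissue="muscle", dC_mean=1.8, dC_sd=0,
                        dN_mean=0.0, dN_sd=0))


class TestBulkPropagation:
    def test_no_error_sources_no_error(self):
        b = _baseline(6.0, 0.0)
        tef = TEF(tissue="muscle", dC_mean=1.8, dC_sd=0, dN_mean=1.9, dN_sd=0)
        sd = tp_bulk_propagated_sd(
            10.0, b, tef, AnalyticalPrecision(0.0, 0.0, 0.0)
        )
        assert sd == 0.0

    @staticmethod
    def _mc_spread(draws):
        # the ratio in TEF makes the raw MC variance non-convergent (the
        # denominator has mass near zero), so spread is measured by the
        # central 68.27% quantile range, which equals the SD for a Gaussian
        # and is what the linearised delta method estimates
        q_lo, q_hi = np.quantile(draws, [0.158655, 0.841345])
        return (q_hi - q_lo) / 2.0

    def test_matches_monte_carlo_within_2pct(self):
        """Delta method vs. 10^6-draw simulation at moderate TEF uncertainty.

        First-order propagation tracks simulation to 2% when the TEF's
        coefficient of variation is around 10%; larger denominator CVs add
        genuine second-order spread (see the following test).
        """
        rng = np.random.default_rng(0)
        n = 1_000_000
        cons = rng.normal(10.081, 0.2, n)
        base = rng.normal(2.8, 1.0, n)
        tef = rng.normal(1.9, 0.2, n)
        mc = self._mc_spread((cons - base) / tef + 2.0)
        closed = tp_bulk_propagated_sd(
            10.081, _baseline(2.8, 1.0, "central_south"),
            TEF(tissue="muscle", dC_mean=1.8, dC_sd=0.0, dN_mean=1.9, dN_sd=0.2),
        )
        assert closed == pytest.approx(mc, rel=0.02)

    def test_deviation_at_study_tef_uncertainty_is_bounded(self):
        """At the study's TEF CV of 21% the linearised SD under-estimates
        the simulated spread by 2-4% (a second-order effect, not an error
        in the formula); both study baselines stay within 5%."""
        rng = np.random.default_rng(0)
        n = 1_000_000
        cons = rng.normal(10.081, 0.2, n)
        tef = rng.normal(1.9, 0.4, n)
        for mean, sd, region in ((6.0, 3.1, "north"),
                                 (2.8, 1.0, "central_south")):
            base = rng.normal(mean, sd, n)
            mc = self._mc_spread((cons - base) / tef + 2.0)
            closed = tp_bulk_propagated_sd(
                10.081, _baseline(mean, sd, region), TEF_MUSCLE
            )
            assert closed == pytest.approx(mc, rel=0.05)

    def test_soft_check_against_published_values(self):
        north = tp_bulk_propagated_sd(10.081, _baseline(6.0, 3.1), TEF_MUSCLE)
        south = tp_bulk_propagated_sd(
            10.081, _baseline(2.8, 1.0, "central_south"), TEF_MUSCLE
        )
        assert north == pytest.approx(1.8, abs=0.15)
        assert south == pytest.approx(0.9, abs=0.15)


class TestCsiaTP:
    def test_primary_producer_is_level_one(self):
        est = tp_csia(3.4 + 5.0, 5.0, TDF_TUNA)
        assert est.tp == pytest.approx(1.0)

    def test_published_muscle_with_tuna_tdf(self):
        # n-weighted means over the CSIA subset: Glu 25.728, Phe 6.306
        est = tp_csia(25.728, 6.306, TDF_TUNA)
        assert round(est.tp, 1) == 3.5

    def test_published_muscle_with_teleost_tdf(self):
        tdf = AminoAcidTDF(tdf_mean=5.7, tdf_sd=0.3)
        est = tp_csia(25.728, 6.306, tdf)
        assert round(est.tp, 1) == 3.8

    def test_invariant_to_common_shift(self):
        a = tp_csia(25.7, 6.3, TDF_TUNA).tp
        b = tp_csia(25.7 + 11.1, 6.3 + 11.1, TDF_TUNA).tp
        assert a == pytest.approx(b)


class TestCsiaPropagation:
    def test_no_error_sources_no_error(self):
        tdf = AminoAcidTDF(tdf_mean=6.3, tdf_sd=0.0, beta_mean=3.4, beta_sd=0.0)
        sd = tp_csia_propagated_sd(25.7, 6.3, tdf,
                                   AnalyticalPrecision(0.0, 0.0, 0.0))
        assert sd == 0.0

    def test_matches_monte_carlo_within_2pct(self):
        rng = np.random.default_rng(1)
        n = 1_000_000
        glu = rng.normal(25.728, 0.4, n)
        phe = rng.normal(6.306, 0.5, n)
        beta = rng.normal(3.4, 0.9, n)
        tdf = rng.normal(6.3, 0.4, n)
        mc = np.std((glu - phe - beta) / tdf + 1.0, ddof=1)
        closed = tp_csia_propagated_sd(25.728, 6.306, TDF_TUNA)
        assert closed == pytest.approx(mc, rel=0.02)

    def test_increasing_in_beta_uncertainty(self):
        sds = [
            tp_csia_propagated_sd(
                25.7, 6.3,
                AminoAcidTDF(tdf_mean=6.3, tdf_sd=0.4, beta_mean=3.4, beta_sd=b),
            )
            for b in (0.0, 0.5, 0.9, 1.5)
        ]
        assert sds == sorted(sds)


def _model_consumers(north, south, tef, tp, alpha, lam=2.0, sd=0.0, n=40, seed=0):
    rng = np.random.default_rng(seed)
    muN = alpha * north.d15N_mean + (1 - alpha) * south.d15N_mean \
        + tef.dN_mean * (tp - lam)
    muC = alpha * north.d13C_mean + (1 - alpha) * south.d13C_mean \
        + tef.dC_mean * (tp - lam)
    return [
        ConsumerRecord(
            id=str(i), year=2018, tissue="muscle",
            d13C=float(muC + (sd and rng.normal(0, sd))),
            d15N=float(muN + (sd and rng.normal(0, sd))),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="module")
def tight_baselines():
    north = RegionBaseline(region="north", n=500, d13C_mean=-21.3, d13C_sd=0.2,
                           d15N_mean=6.8, d15N_sd=0.2)
    south = RegionBaseline(region="central_south", n=500, d13C_mean=-20.1,
                           d13C_sd=0.2, d15N_mean=2.7, d15N_sd=0.2)
    return north, south


class TestBayesianTP:
    def test_recovers_noise_free_truth(self, tight_baselines):
        north, south = tight_baselines
        tef = TEF(tissue="muscle", dC_mean=1.8, dC_sd=0.0, dN_mean=1.9, dN_sd=0.0)
        cons = _model_consumers(north, south, tef, tp=4.0, alpha=0.5, sd=0.05)
        res = TwoBaselineTPModel(
            cons, north, south, tef,
            BayesianTPConfig(seed=7, n_iter=12000, burn_in=3000),
        ).fit()
        assert res.median_tp == pytest.approx(4.0, abs=0.1)

    def test_zero_enrichment_sits_at_baseline_level(self, tight_baselines):
        north, south = tight_baselines
        tef = TEF(tissue="muscle", dC_mean=1.8, dC_sd=0.0, dN_mean=1.9, dN_sd=0.0)
        cons = _model_consumers(north, south, tef, tp=2.0, alpha=0.5, sd=0.05)
        res = TwoBaselineTPModel(
            cons, north, south, tef,
            BayesianTPConfig(seed=8, n_iter=12000, burn_in=3000),
        ).fit()
        assert res.median_tp < 2.2

    def test_alpha_fixed_at_one_matches_bulk_estimate(self, tight_baselines):
        north, south = tight_baselines
        tef = TEF(tissue="muscle", dC_mean=1.8, dC_sd=0.0, dN_mean=1.9, dN_sd=0.0)
        cons = _model_consumers(north, south, tef, tp=4.3, alpha=1.0, sd=0.02)
        res = TwoBaselineTPModel(
            cons, north, south, tef,
            BayesianTPConfig(seed=9, n_iter=12000, burn_in=3000),
        ).fit(alpha_fixed=1.0)
        bulk = tp_bulk(float(np.mean([c.d15N for c in cons])), north, tef)
        assert res.samples_tp.mean() == pytest.approx(bulk.tp, abs=0.1)

    def test_mismatched_baseline_tp_rejected(self, tight_baselines):
        north, south = tight_baselines
        from dataclasses import replace

        with pytest.raises(ValueError):
            TwoBaselineTPModel(
                _model_consumers(north, south, TEF_MUSCLE, 4.0, 0.5),
                north, replace(south, tp_baseline=2.5), TEF_MUSCLE,
            )


class TestSizeRelationship:
    def test_constant_tp_is_undefined(self):
        rep = tp_size_relationship([120, 130, 140], [4.0, 4.0, 4.0])
        assert rep["r"] is None

    def test_exact_linear_relation_gives_unit_correlation(self):
        cfl = np.array([120.0, 130, 140, 150])
        rep = tp_size_relationship(cfl, 0.01 * cfl + 2)
        assert rep["r"] == pytest.approx(1.0)

    def test_recovers_population_correlation(self):
        # r = 0.3 population at n = 72; check the Fisher-z 95% interval
        rng = np.random.default_rng(12)
        n, rho = 72, 0.3
        x = rng.standard_normal(n)
        y = rho * x + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        rep = tp_size_relationship(130 + 10 * x, 4 + 0.3 * y)
        z, zr = math.atanh(rep["r"]), math.atanh(rho)
        assert abs(z - zr) < 1.96 / math.sqrt(n - 3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tp_size_relationship([120, 130], [4.0, 4.1])
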