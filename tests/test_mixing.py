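"""Two-source Bayesian mixing model: TEF correction, sampler, and oracle."""

import math

import numpy as np
import pytest

from isotroph.mixing import (
    MixingConfig,
    MixingSourceSet,
    Source,
    TwoSourceMixingModel,
    grid_posterior_oracle,
    mixing_posterior,
    oracle_cdf,
    summarize_posterior,
    tef_correct_sources,
)
from isotroph.records import ConsumerRecord, TEF
from isotroph._mcmc import kde_mode

TEF_MUSCLE = TEF(tissue="muscle", dC_mean=1.8, dC_sd=0.0, dN_mean=1.9, dN_sd=0.4)


def _consumers(d13C, d15N, rng=None, sd=0.0, n=1):
    rng = rng or np.random.default_rng(0)
    return [
        ConsumerRecord(
            id=str(i), year=2018, tissue="muscle",
            d13C=float(d13C + (sd and rng.normal(0, sd))),
            d15N=float(d15N + (sd and rng.normal(0, sd))),
        )
        for i in range(n)
    ]


def _sources(mC1=-19.5, mN1=8.7, mC2=-18.3, mN2=4.6, sd=0.5, tef_steps=0.0):
    tef = TEF(tissue="muscle", dC_mean=1.8, dC_sd=0.0, dN_mean=1.9, dN_sd=0.0)
    return MixingSourceSet(
        sources=(
            Source("north", mC1, sd, mN1, sd),
            Source("central_south", mC2, sd, mN2, sd),
        ),
        tef=tef,
        prey_offset_steps=tef_steps,
    )


class TestTefCorrection:
    def test_zero_steps_leaves_sources_unchanged(self):
        ss = MixingSourceSet(
            sources=(Source("a", -21.3, 0.9, 6.8, 2.6),
                     Source("b", -20.1, 0.8, 2.7, 0.9)),
            tef=TEF_MUSCLE, prey_offset_steps=0.0,
        )
        c1, c2 = tef_correct_sources(ss)
        assert (c1.mean_N, c1.sd_N) == (6.8, 2.6)
        assert (c2.mean_C, c2.sd_C) == (-20.1, 0.8)

    def test_one_step_shifts_nitrogen_mean(self):
        ss = MixingSourceSet(
            sources=(Source("a", -21.3, 0.9, 6.8, 2.6),
                     Source("b", -20.1, 0.8, 2.7, 0.9)),
            tef=TEF_MUSCLE,
        )
        c1, _ = tef_correct_sources(ss)
        assert c1.mean_N == pytest.approx(8.7)
        assert c1.mean_C == pytest.approx(-19.5)

    def test_sd_combines_in_quadrature(self):
        ss = MixingSourceSet(
            sources=(Source("a", -21.3, 0.9, 6.8, 2.6),
                     Source("b", -20.1, 0.8, 2.7, 0.9)),
            tef=TEF_MUSCLE,
        )
        c1, _ = tef_correct_sources(ss)
        assert c1.sd_N == pytest.approx(math.sqrt(2.6 ** 2 + 0.4 ** 2), abs=1e-9)
        assert c1.sd_N == pytest.approx(2.631, abs=5e-4)


class TestPosterior:
    def test_consumers_at_source1_force_high_proportion(self):
        ss = _sources(sd=0.01)
        cons = _consumers(-19.5, 8.7, n=10)
        post = TwoSourceMixingModel(
            cons, ss, MixingConfig(seed=1, n_iter=4000, burn_in=800)
        ).fit()
        assert post.mode_p >= 0.95

    def test_midpoint_consumers_give_balanced_mixture(self):
        ss = _sources(sd=0.5)
        cons = _consumers(-18.9, 6.65, n=10)
        post = TwoSourceMixingModel(
            cons, ss, MixingConfig(seed=2, n_iter=4000, burn_in=800)
        ).fit()
        assert 0.4 <= post.mode_p <= 0.6

    def test_draws_in_unit_interval_and_proportions_sum_to_one(self):
        ss = _sources()
        post = mixing_posterior(
            _consumers(-19.0, 7.0, n=5),
            ss, MixingConfig(seed=3, n_iter=2000, burn_in=400),
        )
        p = post.pooled_p
        assert np.all((p >= 0) & (p <= 1))
        rep = summarize_posterior(post)
        assert (
            rep["north"]["mode_pct"] + rep["central_south"]["mode_pct"]
            == pytest.approx(100.0, abs=1e-9)
        )
        assert post.ci95_p[0] <= post.mode_p <= post.ci95_p[1]

    def test_label_swap_flips_draws_exactly(self):
        tef = TEF(tissue="muscle", dC_mean=1.8, dC_sd=0.0, dN_mean=1.9, dN_sd=0.4)
        a = Source("north", -21.3, 0.9, 6.8, 2.6)
        b = Source("central_south", -20.1, 0.8, 2.7, 0.9)
        cons = _consumers(-18.5, 8.0, n=8)
        cfg = MixingConfig(seed=42, n_iter=2000, burn_in=400)
        post_ab = TwoSourceMixingModel(
            cons, MixingSourceSet((a, b), tef), cfg
        ).fit(seed=42)
        post_ba = TwoSourceMixingModel(
            cons, MixingSourceSet((b, a), tef), cfg
        ).fit(seed=42)
        assert np.allclose(post_ab.samples_p, 1.0 - post_ba.samples_p, atol=1e-12)

    def test_interval_tightens_with_sample_size(self):
        ss = _sources(sd=0.5)
        rng = np.random.default_rng(11)
        widths = []
        for n in (5, 50, 500):
            cons = _consumers(-18.9, 6.65, rng=rng, sd=0.5, n=n)
            post = TwoSourceMixingModel(
                cons, ss, MixingConfig(seed=n, n_iter=3000, burn_in=600)
            ).fit()
            widths.append(post.ci95_p[1] - post.ci95_p[0])
        assert widths[0] > widths[1] > widths[2]

    def test_two_end_member_algebraic_limit(self):
        # carbon carries no information; tight sources pin p algebraically
        ss = MixingSourceSet(
            sources=(Source("a", -19.0, 0.01, 10.0, 0.01),
                     Source("b", -19.0, 0.01, 4.0, 0.01)),
            tef=TEF(tissue="muscle", dC_mean=0, dC_sd=0, dN_mean=0.1, dN_sd=0),
            prey_offset_steps=0.0,
        )
        x = 8.2
        cons = _consumers(-19.0, x, n=40)
        post = TwoSourceMixingModel(
            cons, ss, MixingConfig(seed=5, n_iter=4000, burn_in=800)
        ).fit()
        expected = (x - 4.0) / (10.0 - 4.0)
        assert post.pooled_p.mean() == pytest.approx(expected, abs=0.02)

    def test_empty_consumer_set_rejected(self):
        with pytest.raises(ValueError):
            TwoSourceMixingModel([], _sources())

    def test_burn_in_must_be_smaller_than_iterations(self):
        with pytest.raises(ValueError):
            MixingConfig(n_iter=100, burn_in=100)


class TestGridOracle:
    def test_uninformative_data_returns_the_prior(self):
        # identical sources: the data cannot distinguish them
        ss = MixingSourceSet(
            sources=(Source("a", -19.0, 0.0, 6.0, 0.0),
                     Source("b", -19.0, 0.0, 6.0, 0.0)),
            tef=TEF(tissue="muscle", dC_mean=0, dC_sd=0, dN_mean=0.1, dN_sd=0),
            prey_offset_steps=0.0,
        )
        p, dens = grid_posterior_oracle(_consumers(-19.0, 6.0, n=3), ss)
        assert np.all(np.abs(dens - 1.0) < 0.01)

    def test_density_normalises_to_one(self, study_muscle, study_source_set):
        p, dens = grid_posterior_oracle(study_muscle[:10], study_source_set)
        assert np.trapezoid(dens, p) == pytest.approx(1.0, abs=1e-6)

    def test_mcmc_marginal_matches_oracle(self, study_muscle, study_source_set):
        """Sampler vs. exhaustive quadrature on a 10-consumer fixture."""
        sub = study_muscle[:10]
        post = TwoSourceMixingModel(
            sub, study_source_set,
            MixingConfig(seed=2, n_iter=20000, burn_in=2000),
        ).fit()
        pg, dens = grid_posterior_oracle(sub, study_source_set)
        cdf = oracle_cdf(pg, dens)
        emp = np.searchsorted(np.sort(post.pooled_p), pg) / post.pooled_p.size
        assert np.abs(emp - cdf).max() < 0.02
        # quantile agreement
        oq = np.interp([0.05, 0.25, 0.5, 0.75, 0.95], cdf, pg)
        mq = np.quantile(post.pooled_p, [0.05, 0.25, 0.5, 0.75, 0.95])
        assert np.allclose(oq, mq, atol=0.02)


class TestSummary:
    def test_degenerate_posterior_reports_fifty_fifty(self):
        from isotroph.mixing import MixingPosterior

        draws = np.full((2, 600), 0.5)
        post = MixingPosterior(
            source_names=("north", "central_south"),
            samples_p=draws, samples_resid={}, mode_p=0.5,
            ci95_p=(0.5, 0.5), rhat={},
        )
        rep = summarize_posterior(post)
        assert rep["north"]["mode_pct"] == pytest.approx(50.0)
        assert rep["central_south"]["mode_pct"] == pytest.approx(50.0)

    def test_beta_mode_recovered_from_draws(self):
        rng = np.random.default_rng(0)
        draws = rng.beta(8, 2, 200_000)
        # analytic Beta(8,2) mode: (a-1)/(a+b-2)
        assert kde_mode(draws) == pytest.approx(7 / 8, abs=0.02)
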