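"""Adaptive Metropolis machinery shared by the Bayesian models.

Sampling runs on unconstrained parameterisations (logit for proportions and
bounded quantities, log for scales) in two phases: a component-wise
random-walk warm-up whose per-component proposal scales are tuned by
Robbins-Monro stochastic approximation, followed by joint multivariate
proposals built from the empirical covariance of the warm-up draws (Haario
style), with a single global scale tuned towards a target acceptance rate.
All adaptation happens during burn-in; the proposal is frozen afterwards so
the retained draws come from a valid Markov chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ChainResult:
    samples: np.ndarray     # (n_kept, dim)
    acceptance: float       # post-burn-in acceptance rate
    scales: np.ndarray      # frozen component scales from the warm-up phase


def _component_sweep(logpost, x, lp, scales, rng, adapt, it, target):
    for k in range(x.size):
        old = x[k]
        x[k] = old + scales[k] * rng.standard_normal()
        lp_prop = logpost(x)
        ratio = lp_prop - lp
        if ratio >= 0.0 or math.log(rng.random()) < ratio:
            lp = lp_prop
        else:
            x[k] = old
        if adapt:
            prob = 1.0 if ratio >= 0 else math.exp(max(ratio, -50.0))
            gamma = (it + 1.0) ** -0.6
            scales[k] = min(
                10.0, max(1e-4, scales[k] * math.exp(gamma * (prob - target)))
            )
    return lp


def rw_metropolis(
    logpost,
    x0,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    scales=None,
    target_accept: float = 0.3,
) -> ChainResult:
    """One chain of two-phase adaptive Metropolis.

    Warm-up (first half of burn-in): component-wise random-walk with scale
    adaptation.  Second half of burn-in: joint Gaussian proposals with the
    empirical covariance of the warm-up draws, global scale adapted.  After
    burn-in the joint proposal is frozen.  Short burn-ins (< 100 draws) stay
    purely component-wise.  Returns post-burn-in draws only.
    """
    if not 0 <= burn_in < n_iter:
        raise ValueError("need 0 <= burn_in < n_iter")
    x = np.array(x0, dtype=float)
    dim = x.size
    scales = np.full(dim, 0.5) if scales is None else np.array(scales, dtype=float)
    lp = logpost(x)
    if not math.isfinite(lp):
        raise ValueError("log posterior is not finite at the initial point")

    joint = burn_in >= 100
    phase_a = burn_in // 2 if joint else burn_in
    warmup = np.empty((phase_a, dim)) if joint else None

    L = None
    log_s = math.log(2.38 / math.sqrt(dim))
    kept = np.empty((n_iter - burn_in, dim))
    n_acc = 0
    for it in range(n_iter):
        if it < phase_a:
            lp = _component_sweep(
                logpost, x, lp, scales, rng, adapt=True, it=it, target=0.35
            )
            warmup[it] = x
            if it == phase_a - 1 and joint:
                cov = np.cov(warmup[phase_a // 2:].T).reshape(dim, dim)
                cov += 1e-8 * np.eye(dim) * max(1.0, np.trace(cov) / dim)
                L = np.linalg.cholesky(cov)
        elif joint:
            step = math.exp(log_s) * (L @ rng.standard_normal(dim))
            prop = x + step
            lp_prop = logpost(prop)
            ratio = lp_prop - lp
            if ratio >= 0.0 or math.log(rng.random()) < ratio:
                x, lp = prop, lp_prop
                accepted = True
            else:
                accepted = False
            if it < burn_in:
                prob = 1.0 if ratio >= 0 else math.exp(max(ratio, -50.0))
                gamma = (it - phase_a + 1.0) ** -0.6
                log_s += gamma * (prob - target_accept)
                log_s = min(5.0, max(-10.0, log_s))
            elif accepted:
                n_acc += 1
        else:
            lp = _component_sweep(
                logpost, x, lp, scales, rng,
                adapt=it < burn_in, it=it, target=target_accept,
            )
        if it >= burn_in:
            kept[it - burn_in] = x
    return ChainResult(
        samples=kept,
        acceptance=n_acc / max(1, n_iter - burn_in),
        scales=scales,
    )


def run_chains(
    logpost, x0, n_iter, burn_in, n_chains, seed, scales=None, jitter=0.1
) -> np.ndarray:
    """Run several independent chains; returns (n_chains, n_kept, dim).

    Per-chain RNG streams are spawned deterministically from the master
    seed; starting points are jittered so chains begin over-dispersed.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_chains):
        rng = np.random.default_rng(child)
        start = np.array(x0, dtype=float) + jitter * rng.standard_normal(len(x0))
        res = rw_metropolis(logpost, start, n_iter, burn_in, rng, scales=scales)
        out.append(res.samples)
    return np.stack(out)


def rhat(chains: np.ndarray) -> float:
    """Rank-normalised split R-hat for one parameter (chains, draws)."""
    import arviz as az

    c = np.asarray(chains, dtype=float)
    return float(az.rhat(az.convert_to_dataset(c))["x"].values)


def kde_mode(draws: np.ndarray, lo: float = 0.0, hi: float = 1.0, n: int = 512) -> float:
    """Gaussian-KDE density mode (Silverman bandwidth) on a fixed grid."""
    from scipy.stats import gaussian_kde

    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) < 1e-12:
        return float(draws[0])
    grid = np.linspace(lo, hi, n)
    dens = gaussian_kde(draws, bw_method="silverman")(grid)
    return float(grid[np.argmax(dens)])


def log_half_cauchy(x: float, scale: float) -> float:
    """Log density of a half-Cauchy(scale) at x > 0."""
    if x <= 0:
        return -math.inf
    return math.log(2.0 / (math.pi * scale * (1.0 + (x / scale) ** 2)))
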