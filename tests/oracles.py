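"""Independent oracles used to validate the samplers and the simulator.

Everything here is deliberately computed by a different route than the
implementation under test: direct numerical quadrature, closed forms, or
exhaustive enumeration at small n.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit
from scipy.stats import binom

from bayesbasket.hbm import independent_conjugate

# dense fixed grid: the posteriors here can be orders of magnitude narrower
# than the prior support, which defeats adaptive quadrature
_GRID_POINTS = 400_001


def _posterior_grid(prior_sd: float, mu0: float = 0.0) -> np.ndarray:
    return np.linspace(mu0 - 40 * prior_sd, mu0 + 40 * prior_sd, _GRID_POINTS)


def logit_normal_exceedance(
    r: int, n: int, p0: float, prior_sd: float, mu0: float = 0.0
) -> float:
    """P(delta > 0 | r, n) for delta ~ N(mu0, prior_sd^2), grid-integrated.

    The single-cohort, borrowing-off marginal of the hierarchical model:
    the effect prior collapses to a Normal with variance s0^2 + tau^2.
    """
    lp0 = math.log(p0 / (1.0 - p0))
    d = _posterior_grid(prior_sd, mu0)
    logw = r * (d + lp0) - n * np.logaddexp(0.0, d + lp0)
    logw -= 0.5 * ((d - mu0) / prior_sd) ** 2
    w = np.exp(logw - logw.max())
    return float(w[d > 0].sum() / w.sum())


def pooled_exceedance_and_mean(
    rs: list[int], ns: list[int], p0: float, prior_sd: float
) -> tuple[float, float]:
    """Fully pooled oracle: one shared effect delta for all cohorts.

    The tau -> 0 limit of the hierarchical model when every cohort shares
    one cluster and one historical rate: delta ~ N(0, prior_sd^2) with the
    pooled binomial likelihood. Returns (P(delta > 0), E[p]).
    """
    lp0 = math.log(p0 / (1.0 - p0))
    R, N = sum(rs), sum(ns)
    d = _posterior_grid(prior_sd)
    logw = R * (d + lp0) - N * np.logaddexp(0.0, d + lp0)
    logw -= 0.5 * (d / prior_sd) ** 2
    w = np.exp(logw - logw.max())
    exceedance = float(w[d > 0].sum() / w.sum())
    mean = float((w * expit(d + lp0)).sum() / w.sum())
    return exceedance, mean


def single_look_futility_probability(
    n: int, true_rate: float, p0: float, threshold: float = 0.10,
    beta_prior: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Exact futility-stop probability at one look, by enumeration over r."""
    return float(
        sum(
            binom.pmf(r, n, true_rate)
            for r in range(n + 1)
            if independent_conjugate(r, n, beta_prior, p0) < threshold
        )
    )


def single_look_success_probability(
    n: int, true_rate: float, p0: float, threshold: float = 0.95,
    beta_prior: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Exact success-stop probability at one look, by enumeration over r."""
    return float(
        sum(
            binom.pmf(r, n, true_rate)
            for r in range(n + 1)
            if independent_conjugate(r, n, beta_prior, p0) >= threshold
        )
    )


def total_variation(dist_a: dict, dist_b: dict) -> float:
    """TV distance between two distributions over hashable outcomes."""
    keys = set(dist_a) | set(dist_b)
    return 0.5 * sum(abs(dist_a.get(k, 0.0) - dist_b.get(k, 0.0)) for k in keys)
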