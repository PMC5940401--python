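"""Dirichlet-process mixture clustering of cohorts by historical response rate.

Cohorts whose published (historical) response rates are similar are grouped
so that the hierarchical model borrows strength only within a group. The
model works on the logit scale: each cohort contributes one observation
x_j = logit(p0_j); a cluster has a latent center theta_c ~ N(m0, v0) and
x_j | theta_c ~ N(theta_c, kappa^2). The partition prior is the Chinese
restaurant process with concentration alpha, so the partition posterior is

    P(partition | x)  ∝  alpha^K  ·  prod_c (|c|-1)!  ·  prod_c m(x_c),

with m(x_c) the Normal-Normal marginal likelihood of cluster c. Inference
is collapsed Gibbs sampling over cluster assignments (theta integrated
out); for small numbers of cohorts the exact posterior over all set
partitions is available as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin


@dataclass
class DPConfig:
    """Parameters of the DP mixture on logit historical rates.

    alpha : CRP concentration (>0); larger favors more clusters.
    base_mean, base_var : N(m0, v0) base measure for cluster centers on
        the logit scale; defaults center on logit(0.15) with v0 = 4,
        weakly informative over plausible oncology response rates.
    kernel_sd : within-cluster spread kappa of logit rates; 0.25 separates
        rates differing by more than ~10 percentage points.
    """

    alpha: float = 1.0
    base_mean: float = math.log(0.15 / 0.85)
    base_var: float = 4.0
    kernel_sd: float = 0.25
    n_sweeps: int = 2000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.base_var <= 0 or self.kernel_sd <= 0:
            raise ValueError("base_var and kernel_sd must be positive")
        if not self.n_sweeps > self.burn_in >= 0:
            raise ValueError("need n_sweeps > burn_in >= 0")


def canonicalize(labels: Sequence[int]) -> tuple[int, ...]:
    """Relabel clusters in order of first occurrence (0, 1, 2, ...)."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


@dataclass(frozen=True)
class Partition:
    """A canonical cluster assignment of cohorts."""

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", canonicalize(self.labels))

    @property
    def k(self) -> int:
        return len(set(self.labels))

    def clusters(self) -> list[tuple[int, ...]]:
        out: dict[int, list[int]] = {}
        for i, lab in enumerate(self.labels):
            out.setdefault(lab, []).append(i)
        return [tuple(out[lab]) for lab in sorted(out)]

    def __len__(self) -> int:
        return len(self.labels)


def _check_rates(rates: Sequence[float]) -> np.ndarray:
    x = np.asarray(rates, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("rates must be a non-empty 1-D vector")
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("all rates must lie strictly in (0, 1)")
    return np.log(x / (1.0 - x))


def _cluster_log_marginal(x: np.ndarray, cfg: DPConfig) -> float:
    """log m(x) for one cluster: x ~ N(m0·1, kappa^2 I + v0 J)."""
    n = x.size
    k2, v0, m0 = cfg.kernel_sd**2, cfg.base_var, cfg.base_mean
    d = x - m0
    denom = k2 + n * v0
    quad = (d @ d - v0 * d.sum() ** 2 / denom) / k2
    logdet = (n - 1) * math.log(k2) + math.log(denom)
    return -0.5 * (n * math.log(2 * math.pi) + logdet + quad)


def _predictive_logpdf(x_new: float, members: np.ndarray, cfg: DPConfig) -> float:
    """log p(x_new | cluster members), theta integrated out."""
    k2, v0, m0 = cfg.kernel_sd**2, cfg.base_var, cfg.base_mean
    n = members.size
    if n == 0:
        mean, var = m0, v0 + k2
    else:
        post_var = 1.0 / (1.0 / v0 + n / k2)
        mean = post_var * (m0 / v0 + members.sum() / k2)
        var = post_var + k2
    return -0.5 * (math.log(2 * math.pi * var) + (x_new - mean) ** 2 / var)


def _set_partitions(n: int) -> Iterator[tuple[int, ...]]:
    """All set partitions of range(n) as canonical label vectors."""

    def rec(i: int, labels: list[int], k: int) -> Iterator[tuple[int, ...]]:
        if i == n:
            yield tuple(labels)
            return
        for lab in range(k + 1):
            labels.append(lab)
            yield from rec(i + 1, labels, max(k, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)


def partition_log_posterior(labels: Sequence[int], x: np.ndarray, cfg: DPConfig) -> float:
    """Unnormalized log posterior of a partition: CRP prior x marginal likelihood."""
    labels = canonicalize(labels)
    logp = 0.0
    for lab in set(labels):
        idx = [i for i, l in enumerate(labels) if l == lab]
        logp += (
            math.log(cfg.alpha)
            + math.lgamma(len(idx))
            + _cluster_log_marginal(x[idx], cfg)
        )
    return logp


def partition_posterior_exact(
    rates: Sequence[float], config: DPConfig | None = None
) -> list[tuple[Partition, float]]:
    """Exact partition posterior by Bell-number enumeration (n <= 10).

    Oracle for testing the Gibbs sampler: returns every set partition with
    its normalized posterior probability, sorted most probable first.
    """
    config = config or DPConfig()
    x = _check_rates(rates)
    n = x.size
    if n > 10:
        raise ValueError("exact enumeration limited to <= 10 cohorts")
    parts = list(_set_partitions(n))
    logps = np.array([partition_log_posterior(p, x, config) for p in parts])
    probs = np.exp(logps - logsumexp(logps))
    order = np.argsort(-probs)
    return [(Partition(parts[i]), float(probs[i])) for i in order]


def crp_gibbs(rates: Sequence[float], config: DPConfig | None = None) -> list[Partition]:
    """Collapsed Gibbs sampling of the partition posterior.

    One sweep resamples each cohort's assignment in fixed cohort order from
    its CRP full conditional; returns the post-burn-in partition samples.
    """
    config = config or DPConfig()
    x = _check_rates(rates)
    n = x.size
    rng = np.random.default_rng(config.seed)
    labels = np.zeros(n, dtype=int)
    samples: list[Partition] = []
    for sweep in range(config.n_sweeps):
        for i in range(n):
            others = np.delete(np.arange(n), i)
            other_labels = labels[others]
            uniq = list(dict.fromkeys(other_labels.tolist()))
            logw = []
            for lab in uniq:
                members = x[others[other_labels == lab]]
                logw.append(
                    math.log(members.size)
                    + _predictive_logpdf(x[i], members, config)
                )
            logw.append(
                math.log(config.alpha)
                + _predictive_logpdf(x[i], np.empty(0), config)
            )
            w = np.exp(np.array(logw) - logsumexp(logw))
            choice = rng.choice(len(w), p=w)
            if choice == len(uniq):
                labels[i] = (max(labels.max(), max(uniq, default=0)) + 1) if n > 1 else 0
            else:
                labels[i] = uniq[choice]
        labels = np.array(canonicalize(labels))
        if sweep >= config.burn_in:
            samples.append(Partition(tuple(labels)))
    return samples


def coclustering_matrix(samples: Sequence[Partition]) -> np.ndarray:
    """Pairwise posterior co-clustering probabilities from partition samples."""
    n = len(samples[0])
    mat = np.zeros((n, n))
    for p in samples:
        lab = np.asarray(p.labels)
        mat += (lab[:, None] == lab[None, :]).astype(float)
    return mat / len(samples)


def map_partition(
    source: Sequence[Partition] | Sequence[tuple[Partition, float]],
) -> Partition:
    """Point-estimate partition.

    From an exact posterior table, the maximum-probability partition; from
    Gibbs samples, Dahl's least-squares partition (the sample minimizing
    squared distance to the pairwise co-clustering matrix). Ties break by
    canonical-label lexicographic order.
    """
    if len(source) == 0:
        raise ValueError("empty input")
    first = source[0]
    if isinstance(first, tuple):  # exact table
        best = max(source, key=lambda t: (t[1], tuple(-l for l in t[0].labels)))
        return best[0]
    samples: Sequence[Partition] = source  # type: ignore[assignment]
    pi = coclustering_matrix(samples)
    best_part, best_score = None, math.inf
    for p in samples:
        lab = np.asarray(p.labels)
        delta = (lab[:, None] == lab[None, :]).astype(float)
        score = float(((delta - pi) ** 2).sum())
        if score < best_score - 1e-12 or (
            abs(score - best_score) <= 1e-12
            and best_part is not None
            and p.labels < best_part.labels
        ):
            best_part, best_score = p, score
    assert best_part is not None
    return best_part


class DirichletProcessRateClusterer(ClusterMixin, BaseEstimator):
    """DP-mixture clustering of historical response rates, sklearn-style.

    Parameters mirror :class:`DPConfig`. ``fit`` accepts a 1-D array of
    rates in (0,1) (or an (n,1) column) and sets:

    labels_ : canonical MAP cluster labels (Dahl's least-squares partition,
        or the exact posterior mode when ``exact=True`` and n <= 10).
    n_clusters_ : number of clusters in ``labels_``.
    samples_ : list of posterior :class:`Partition` samples (Gibbs mode).
    coclustering_ : pairwise co-clustering probability matrix.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        base_mean: float = math.log(0.15 / 0.85),
        base_var: float = 4.0,
        kernel_sd: float = 0.25,
        n_sweeps: int = 2000,
        burn_in: int = 500,
        exact: bool = False,
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.base_mean = base_mean
        self.base_var = base_var
        self.kernel_sd = kernel_sd
        self.n_sweeps = n_sweeps
        self.burn_in = burn_in
        self.exact = exact
        self.random_state = random_state

    def _config(self) -> DPConfig:
        return DPConfig(
            alpha=self.alpha,
            base_mean=self.base_mean,
            base_var=self.base_var,
            kernel_sd=self.kernel_sd,
            n_sweeps=self.n_sweeps,
            burn_in=self.burn_in,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        rates = np.asarray(X, dtype=float)
        if rates.ndim == 2 and rates.shape[1] == 1:
            rates = rates[:, 0]
        cfg = self._config()
        if self.exact:
            table = partition_posterior_exact(rates, cfg)
            part = map_partition(table)
            self.posterior_table_ = table
            self.samples_ = None
            self.coclustering_ = None
        else:
            samples = crp_gibbs(rates, cfg)
            part = map_partition(samples)
            self.samples_ = samples
            self.coclustering_ = coclustering_matrix(samples)
            self.posterior_table_ = None
        self.labels_ = np.asarray(part.labels, dtype=int)
        self.n_clusters_ = part.k
        self.map_partition_ = part
        return self
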