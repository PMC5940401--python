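"""Interim futility/success decision rules for cohort monitoring.

A cohort stops early for futility when, with at least 10 evaluable
patients at 16 weeks, the posterior probability that its benefit rate
exceeds the historical rate falls strictly below 10%. It stops early for
success when, with at least 15 evaluable patients, that probability is at
least 95%. Success is checked first; with the default thresholds the two
rules cannot co-fire. Beyond 30 evaluable patients without success the
cohort simply runs to its final analysis — the 15-30 window bounds early
success, it is not an accrual cap rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

from .hbm import independent_conjugate


class Verdict(str, Enum):
    CONTINUE = "continue"
    STOP_FUTILITY = "stop_futility"
    STOP_SUCCESS = "stop_success"


@dataclass(frozen=True)
class DecisionRuleConfig:
    futility_threshold: float = 0.10
    success_threshold: float = 0.95
    futility_min_n: int = 10
    success_min_n: int = 15
    success_max_n: int = 30
    cohort_min: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.futility_threshold < self.success_threshold < 1.0:
            raise ValueError(
                "need 0 < futility_threshold < success_threshold < 1"
            )
        if not self.futility_min_n <= self.success_min_n <= self.success_max_n:
            raise ValueError(
                "need futility_min_n <= success_min_n <= success_max_n"
            )


@dataclass
class CohortDecision:
    cohort: str
    week: float
    n_evaluable_16wk: int
    exceedance_prob: float
    verdict: Verdict

    def __post_init__(self) -> None:
        cfg = DecisionRuleConfig()
        # invariant guards, using the defaults the rule set was built with
        if self.verdict is Verdict.STOP_FUTILITY and (
            self.n_evaluable_16wk < cfg.futility_min_n
        ):
            raise ValueError("futility stop below the minimum evaluable count")
        if self.verdict is Verdict.STOP_SUCCESS and (
            self.n_evaluable_16wk < cfg.success_min_n
        ):
            raise ValueError("success stop below the minimum evaluable count")


def evaluate_cohort(
    n_evaluable_16wk: int,
    exceedance_prob: float,
    config: DecisionRuleConfig | None = None,
) -> Verdict:
    """Apply the interim rules to one cohort at one look.

    stop_success iff n >= success_min_n and prob >= success_threshold
    (inclusive); stop_futility iff n >= futility_min_n and
    prob < futility_threshold (strict); otherwise continue.
    """
    cfg = config or DecisionRuleConfig()
    if not 0.0 <= exceedance_prob <= 1.0:
        raise ValueError("exceedance probability must lie in [0, 1]")
    if n_evaluable_16wk < 0:
        raise ValueError("evaluable count must be non-negative")
    if (
        n_evaluable_16wk >= cfg.success_min_n
        and exceedance_prob >= cfg.success_threshold
    ):
        return Verdict.STOP_SUCCESS
    if (
        n_evaluable_16wk >= cfg.futility_min_n
        and exceedance_prob < cfg.futility_threshold
    ):
        return Verdict.STOP_FUTILITY
    return Verdict.CONTINUE


@dataclass
class CohortHistory:
    """Time-ordered 16-week outcome stream for one cohort.

    ``events`` holds (week_evaluable, clinical_benefit) pairs: the week at
    which the patient's 16-week assessment lands, and its result.
    """

    cohort: str
    p0: float
    events: list[tuple[float, bool]] = field(default_factory=list)

    def sorted_events(self) -> list[tuple[float, bool]]:
        return sorted(self.events, key=lambda e: e[0])


def conjugate_engine(
    beta_prior: tuple[float, float] = (1.0, 1.0)
) -> Callable[[Mapping[str, tuple[int, int, float]]], dict[str, float]]:
    """Analysis engine computing exceedance per cohort independently.

    Returns a callable mapping {cohort: (r, n, p0)} -> {cohort: P(p > p0)}.
    """

    def engine(data: Mapping[str, tuple[int, int, float]]) -> dict[str, float]:
        return {
            k: independent_conjugate(r, n, beta_prior, p0)
            for k, (r, n, p0) in data.items()
        }

    return engine


def hierarchical_engine(config=None, clusterer=None):
    """Analysis engine refitting the clustered hierarchical model per look.

    ``config`` is a :class:`~bayesbasket.hbm.BHMConfig`; cohorts are
    clustered on their historical rates with ``clusterer`` (a fitted-per-call
    :class:`~bayesbasket.clustering.DirichletProcessRateClusterer`) or fall
    into a single cluster when None.
    """
    from .hbm import BHMConfig, fit_bhm
    from .roster import CohortData

    cfg = config or BHMConfig()

    def engine(data: Mapping[str, tuple[int, int, float]]) -> dict[str, float]:
        keys = list(data)
        cohorts = [
            CohortData(arm="buparlisib", tumor_type=k, n_evaluable=n,
                       n_benefit=r, p0=p0)
            for k, (r, n, p0) in data.items()
        ]
        if clusterer is not None and len(keys) > 1:
            import numpy as np

            labels = clusterer.fit(
                np.array([data[k][2] for k in keys])
            ).labels_
        else:
            labels = [0] * len(keys)
        summary = fit_bhm(cohorts, labels, cfg)
        return dict(zip(keys, summary.exceedance_prob))

    return engine


def run_interims(
    histories: Sequence[CohortHistory],
    engine: Callable[[Mapping[str, tuple[int, int, float]]], dict[str, float]],
    config: DecisionRuleConfig | None = None,
    look_weeks: Sequence[float] | None = None,
) -> list[CohortDecision]:
    """Replay outcome streams through the interim decision rules.

    Looks are event-driven by default: a look fires whenever any open
    cohort's evaluable count reaches a new integer >= futility_min_n.
    ``look_weeks`` switches to a fixed calendar of analysis times. At each
    look the engine is refit on all open cohorts jointly and each open
    cohort is evaluated; stopped cohorts are closed permanently (their
    accrued data stay in the engine's input).
    """
    cfg = config or DecisionRuleConfig()
    streams = {h.cohort: h.sorted_events() for h in histories}
    p0s = {h.cohort: h.p0 for h in histories}
    open_cohorts = set(streams)
    decisions: list[CohortDecision] = []

    if look_weeks is None:
        trigger_weeks = sorted(
            {
                ev[0]
                for h in histories
                for i, ev in enumerate(h.sorted_events(), start=1)
                if i >= cfg.futility_min_n
            }
        )
    else:
        trigger_weeks = sorted(look_weeks)

    last_counts: dict[str, int] = {}
    for week in trigger_weeks:
        if not open_cohorts:
            break
        data = {}
        for cohort, events in streams.items():
            seen = [e for e in events if e[0] <= week]
            data[cohort] = (
                sum(b for _, b in seen),
                len(seen),
                p0s[cohort],
            )
        probs = engine({k: v for k, v in data.items()})
        for cohort in sorted(open_cohorts):
            r, n, _ = data[cohort]
            if n < cfg.futility_min_n or n == last_counts.get(cohort):
                continue
            last_counts[cohort] = n
            verdict = evaluate_cohort(n, probs[cohort], cfg)
            decisions.append(
                CohortDecision(cohort, week, n, probs[cohort], verdict)
            )
            if verdict is not Verdict.CONTINUE:
                open_cohorts.discard(cohort)
    return decisions
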