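"""Filter Detection Task engine.

Implements the adaptive staircase used to titrate an inspiratory-resistance
detection task: trials are presented in pseudo-randomised blocks of ten
(five "resistance", five "sham"), and after each trial a Bayesian estimate
of the performer's accuracy at the current filter level decides whether to
add or remove a filter.  The posterior on accuracy under a uniform prior is
Beta(k+1, n-k+1) for k correct out of n trials; if the posterior probability
that accuracy lies inside the target band [0.65, 0.80] drops below 0.20, the
difficulty is stepped in the direction indicated by the accuracy point
estimate.  A session ends once any single filter level has accumulated 60
trials; those 60 trials are the analysed set.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Protocol

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

Condition = Literal["resistance", "sham"]
Action = Literal["add_filter", "remove_filter", "stay"]

__all__ = [
    "TrialRecord",
    "StaircaseConfig",
    "StaircaseState",
    "SessionResult",
    "Responder",
    "schedule_block",
    "beta_interval_probability",
    "staircase_decision",
    "run_session",
    "interoceptive_sensitivity",
    "session_to_frame",
    "save_session",
]


@dataclass(frozen=True)
class TrialRecord:
    """One decision event: condition, response, confidence, staircase level."""

    index: int
    condition: Condition
    filter_count: int
    response: Literal["yes", "no"]
    correct: bool
    confidence: int
    level_at_trial: int

    def __post_init__(self) -> None:
        if not 1 <= self.confidence <= 10:
            raise ValueError(f"confidence must be in 1..10, got {self.confidence}")
        expected = (self.condition == "resistance") == (self.response == "yes")
        if self.correct != expected:
            raise ValueError("correct flag inconsistent with condition/response")


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the accuracy-targeting staircase.

    ``acc_lo``/``acc_hi`` bound the target accuracy band; ``prob_threshold``
    is the posterior-mass trigger below which a step is taken;
    ``min_trials_before_move`` is the evidence floor at a level before the
    trigger may fire (avoids the degenerate fresh-level case, where the
    uniform prior alone carries band mass 0.15 < 0.20).
    """

    acc_lo: float = 0.65
    acc_hi: float = 0.80
    prob_threshold: float = 0.20
    trials_per_block: int = 10
    stop_trials: int = 60
    min_level: int = 1
    max_level: int = 12
    start_level: int = 4
    min_trials_before_move: int = 5
    point_estimate_rule: Literal["posterior_mean", "mle"] = "posterior_mean"
    max_total_trials: int = 400

    def __post_init__(self) -> None:
        if not 0.0 < self.acc_lo < self.acc_hi < 1.0:
            raise ValueError("require 0 < acc_lo < acc_hi < 1")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.trials_per_block % 2 != 0:
            raise ValueError("trials_per_block must be even (equal condition counts)")
        if not self.min_level <= self.start_level <= self.max_level:
            raise ValueError("start_level must lie within [min_level, max_level]")


@dataclass
class StaircaseState:
    """Per-level correct/total tallies plus the running trial log.

    Tallies persist across level changes: leaving a level and later
    returning continues its trial count rather than restarting it.
    """

    current_level: int
    k: dict[int, int] = field(default_factory=lambda: defaultdict(int))
    n: dict[int, int] = field(default_factory=lambda: defaultdict(int))
    trials: list[TrialRecord] = field(default_factory=list)

    def record(self, trial: TrialRecord) -> None:
        self.trials.append(trial)
        self.n[trial.level_at_trial] += 1
        if trial.correct:
            self.k[trial.level_at_trial] += 1


@dataclass(frozen=True)
class SessionResult:
    trials: tuple[TrialRecord, ...]
    final_level: int
    analyzed_trials: tuple[TrialRecord, ...]
    total_trials: int
    accuracy_at_final: float
    validity_flag: bool
    completed: bool

    @property
    def n_analyzed(self) -> int:
        return len(self.analyzed_trials)


class Responder(Protocol):
    """Anything that can answer one trial (see synthetic_data.observer_respond)."""

    def __call__(
        self, filter_count: int, condition: Condition, rng: np.random.Generator
    ) -> tuple[Literal["yes", "no"], int]: ...


def schedule_block(rng: np.random.Generator, trials_per_block: int = 10) -> list[Condition]:
    """Return one pseudo-randomised block: equal resistance/sham counts, shuffled."""
    half = trials_per_block // 2
    block: list[Condition] = ["resistance"] * half + ["sham"] * half
    rng.shuffle(block)
    return block


def beta_interval_probability(k: int, n: int, lo: float = 0.65, hi: float = 0.80) -> float:
    """Posterior probability that accuracy lies in [lo, hi] after k/n correct.

    Uniform Beta(1, 1) prior on accuracy, hence posterior Beta(k+1, n-k+1);
    returns F(hi) - F(lo) of that posterior.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("require 0 < lo < hi < 1")
    a, b = k + 1, n - k + 1
    return float(beta_dist.cdf(hi, a, b) - beta_dist.cdf(lo, a, b))


def _point_estimate(k: int, n: int, rule: str) -> float:
    if rule == "posterior_mean":
        return (k + 1) / (n + 2)
    if rule == "mle":
        return k / n if n > 0 else 0.5
    raise ValueError(f"unknown point_estimate_rule {rule!r}")


def staircase_decision(state: StaircaseState, config: StaircaseConfig) -> Action:
    """Decide add/remove/stay from the tallies at the current level."""
    level = state.current_level
    k, n = state.k[level], state.n[level]
    if n < config.min_trials_before_move:
        return "stay"
    p_band = beta_interval_probability(k, n, config.acc_lo, config.acc_hi)
    if p_band >= config.prob_threshold:
        return "stay"
    estimate = _point_estimate(k, n, config.point_estimate_rule)
    if estimate < config.acc_lo:
        return "add_filter"
    if estimate > config.acc_hi:
        if level <= config.min_level:
            return "stay"  # clamped at the easiest available resistance
        return "remove_filter"
    return "stay"


def run_session(
    respond: Responder,
    config: StaircaseConfig = StaircaseConfig(),
    seed: int | np.random.Generator = 0,
) -> SessionResult:
    """Run a full staircase session against a responder.

    Blocks of ten are scheduled lazily; the staircase is consulted after
    every trial and the session stops the moment any level accumulates
    ``stop_trials`` trials.  If ``max_total_trials`` elapse first the session
    is returned with ``completed=False`` (flagged, never silently truncated).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = StaircaseState(current_level=config.start_level)
    pending: list[Condition] = []
    index = 0
    while True:
        if not pending:
            pending = schedule_block(rng, config.trials_per_block)
        condition = pending.pop(0)
        index += 1
        level = state.current_level
        filter_count = level if condition == "resistance" else 0
        response, confidence = respond(level, condition, rng)
        correct = (condition == "resistance") == (response == "yes")
        state.record(
            TrialRecord(
                index=index,
                condition=condition,
                filter_count=filter_count if condition == "resistance" else 0,
                response=response,
                correct=correct,
                confidence=confidence,
                level_at_trial=level,
            )
        )
        if state.n[level] >= config.stop_trials:
            return _finish(state, level, config, completed=True)
        if index >= config.max_total_trials:
            # persistent failure to settle: flag, keep the best-sampled level
            busiest = max(state.n, key=lambda lv: state.n[lv])
            return _finish(state, busiest, config, completed=False)
        action = staircase_decision(state, config)
        if action == "add_filter" and state.current_level < config.max_level:
            state.current_level += 1
        elif action == "remove_filter":
            state.current_level -= 1


def _finish(
    state: StaircaseState, final_level: int, config: StaircaseConfig, completed: bool
) -> SessionResult:
    analyzed = tuple(t for t in state.trials if t.level_at_trial == final_level)
    if completed:
        analyzed = analyzed[: config.stop_trials]
    accuracy = float(np.mean([t.correct for t in analyzed])) if analyzed else float("nan")
    return SessionResult(
        trials=tuple(state.trials),
        final_level=final_level,
        analyzed_trials=analyzed,
        total_trials=len(state.trials),
        accuracy_at_final=accuracy,
        validity_flag=bool(completed and 0.60 <= accuracy <= 0.85),
        completed=completed,
    )


def interoceptive_sensitivity(session: SessionResult) -> tuple[int, bool]:
    """Number of filters at the analysed level, plus the 60-85% validity flag.

    Fewer filters means higher interoceptive sensitivity (inverse scale).
    """
    if not session.completed:
        raise ValueError("session did not complete; sensitivity undefined")
    return session.final_level, session.validity_flag


def session_to_frame(session: SessionResult) -> pd.DataFrame:
    """Trial log as a DataFrame (column layout matches the CSV interface)."""
    return pd.DataFrame([asdict(t) for t in session.trials])


def save_session(session: SessionResult, csv_path: str | Path, meta: dict | None = None) -> None:
    """Write the trial log CSV and a JSON sidecar with session metadata."""
    csv_path = Path(csv_path)
    session_to_frame(session).to_csv(csv_path, index=False)
    sidecar = {
        "final_level": session.final_level,
        "total_trials": session.total_trials,
        "accuracy_at_final": session.accuracy_at_final,
        "validity_flag": session.validity_flag,
        "completed": session.completed,
    }
    if meta:
        sidecar.update(meta)
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
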