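"""Generative model of the aversive probabilistic learning task.

A session is 320 trials in 10 blocks of 26-38 trials. Within a block a fixed
contingency p(snake | stimulus A) governs outcomes, with the reciprocal
probability for stimulus B: p(snake|B) = 1 - p(snake|A). The block
contingencies are four repeats of the strongly biased level (two at 90/10,
two at 10/90), four of the moderately biased level (70/30 twice per
direction) and two unbiased 50/50 blocks. Subjective stress ratings are
prompted every 4-6 trials, 65 per session. Per-trial event timings (stimulus,
decision window, prediction display, outcome, ITI) are jittered uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from uncstress._utils import ConfigurationError

# (p(snake|A), number of blocks) pairs: 90/10 x4 (2 per direction),
# 70/30 x4, 50/50 x2.
DEFAULT_PROBABILITY_CLASSES: tuple[tuple[float, int], ...] = (
    (0.9, 2),
    (0.1, 2),
    (0.7, 2),
    (0.3, 2),
    (0.5, 2),
)


@dataclass
class TaskConfig:
    """Structural parameters of one task session.

    Timing fields are (mean, half-range) pairs in ms; jitter is uniform on
    mean +/- half-range.
    """

    n_trials: int = 320
    n_blocks: int = 10
    block_len_min: int = 26
    block_len_max: int = 38
    probability_classes: tuple[tuple[float, int], ...] = DEFAULT_PROBABILITY_CLASSES
    n_ratings: int = 65
    rating_gap_min: int = 4
    rating_gap_max: int = 6
    stimulus_ms: tuple[float, float] = (300.0, 50.0)
    decision_ms: tuple[float, float] = (1000.0, 200.0)
    prediction_ms: tuple[float, float] = (1200.0, 200.0)
    outcome_ms: tuple[float, float] = (1000.0, 200.0)
    iti_ms: tuple[float, float] = (2000.0, 500.0)
    break_interval_min: float = 10.0
    n_subjects: int = 45
    seed: int = 0

    def validate(self) -> None:
        reps = sum(r for _, r in self.probability_classes)
        if reps != self.n_blocks:
            raise ConfigurationError(
                f"probability-class repeats sum to {reps}, expected n_blocks={self.n_blocks}"
            )
        if not (
            self.n_blocks * self.block_len_min
            <= self.n_trials
            <= self.n_blocks * self.block_len_max
        ):
            raise ConfigurationError(
                "n_trials cannot be partitioned into n_blocks blocks within "
                f"[{self.block_len_min}, {self.block_len_max}]"
            )
        # n_ratings - 1 gaps of at least gap_min, plus the first prompt, must fit.
        if self.rating_gap_min + (self.n_ratings - 1) * self.rating_gap_min > self.n_trials:
            raise ConfigurationError(
                f"{self.n_ratings} rating prompts with gaps >= {self.rating_gap_min} "
                f"do not fit in {self.n_trials} trials"
            )
        if self.rating_gap_min > self.rating_gap_max or self.rating_gap_min < 1:
            raise ConfigurationError("invalid rating gap bounds")
        for name in ("stimulus_ms", "decision_ms", "prediction_ms", "outcome_ms", "iti_ms"):
            mean, jit = getattr(self, name)
            if jit < 0 or mean - jit <= 0:
                raise ConfigurationError(f"timing {name}: jitter bounds must stay positive")


@dataclass
class TaskSchedule:
    """One generated session. All per-trial arrays have length n_trials."""

    config: TaskConfig
    stimulus: np.ndarray  # 0 = A, 1 = B
    p_snake_given_A: np.ndarray
    block_index: np.ndarray
    outcome: np.ndarray  # 1 = snake (shock), 0 = no snake
    onset_stimulus_ms: np.ndarray
    onset_decision_ms: np.ndarray
    onset_prediction_ms: np.ndarray
    onset_outcome_ms: np.ndarray
    onset_iti_ms: np.ndarray
    trial_end_ms: np.ndarray
    is_rating_trial: np.ndarray  # bool
    break_after_trial: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_trials(self) -> int:
        return len(self.outcome)

    @property
    def rating_trials(self) -> np.ndarray:
        """1-based trial indices of rating prompts."""
        return np.flatnonzero(self.is_rating_trial) + 1

    @property
    def p_snake_given_shown(self) -> np.ndarray:
        """True p(snake) for the stimulus actually shown on each trial."""
        return np.where(self.stimulus == 0, self.p_snake_given_A, 1.0 - self.p_snake_given_A)

    @property
    def block_lengths(self) -> np.ndarray:
        return np.bincount(self.block_index, minlength=self.config.n_blocks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "block": self.block_index,
                "stimulus": np.where(self.stimulus == 0, "A", "B"),
                "p_snake_given_A": self.p_snake_given_A,
                "outcome": self.outcome,
                "onset_stimulus_ms": self.onset_stimulus_ms,
                "onset_decision_ms": self.onset_decision_ms,
                "onset_prediction_ms": self.onset_prediction_ms,
                "onset_outcome_ms": self.onset_outcome_ms,
                "onset_iti_ms": self.onset_iti_ms,
                "trial_end_ms": self.trial_end_ms,
                "is_rating": self.is_rating_trial.astype(int),
            }
        )


def _block_lengths(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded block lengths in bounds summing exactly to n_trials."""
    lo, hi, k = config.block_len_min, config.block_len_max, config.n_blocks
    lengths = rng.integers(lo, hi + 1, size=k)
    # Minimal adjustment toward the exact total, respecting bounds.
    deficit = config.n_trials - int(lengths.sum())
    step = 1 if deficit > 0 else -1
    while deficit != 0:
        order = rng.permutation(k)
        moved = False
        for i in order:
            if deficit == 0:
                break
            if lo <= lengths[i] + step <= hi:
                lengths[i] += step
                deficit -= step
                moved = True
        if not moved:  # pragma: no cover - excluded by config validation
            raise ConfigurationError("cannot adjust block lengths to n_trials")
    return lengths


def _block_probabilities(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded block order; no two consecutive blocks share a contingency."""
    values = np.array([p for p, r in config.probability_classes for _ in range(r)])
    for _ in range(1000):
        perm = rng.permutation(values)
        if np.all(np.diff(perm) != 0):
            return perm
    raise ConfigurationError("could not order blocks without repeating a contingency")


def _rating_trials(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """1-based trial indices of prompts; gaps uniform on [gap_min, gap_max],
    minimally shrunk (seeded) until the final prompt fits the session."""
    lo, hi = config.rating_gap_min, config.rating_gap_max
    gaps = rng.integers(lo, hi + 1, size=config.n_ratings)  # gaps[0] = first prompt trial
    while gaps.sum() > config.n_trials:
        shrinkable = np.flatnonzero(gaps > lo)
        if len(shrinkable) == 0:  # pragma: no cover - excluded by config validation
            raise ConfigurationError("rating prompts cannot fit in session")
        gaps[rng.choice(shrinkable)] -= 1
    return np.cumsum(gaps)


def generate_schedule(config: TaskConfig | None = None, seed: int = 0) -> TaskSchedule:
    """Generate one seeded task session.

    Outcomes are Bernoulli draws from the block contingency given the shown
    stimulus; stimuli are i.i.d. uniform over {A, B}; block order is a seeded
    permutation of the configured contingency repeats.
    """
    if config is None:
        config = TaskConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    lengths = _block_lengths(config, rng)
    probs = _block_probabilities(config, rng)
    block_index = np.repeat(np.arange(config.n_blocks), lengths)
    p_A = probs[block_index]

    stimulus = rng.integers(0, 2, size=config.n_trials)
    p_shown = np.where(stimulus == 0, p_A, 1.0 - p_A)
    outcome = (rng.random(config.n_trials) < p_shown).astype(int)

    is_rating = np.zeros(config.n_trials, dtype=bool)
    is_rating[_rating_trials(config, rng) - 1] = True

    # Per-trial event chain with uniform jitter; rating prompts add 3 s.
    def draw(spec: tuple[float, float]) -> np.ndarray:
        mean, jit = spec
        return rng.uniform(mean - jit, mean + jit, size=config.n_trials)

    d_stim = draw(config.stimulus_ms)
    d_dec = draw(config.decision_ms)
    d_pred = draw(config.prediction_ms)
    d_out = draw(config.outcome_ms)
    d_iti = draw(config.iti_ms)
    d_rating = np.where(is_rating, 3000.0, 0.0)

    trial_dur = d_stim + d_dec + d_pred + d_out + d_iti + d_rating
    start = np.concatenate([[0.0], np.cumsum(trial_dur)[:-1]])
    onset_stimulus = start
    onset_decision = onset_stimulus + d_stim
    onset_prediction = onset_decision + d_dec
    onset_outcome = onset_prediction + d_pred
    onset_iti = onset_outcome + d_out
    trial_end = start + trial_dur

    # Self-paced breaks roughly every break_interval_min of task time.
    break_ms = config.break_interval_min * 60_000.0
    breaks = []
    next_break = break_ms
    for k in range(config.n_trials - 1):
        if trial_end[k] >= next_break:
            breaks.append(k + 1)  # 1-based trial after which the break occurs
            next_break += break_ms

    return TaskSchedule(
        config=config,
        stimulus=stimulus,
        p_snake_given_A=p_A,
        block_index=block_index,
        outcome=outcome,
        onset_stimulus_ms=onset_stimulus,
        onset_decision_ms=onset_decision,
        onset_prediction_ms=onset_prediction,
        onset_outcome_ms=onset_outcome,
        onset_iti_ms=onset_iti,
        trial_end_ms=trial_end,
        is_rating_trial=is_rating,
        break_after_trial=np.asarray(breaks, dtype=int),
    )
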