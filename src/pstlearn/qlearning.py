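"""Q-learning with asymmetric learning rates and softmax choice.

Each symbol *i* carries a value ``Q_i`` updated only when that symbol is
chosen::

    Q_i(t+1) = Q_i(t) + alpha_approach * max(r(t) - Q_i(t), 0)
                      + alpha_avoid    * min(r(t) - Q_i(t), 0)

with reward ``r(t)`` equal to 1 for positive and 0 for negative feedback.
Because rewards are binary and Q stays in [0, 1], the rectified form reduces
to "use alpha_approach after positive outcomes, alpha_avoid after negative
ones". The canonical single-rate model is the special case
``alpha_approach == alpha_avoid``.

Choices follow a softmax on the value difference with temperature ``beta``:
``p(first) = 1 / (1 + exp(-(Q_first - Q_second) / beta))``; small ``beta``
approaches greedy selection of the higher-valued symbol (exploitation), large
``beta`` approaches random choice (exploration).

Likelihoods of observed choice sequences replay the participant's actual
choices and outcomes — they never re-simulate. Test-phase choices are scored
on the Q-values frozen at the end of training, since no feedback is given
during test and no further learning can occur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .task import (
    SYMBOL_INDEX,
    SYMBOLS,
    PairSpec,
    TaskConfig,
    TrialRecord,
    build_test_schedule,
    build_training_block,
    criterion_met,
    sample_feedback,
)

__all__ = [
    "ModelParams",
    "QState",
    "AgentLog",
    "update_q",
    "choice_probability",
    "replay_training",
    "nll_training",
    "nll_test",
    "simulate_agent",
]

VARIANTS = ("canonical", "approach_avoid")

#: Number of probabilities floored at 1e-300 triggers a warning, never an error.
P_FLOOR = _kernels.P_FLOOR


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the choice model.

    ``variant='canonical'`` uses a single learning rate ``alpha`` for both
    positive and negative prediction errors (k=2 free parameters);
    ``variant='approach_avoid'`` splits it into ``alpha_approach`` /
    ``alpha_avoid`` (k=3). ``beta`` is the softmax temperature.
    """

    beta: float
    variant: str = "approach_avoid"
    alpha: float | None = None
    alpha_approach: float | None = None
    alpha_avoid: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.variant == "canonical":
            if self.alpha is None:
                raise ValueError("canonical variant requires alpha")
            object.__setattr__(self, "alpha_approach", self.alpha)
            object.__setattr__(self, "alpha_avoid", self.alpha)
        else:
            if self.alpha_approach is None or self.alpha_avoid is None:
                raise ValueError(
                    "approach_avoid variant requires alpha_approach and alpha_avoid"
                )
        for name in ("alpha", "alpha_approach", "alpha_avoid"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def canonical(cls, alpha: float, beta: float) -> "ModelParams":
        return cls(beta=beta, variant="canonical", alpha=alpha)

    @classmethod
    def approach_avoid(
        cls, alpha_approach: float, alpha_avoid: float, beta: float
    ) -> "ModelParams":
        return cls(
            beta=beta,
            variant="approach_avoid",
            alpha_approach=alpha_approach,
            alpha_avoid=alpha_avoid,
        )

    @property
    def k(self) -> int:
        """Number of free parameters (2 canonical, 3 approach/avoid)."""
        return 2 if self.variant == "canonical" else 3

    @property
    def rates(self) -> tuple[float, float]:
        return (self.alpha_approach, self.alpha_avoid)


@dataclass
class QState:
    """Value table over the six symbols."""

    q: dict[str, float]
    q0: float = 0.5

    @classmethod
    def initial(cls, q0: float = 0.5) -> "QState":
        return cls(q={s: q0 for s in SYMBOLS}, q0=q0)

    def as_array(self) -> np.ndarray:
        return np.array([self.q[s] for s in SYMBOLS])


def update_q(q_chosen: float, outcome: int, params: ModelParams) -> float:
    """One-step value update of the chosen symbol.

    Positive prediction errors are scaled by ``alpha_approach``, negative
    ones by ``alpha_avoid``; the unchosen symbol is untouched.
    """
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    pe = outcome - q_chosen
    if pe > 0:
        return q_chosen + params.alpha_approach * pe
    return q_chosen + params.alpha_avoid * pe


def choice_probability(q_first: float, q_second: float, beta: float) -> float:
    """Softmax probability of choosing the first symbol of a pair."""
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    x = (q_first - q_second) / beta
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def _check_training_trials(trials: Sequence[TrialRecord]) -> None:
    last = None
    for t in trials:
        if t.phase != "training":
            raise ValueError("replay expects training-phase trials")
        if not t.responded or t.outcome is None:
            raise ValueError(
                f"training trial {t.trial_index} lacks a choice or outcome"
            )
        if last is not None and t.trial_index <= last:
            raise ValueError("training trials out of order")
        last = t.trial_index


def encode_trials(
    trials: Sequence[TrialRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode responded trials into (chosen, other, outcome) integer arrays;
    outcomes of test trials encode as -1."""
    chosen = np.empty(len(trials), dtype=np.int64)
    other = np.empty(len(trials), dtype=np.int64)
    outcome = np.empty(len(trials), dtype=np.float64)
    for i, t in enumerate(trials):
        chosen[i] = SYMBOL_INDEX[t.chosen]
        other[i] = SYMBOL_INDEX[t.unchosen]
        outcome[i] = -1.0 if t.outcome is None else float(t.outcome)
    return chosen, other, outcome


def replay_training(
    trials: Sequence[TrialRecord],
    params: ModelParams,
    q0: float = 0.5,
) -> tuple[QState, np.ndarray]:
    """Replay one participant's observed training sequence.

    For each trial the probability of the *observed* choice is computed from
    the current values, then the chosen symbol's value is updated with the
    observed outcome. Returns the final value table and the probability
    sequence. Pure-Python reference implementation of the fitting kernels.
    """
    _check_training_trials(trials)
    state = QState.initial(q0)
    probs = np.empty(len(trials))
    for i, t in enumerate(trials):
        probs[i] = choice_probability(
            state.q[t.chosen], state.q[t.unchosen], params.beta
        )
        state.q[t.chosen] = update_q(state.q[t.chosen], t.outcome, params)
    return state, probs


def _warn_floor(floored: int) -> None:
    if floored:
        warnings.warn(
            f"{floored} choice probabilities floored at {P_FLOOR:g} to avoid "
            "-inf log-likelihood",
            RuntimeWarning,
            stacklevel=3,
        )


def nll_training(
    trials: Sequence[TrialRecord], params: ModelParams, q0: float = 0.5
) -> float:
    """Negative log-likelihood of observed training choices:
    ``-sum(log p(observed choice))``."""
    _check_training_trials(trials)
    chosen, other, outcome = encode_trials(trials)
    nll, _, _, floored = _kernels.replay_kernel(
        chosen, other, outcome, params.alpha_approach, params.alpha_avoid,
        params.beta, q0,
    )
    _warn_floor(floored)
    return float(nll)


def nll_test(
    training_trials: Sequence[TrialRecord],
    test_trials: Sequence[TrialRecord],
    params: ModelParams,
    q0: float = 0.5,
) -> float:
    """Negative log-likelihood of test-phase choices.

    Training is replayed with the learning rates to obtain the end-of-training
    value table; each responded test choice is then scored through the softmax
    with ``beta`` on those frozen values. The learning rates influence this
    likelihood only through the final values; non-responded test trials are
    skipped.
    """
    _check_training_trials(training_trials)
    for t in test_trials:
        if t.phase != "test":
            raise ValueError("nll_test expects test-phase trials")
    ch_tr, ot_tr, out_tr = encode_trials(training_trials)
    _, q_final, _, fl1 = _kernels.replay_kernel(
        ch_tr, ot_tr, out_tr, params.alpha_approach, params.alpha_avoid,
        params.beta, q0,
    )
    responded = [t for t in test_trials if t.responded]
    ch_te, ot_te, _ = encode_trials(responded)
    nll, _, fl2 = _kernels.test_nll_kernel(q_final, ch_te, ot_te, params.beta)
    _warn_floor(fl1 + fl2)
    return float(nll)


@dataclass
class AgentLog:
    """Trial log of one simulated agent plus its exclusion flag."""

    participant_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    excluded: bool = False
    n_blocks: int = 0

    @property
    def training(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.phase == "training"]

    @property
    def test(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.phase == "test"]


def simulate_agent(
    train_params: ModelParams,
    config: TaskConfig,
    rng: np.random.Generator,
    test_params: ModelParams | None = None,
    q0: float = 0.5,
    participant_id: str = "agent",
    stop_at_criterion: bool = True,
) -> AgentLog:
    """Simulate one agent through training and test.

    During training the agent chooses by softmax on its current values under
    ``train_params``, receives Bernoulli feedback from the task contingencies
    and updates the chosen symbol's value. Blocks continue until the learning
    criterion is met or ``max_blocks`` is reached (the agent is then flagged
    excluded). Test choices are drawn by softmax with ``test_params.beta`` on
    the value table obtained by re-deriving end-of-training values under
    ``test_params``' learning rates applied to the agent's own training
    history — the generative counterpart of the two-system account in which a
    slower habitual system learns from the same experience as the fast
    working-memory system that drove the choices.

    ``test_params`` defaults to ``train_params`` (a single-system agent).
    """
    if test_params is None:
        test_params = train_params
    log = AgentLog(participant_id=participant_id)
    state = QState.initial(q0)
    trial_index = 0
    met = False
    for block in range(config.max_blocks):
        block_trials: list[TrialRecord] = []
        for pair in build_training_block(config, rng):
            p_first = choice_probability(
                state.q[pair.first], state.q[pair.second], train_params.beta
            )
            chosen = pair.first if rng.random() < p_first else pair.second
            outcome = sample_feedback(chosen, config.contingencies, rng)
            rec = TrialRecord(
                participant_id=participant_id,
                phase="training",
                block_index=block,
                trial_index=trial_index,
                pair=pair,
                chosen=chosen,
                outcome=outcome,
            )
            block_trials.append(rec)
            state.q[chosen] = update_q(state.q[chosen], outcome, train_params)
            trial_index += 1
        log.trials.extend(block_trials)
        log.n_blocks = block + 1
        if stop_at_criterion and criterion_met(block_trials, config):
            met = True
            break
    log.excluded = stop_at_criterion and not met

    # habitual-system values: same history, test_params' learning rates
    habit, _ = replay_training(log.training, test_params, q0)
    test_index = 0
    for pair in build_test_schedule(config, rng):
        p_first = choice_probability(
            habit.q[pair.first], habit.q[pair.second], test_params.beta
        )
        chosen = pair.first if rng.random() < p_first else pair.second
        log.trials.append(
            TrialRecord(
                participant_id=participant_id,
                phase="test",
                block_index=None,
                trial_index=test_index,
                pair=pair,
                chosen=chosen,
                outcome=None,
            )
        )
        test_index += 1
    return log
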