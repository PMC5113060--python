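"""Structure of the probabilistic selection task (PST).

Three symbol pairs (AB, CD, EF) carry complementary positive-feedback
probabilities of 80/20, 70/30 and 60/40 percent. Participants train on these
pairs in blocks until they select A on at least 60% of AB trials and C on at
least 55% of CD trials within a single block, then move to a no-feedback test
phase presenting the twelve novel cross-pairings of the six symbols.

This module holds the task constants, configuration, trial records, schedule
builders and the Bernoulli feedback sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SYMBOLS",
    "TRAINED_PAIRS",
    "NOVEL_PAIRS",
    "DEFAULT_CONTINGENCIES",
    "SymbolSpec",
    "PairSpec",
    "TaskConfig",
    "TrialRecord",
    "build_training_block",
    "build_test_schedule",
    "sample_feedback",
    "criterion_met",
]

SYMBOLS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")
SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(SYMBOLS)}

TRAINED_PAIRS: tuple[str, ...] = ("AB", "CD", "EF")
NOVEL_PAIRS: tuple[str, ...] = (
    "AC", "AD", "AE", "AF",
    "BC", "BD", "BE", "BF",
    "CE", "CF", "DE", "DF",
)

#: Probability of positive feedback for selecting each symbol; within a
#: trained pair the two probabilities sum to one (80/20, 70/30, 60/40).
DEFAULT_CONTINGENCIES: dict[str, float] = {
    "A": 0.8, "B": 0.2,
    "C": 0.7, "D": 0.3,
    "E": 0.6, "F": 0.4,
}


@dataclass(frozen=True)
class SymbolSpec:
    """A task symbol and its probability of yielding positive feedback."""

    symbol_id: str
    p_positive: float

    def __post_init__(self) -> None:
        if self.symbol_id not in SYMBOLS:
            raise ValueError(f"unknown symbol {self.symbol_id!r}")
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError(f"p_positive must be in [0, 1], got {self.p_positive}")


@dataclass(frozen=True)
class PairSpec:
    """One two-symbol presentation; ``first``/``second`` is the screen order."""

    first: str
    second: str
    phase_role: str = "trained"  # trained | novel

    def __post_init__(self) -> None:
        if self.first not in SYMBOLS or self.second not in SYMBOLS:
            raise ValueError(f"unknown symbols in pair {self.first}{self.second}")
        if self.first == self.second:
            raise ValueError("a pair must contain two distinct symbols")
        if self.phase_role not in ("trained", "novel"):
            raise ValueError(f"invalid phase_role {self.phase_role!r}")
        if self.key not in (TRAINED_PAIRS if self.phase_role == "trained" else NOVEL_PAIRS):
            raise ValueError(
                f"pair {self.key} is not a {self.phase_role} pair of the task"
            )

    @property
    def key(self) -> str:
        """Canonical (alphabetical) two-letter pair identifier."""
        return "".join(sorted((self.first, self.second)))

    @property
    def symbols(self) -> tuple[str, str]:
        return (self.first, self.second)


def pair_from_key(key: str) -> PairSpec:
    """Build a canonical-orientation :class:`PairSpec` from a two-letter key."""
    if key in TRAINED_PAIRS:
        return PairSpec(key[0], key[1], "trained")
    if key in NOVEL_PAIRS:
        return PairSpec(key[0], key[1], "novel")
    raise ValueError(f"unknown pair {key!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Block structure, learning criteria and test schedule of the PST.

    Parameters
    ----------
    block_size : int
        Trials per training block (default 60; three pairs, 20 trials each).
    trials_per_pair_per_block : int
        Presentations of each trained pair per block.
    criterion_A, criterion_C : float
        Minimum within-block selection rates of A on AB trials and C on CD
        trials required to end training (0.60 and 0.55).
    max_blocks : int
        Training-time cap; agents not reaching criterion within this many
        blocks are flagged excluded (stands in for a 45-minute session limit).
    test_reps_per_pair : int
        Repetitions of each of the 12 novel pairs in the test schedule.
    max_consecutive_repeats : int or None
        Interleaving constraint: no pair may occur more than this many times
        in a row within a schedule. ``None`` disables the constraint.
    contingencies : mapping
        Per-symbol positive-feedback probabilities.
    """

    block_size: int = 60
    trials_per_pair_per_block: int = 20
    criterion_A: float = 0.60
    criterion_C: float = 0.55
    max_blocks: int = 12
    test_reps_per_pair: int = 8
    max_consecutive_repeats: int | None = 3
    contingencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTINGENCIES)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.block_size != 3 * self.trials_per_pair_per_block:
            raise ValueError("block_size must equal 3 * trials_per_pair_per_block")
        for name in ("criterion_A", "criterion_C"):
            c = getattr(self, name)
            if not 0.5 < c <= 1.0:
                raise ValueError(f"{name} must lie in (0.5, 1], got {c}")
        if self.max_blocks < 1:
            raise ValueError("max_blocks must be >= 1")
        if self.test_reps_per_pair < 1:
            raise ValueError("test_reps_per_pair must be >= 1")
        if self.max_consecutive_repeats is not None and self.max_consecutive_repeats < 1:
            raise ValueError("max_consecutive_repeats must be >= 1 or None")
        for sym in SYMBOLS:
            p = self.contingencies.get(sym)
            if p is None:
                raise ValueError(f"contingencies missing symbol {sym}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"contingency for {sym} out of [0, 1]: {p}")
        for a, b in TRAINED_PAIRS:
            total = self.contingencies[a] + self.contingencies[b]
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"contingencies of trained pair {a}{b} must sum to 1, got {total}"
                )

    def replace(self, **changes) -> "TaskConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class TrialRecord:
    """One PST trial: the atomic unit every likelihood is built from.

    ``outcome`` is 1 for positive feedback, 0 for negative, and ``None`` for
    all test-phase trials (no feedback is given) or non-responses.
    """

    participant_id: str
    phase: str  # training | test
    block_index: int | None
    trial_index: int
    pair: PairSpec
    chosen: str | None
    outcome: int | None

    def __post_init__(self) -> None:
        if self.phase not in ("training", "test"):
            raise ValueError(f"invalid phase {self.phase!r}")
        if self.chosen is not None and self.chosen not in self.pair.symbols:
            raise ValueError(
                f"chosen symbol {self.chosen!r} not in pair {self.pair.key}"
            )
        if self.phase == "test":
            if self.outcome is not None:
                raise ValueError("test-phase trials carry no feedback")
        else:
            if self.chosen is not None and self.outcome not in (0, 1):
                raise ValueError("responded training trials need outcome in {0, 1}")

    @property
    def responded(self) -> bool:
        return self.chosen is not None

    @property
    def unchosen(self) -> str | None:
        if self.chosen is None:
            return None
        a, b = self.pair.symbols
        return b if self.chosen == a else a


def _shuffle_with_run_limit(
    items: list[PairSpec], max_run: int | None, rng: np.random.Generator
) -> list[PairSpec]:
    """Shuffle, rejecting permutations with more than ``max_run`` identical
    consecutive pair keys. Expected number of attempts is small for the
    default 20/20/20 block."""
    items = list(items)
    for _ in range(10_000):
        perm = [items[i] for i in rng.permutation(len(items))]
        if max_run is None:
            return perm
        run, ok = 1, True
        for prev, cur in zip(perm, perm[1:]):
            run = run + 1 if cur.key == prev.key else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return perm
    raise RuntimeError("could not satisfy the interleaving constraint")


def build_training_block(
    config: TaskConfig, rng: np.random.Generator
) -> list[PairSpec]:
    """Return one block's presentation order of the trained pairs.

    Each trained pair appears exactly ``trials_per_pair_per_block`` times,
    shuffled subject to the interleaving constraint. Deterministic given the
    generator state.
    """
    base = [
        pair_from_key(key)
        for key in TRAINED_PAIRS
        for _ in range(config.trials_per_pair_per_block)
    ]
    return _shuffle_with_run_limit(base, config.max_consecutive_repeats, rng)


def build_test_schedule(
    config: TaskConfig, rng: np.random.Generator
) -> list[PairSpec]:
    """Return the test-phase schedule: the 12 novel pairs, each repeated
    ``test_reps_per_pair`` times, with left/right symbol order counterbalanced
    across repetitions, fully shuffled."""
    trials: list[PairSpec] = []
    for key in NOVEL_PAIRS:
        reps = config.test_reps_per_pair
        n_forward = reps // 2
        if reps % 2:
            n_forward += int(rng.integers(2))
        for i in range(reps):
            if i < n_forward:
                trials.append(PairSpec(key[0], key[1], "novel"))
            else:
                trials.append(PairSpec(key[1], key[0], "novel"))
    return _shuffle_with_run_limit(trials, config.max_consecutive_repeats, rng)


def _as_contingency_map(
    contingencies: Mapping[str, float] | Iterable[SymbolSpec],
) -> Mapping[str, float]:
    if isinstance(contingencies, Mapping):
        return contingencies
    return {spec.symbol_id: spec.p_positive for spec in contingencies}


def sample_feedback(
    chosen: str,
    contingencies: Mapping[str, float] | Iterable[SymbolSpec],
    rng: np.random.Generator,
) -> int:
    """Bernoulli feedback draw: 1 with the chosen symbol's p_positive."""
    table = _as_contingency_map(contingencies)
    if chosen not in table:
        raise KeyError(
            f"symbol {chosen!r} has no entry in the contingency table"
        )
    return int(rng.random() < table[chosen])


def criterion_met(block_trials: Sequence[TrialRecord], config: TaskConfig) -> bool:
    """Whether one training block meets both learning criteria.

    Selection rates are computed over responded trials only: A on AB trials
    must reach ``criterion_A`` and C on CD trials ``criterion_C``.
    """
    blocks = {t.block_index for t in block_trials}
    if len(blocks) > 1:
        raise ValueError("criterion_met expects trials from a single block")
    ab = [t for t in block_trials if t.pair.key == "AB" and t.responded]
    cd = [t for t in block_trials if t.pair.key == "CD" and t.responded]
    if not ab or not cd:
        raise ValueError("block has no responded AB or CD trials")
    rate_a = sum(t.chosen == "A" for t in ab) / len(ab)
    rate_c = sum(t.chosen == "C" for t in cd) / len(cd)
    return rate_a >= config.criterion_A and rate_c >= config.criterion_C
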