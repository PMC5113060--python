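"""Synthetic cohorts of task participants.

Each agent is a Q-learning decision maker with two parameter sets: a fast
working-memory system (``train_params``) that drives choices and learns
during training, and a slower habitual system (``test_params``) that learns
from the same trial history and drives test-phase choices. Trait
questionnaire scores are linear-Gaussian in the habitual learning-rate
asymmetry ``alpha_avoid − alpha_approach``: agents whose habitual system
weights negative feedback relatively more (which, under probabilistic
feedback, favours selecting the frequently rewarded symbol over rejecting
the frequently punished one) receive higher reward-sensitivity and lower
punishment-sensitivity latents. This is the simplest generative structure
consistent with the group-level pattern the analysis is meant to detect, and
the coupling strength and noise are configurable.

Dual-system agents share everything between the two systems except the rate
asymmetry: the habitual rates are the working-memory mean rate shifted by
±asymmetry/2, so overall plasticity is held at the working-memory level and
the asymmetry is the single habitual degree of freedom. The habitual softmax
temperature is drawn separately (and low — the habitual read-out is the less
noisy, overtrained channel). Working-memory rates favour positive feedback
and temperatures sit well below 1, spanning the plausible range for this
task; training temperatures are set so that agents typically need more than
one block to reach criterion, as human cohorts do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .qlearning import AgentLog, ModelParams, simulate_agent
from .task import TaskConfig

__all__ = [
    "AgentProfile",
    "CohortConfig",
    "sample_cohort",
    "generate_cohort_logs",
]

#: raw-score scales of the questionnaire subscales: (min, center, spread, max)
_TRAIT_SCALES = {
    "sr": (0, 11.0, 4.0, 24),
    "sp": (0, 11.0, 4.0, 24),
    "bis": (7, 17.5, 3.5, 28),
    "drive": (4, 10.0, 2.0, 16),
    "fun_seeking": (4, 10.0, 2.0, 16),
    "reward_responsiveness": (5, 15.0, 2.2, 20),
}


@dataclass(frozen=True)
class AgentProfile:
    """Generative parameters and raw trait scores of one synthetic agent."""

    participant_id: str
    train_params: ModelParams
    test_params: ModelParams
    traits_raw: dict[str, int] = field(default_factory=dict)
    excluded: bool = False

    @property
    def habitual_asymmetry(self) -> float:
        return self.test_params.alpha_avoid - self.test_params.alpha_approach


@dataclass(frozen=True)
class CohortConfig:
    """Size, parameter distributions and trait coupling of a cohort.

    ``habitual_asymmetry`` is the range of the dual-system shift h: habitual
    rates are ``mean(train rates) ∓ h/2`` (clipped to [0, 1]), so positive h
    means the habitual system weights negative feedback relatively more.
    ``coupling`` scales how strongly the latent SR−SP contrast follows the
    (standardised) habitual-rate asymmetry; ``trait_noise_sd`` is the SD of
    the Gaussian noise added on top (both on the z scale).
    ``dual_system_fraction`` is the fraction of agents with a distinct
    habitual system; the rest are single-system (test_params = train_params).
    """

    n: int = 60
    seed: int = 0
    train_alpha_approach: tuple[float, float] = (0.12, 0.45)
    train_alpha_avoid: tuple[float, float] = (0.005, 0.15)
    train_beta: tuple[float, float] = (0.30, 0.50)
    habitual_asymmetry: tuple[float, float] = (-0.4, 0.4)
    test_beta: tuple[float, float] = (0.05, 0.12)
    coupling: float = 1.2
    trait_noise_sd: float = 0.4
    idiosyncratic_sd: float = 0.3
    dual_system_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        if not np.isfinite(self.coupling):
            raise ValueError("coupling must be finite")
        if self.trait_noise_sd < 0 or self.idiosyncratic_sd < 0:
            raise ValueError("trait noise SDs must be >= 0")
        if not 0.0 <= self.dual_system_fraction <= 1.0:
            raise ValueError("dual_system_fraction must be in [0, 1]")
        for name in ("train_alpha_approach", "train_alpha_avoid"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} range must satisfy 0 <= lo <= hi <= 1")
        lo, hi = self.habitual_asymmetry
        if not (-1.0 <= lo <= hi <= 1.0):
            raise ValueError("habitual_asymmetry range must lie within [-1, 1]")
        for name in ("train_beta", "test_beta"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} range must be positive")

    def replace(self, **changes) -> "CohortConfig":
        return replace(self, **changes)


def _raw_score(name: str, latent: float) -> int:
    lo, center, spread, hi = _TRAIT_SCALES[name]
    return int(np.clip(round(center + spread * latent), lo, hi))


def sample_cohort(config: CohortConfig) -> list[AgentProfile]:
    """Draw a cohort of agent profiles; deterministic given ``config.seed``.

    Habitual-rate asymmetries are standardised within the cohort and the
    latent SR−SP contrast is ``coupling * z(asymmetry) + noise``, split
    symmetrically into SR and SP latents before conversion to raw subscale
    sums. BIS/BAS latents are drawn independently of the learning parameters
    (uncoupled, matching their null role in the analysis).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    u = lambda lohi, size=n: rng.uniform(*lohi, size=size)
    train_a_app = u(config.train_alpha_approach)
    train_a_av = u(config.train_alpha_avoid)
    train_beta = u(config.train_beta)
    # habitual system: working-memory mean rate shifted by the asymmetry
    h = u(config.habitual_asymmetry)
    mid = (train_a_app + train_a_av) / 2.0
    test_a_app = np.clip(mid - h / 2.0, 0.0, 1.0)
    test_a_av = np.clip(mid + h / 2.0, 0.0, 1.0)
    test_beta = u(config.test_beta)
    dual = rng.random(n) < config.dual_system_fraction
    test_a_app = np.where(dual, test_a_app, train_a_app)
    test_a_av = np.where(dual, test_a_av, train_a_av)
    test_beta = np.where(dual, test_beta, train_beta)

    asym = test_a_av - test_a_app
    sd = asym.std(ddof=1)
    z_asym = (asym - asym.mean()) / sd if sd > 0 else np.zeros(n)
    srsp = config.coupling * z_asym + rng.normal(0, config.trait_noise_sd, n)
    idio = rng.normal(0, config.idiosyncratic_sd, size=(n, 2))  # trait-specific scatter
    sr_latent = srsp / 2.0 + idio[:, 0]
    sp_latent = -srsp / 2.0 + idio[:, 1]
    bas_bis = rng.normal(0, 1, size=(n, 4))  # drive, fun, rewresp, bis

    profiles = []
    for i in range(n):
        traits = {
            "sr": _raw_score("sr", sr_latent[i]),
            "sp": _raw_score("sp", sp_latent[i]),
            "bis": _raw_score("bis", bas_bis[i, 3]),
            "drive": _raw_score("drive", bas_bis[i, 0]),
            "fun_seeking": _raw_score("fun_seeking", bas_bis[i, 1]),
            "reward_responsiveness": _raw_score("reward_responsiveness", bas_bis[i, 2]),
        }
        profiles.append(
            AgentProfile(
                participant_id=f"agent{i:03d}",
                train_params=ModelParams.approach_avoid(
                    train_a_app[i], train_a_av[i], train_beta[i]
                ),
                test_params=ModelParams.approach_avoid(
                    test_a_app[i], test_a_av[i], test_beta[i]
                ),
                traits_raw=traits,
            )
        )
    return profiles


def generate_cohort_logs(
    profiles: Sequence[AgentProfile],
    task_config: TaskConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[AgentProfile]]:
    """Simulate every agent through the task.

    Returns (trial-log DataFrame in the standard CSV dialect, traits
    DataFrame of raw subscale sums, profiles with exclusion flags set).
    Excluded agents (criterion never met) keep their training log but are
    flagged; per-agent RNG substreams are spawned from ``seed``.
    """
    from .io import records_to_frame

    streams = np.random.SeedSequence(seed).spawn(len(profiles))
    frames = []
    trait_rows = []
    flagged: list[AgentProfile] = []
    for profile, stream in zip(profiles, streams):
        log: AgentLog = simulate_agent(
            profile.train_params,
            task_config,
            np.random.default_rng(stream),
            test_params=profile.test_params,
            participant_id=profile.participant_id,
        )
        frames.append(records_to_frame(log.trials))
        trait_rows.append(
            {"participant_id": profile.participant_id, **profile.traits_raw}
        )
        flagged.append(replace(profile, excluded=log.excluded))
    trials = pd.concat(frames, ignore_index=True)
    traits = pd.DataFrame(trait_rows)
    return trials, traits, flagged
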