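"""Validation experiments: parameter recovery, model recovery, headline
group-level patterns, and the learning-rate/performance mechanism curve.

These are the standard simulation checks for a trial-level choice model:
simulate agents at known parameters, push the data through the same pipeline
a real cohort would take, and measure how well truth is recovered. The fixed
experiment design is six 60-trial blocks (360 training trials) without
criterion gating, so every simulated agent contributes the same amount of
data; cohort-level experiments use the criterion-gated task as real
participants would experience it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import group_stats, interaction_test, learner_metrics_table, score_traits
from .cohort import CohortConfig, generate_cohort_logs, sample_cohort
from .comparison import compare_cohort
from .fitting import FitOptions, QLearningModel, fit_phase
from .qlearning import ModelParams, simulate_agent
from .task import TaskConfig

__all__ = [
    "parameter_recovery",
    "model_recovery",
    "headline_patterns",
    "mechanism_curve",
]

logger = logging.getLogger(__name__)

RECOVERY_BLOCKS = 6  # 360 training trials


def _fixed_length_config(n_blocks: int = RECOVERY_BLOCKS) -> TaskConfig:
    return TaskConfig(max_blocks=n_blocks)


def parameter_recovery(
    n_agents: int = 200,
    seed: int = 0,
    alpha_range: tuple[float, float] = (0.05, 0.5),
    beta_range: tuple[float, float] = (0.1, 0.5),
    n_blocks: int = RECOVERY_BLOCKS,
    options: FitOptions | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate agents at known two-rate parameters and refit them.

    Returns (per-agent table of true and recovered parameters, Spearman
    correlations between truth and estimate per parameter).
    """
    rng = np.random.default_rng(seed)
    config = _fixed_length_config(n_blocks)
    options = options or FitOptions(seed=seed)
    rows = []
    for i in range(n_agents):
        true = ModelParams.approach_avoid(
            rng.uniform(*alpha_range), rng.uniform(*alpha_range),
            rng.uniform(*beta_range),
        )
        log = simulate_agent(
            true, config, rng, participant_id=f"rec{i:03d}",
            stop_at_criterion=False,
        )
        fit = fit_phase(log.training, None, "approach_avoid", "training", options)
        rows.append(
            {
                "participant_id": log.participant_id,
                "true_alpha_approach": true.alpha_approach,
                "true_alpha_avoid": true.alpha_avoid,
                "true_beta": true.beta,
                "fit_alpha_approach": fit.params.alpha_approach,
                "fit_alpha_avoid": fit.params.alpha_avoid,
                "fit_beta": fit.params.beta,
                "nll": fit.nll,
            }
        )
        if (i + 1) % 50 == 0:
            logger.info("parameter recovery: %d/%d agents", i + 1, n_agents)
    table = pd.DataFrame(rows)
    correlations = {
        p: float(stats.spearmanr(table[f"true_{p}"], table[f"fit_{p}"]).statistic)
        for p in ("alpha_approach", "alpha_avoid", "beta")
    }
    return table, correlations


def _simulate_generator_cohort(
    variant: str, n: int, rng: np.random.Generator, config: TaskConfig
) -> dict:
    """One cohort generated from a given model variant; two-rate agents are
    drawn with |alpha_approach - alpha_avoid| >= 0.2."""
    cohort = {}
    for i in range(n):
        if variant == "canonical":
            params = ModelParams.canonical(
                alpha=rng.uniform(0.1, 0.4), beta=rng.uniform(0.15, 0.35)
            )
        else:
            a_app = rng.uniform(0.3, 0.5)
            a_av = rng.uniform(0.02, a_app - 0.2)
            params = ModelParams.approach_avoid(a_app, a_av, rng.uniform(0.15, 0.35))
        log = simulate_agent(
            params, config, rng, participant_id=f"{variant[:3]}{i:03d}",
            stop_at_criterion=False,
        )
        cohort[log.participant_id] = (log.training, log.test)
    return cohort


def _fit_both_variants(cohort: dict, options: FitOptions) -> pd.DataFrame:
    rows = []
    for pid, (train, _test) in cohort.items():
        for variant in ("canonical", "approach_avoid"):
            fit = fit_phase(train, None, variant, "training", options)
            row = fit.to_row()
            row["participant_id"] = pid
            row["error"] = ""
            rows.append(row)
    return pd.DataFrame(rows)


def model_recovery(
    n_per_cohort: int = 40,
    n_replicates: int = 20,
    seed: int = 0,
    n_blocks: int = RECOVERY_BLOCKS,
    options: FitOptions | None = None,
) -> dict:
    """Can AIC tell the generating model apart?

    Two checks: (a) a confusion matrix — one cohort per generating variant,
    both variants fitted, per-participant AIC preference tallied; (b) power —
    ``n_replicates`` two-rate cohorts, fraction whose paired AIC t-test
    favours the two-rate model at p < 0.05.
    """
    config = _fixed_length_config(n_blocks)
    options = options or FitOptions(seed=seed)
    rng = np.random.default_rng(seed)

    confusion = {}
    for variant in ("canonical", "approach_avoid"):
        cohort = _simulate_generator_cohort(variant, n_per_cohort, rng, config)
        fits = _fit_both_variants(cohort, options)
        comp, _ = compare_cohort(fits)
        frac = (comp["preferred"] == variant).mean()
        confusion[variant] = float(frac)
        logger.info("model recovery: generator=%s preferred fraction %.2f",
                    variant, frac)

    favoured = 0
    for r in range(n_replicates):
        cohort = _simulate_generator_cohort("approach_avoid", n_per_cohort, rng, config)
        fits = _fit_both_variants(cohort, options)
        _, ttest = compare_cohort(fits)
        row = ttest.iloc[0]
        if row["p"] < 0.05 and row["mean_aic_approach_avoid"] < row["mean_aic_canonical"]:
            favoured += 1
        logger.info("model recovery: replicate %d/%d t=%.2f p=%.4f",
                    r + 1, n_replicates, row["t"], row["p"])
    return {
        "confusion_preferred_fraction": confusion,
        "tworate_ttest_favoured_fraction": favoured / n_replicates,
        "n_replicates": n_replicates,
    }


@dataclass
class HeadlineResult:
    """Group-level pattern recovery on one default synthetic cohort."""

    n_included: int
    n_approach: int
    n_avoidance: int
    srsp_t: float
    srsp_p_one_sided: float
    habitual_interaction_t: float
    habitual_interaction_p: float
    habitual_crossover_direction_ok: bool
    wm_interaction_null_fraction: float
    wm_interaction_ps: list[float] = field(default_factory=list)


def _cohort_tables(
    cohort_config: CohortConfig,
    task_config: TaskConfig,
    options: FitOptions,
    fit_phases: tuple[str, ...] = ("test",),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort, drop excluded agents, classify, score traits and
    fit the two-rate model for the requested phases."""
    from .io import split_cohort

    profiles = sample_cohort(cohort_config)
    trials, traits_raw, flagged = generate_cohort_logs(
        profiles, task_config, seed=cohort_config.seed + 1
    )
    included = {p.participant_id for p in flagged if not p.excluded}
    trials = trials[trials["participant_id"].isin(included)]
    traits_raw = traits_raw[traits_raw["participant_id"].isin(included)]
    split = split_cohort(trials)
    metrics = learner_metrics_table({pid: t for pid, (_tr, t) in split.items()})
    traits = score_traits(traits_raw)
    rows = []
    for pid, (train, test) in split.items():
        for phase in fit_phases:
            fit = fit_phase(train, test, "approach_avoid", phase, options)
            row = fit.to_row()
            row["participant_id"] = pid
            row["error"] = ""
            rows.append(row)
    return metrics, traits, pd.DataFrame(rows)


def headline_patterns(
    seed: int = 0,
    cohort_config: CohortConfig | None = None,
    task_config: TaskConfig | None = None,
    n_null_replicates: int = 10,
    options: FitOptions | None = None,
) -> HeadlineResult:
    """Recover the three group-level patterns from a default cohort.

    (i) approach learners score higher than avoidance learners on SR−SP
    (one-sided pooled t); (ii) the Group x habitual-learning-rate interaction
    is a crossover, approach learners showing relatively larger alpha_avoid;
    (iii) with group-identical generative training parameters, the Group x
    working-memory-rate interaction is null — checked over
    ``n_null_replicates`` fresh cohorts.
    """
    cohort_config = cohort_config or CohortConfig(seed=seed)
    task_config = task_config or TaskConfig()
    options = options or FitOptions(seed=seed)

    metrics, traits, fits = _cohort_tables(
        cohort_config, task_config, options, fit_phases=("test",)
    )
    result = group_stats(metrics, traits, fits)
    data = metrics.merge(traits, on="participant_id")
    app = data[data["learner_class"] == "approach"]["sr_minus_sp"]
    avd = data[data["learner_class"] == "avoidance"]["sr_minus_sp"]
    t_res = stats.ttest_ind(app, avd, equal_var=True)
    p_one = t_res.pvalue / 2 if t_res.statistic > 0 else 1 - t_res.pvalue / 2

    inter = result.interactions.set_index("interaction")
    hab = inter.loc["group x habitual rate"]
    # orientation: t on (alpha_approach - alpha_avoid), approach - avoidance
    # group; the crossover direction is approach learners having relatively
    # larger alpha_avoid, i.e. t < 0
    direction_ok = hab["t"] < 0

    wm_ps = []
    for r in range(n_null_replicates):
        cc = cohort_config.replace(seed=cohort_config.seed + 1000 + r)
        m_r, t_r, f_r = _cohort_tables(
            cc, task_config, options.replace(seed=options.seed + 1000 + r),
            fit_phases=("training",),
        )
        res_r = group_stats(m_r, t_r, f_r)
        inter_r = res_r.interactions.set_index("interaction")
        wm_ps.append(float(inter_r.loc["group x WM rate", "p"]))
        logger.info("headline: WM-null replicate %d/%d p=%.3f",
                    r + 1, n_null_replicates, wm_ps[-1])

    return HeadlineResult(
        n_included=len(data),
        n_approach=int((data["learner_class"] == "approach").sum()),
        n_avoidance=int((data["learner_class"] == "avoidance").sum()),
        srsp_t=float(t_res.statistic),
        srsp_p_one_sided=float(p_one),
        habitual_interaction_t=float(hab["t"]),
        habitual_interaction_p=float(hab["p"]),
        habitual_crossover_direction_ok=bool(direction_ok),
        wm_interaction_null_fraction=float(np.mean([p > 0.05 for p in wm_ps])),
        wm_interaction_ps=wm_ps,
    )


def mechanism_curve(
    alpha_grid: tuple[float, ...] = (0.05, 0.2, 0.35, 0.5, 0.65, 0.8),
    alpha_avoid: float = 0.1,
    beta: float = 0.25,
    n_agents: int = 500,
    n_blocks: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Test accuracy on the frequently rewarded symbol as a function of the
    positive-feedback learning rate.

    Under 80/20 probabilistic feedback a large learning rate chases the most
    recent outcomes and destabilises the value of the frequently rewarded A
    symbol, so select-A accuracy should fall as alpha_approach grows. Returns
    (per-cell table, Spearman rank correlation of cell-mean accuracy with
    alpha_approach across the grid).
    """
    config = _fixed_length_config(n_blocks)
    rows = []
    for cell, a_app in enumerate(alpha_grid):
        rng = np.random.default_rng(np.random.SeedSequence((seed, cell)))
        params = ModelParams.approach_avoid(a_app, alpha_avoid, beta)
        accs = np.empty(n_agents)
        for i in range(n_agents):
            log = simulate_agent(
                params, config, rng, participant_id=f"m{cell}_{i}",
                stop_at_criterion=False,
            )
            a_trials = [
                t for t in log.test if "A" in t.pair.symbols and t.responded
            ]
            accs[i] = np.mean([t.chosen == "A" for t in a_trials])
        rows.append(
            {
                "alpha_approach": a_app,
                "mean_select_a": float(accs.mean()),
                "sem_select_a": float(accs.std(ddof=1) / np.sqrt(n_agents)),
            }
        )
        logger.info("mechanism: alpha=%.2f select-A=%.3f", a_app, accs.mean())
    table = pd.DataFrame(rows)
    rho = float(
        stats.spearmanr(table["alpha_approach"], table["mean_select_a"]).statistic
    )
    return table, rho
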