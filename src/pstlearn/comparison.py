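"""Model comparison: AIC, pseudo-R² against the random-choice null, and
cohort-level selection between the one- and two-learning-rate models.

AIC = 2·NLL + 2k penalises the extra learning rate of the approach/avoid
model (k=3) relative to the canonical model (k=2). The parameter-free null
assumes equiprobable choice on every two-alternative trial, so its negative
log-likelihood is n·ln 2; pseudo-R² = 1 − NLL_fit / NLL_random measures the
proportional likelihood improvement over that null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "aic",
    "random_model_nll",
    "pseudo_r2",
    "ComparisonRow",
    "compare_cohort",
    "model_fit_summary",
]


def aic(nll: float, k: int) -> float:
    """Akaike information criterion from a negative log-likelihood."""
    if nll < 0:
        raise ValueError(f"negative log-likelihood must be >= 0, got {nll}")
    if k < 0:
        raise ValueError(f"parameter count must be >= 0, got {k}")
    return 2.0 * nll + 2.0 * k


def random_model_nll(n_scored_trials: int) -> float:
    """NLL of the equiprobable-choice null on two-alternative trials."""
    if n_scored_trials < 0:
        raise ValueError("trial count must be >= 0")
    return n_scored_trials * math.log(2.0)


def pseudo_r2(nll_fitted: float, nll_random: float) -> float:
    """Proportional likelihood improvement over the random-choice null."""
    if nll_random <= 0:
        raise ValueError("nll_random must be positive")
    return 1.0 - nll_fitted / nll_random


@dataclass(frozen=True)
class ComparisonRow:
    """Per-participant, per-phase comparison of the two model variants."""

    participant_id: str
    phase: str
    aic_canonical: float
    aic_approach_avoid: float
    pseudo_r2_canonical: float
    pseudo_r2_approach_avoid: float
    nll_random: float
    preferred: str

    @classmethod
    def from_fits(cls, canonical: pd.Series, approach_avoid: pd.Series) -> "ComparisonRow":
        preferred = (
            "canonical"
            if canonical["aic"] <= approach_avoid["aic"]
            else "approach_avoid"
        )
        return cls(
            participant_id=str(canonical["participant_id"]),
            phase=canonical["phase"],
            aic_canonical=canonical["aic"],
            aic_approach_avoid=approach_avoid["aic"],
            pseudo_r2_canonical=canonical["pseudo_r2"],
            pseudo_r2_approach_avoid=approach_avoid["pseudo_r2"],
            nll_random=random_model_nll(int(canonical["n_trials"])),
            preferred=preferred,
        )


def compare_cohort(fit_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair the two variants per participant x phase and test mean AIC.

    Returns (comparison table, per-phase paired t-test table with columns
    phase, t, df, p, mean_aic_canonical, mean_aic_approach_avoid). The paired
    two-sided t-test compares per-participant AICs across the cohort; the
    sign of ``t`` is (canonical − approach_avoid), so positive favours the
    two-rate model.
    """
    fits = fit_table
    if "error" in fits.columns:
        fits = fits[fits["error"].fillna("") == ""]
    rows = []
    tests = []
    for phase, grp in fits.groupby("phase", sort=True):
        can = grp[grp["variant"] == "canonical"].set_index("participant_id")
        av = grp[grp["variant"] == "approach_avoid"].set_index("participant_id")
        if set(can.index) != set(av.index) or can.index.has_duplicates:
            raise ValueError(
                f"phase {phase!r}: participants are not matched across variants"
            )
        av = av.loc[can.index]
        for pid in can.index:
            c = can.loc[pid].copy()
            c["participant_id"] = pid
            rows.append(ComparisonRow.from_fits(c, av.loc[pid]).__dict__)
        diff = can["aic"].to_numpy() - av["aic"].to_numpy()
        n = len(diff)
        if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(can["aic"], av["aic"])
        tests.append(
            {
                "phase": phase,
                "t": float(t_stat),
                "df": n - 1,
                "p": float(p),
                "mean_aic_canonical": float(can["aic"].mean()),
                "mean_aic_approach_avoid": float(av["aic"].mean()),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(tests)


def _mean_sem(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "-"
    sem = x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0
    return f"{x.mean():.3f}±{sem:.3f}"


def model_fit_summary(fit_table: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary of model fits: one row per phase x model (including the
    random-choice null), cells mean±SEM of −LL, AIC, pseudo-R² and the fitted
    parameters."""
    fits = fit_table
    if "error" in fits.columns:
        fits = fits[fits["error"].fillna("") == ""]
    rows = []
    phase_label = {"training": "working_memory", "test": "habitual"}
    for phase, grp in fits.groupby("phase", sort=True):
        nll_rand = grp.groupby("participant_id")["n_trials"].first().map(
            random_model_nll
        )
        rows.append(
            {
                "system": phase_label.get(phase, phase),
                "phase": phase,
                "model": "random_choice",
                "neg_ll": _mean_sem(nll_rand),
                "aic": _mean_sem(2.0 * nll_rand),
                "pseudo_r2": "-",
                "alpha": "-",
                "alpha_approach": "-",
                "alpha_avoid": "-",
                "beta": "-",
            }
        )
        for variant in ("canonical", "approach_avoid"):
            sub = grp[grp["variant"] == variant]
            if sub.empty:
                continue
            rows.append(
                {
                    "system": phase_label.get(phase, phase),
                    "phase": phase,
                    "model": variant,
                    "neg_ll": _mean_sem(sub["nll"]),
                    "aic": _mean_sem(sub["aic"]),
                    "pseudo_r2": _mean_sem(sub["pseudo_r2"]),
                    "alpha": _mean_sem(sub["alpha"]) if variant == "canonical" else "-",
                    "alpha_approach": (
                        _mean_sem(sub["alpha_approach"])
                        if variant == "approach_avoid"
                        else "-"
                    ),
                    "alpha_avoid": (
                        _mean_sem(sub["alpha_avoid"])
                        if variant == "approach_avoid"
                        else "-"
                    ),
                    "beta": _mean_sem(sub["beta"]),
                }
            )
    return pd.DataFrame(rows)
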