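"""Test-phase approach/avoidance metrics, learner classification, training
curves, trait scoring and the group-level statistics.

Approach learning is indexed by how often the most frequently rewarded symbol
(A) is selected in novel test pairs; avoidance learning by how often the most
frequently punished symbol (B) is rejected. Participants are classified as
approach learners when select-A strictly exceeds reject-B, otherwise as
avoidance learners.

The 2x2 Group x within-factor interactions are computed as an
independent-samples t-test on within-participant difference scores, which is
algebraically equivalent to the interaction of the classical mixed-design
ANOVA (F = t²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .task import TrialRecord

__all__ = [
    "A_PAIRS",
    "B_PAIRS",
    "LearnerMetrics",
    "TrainingCurve",
    "GroupStatsResult",
    "compute_learner_metrics",
    "learner_metrics_table",
    "interaction_test",
    "fit_training_curves",
    "score_traits",
    "group_stats",
]

A_PAIRS = frozenset({"AC", "AD", "AE", "AF"})
B_PAIRS = frozenset({"BC", "BD", "BE", "BF"})

#: training-curve slopes are reported at this cap when separation is detected
SLOPE_CAP = 5.0

#: raw trait columns expected by :func:`score_traits`
TRAIT_COLUMNS = ("drive", "fun_seeking", "reward_responsiveness", "bis", "sr", "sp")


@dataclass(frozen=True)
class LearnerMetrics:
    """Test-phase approach/avoidance performance of one participant."""

    participant_id: str
    select_a_rate: float
    reject_b_rate: float
    learner_class: str  # approach | avoidance

    @property
    def select_minus_reject(self) -> float:
        return self.select_a_rate - self.reject_b_rate


@dataclass(frozen=True)
class TrainingCurve:
    """Per-pair logistic learning curve: log-odds of a correct choice per
    within-pair trial."""

    participant_id: str
    pair: str
    slope: float
    intercept: float
    separated: bool = False


def compute_learner_metrics(
    test_trials: Sequence[TrialRecord], tie_class: str = "avoidance"
) -> LearnerMetrics:
    """Select-A and reject-B rates over responded novel test trials.

    Ties (equal rates) are classified ``tie_class`` (default avoidance: a
    participant must be strictly better at selecting A to count as an
    approach learner).
    """
    a_total = a_hit = b_total = b_hit = 0
    pid = "participant"
    for t in test_trials:
        if t.phase != "test" or not t.responded:
            continue
        pid = t.participant_id
        key = t.pair.key
        if key in A_PAIRS:
            a_total += 1
            a_hit += t.chosen == "A"
        elif key in B_PAIRS:
            b_total += 1
            b_hit += t.chosen != "B"
    if a_total == 0 or b_total == 0:
        raise ValueError("need responded trials with both A- and B-pairs")
    select_a = a_hit / a_total
    reject_b = b_hit / b_total
    learner = "approach" if select_a > reject_b else tie_class
    return LearnerMetrics(pid, select_a, reject_b, learner)


def learner_metrics_table(
    cohort: Mapping[str, Sequence[TrialRecord]], tie_class: str = "avoidance"
) -> pd.DataFrame:
    """Metrics for a mapping participant_id -> test trials."""
    rows = []
    for pid, trials in cohort.items():
        m = compute_learner_metrics(trials, tie_class)
        rows.append(
            {
                "participant_id": str(pid),
                "select_a_rate": m.select_a_rate,
                "reject_b_rate": m.reject_b_rate,
                "select_minus_reject": m.select_minus_reject,
                "learner_class": m.learner_class,
            }
        )
    return pd.DataFrame(rows)


def interaction_test(
    within_group1: np.ndarray,
    within_group2: np.ndarray,
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Group x within-factor interaction via difference scores.

    ``within_groupX`` are (n, 2) arrays of the two within-participant values.
    The interaction of the 2x2 mixed ANOVA equals the square of the
    independent-samples t on the per-participant differences; the pooled
    (classical-ANOVA) test is the default. Returns (t, df, p) with t oriented
    as group1 − group2 of the (value1 − value2) differences.
    """
    g1 = np.asarray(within_group1, dtype=float)
    g2 = np.asarray(within_group2, dtype=float)
    if g1.ndim != 2 or g1.shape[1] != 2 or g2.ndim != 2 or g2.shape[1] != 2:
        raise ValueError("expected (n, 2) arrays of within-participant values")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 participants")
    d1 = g1[:, 0] - g1[:, 1]
    d2 = g2[:, 0] - g2[:, 1]
    res = stats.ttest_ind(d1, d2, equal_var=equal_var)
    df = len(d1) + len(d2) - 2 if equal_var else float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


def fit_training_curves(
    training_trials: Sequence[TrialRecord], min_trials: int = 5
) -> list[TrainingCurve]:
    """Per-pair logistic regression of correct choice on within-pair trial
    number.

    "Correct" means choosing the higher-probability symbol (A, C or E).
    Complete separation is flagged and the slope reported at ±SLOPE_CAP.
    """
    pid = training_trials[0].participant_id if training_trials else "participant"
    by_pair: dict[str, list[TrialRecord]] = {}
    for t in training_trials:
        if t.phase == "training" and t.responded:
            by_pair.setdefault(t.pair.key, []).append(t)
    curves = []
    for pair, trials in sorted(by_pair.items()):
        if len(trials) < min_trials:
            raise ValueError(
                f"pair {pair}: {len(trials)} responded trials (need >= {min_trials})"
            )
        trials = sorted(trials, key=lambda t: t.trial_index)
        y = np.array([1.0 if t.chosen == pair[0] else 0.0 for t in trials])
        x = sm.add_constant(np.arange(len(trials), dtype=float))
        separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            intercept, slope = fit.params
            if not np.isfinite(slope) or abs(slope) > SLOPE_CAP or not fit.mle_retvals["converged"]:
                separated = True
        except Exception:  # perfect separation raises in some statsmodels versions
            separated = True
            intercept, slope = 0.0, 0.0
        if separated:
            direction = 1.0 if y[len(y) // 2 :].mean() >= y[: len(y) // 2].mean() else -1.0
            slope = direction * SLOPE_CAP
            intercept = float("nan")
        curves.append(TrainingCurve(pid, pair, float(slope), float(intercept), separated))
    return curves


def score_traits(raw: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Within-cohort z-scores of the questionnaire subscales.

    ``raw`` holds one row per participant with raw subscale sums
    (drive, fun_seeking, reward_responsiveness, bis, sr, sp). The BAS
    composite z-scores the sum of the Drive, Fun Seeking and Reward
    Responsiveness subscales; BIS, SR and SP are z-scored individually.
    Sample-SD (ddof=1) z-scores; z-scoring puts subscales with different item
    counts on a common scale.
    """
    if len(raw) < 2:
        raise ValueError("cohort must have at least 2 participants")
    missing = [c for c in TRAIT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing trait columns: {missing}")

    def z(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance in trait column {col.name!r}")
        return (col - col.mean()) / sd

    bas_sum = raw["drive"] + raw["fun_seeking"] + raw["reward_responsiveness"]
    out = pd.DataFrame(
        {
            "participant_id": raw["participant_id"].astype(str),
            "bas_z": z(bas_sum.rename("bas")),
            "bis_z": z(raw["bis"]),
            "sr_z": z(raw["sr"]),
            "sp_z": z(raw["sp"]),
        }
    )
    out["sr_minus_sp"] = out["sr_z"] - out["sp_z"]
    return out.reset_index(drop=True)


def _mean_sem(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "-"
    sem = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    return f"{x.mean():.3f}±{sem:.3f}"


def _between_t(a: pd.Series, b: pd.Series) -> dict:
    res = stats.ttest_ind(a.dropna(), b.dropna(), equal_var=True)
    return {
        "t": float(res.statistic),
        "df": len(a.dropna()) + len(b.dropna()) - 2,
        "p": float(res.pvalue),
    }


def _paired_t(a: pd.Series, b: pd.Series) -> dict:
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "df": len(a) - 1, "p": float(res.pvalue)}


@dataclass
class GroupStatsResult:
    """Bundle of the cohort-level statistics tables."""

    group_summary: pd.DataFrame
    param_summary: pd.DataFrame
    group_ttests: pd.DataFrame
    paired_ttests: pd.DataFrame
    interactions: pd.DataFrame
    spearman_rho: pd.DataFrame
    spearman_p: pd.DataFrame
    bonferroni_divisor: int = 105

    @property
    def spearman_significant(self) -> pd.DataFrame:
        """Boolean mask of correlations below the Bonferroni-corrected
        threshold 0.05 / divisor."""
        return self.spearman_p < (0.05 / self.bonferroni_divisor)

    def to_markdown(self) -> str:
        parts = [
            "## Selection rates and trait scores by learner group",
            self.group_summary.to_markdown(index=False),
            "\n## Fitted model parameters by learner group",
            self.param_summary.to_markdown(index=False),
            "\n## Between-group t-tests",
            self.group_ttests.to_markdown(index=False),
            "\n## Within-group paired t-tests",
            self.paired_ttests.to_markdown(index=False),
            "\n## Group x within-factor interactions (difference-score t)",
            self.interactions.to_markdown(index=False),
            "\n## Spearman correlation matrix",
            self.spearman_rho.round(2).to_markdown(),
            f"\nBonferroni-corrected threshold: 0.05/{self.bonferroni_divisor}"
            f" = {0.05 / self.bonferroni_divisor:.6f}",
        ]
        return "\n".join(parts)


def _merge_fit_params(frame: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Attach approach/avoid-model parameters per phase as wm_*/hab_* columns."""
    fits = fits[fits.get("error", pd.Series("", index=fits.index)).fillna("") == ""]
    av = fits[fits["variant"] == "approach_avoid"]
    prefix = {"training": "wm", "test": "hab"}
    for phase, grp in av.groupby("phase"):
        tag = prefix.get(phase, phase)
        cols = grp.set_index(grp["participant_id"].astype(str))[
            ["alpha_approach", "alpha_avoid", "beta"]
        ]
        cols.columns = [f"{tag}_{c}" for c in cols.columns]
        frame = frame.join(cols, on="participant_id")
    return frame


def group_stats(
    metrics: pd.DataFrame,
    traits: pd.DataFrame,
    fits: pd.DataFrame | None = None,
    bonferroni_divisor: int = 105,
) -> GroupStatsResult:
    """Cohort statistics: group summaries, between/within t-tests, the
    Group x within-factor interactions and the Spearman correlation matrix.

    ``metrics`` must carry learner_class/select_a_rate/reject_b_rate,
    ``traits`` the z-scored trait columns; ``fits`` is the fit_cohort table
    (approach/avoid rows are used). Participant IDs must align across tables.
    """
    m = metrics.copy()
    m["participant_id"] = m["participant_id"].astype(str)
    t = traits.copy()
    t["participant_id"] = t["participant_id"].astype(str)
    if set(m["participant_id"]) != set(t["participant_id"]):
        raise ValueError("participant IDs of metrics and traits do not align")
    data = m.merge(t, on="participant_id").set_index("participant_id")
    if fits is not None:
        data = _merge_fit_params(data, fits)
    app = data[data["learner_class"] == "approach"]
    avd = data[data["learner_class"] == "avoidance"]

    summary_vars = [
        "select_a_rate", "reject_b_rate", "bas_z", "bis_z", "sr_z", "sp_z",
    ]
    group_summary = pd.DataFrame(
        [
            {
                "measure": v,
                f"approach (n={len(app)})": _mean_sem(app[v]),
                f"avoidance (n={len(avd)})": _mean_sem(avd[v]),
            }
            for v in summary_vars
        ]
    )

    param_rows = []
    for tag, system in (("wm", "working_memory"), ("hab", "habitual")):
        for p in ("alpha_approach", "alpha_avoid", "beta"):
            col = f"{tag}_{p}"
            if col in data.columns:
                param_rows.append(
                    {
                        "system": system,
                        "parameter": p,
                        f"approach (n={len(app)})": _mean_sem(app[col]),
                        f"avoidance (n={len(avd)})": _mean_sem(avd[col]),
                    }
                )
    param_summary = pd.DataFrame(param_rows)

    between_vars = summary_vars + [
        c for c in data.columns if c.startswith(("wm_", "hab_"))
    ]
    group_ttests = pd.DataFrame(
        [
            {"measure": v, **_between_t(app[v], avd[v])}
            for v in between_vars
            if len(app[v].dropna()) >= 2 and len(avd[v].dropna()) >= 2
        ]
    )

    paired_rows = []
    for name, grp in (("approach", app), ("avoidance", avd)):
        if len(grp) >= 2:
            paired_rows.append(
                {"group": name, "comparison": "sr_z vs sp_z",
                 **_paired_t(grp["sr_z"], grp["sp_z"])}
            )
            for tag, system in (("wm", "working_memory"), ("hab", "habitual")):
                a, b = f"{tag}_alpha_approach", f"{tag}_alpha_avoid"
                if a in grp.columns and grp[a].notna().all():
                    paired_rows.append(
                        {"group": name,
                         "comparison": f"{system}: alpha_approach vs alpha_avoid",
                         **_paired_t(grp[a], grp[b])}
                    )
    paired_ttests = pd.DataFrame(paired_rows)

    inter_rows = []
    def _interaction(name: str, col1: str, col2: str) -> None:
        if col1 not in data.columns or col2 not in data.columns:
            return
        g1 = app[[col1, col2]].dropna().to_numpy()
        g2 = avd[[col1, col2]].dropna().to_numpy()
        if len(g1) < 2 or len(g2) < 2:
            return
        t_stat, df, p = interaction_test(g1, g2)
        inter_rows.append(
            {"interaction": name, "t": t_stat, "df": df, "p": p, "F": t_stat**2}
        )

    _interaction("group x symbol (select_a, reject_b)", "select_a_rate", "reject_b_rate")
    _interaction("group x SPSRQ (sr, sp)", "sr_z", "sp_z")
    _interaction("group x BIS/BAS (bis, bas)", "bis_z", "bas_z")
    _interaction("group x WM rate", "wm_alpha_approach", "wm_alpha_avoid")
    _interaction("group x habitual rate", "hab_alpha_approach", "hab_alpha_avoid")
    interactions = pd.DataFrame(inter_rows)

    corr_vars = {
        "select_a": data["select_a_rate"],
        "reject_b": data["reject_b_rate"],
        "select_a_minus_reject_b": data["select_a_rate"] - data["reject_b_rate"],
        "sr": data["sr_z"],
        "sp": data["sp_z"],
        "sr_minus_sp": data["sr_z"] - data["sp_z"],
    }
    for tag in ("wm", "hab"):
        a, b = f"{tag}_alpha_approach", f"{tag}_alpha_avoid"
        if a in data.columns:
            corr_vars[a] = data[a]
            corr_vars[b] = data[b]
            corr_vars[f"{tag}_alpha_diff"] = data[a] - data[b]
    if "wm_alpha_approach" in data.columns and "hab_alpha_approach" in data.columns:
        corr_vars["wm_minus_hab_alpha_approach"] = (
            data["wm_alpha_approach"] - data["hab_alpha_approach"]
        )
        corr_vars["wm_minus_hab_alpha_avoid"] = (
            data["wm_alpha_avoid"] - data["hab_alpha_avoid"]
        )
    corr = pd.DataFrame(corr_vars)
    names = list(corr.columns)
    k = len(names)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = corr.iloc[:, [i, j]].dropna()
            r, p = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    spearman_rho = pd.DataFrame(rho, index=names, columns=names)
    spearman_p = pd.DataFrame(pmat, index=names, columns=names)

    return GroupStatsResult(
        group_summary=group_summary,
        param_summary=param_summary,
        group_ttests=group_ttests,
        paired_ttests=paired_ttests,
        interactions=interactions,
        spearman_rho=spearman_rho,
        spearman_p=spearman_p,
        bonferroni_divisor=bonferroni_divisor,
    )
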