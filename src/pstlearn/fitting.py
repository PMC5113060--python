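"""Maximum-likelihood estimation of the choice model, per participant.

The central objects follow the Model/Results convention: a
:class:`QLearningModel` is built from one participant's trial log (optionally
via :meth:`QLearningModel.from_dataframe`), and :meth:`QLearningModel.fit`
returns a :class:`QLearningResults` carrying the estimates, fit statistics
and a ``summary()`` table.

Fitting minimises the phase-specific negative log-likelihood over bounded
parameters (learning rates in [0, 1], softmax temperature in [0.01, 10]) with
L-BFGS-B restarted from quasi-random (Halton) interior points — the
test-phase likelihood surface in particular can be multimodal, so a single
local search is not trusted. Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import _kernels
from .comparison import aic as _aic
from .comparison import pseudo_r2 as _pseudo_r2
from .comparison import random_model_nll
from .qlearning import ModelParams, encode_trials
from .task import TrialRecord

__all__ = [
    "FitOptions",
    "FitResult",
    "QLearningModel",
    "QLearningResults",
    "fit_phase",
    "fit_cohort",
]

logger = logging.getLogger(__name__)

ALPHA_BOUNDS = (0.0, 1.0)
BETA_BOUNDS = (0.01, 10.0)
MIN_SCORED_TRIALS = 10
#: a fitted parameter within this distance of a bound is flagged ``at_bound``
BOUND_TOL = 1e-6


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings shared across fits.

    ``n_starts`` local searches are launched from Halton points in the
    interior of the box; temperatures are started log-uniformly (typical
    fitted values are well below 1). ``tol`` is the convergence tolerance on
    the negative log-likelihood.
    """

    n_starts: int = 10
    seed: int = 0
    tol: float = 1e-6
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS
    beta_bounds: tuple[float, float] = BETA_BOUNDS
    q0: float = 0.5

    def replace(self, **changes) -> "FitOptions":
        return replace(self, **changes)


@dataclass
class FitResult:
    """Fitted parameters and fit statistics for one participant x phase x
    model variant."""

    participant_id: str
    phase: str
    variant: str
    params: ModelParams
    nll: float
    n_trials: int
    k: int
    aic: float
    pseudo_r2: float
    converged: bool
    n_starts: int
    at_bound: frozenset[str]

    def to_row(self) -> dict:
        p = self.params
        return {
            "participant_id": self.participant_id,
            "phase": self.phase,
            "variant": self.variant,
            "alpha_approach": p.alpha_approach,
            "alpha_avoid": p.alpha_avoid,
            "alpha": p.alpha,
            "beta": p.beta,
            "nll": self.nll,
            "n_trials": self.n_trials,
            "k": self.k,
            "aic": self.aic,
            "pseudo_r2": self.pseudo_r2,
            "converged": self.converged,
            "at_bound": ",".join(sorted(self.at_bound)),
        }


class QLearningModel:
    """Choice model for one participant's trial log.

    Parameters
    ----------
    train_trials : sequence of TrialRecord
        The participant's training phase, ordered by trial index.
    test_trials : sequence of TrialRecord, optional
        Required when ``phase='test'``: the likelihood then scores test
        choices on the end-of-training values implied by the candidate
        learning rates (the habitual-system read-out).
    variant : {'approach_avoid', 'canonical'}
        Two learning rates (k=3) or one (k=2).
    phase : {'training', 'test'}
        Which phase's choices enter the likelihood.
    """

    def __init__(
        self,
        train_trials: Sequence[TrialRecord],
        test_trials: Sequence[TrialRecord] | None = None,
        *,
        variant: str = "approach_avoid",
        phase: str = "training",
        q0: float = 0.5,
        participant_id: str | None = None,
    ) -> None:
        if variant not in ("canonical", "approach_avoid"):
            raise ValueError(f"unknown variant {variant!r}")
        if phase not in ("training", "test"):
            raise ValueError(f"unknown phase {phase!r}")
        if phase == "test" and test_trials is None:
            raise ValueError("test-phase fitting requires test trials")
        self.variant = variant
        self.phase = phase
        self.q0 = q0
        self.train_trials = list(train_trials)
        self.test_trials = list(test_trials) if test_trials is not None else None
        if participant_id is None and self.train_trials:
            participant_id = self.train_trials[0].participant_id
        self.participant_id = participant_id or "participant"

        self._ch_tr, self._ot_tr, self._out_tr = encode_trials(self.train_trials)
        if np.any(self._out_tr < 0):
            raise ValueError("training trials must all carry outcomes")
        if self.test_trials is not None:
            responded = [t for t in self.test_trials if t.responded]
            self._ch_te, self._ot_te, _ = encode_trials(responded)
        else:
            self._ch_te = self._ot_te = None

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        participant_id: str | None = None,
        **kwargs,
    ) -> "QLearningModel":
        """Build from a trial-log DataFrame (the CSV dialect of
        :mod:`pstlearn.io`), optionally selecting one participant."""
        from .io import frame_to_records

        if participant_id is not None:
            frame = frame[frame["participant_id"].astype(str) == str(participant_id)]
        records = frame_to_records(frame)
        train = [t for t in records if t.phase == "training"]
        test = [t for t in records if t.phase == "test"] or None
        return cls(train, test, participant_id=participant_id, **kwargs)

    @property
    def k(self) -> int:
        return 2 if self.variant == "canonical" else 3

    @property
    def n_scored(self) -> int:
        """Number of trials entering the likelihood."""
        if self.phase == "training":
            return len(self._ch_tr)
        return len(self._ch_te)

    def _rates(self, theta: np.ndarray) -> tuple[float, float]:
        if self.variant == "canonical":
            return theta[0], theta[0]
        return theta[0], theta[1]

    def nll(self, theta: np.ndarray) -> float:
        """Phase negative log-likelihood at parameter vector ``theta``
        (``[alpha, beta]`` canonical, ``[alpha_approach, alpha_avoid, beta]``
        otherwise)."""
        a_app, a_av = self._rates(theta)
        beta = theta[-1]
        nll_tr, q_final, _, _ = _kernels.replay_kernel(
            self._ch_tr, self._ot_tr, self._out_tr, a_app, a_av, beta, self.q0
        )
        if self.phase == "training":
            return float(nll_tr)
        nll_te, _, _ = _kernels.test_nll_kernel(
            q_final, self._ch_te, self._ot_te, beta
        )
        return float(nll_te)

    def loglike(self, theta: np.ndarray) -> float:
        return -self.nll(theta)

    def _start_points(self, options: FitOptions) -> np.ndarray:
        sampler = qmc.Halton(d=self.k, seed=options.seed)
        u = sampler.random(options.n_starts)
        starts = np.empty_like(u)
        a_lo, a_hi = options.alpha_bounds
        span = a_hi - a_lo
        starts[:, :-1] = a_lo + span * (0.02 + 0.96 * u[:, :-1])
        # temperatures log-uniform over the empirically plausible range
        b_lo = max(options.beta_bounds[0] * 2.0, 0.02)
        b_hi = min(options.beta_bounds[1] / 2.0, 2.0)
        starts[:, -1] = np.exp(
            np.log(b_lo) + u[:, -1] * (np.log(b_hi) - np.log(b_lo))
        )
        return starts

    def fit(self, options: FitOptions | None = None, **changes) -> "QLearningResults":
        """Multistart bounded maximum-likelihood fit.

        Raises ``ValueError('insufficient data')`` with fewer than 10 scored
        trials. All-identical choices are legal and typically pin a parameter
        at a bound, flagged in ``at_bound``.
        """
        options = (options or FitOptions()).replace(**changes)
        if self.n_scored < MIN_SCORED_TRIALS:
            raise ValueError(
                f"insufficient data: {self.n_scored} scored trials "
                f"(need >= {MIN_SCORED_TRIALS})"
            )
        bounds = [options.alpha_bounds] * (self.k - 1) + [options.beta_bounds]
        best = None
        best_converged = False
        for x0 in self._start_points(options):
            res = optimize.minimize(
                self.nll,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": options.tol * 1e-3, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 0.0:
                best = res
                best_converged = bool(res.success)
            elif abs(res.fun - best.fun) <= options.tol:
                best_converged = best_converged or bool(res.success)
        theta = best.x
        at_bound = set()
        names = (
            ["alpha"] if self.variant == "canonical" else ["alpha_approach", "alpha_avoid"]
        ) + ["beta"]
        for name, value, (lo, hi) in zip(names, theta, bounds):
            if value - lo <= BOUND_TOL or hi - value <= BOUND_TOL:
                at_bound.add(name)
        if self.variant == "canonical":
            params = ModelParams.canonical(alpha=theta[0], beta=theta[1])
        else:
            params = ModelParams.approach_avoid(
                alpha_approach=theta[0], alpha_avoid=theta[1], beta=theta[2]
            )
        return QLearningResults(
            model=self,
            params=params,
            nll=float(best.fun),
            converged=best_converged,
            n_starts=options.n_starts,
            at_bound=frozenset(at_bound),
        )


class QLearningResults:
    """Results of a :class:`QLearningModel` fit."""

    def __init__(
        self,
        model: QLearningModel,
        params: ModelParams,
        nll: float,
        converged: bool,
        n_starts: int,
        at_bound: frozenset[str],
    ) -> None:
        self.model = model
        self.params = params
        self.nll = nll
        self.converged = converged
        self.n_starts = n_starts
        self.at_bound = at_bound

    @property
    def n_trials(self) -> int:
        return self.model.n_scored

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def aic(self) -> float:
        return _aic(self.nll, self.k)

    @property
    def nll_random(self) -> float:
        return random_model_nll(self.n_trials)

    @property
    def pseudo_r2(self) -> float:
        return _pseudo_r2(self.nll, self.nll_random)

    def as_fit_result(self) -> FitResult:
        return FitResult(
            participant_id=self.model.participant_id,
            phase=self.model.phase,
            variant=self.model.variant,
            params=self.params,
            nll=self.nll,
            n_trials=self.n_trials,
            k=self.k,
            aic=self.aic,
            pseudo_r2=self.pseudo_r2,
            converged=self.converged,
            n_starts=self.n_starts,
            at_bound=self.at_bound,
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Q-learning maximum-likelihood fit",
            "=" * 44,
            f"participant:     {self.model.participant_id}",
            f"phase:           {self.model.phase}",
            f"variant:         {self.model.variant} (k={self.k})",
            f"scored trials:   {self.n_trials}",
            "-" * 44,
        ]
        if p.variant == "canonical":
            lines.append(f"alpha            {p.alpha:10.4f}")
        else:
            lines.append(f"alpha_approach   {p.alpha_approach:10.4f}")
            lines.append(f"alpha_avoid      {p.alpha_avoid:10.4f}")
        lines += [
            f"beta             {p.beta:10.4f}",
            "-" * 44,
            f"-LL              {self.nll:10.3f}",
            f"AIC              {self.aic:10.3f}",
            f"pseudo-R2        {self.pseudo_r2:10.3f}",
            f"random-model -LL {self.nll_random:10.3f}",
            f"converged:       {self.converged}   starts: {self.n_starts}",
        ]
        if self.at_bound:
            lines.append(f"at bound:        {', '.join(sorted(self.at_bound))}")
        return "\n".join(lines)

    def plot_fit(self, ax=None, bins: int = 10):
        """Diagnostic plot: binned observed accuracy on trained pairs over
        training against the model-implied choice probability."""
        import matplotlib.pyplot as plt

        from .qlearning import replay_training

        trials = self.model.train_trials
        state_probs = replay_training(trials, self.params, self.model.q0)[1]
        correct = np.array(
            [1.0 if t.chosen in ("A", "C", "E") else 0.0 for t in trials]
        )
        p_correct = np.array(
            [
                sp if t.chosen in ("A", "C", "E") else 1.0 - sp
                for t, sp in zip(trials, state_probs)
            ]
        )
        edges = np.linspace(0, len(trials), bins + 1).astype(int)
        centers, obs, pred = [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                centers.append((lo + hi) / 2)
                obs.append(correct[lo:hi].mean())
                pred.append(p_correct[lo:hi].mean())
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(centers, pred, "-", label="model")
        ax.plot(centers, obs, "o", label="observed")
        ax.set_xlabel("training trial")
        ax.set_ylabel("p(correct)")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax


def _substream_seed(seed: int, *parts: str) -> int:
    """Deterministic per-fit seed from the cohort seed and fit coordinates."""
    digest = hashlib.sha256(
        ("|".join([str(seed), *parts])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def fit_phase(
    trials_train: Sequence[TrialRecord],
    trials_test: Sequence[TrialRecord] | None,
    variant: str,
    phase: str,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one participant x phase x variant; see :class:`QLearningModel`."""
    options = options or FitOptions()
    model = QLearningModel(
        trials_train,
        trials_test,
        variant=variant,
        phase=phase,
        q0=options.q0,
    )
    return model.fit(options).as_fit_result()


def fit_cohort(
    cohort: Mapping[str, tuple[Sequence[TrialRecord], Sequence[TrialRecord]]]
    | pd.DataFrame,
    variants: Iterable[str] = ("canonical", "approach_avoid"),
    phases: Iterable[str] = ("training", "test"),
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Fit every participant x variant x phase combination.

    ``cohort`` is either a trial-log DataFrame (split by participant_id) or a
    mapping ``participant_id -> (train_trials, test_trials)``. Per-fit
    failures are recorded in the ``error`` column and never abort the batch.
    Per-fit seeds are derived deterministically from
    ``(options.seed, participant_id, variant, phase)``.
    """
    options = options or FitOptions()
    if isinstance(cohort, pd.DataFrame):
        from .io import split_cohort

        cohort = split_cohort(cohort)
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for pid, (train, test) in cohort.items():
        for variant in variants:
            for phase in phases:
                t0 = time.perf_counter()
                sub = options.replace(
                    seed=_substream_seed(options.seed, str(pid), variant, phase)
                )
                try:
                    result = fit_phase(train, test, variant, phase, sub)
                    row = result.to_row()
                    row["participant_id"] = str(pid)
                    row["error"] = ""
                except Exception as exc:  # noqa: BLE001 - isolation contract
                    row = {
                        "participant_id": str(pid),
                        "phase": phase,
                        "variant": variant,
                        "error": str(exc),
                    }
                rows.append(row)
                logger.info(
                    "fit %s/%s/%s in %.2fs", pid, variant, phase,
                    time.perf_counter() - t0,
                )
    return pd.DataFrame(rows)
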