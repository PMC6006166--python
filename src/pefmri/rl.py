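"""Q-learning (Rescorla-Wagner) agent: simulation, prediction errors, ML fitting.

The model maintains one value per stimulus per pair and updates only the
chosen stimulus after each outcome:

    delta_t = r_t - Q(chosen)          (reward prediction error)
    Q(chosen) <- Q(chosen) + alpha * delta_t

Choices follow a softmax (logistic in the value difference) with inverse
temperature beta.  Neutral feedback carries r = 0 in every pair type; only
monetary value enters the update.  Fitting is bounded maximum likelihood on
the choice sequence with multiple random restarts of a gradient-free local
optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .task import PAIR_TYPES, TaskSchedule, sample_outcome

__all__ = [
    "QParams",
    "SubjectBehaviour",
    "FitResult",
    "update_q",
    "choice_prob",
    "simulate_agent",
    "negative_log_likelihood",
    "fit_q_model",
    "pe_series",
]

DEFAULT_BOUNDS = ((0.001, 0.999), (0.01, 20.0))  # (alpha, beta)


@dataclass(frozen=True)
class QParams:
    """Parameters of the Q-learning agent.

    alpha : learning rate in [0, 1]
    beta  : softmax inverse temperature >= 0 (0 = random choice)
    q0    : initial action value for every stimulus
    """

    alpha: float
    beta: float
    q0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass
class SubjectBehaviour:
    """Per-trial record of one subject: choices, outcomes, RTs and PEs.

    ``choices`` codes the chosen stimulus within the pair (0 = designated
    correct/high-probability stimulus, 1 = the other).  ``deltas`` holds the
    prediction error experienced at each outcome.
    """

    schedule: TaskSchedule
    choices: np.ndarray
    outcome_values: np.ndarray
    feedback_kinds: list[str]
    rts: np.ndarray
    deltas: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.schedule)
        for name in ("choices", "outcome_values", "feedback_kinds", "rts", "deltas"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != schedule length ({n})")
        if not np.all(np.isfinite(self.deltas)):
            raise ValueError("prediction errors must be finite")

    @property
    def n_trials(self) -> int:
        return len(self.schedule)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.schedule.trials],
                "pair_type": [t.pair_type for t in self.schedule.trials],
                "choice": self.choices,
                "outcome_value": self.outcome_values,
                "feedback_kind": self.feedback_kinds,
                "rt_ms": self.rts,
                "delta": self.deltas,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FitResult:
    params: QParams
    nll: float
    converged: bool
    n_restarts_used: int


def update_q(q: float, outcome_value: float, alpha: float) -> tuple[float, float]:
    """One Rescorla-Wagner update; returns (delta, q_new)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    delta = outcome_value - q
    return delta, q + alpha * delta


def choice_prob(q_chosen: float, q_other: float, beta: float) -> float:
    """Softmax probability of the chosen stimulus; overflow-safe."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return float(expit(beta * (np.asarray(q_chosen) - np.asarray(q_other))))


def simulate_agent(
    params: QParams, schedule: TaskSchedule, rng: np.random.Generator
) -> SubjectBehaviour:
    """Simulate one agent through a schedule.

    Value tables are maintained independently per pair type; the unchosen
    stimulus is never updated.  RTs are filled with NaN (see
    :func:`pefmri.cohort.generate_rts` for the response-time model).
    """
    q = {pt: np.full(2, params.q0, dtype=float) for pt in PAIR_TYPES}
    n = len(schedule)
    choices = np.empty(n, dtype=int)
    values = np.empty(n, dtype=float)
    kinds: list[str] = []
    deltas = np.empty(n, dtype=float)
    for i, trial in enumerate(schedule.trials):
        qt = q[trial.pair_type]
        p_high = expit(params.beta * (qt[0] - qt[1]))
        c = 0 if rng.random() < p_high else 1
        outcome = sample_outcome(trial, chose_high=(c == 0), rng=rng)
        delta, qt[c] = update_q(qt[c], outcome.value, params.alpha)
        choices[i] = c
        values[i] = outcome.value
        kinds.append(outcome.feedback_kind)
        deltas[i] = delta
    return SubjectBehaviour(
        schedule=schedule,
        choices=choices,
        outcome_values=values,
        feedback_kinds=kinds,
        rts=np.full(n, np.nan),
        deltas=deltas,
    )


def _replay(
    pair_types: np.ndarray,
    choices: np.ndarray,
    outcome_values: np.ndarray,
    alpha: float,
    beta: float,
    q0: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Replay a choice/outcome sequence under (alpha, beta).

    Returns (negative log-likelihood of the choices, per-trial deltas).
    """
    q = {pt: [q0, q0] for pt in PAIR_TYPES}
    nll = 0.0
    deltas = np.empty(len(choices), dtype=float)
    for i in range(len(choices)):
        qt = q[pair_types[i]]
        c = choices[i]
        diff = qt[c] - qt[1 - c]
        nll -= log_expit(beta * diff)
        delta = outcome_values[i] - qt[c]
        qt[c] += alpha * delta
        deltas[i] = delta
    return float(nll), deltas


def negative_log_likelihood(behaviour: SubjectBehaviour, params: QParams) -> float:
    """Choice NLL of the data under the given parameters."""
    nll, _ = _replay(
        behaviour.schedule.pair_types,
        behaviour.choices,
        behaviour.outcome_values,
        params.alpha,
        params.beta,
        params.q0,
    )
    return nll


def pe_series(behaviour: SubjectBehaviour, params: QParams) -> np.ndarray:
    """Trial-wise prediction errors from replaying the subject's choices.

    This is the model-based regressor path: the fitted (or known) parameters
    are applied to the observed choice/outcome sequence and the resulting
    delta_t, aligned to outcome onsets, serve as a parametric modulator.
    """
    if len(behaviour.choices) != len(behaviour.schedule):
        raise ValueError("choice sequence length does not match schedule")
    _, deltas = _replay(
        behaviour.schedule.pair_types,
        behaviour.choices,
        behaviour.outcome_values,
        params.alpha,
        params.beta,
        params.q0,
    )
    return deltas


def fit_q_model(
    behaviour: SubjectBehaviour,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Bounded maximum-likelihood fit of (alpha, beta) to the choice data.

    Uses Nelder-Mead with box bounds from ``n_restarts`` random starting
    points (plus one start at the centre of the box).  Ties between restarts
    are broken by lowest NLL, then lowest beta.  A fit that lands on the
    boundary of the box is flagged ``converged=False``.
    """
    if behaviour.n_trials < 1:
        raise ValueError("need at least one trial to fit")
    pair_types = behaviour.schedule.pair_types
    choices = np.asarray(behaviour.choices)
    values = np.asarray(behaviour.outcome_values, dtype=float)
    (a_lo, a_hi), (b_lo, b_hi) = bounds

    def objective(x: np.ndarray) -> float:
        a = float(np.clip(x[0], a_lo, a_hi))
        b = float(np.clip(x[1], b_lo, b_hi))
        nll, _ = _replay(pair_types, choices, values, a, b)
        return nll

    rng = np.random.default_rng(seed)
    starts = [np.array([(a_lo + a_hi) / 2, (b_lo + b_hi) / 2])]
    for _ in range(n_restarts):
        starts.append(
            np.array([rng.uniform(a_lo, a_hi), np.exp(rng.uniform(np.log(b_lo), np.log(b_hi)))])
        )

    best: tuple[float, float, np.ndarray] | None = None  # (nll, beta, x)
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                bounds=[(a_lo, a_hi), (b_lo, b_hi)],
                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000},
            )
        x = np.clip(res.x, [a_lo, b_lo], [a_hi, b_hi])
        key = (res.fun, x[1])
        if best is None or key < (best[0], best[1]):
            best = (float(res.fun), float(x[1]), x)

    assert best is not None
    nll, _, x = best
    on_boundary = bool(
        np.isclose(x[0], a_lo) or np.isclose(x[0], a_hi)
        or np.isclose(x[1], b_lo) or np.isclose(x[1], b_hi)
    )
    return FitResult(
        params=QParams(alpha=float(x[0]), beta=float(x[1])),
        nll=nll,
        converged=not on_boundary,
        n_restarts_used=len(starts),
    )
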