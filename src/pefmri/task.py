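"""Probabilistic monetary learning task: schedule generation and outcome sampling.

The task presents three pairs of abstract stimuli, each pair shown
``n_per_pair`` times (30 by default, 90 trials total).  The
stimuli within a pair differ in their outcome contingencies:

* **reward** pair — the high-probability stimulus wins £1 on 80% of choices
  (neutral feedback otherwise); the low-probability stimulus wins on 20%.
* **bivalent** pair — either stimulus wins £1 or loses £1 with probability
  0.5 each, so wins are maximally unpredictable.
* **neutral** pair — no money changes hands; the high-probability stimulus
  shows neutral feedback kind A on 80% of choices (kind B otherwise), the
  other stimulus shows kind A on 20%.

Within each pair, stimulus 0 is the designated "correct" stimulus: the
high-probability winner for reward pairs, the kind-A-dominant stimulus for
neutral pairs, and an arbitrary fixed designation for bivalent pairs (where
contingencies are identical for both stimuli and "correctness" only serves
the behavioural preference analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PAIR_TYPES",
    "Outcome",
    "TrialSpec",
    "TaskSchedule",
    "generate_schedule",
    "sample_outcome",
]

PAIR_TYPES = ("reward", "bivalent", "neutral")

#: Maximum run length of a single pair type allowed by the pseudo-randomiser.
MAX_RUN_LENGTH = 4

#: Probability that the designated high-probability stimulus delivers its
#: frequent outcome (win for reward pairs, feedback kind A for neutral pairs).
HIGH_PROB = 0.8

FEEDBACK_KINDS = ("win", "loss", "neutral_A", "neutral_B")


@dataclass(frozen=True)
class Outcome:
    """Feedback delivered at the end of a trial.

    ``value`` is the monetary payoff in pounds (+1, 0 or -1) and is the
    quantity that enters value learning; ``feedback_kind`` distinguishes the
    two visually distinct neutral feedback screens used by neutral pairs.
    """

    value: int
    feedback_kind: str

    def __post_init__(self) -> None:
        if self.feedback_kind not in FEEDBACK_KINDS:
            raise ValueError(f"unknown feedback kind {self.feedback_kind!r}")
        expected = {"win": 1, "loss": -1, "neutral_A": 0, "neutral_B": 0}[self.feedback_kind]
        if self.value != expected:
            raise ValueError(
                f"outcome value {self.value} inconsistent with kind {self.feedback_kind!r}"
            )


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the schedule.

    ``high_prob_side`` records which screen side the designated correct
    stimulus was displayed on (counterbalanced exactly within pair type).
    """

    index: int  # 1-based position in the schedule
    pair_type: str
    high_prob_side: str  # 'left' | 'right'

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"unknown pair type {self.pair_type!r}")
        if self.high_prob_side not in ("left", "right"):
            raise ValueError(f"high_prob_side must be 'left' or 'right'")

    def contingency(self, chose_high: bool) -> list[tuple[Outcome, float]]:
        """Outcome distribution for choosing the high- or low-probability stimulus."""
        p = HIGH_PROB if chose_high else 1.0 - HIGH_PROB
        if self.pair_type == "reward":
            return [(Outcome(1, "win"), p), (Outcome(0, "neutral_A"), 1.0 - p)]
        if self.pair_type == "bivalent":
            return [(Outcome(1, "win"), 0.5), (Outcome(-1, "loss"), 0.5)]
        # neutral: two neutral feedback kinds, no monetary value
        return [(Outcome(0, "neutral_A"), p), (Outcome(0, "neutral_B"), 1.0 - p)]


@dataclass
class TaskSchedule:
    """Pseudo-randomised trial sequence for one subject."""

    trials: list[TrialSpec]
    n_per_pair: int
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def pair_types(self) -> np.ndarray:
        return np.array([t.pair_type for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a BIDS-events-like table, one row per trial."""
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "pair_type": [t.pair_type for t in self.trials],
                "high_prob_side": [t.high_prob_side for t in self.trials],
                "correct_stimulus": 0,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_per_pair: int | None = None, seed: int = -1) -> "TaskSchedule":
        df = pd.read_csv(path, sep="\t")
        trials = [
            TrialSpec(int(r.trial), str(r.pair_type), str(r.high_prob_side))
            for r in df.itertuples()
        ]
        if n_per_pair is None:
            n_per_pair = len(trials) // len(PAIR_TYPES)
        return cls(trials=trials, n_per_pair=n_per_pair, seed=seed)


def _run_lengths_ok(types: np.ndarray, max_run: int = MAX_RUN_LENGTH) -> bool:
    run = 1
    for a, b in zip(types[:-1], types[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return False
    return True


def _constrained_order(rng: np.random.Generator, n_per_pair: int) -> list[str]:
    """Random trial-type order with bounded run lengths.

    Draws the next pair type proportionally to its remaining count, never
    extending a run beyond MAX_RUN_LENGTH; rare dead ends (all remaining
    trials belong to the running type) restart the draw.
    """
    for _ in range(1000):
        remaining = {pt: n_per_pair for pt in PAIR_TYPES}
        order: list[str] = []
        run_type, run_len = None, 0
        while any(remaining.values()):
            avail = [
                pt
                for pt in PAIR_TYPES
                if remaining[pt] > 0 and not (pt == run_type and run_len >= MAX_RUN_LENGTH)
            ]
            if not avail:
                break
            weights = np.array([remaining[pt] for pt in avail], dtype=float)
            pt = avail[rng.choice(len(avail), p=weights / weights.sum())]
            order.append(pt)
            remaining[pt] -= 1
            run_len = run_len + 1 if pt == run_type else 1
            run_type = pt
        if len(order) == 3 * n_per_pair:
            return order
    raise RuntimeError("could not build a run-length-constrained order")


def generate_schedule(n_per_pair: int, seed: int) -> TaskSchedule:
    """Generate a reproducible pseudo-randomised schedule.

    Each pair type appears exactly ``n_per_pair`` times.  The trial order is a
    uniform shuffle subject to a run-length constraint (no more than
    ``MAX_RUN_LENGTH`` consecutive trials of one pair type), and the side of
    the high-probability stimulus is counterbalanced exactly (half left, half
    right) within each pair type, which requires ``n_per_pair`` to be even.
    """
    if not isinstance(n_per_pair, (int, np.integer)):
        raise ValueError("n_per_pair must be an integer")
    if n_per_pair <= 0 or n_per_pair % 2 != 0:
        raise ValueError(f"n_per_pair must be positive and even, got {n_per_pair}")

    rng = np.random.default_rng(seed)
    order = _constrained_order(rng, int(n_per_pair))

    # exact left/right counterbalancing within each pair type
    half = n_per_pair // 2
    sides: dict[str, list[str]] = {}
    for pt in PAIR_TYPES:
        s = np.array(["left"] * half + ["right"] * half)
        sides[pt] = list(rng.permutation(s))

    trials = []
    counters = {pt: 0 for pt in PAIR_TYPES}
    for i, pt in enumerate(order, start=1):
        side = sides[pt][counters[pt]]
        counters[pt] += 1
        trials.append(TrialSpec(index=i, pair_type=str(pt), high_prob_side=side))
    return TaskSchedule(trials=trials, n_per_pair=int(n_per_pair), seed=int(seed))


def sample_outcome(trial: TrialSpec, chose_high: bool, rng: np.random.Generator) -> Outcome:
    """Draw one outcome from the trial's contingency for the chosen stimulus."""
    dist = trial.contingency(bool(chose_high))
    u = rng.random()
    acc = 0.0
    for outcome, p in dist:
        acc += p
        if u < acc:
            return outcome
    return dist[-1][0]  # guard against floating-point shortfall
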