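"""Scoring of inclusion-exclusion (process-dissociation) generation runs.

After ASRT training, participants generate sequences on the same four
keys: first reproducing the practiced stream (inclusion), then producing
sequences unlike it (exclusion).  Each run is 24 presses — three rounds
of the eight-element alternation — and is scored by the percentage of
its 22 overlapping triplets that are high-probability under the trained
pattern cycle.  Because exactly one of the four continuations of any
two-press context is the pattern successor, chance level is 25%.
Above-chance production under exclusion indicates knowledge the
participant cannot consciously withhold, i.e. implicit knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sequence import PatternCycle, make_cycle, classify_triplet, HIGH, NEITHER
from .stats import jzs_bf_one_sample, BayesResult

__all__ = [
    "RUN_LENGTH",
    "GenerationRun",
    "score_run",
    "score_presses",
    "score_streams",
    "participant_generation_scores",
    "chance_level",
    "compare_to_chance",
    "runs_from_frame",
]

#: presses per run: three rounds of the eight-element alternating sequence
RUN_LENGTH = 24
CONDITIONS = ("inclusion", "exclusion")
DEFAULT_RUNS_PER_CONDITION = 4


@dataclass(frozen=True)
class GenerationRun:
    """One generation run: 24 ordered presses under one condition."""

    condition: str
    presses: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if len(self.presses) != RUN_LENGTH:
            raise ValueError(
                f"a run has exactly {RUN_LENGTH} presses, got {len(self.presses)}"
            )
        if any(not 1 <= p <= 4 for p in self.presses):
            raise ValueError("presses must be positions in 1..4")


def score_presses(
    presses, cycle: PatternCycle, exclude_trills_reps: bool = False
) -> float:
    """Percentage of high-probability triplets among a press stream.

    Triplet windows overlap and are confined to the stream (a 24-press
    run yields 22).  Trills and repetitions count toward the denominator
    by default; ``exclude_trills_reps`` switches on the variant that
    drops them (they are always low-probability, so only the denominator
    changes).
    """
    cycle = make_cycle(cycle)
    presses = tuple(int(p) for p in presses)
    if len(presses) < 3:
        raise ValueError("need at least 3 presses to form a triplet")
    n_high = n_scorable = 0
    for first, middle, third in zip(presses, presses[1:], presses[2:]):
        label, category = classify_triplet(first, middle, third, cycle)
        if exclude_trills_reps and category != NEITHER:
            continue
        n_scorable += 1
        n_high += label == HIGH
    if n_scorable == 0:
        return float("nan")
    return 100.0 * n_high / n_scorable


def score_streams(presses: np.ndarray, cycle: PatternCycle) -> np.ndarray:
    """Vectorised pct_high for many equal-length press streams.

    ``presses`` is an (n_streams, n_presses) integer array of positions;
    returns the percentage of high-probability triplets per stream.
    Used for Monte-Carlo work where per-run scoring would be slow.
    """
    cycle = make_cycle(cycle)
    presses = np.asarray(presses)
    succ = cycle.successor_array
    high = succ[presses[:, :-2]] == presses[:, 2:]
    return 100.0 * high.mean(axis=1)


def score_run(
    run: GenerationRun, cycle: PatternCycle, exclude_trills_reps: bool = False
) -> float:
    """Score one validated 24-press run (see :func:`score_presses`)."""
    return score_presses(run.presses, cycle, exclude_trills_reps)


def participant_generation_scores(
    runs: list[GenerationRun],
    cycle: PatternCycle,
    runs_per_condition: int = DEFAULT_RUNS_PER_CONDITION,
    exclude_trills_reps: bool = False,
) -> dict[str, float]:
    """Mean high-probability percentage per condition for one participant.

    Expects exactly ``runs_per_condition`` runs in each condition; with
    equal-length runs the mean of run percentages equals the pooled
    percentage over all triplets.
    """
    out = {}
    for condition in CONDITIONS:
        sel = [r for r in runs if r.condition == condition]
        if len(sel) != runs_per_condition:
            raise ValueError(
                f"expected {runs_per_condition} {condition} runs, got {len(sel)}"
            )
        out[condition] = float(np.mean([score_run(r, cycle, exclude_trills_reps)
                                        for r in sel]))
    return out


def chance_level(cycle: PatternCycle) -> float:
    """Chance percentage of high-probability continuations, by enumeration.

    For every ordered two-press context exactly one of the four possible
    continuations is the pattern successor of the first press, so the
    chance level is 25% in every context, not merely on average.
    """
    cycle = make_cycle(cycle)
    rates = []
    for first in range(1, 5):
        for middle in range(1, 5):
            n_high = sum(
                classify_triplet(first, middle, third, cycle)[0] == HIGH
                for third in range(1, 5)
            )
            rates.append(n_high / 4)
    return 100.0 * float(np.mean(rates))


@dataclass(frozen=True)
class ChanceComparison:
    condition: str
    n: int
    mean: float
    t: float
    df: int
    p: float
    bayes: BayesResult


def compare_to_chance(
    scores, condition: str = "inclusion", chance: float = 25.0, r: float = 1.0
) -> ChanceComparison:
    """One-sample t-test of participant means against chance, with BF01."""
    x = np.asarray(scores, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 participants")
    if np.std(x, ddof=1) == 0:
        raise ValueError("degenerate (zero-variance) scores")
    t, p = sps.ttest_1samp(x, chance)
    bayes = jzs_bf_one_sample(float(t), len(x), r=r)
    return ChanceComparison(
        condition=condition, n=len(x), mean=float(np.mean(x)),
        t=float(t), df=len(x) - 1, p=float(p), bayes=bayes,
    )


def runs_from_frame(frame: pd.DataFrame) -> dict[str, list[GenerationRun]]:
    """Parse a tidy frame (participant, condition, run, press_index,
    position) into per-participant run lists."""
    out: dict[str, list[GenerationRun]] = {}
    for (participant, condition, _run), g in frame.groupby(
        ["participant", "condition", "run"], observed=True
    ):
        presses = tuple(g.sort_values("press_index")["position"].astype(int))
        out.setdefault(participant, []).append(GenerationRun(condition, presses))
    return out
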