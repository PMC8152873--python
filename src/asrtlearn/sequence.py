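"""ASRT stimulus streams and the probabilistic triplet taxonomy.

The alternating serial reaction time (ASRT) task interleaves a fixed
four-position pattern with uniformly random positions: trials follow the
template P-r-P-r-..., where P walks a fixed cycle over the positions 1-4
and r is drawn uniformly.  Because of the alternation, the third element
of some three-trial windows ("triplets") is predictable from the first:
a triplet (a, x, b) is *high-probability* when b is the pattern successor
of a.  This module builds pattern cycles, generates stimulus blocks,
classifies triplets, and derives the closed-form triplet frequencies.

Positions are coded 1-4 left to right; trial and block indices are 1-based.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PatternCycle",
    "make_cycle",
    "canonical_cycles",
    "generate_block",
    "generate_blocks",
    "annotate_triplets",
    "annotate_stream",
    "enumerate_triplets",
    "analytic_frequencies",
    "FrequencySummary",
    "POSITIONS",
    "BLOCK_LENGTH",
    "N_WARMUP",
]

POSITIONS = (1, 2, 3, 4)
BLOCK_LENGTH = 85
#: random warm-up trials at the start of every block, before the first
#: pattern element
N_WARMUP = 5
#: repetitions of the eight-element P-r template per block
N_SEQUENCE_REPEATS = 10

# triplet labels / categories used throughout the package
HIGH, LOW, UNDEFINED = "high", "low", "undefined"
TRILL, REPETITION, NEITHER = "trill", "repetition", "neither"
ORIGIN_WARMUP, ORIGIN_PATTERN, ORIGIN_RANDOM = "warmup_random", "pattern", "random"


@dataclass(frozen=True)
class PatternCycle:
    """A fixed-point-free 4-cycle over positions 1-4.

    ``order`` lists the pattern elements in the order they are visited,
    e.g. the sequence "2r4r3r1r" yields ``order == (2, 4, 3, 1)`` and the
    successor mapping 2->4, 4->3, 3->1, 1->2.
    """

    order: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for p in self.order:
            if not isinstance(p, (int, np.integer)) or not 1 <= int(p) <= 4:
                raise ValueError(f"position {p!r} is not an integer in 1..4")
            if p in seen:
                raise ValueError(f"duplicate position {p} in pattern cycle")
            seen.add(int(p))
        if len(self.order) != 4:
            raise ValueError(f"a pattern cycle needs 4 positions, got {len(self.order)}")

    @property
    def successor(self) -> dict[int, int]:
        """Mapping position -> next pattern position."""
        o = self.order
        return {o[i]: o[(i + 1) % 4] for i in range(4)}

    def successor_of(self, position: int) -> int:
        return self.successor[position]

    @property
    def successor_array(self) -> np.ndarray:
        """Lookup table ``succ[p]`` for vectorised use (index 0 unused)."""
        arr = np.zeros(5, dtype=np.int64)
        for a, b in self.successor.items():
            arr[a] = b
        return arr

    @property
    def canonical_string(self) -> str:
        """Sequence string rotated so the cycle starts at position 2."""
        i = self.order.index(2)
        rotated = self.order[i:] + self.order[:i]
        return "".join(f"{p}r" for p in rotated)

    def __str__(self) -> str:
        return self.canonical_string


def make_cycle(sequence_spec) -> PatternCycle:
    """Build a :class:`PatternCycle` from a sequence string or 4-permutation.

    Accepts the conventional string form ``"2r4r3r1r"`` (case-insensitive,
    the ``r`` separators optional) or any iterable of four distinct
    positions in 1..4.

    >>> make_cycle("2r4r3r1r").successor
    {2: 4, 4: 3, 3: 1, 1: 2}
    """
    if isinstance(sequence_spec, PatternCycle):
        return sequence_spec
    if isinstance(sequence_spec, str):
        spec = sequence_spec.strip().lower()
        if not re.fullmatch(r"(?:[0-9]r?){4}", spec):
            raise ValueError(
                f"cannot parse sequence spec {sequence_spec!r}; expected e.g. '2r4r3r1r'"
            )
        order = tuple(int(c) for c in spec if c.isdigit())
    else:
        order = tuple(int(p) for p in sequence_spec)
    return PatternCycle(order)


def canonical_cycles() -> list[PatternCycle]:
    """The six distinct pattern cycles, canonically written starting at 2."""
    return [PatternCycle((2,) + rest) for rest in itertools.permutations((1, 3, 4))]


# ---------------------------------------------------------------------------
# stimulus generation
# ---------------------------------------------------------------------------

def generate_blocks(
    cycle: PatternCycle,
    n_blocks: int,
    rng: np.random.Generator,
    first_block: int = 1,
) -> pd.DataFrame:
    """Generate ``n_blocks`` ASRT blocks of 85 trials each.

    Each block: 5 uniform warm-up trials, then ten repetitions of the
    eight-element P-r template.  The pattern phase restarts at
    ``cycle.order[0]`` at trial 6 of every block.  Returns a tidy frame
    with columns ``block, trial, position, origin``.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    cycle = make_cycle(cycle)
    pos = np.empty((n_blocks, BLOCK_LENGTH), dtype=np.int64)
    pos[:, :N_WARMUP] = rng.integers(1, 5, size=(n_blocks, N_WARMUP))
    pattern = np.tile(np.asarray(cycle.order), N_SEQUENCE_REPEATS)
    pos[:, N_WARMUP::2] = pattern  # trials 6, 8, ..., 84
    pos[:, N_WARMUP + 1 :: 2] = rng.integers(1, 5, size=(n_blocks, 40))

    origin = np.empty(BLOCK_LENGTH, dtype=object)
    origin[:N_WARMUP] = ORIGIN_WARMUP
    origin[N_WARMUP::2] = ORIGIN_PATTERN
    origin[N_WARMUP + 1 :: 2] = ORIGIN_RANDOM

    return pd.DataFrame(
        {
            "block": np.repeat(np.arange(first_block, first_block + n_blocks), BLOCK_LENGTH),
            "trial": np.tile(np.arange(1, BLOCK_LENGTH + 1), n_blocks),
            "position": pos.ravel(),
            "origin": np.tile(origin, n_blocks),
        }
    )


def generate_block(
    cycle: PatternCycle, rng: np.random.Generator, block_index: int = 1
) -> pd.DataFrame:
    """Generate a single 85-trial block (see :func:`generate_blocks`)."""
    return generate_blocks(cycle, 1, rng, first_block=block_index)


# ---------------------------------------------------------------------------
# triplet classification
# ---------------------------------------------------------------------------

def classify_triplet(first: int, middle: int, third: int, cycle: PatternCycle):
    """Label and category of a single ordered triple of positions."""
    cycle = make_cycle(cycle)
    label = HIGH if cycle.successor_of(first) == third else LOW
    if first == middle == third:
        category = REPETITION
    elif first == third and middle != third:
        category = TRILL
    else:
        category = NEITHER
    return label, category


def _annotate_positions(pos: np.ndarray, succ: np.ndarray):
    """Vectorised labels/categories for a (n_blocks, block_len) position array.

    The first two trials of each row are undefined: classification does
    not cross block boundaries.
    """
    n_blocks, blen = pos.shape
    label = np.full((n_blocks, blen), UNDEFINED, dtype=object)
    category = np.full((n_blocks, blen), UNDEFINED, dtype=object)
    first, middle, third = pos[:, :-2], pos[:, 1:-1], pos[:, 2:]
    high = succ[first] == third
    rep = (third == middle) & (middle == first)
    trill = (third == first) & (third != middle)
    lab = np.where(high, HIGH, LOW)
    cat = np.where(rep, REPETITION, np.where(trill, TRILL, NEITHER))
    label[:, 2:] = lab
    category[:, 2:] = cat
    return label, category


def annotate_triplets(trials: pd.DataFrame, cycle: PatternCycle) -> pd.DataFrame:
    """Annotate one block of trials with triplet labels and categories.

    Every trial from the third onward is classified as the third element
    of the triplet it closes: ``high`` when its position is the pattern
    successor of the position two trials back, else ``low``.  Structural
    categories: ``repetition`` (a-a-a), ``trill`` (a-b-a), else
    ``neither``.  Trials 1-2 stay ``undefined``.

    Raises if the input spans several blocks or is not ordered by trial.
    """
    cycle = make_cycle(cycle)
    if "block" in trials.columns and trials["block"].nunique() > 1:
        raise ValueError("annotate_triplets expects trials from a single block; "
                         "use annotate_stream for multi-block data")
    t = trials["trial"].to_numpy()
    if not np.all(np.diff(t) == 1):
        raise ValueError("trials must be consecutively ordered by trial index")
    out = trials.copy()
    label, category = _annotate_positions(
        out["position"].to_numpy()[None, :], cycle.successor_array
    )
    out["triplet_label"] = label[0]
    out["triplet_category"] = category[0]
    return out


def annotate_stream(trials: pd.DataFrame, cycle: PatternCycle) -> pd.DataFrame:
    """Annotate a multi-block stream, restarting classification per block."""
    cycle = make_cycle(cycle)
    succ = cycle.successor_array
    out = trials.sort_values(["block", "trial"], kind="stable").reset_index(drop=True)
    lengths = out.groupby("block", sort=True).size()
    if lengths.nunique() == 1:
        blen = int(lengths.iloc[0])
        pos = out["position"].to_numpy().reshape(-1, blen)
        label, category = _annotate_positions(pos, succ)
        out["triplet_label"] = label.ravel()
        out["triplet_category"] = category.ravel()
        return out
    parts = [annotate_triplets(g, cycle) for _, g in out.groupby("block", sort=True)]
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# taxonomy and analytic frequencies
# ---------------------------------------------------------------------------

def enumerate_triplets(cycle: PatternCycle) -> pd.DataFrame:
    """The complete 64-row triplet table for one pattern cycle.

    Columns: ``first, middle, third, label, category, frequency`` where
    ``frequency`` is the expected long-run share of trials ending that
    triplet type (0.625/16 for each high type, 0.375/48 for each low).
    """
    cycle = make_cycle(cycle)
    rows = []
    for first, middle, third in itertools.product(POSITIONS, repeat=3):
        label, category = classify_triplet(first, middle, third, cycle)
        freq = 0.625 / 16 if label == HIGH else 0.375 / 48
        rows.append((first, middle, third, label, category, freq))
    return pd.DataFrame(
        rows, columns=["first", "middle", "third", "label", "category", "frequency"]
    )


@dataclass(frozen=True)
class FrequencySummary:
    """Closed-form triplet frequencies implied by the alternation structure.

    Pattern-ending trials (P-r-P windows) always close a high-probability
    triplet and make up half of all trials; random-ending trials (r-P-r)
    close one by chance 1/4 of the time.  Hence P(high) = 0.5 + 0.5/4.
    """

    p_high: float
    pattern_share: float          # share of all trials: high via P-r-P
    random_share: float           # share of all trials: high via r-P-r chance
    p_high_given_pattern_ending: float
    p_high_given_random_ending: float
    per_high_type_share: float    # long-run share of each of the 16 high types
    per_low_type_share: float     # long-run share of each of the 48 low types
    high_low_type_ratio: float    # per-type frequency ratio


def analytic_frequencies(cycle: PatternCycle) -> FrequencySummary:
    """Exact long-run triplet frequencies for any valid cycle.

    The values depend only on the alternating structure, not on which of
    the six cycles is used.  Warm-up trials are a vanishing fraction in
    the long run and are ignored here.
    """
    make_cycle(cycle)  # validation only
    pattern_share = 0.5            # every pattern-ending trial is high
    random_share = 0.5 * 0.25      # random-ending trials are high by chance
    p_high = pattern_share + random_share
    per_high = p_high / 16
    per_low = (1 - p_high) / 48
    return FrequencySummary(
        p_high=p_high,
        pattern_share=pattern_share,
        random_share=random_share,
        p_high_given_pattern_ending=1.0,
        p_high_given_random_ending=0.25,
        per_high_type_share=per_high,
        per_low_type_share=per_low,
        high_low_type_ratio=per_high / per_low,
    )
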