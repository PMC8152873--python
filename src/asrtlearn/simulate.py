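"""Synthetic two-group ASRT cohorts for pipeline and recovery testing.

Emulates the study design the pipeline targets: two instruction groups
(accuracy-focused: slow, nearly errorless; speed-focused: fast,
error-prone), 25 blocks of 85 trials collapsed into 5 epochs (epochs 1-4
under group-specific instructions, epoch 5 under a shared one), a
general epoch-wise speed-up, a high/low-probability triplet RT and
accuracy advantage that emerges after the first epoch, and
inclusion/exclusion generation streams with a controllable rate of
pattern-successor continuations.

The RT model is multiplicative lognormal noise around a deterministic
cell mean:

    rt = (base - speedup[epoch] - effect[epoch] * 1[high]) * exp(sigma * Z)

so the per-cell median RT equals the deterministic term and the median
learning score recovers ``effect`` directly.  All numeric defaults are
invented, configurable descriptions of a plausible cohort, not empirical
constants; nothing downstream treats them as ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import sequence as seq
from .generation import GenerationRun, RUN_LENGTH, CONDITIONS
from .scoring import assign_epoch

__all__ = [
    "GroupParams",
    "GenerationParams",
    "SimConfig",
    "simulate_participant",
    "simulate_cohort",
    "simulate_generation",
]

N_EPOCHS = 5


@dataclass(frozen=True)
class GroupParams:
    """RT and error model of one instruction group (all values invented)."""

    base_rt_ms: float
    lognormal_sigma: float
    epoch_speedup_ms: tuple[float, ...]   # length 5, subtracted per epoch
    triplet_effect_ms: tuple[float, ...]  # length 5, extra speed-up on high
    base_error_rate: float
    low_triplet_error_increment: float    # extra error probability on low
    epoch_error_drift: tuple[float, ...]  # length 5, added per epoch

    def __post_init__(self) -> None:
        for name in ("epoch_speedup_ms", "triplet_effect_ms", "epoch_error_drift"):
            v = getattr(self, name)
            if len(v) != N_EPOCHS:
                raise ValueError(f"{name} must have length {N_EPOCHS}, got {len(v)}")
        if self.base_rt_ms <= 0:
            raise ValueError("base_rt_ms must be positive")
        if not 0 <= self.base_error_rate <= 1:
            raise ValueError("base_error_rate must be in [0, 1]")


@dataclass(frozen=True)
class GenerationParams:
    """Per-condition probability of continuing with the pattern successor."""

    p_high_inclusion: float = 0.32
    p_high_exclusion: float = 0.30
    runs_per_condition: int = 4
    baseline: str = "exclude_successor"  # or "uniform"

    def p_for(self, condition: str) -> float:
        return {"inclusion": self.p_high_inclusion,
                "exclusion": self.p_high_exclusion}[condition]


def _default_groups() -> dict[str, GroupParams]:
    # Invented defaults encoding the qualitative regime: the speed group
    # is ~100 ms faster and much more error-prone; learning is absent in
    # epoch 1 and stable from epoch 2; in epoch 5 (shared instruction)
    # the accuracy group speeds up and the speed group slows slightly.
    return {
        "accuracy": GroupParams(
            base_rt_ms=450.0, lognormal_sigma=0.18,
            epoch_speedup_ms=(0.0, 10.0, 20.0, 28.0, 60.0),
            triplet_effect_ms=(0.0, 25.0, 25.0, 25.0, 25.0),
            base_error_rate=0.03, low_triplet_error_increment=0.01,
            epoch_error_drift=(0.0, 0.0, 0.0, 0.0, 0.0),
        ),
        "speed": GroupParams(
            base_rt_ms=350.0, lognormal_sigma=0.18,
            epoch_speedup_ms=(0.0, 8.0, 15.0, 20.0, -10.0),
            triplet_effect_ms=(0.0, 25.0, 25.0, 25.0, 25.0),
            base_error_rate=0.12, low_triplet_error_increment=0.05,
            epoch_error_drift=(0.0, 0.01, 0.02, 0.03, -0.02),
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full cohort configuration.

    ``sequence`` fixes one canonical cycle for everyone; ``None`` draws
    each participant's cycle at random from the six, as in the task.
    Group sizes default to 31 (accuracy) and 30 (speed).
    """

    n_accuracy: int = 31
    n_speed: int = 30
    n_blocks: int = 25
    seed: int = 0
    sequence: str | None = None
    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    generation: GenerationParams = field(default_factory=GenerationParams)

    def __post_init__(self) -> None:
        if self.n_accuracy < 1 or self.n_speed < 1:
            raise ValueError("group sizes must be >= 1")
        if not 1 <= self.n_blocks <= 25:
            raise ValueError("n_blocks must be in 1..25")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = {k: GroupParams(**{n: tuple(v) if isinstance(v, list) else v
                                             for n, v in g.items()})
                           for k, g in d["groups"].items()}
        if "generation" in d:
            d["generation"] = GenerationParams(**d["generation"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _participant_cycle(config: SimConfig, rng: np.random.Generator) -> seq.PatternCycle:
    if config.sequence is not None:
        return seq.make_cycle(config.sequence)
    return seq.canonical_cycles()[rng.integers(0, 6)]


def simulate_participant(
    config: SimConfig,
    group: str,
    rng: np.random.Generator,
    participant: str = "p01",
) -> pd.DataFrame:
    """Simulate one participant's trial records (``config.n_blocks`` blocks).

    Stimuli come from the ASRT generator, triplet annotation restarts per
    block, RTs follow the lognormal model in the module docstring and
    errors are Bernoulli with a label- and epoch-dependent rate.  On an
    incorrect trial the recorded response is uniform over the three
    wrong positions; RT is always the first-press latency.
    """
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}; have {sorted(config.groups)}")
    params = config.groups[group]
    cycle = _participant_cycle(config, rng)

    trials = seq.generate_blocks(cycle, config.n_blocks, rng)
    trials = seq.annotate_stream(trials, cycle)
    epoch = assign_epoch(trials["block"].to_numpy())
    is_high = (trials["triplet_label"] == seq.HIGH).to_numpy()
    is_low = (trials["triplet_label"] == seq.LOW).to_numpy()

    speedup = np.asarray(params.epoch_speedup_ms)[epoch - 1]
    effect = np.asarray(params.triplet_effect_ms)[epoch - 1]
    drift = np.asarray(params.epoch_error_drift)[epoch - 1]

    cell_rt = params.base_rt_ms - speedup - effect * is_high
    if np.any(cell_rt <= 0):
        raise ValueError("RT model produced a non-positive cell mean; "
                         "check epoch_speedup_ms/triplet_effect_ms")
    noise = np.exp(params.lognormal_sigma * rng.standard_normal(len(trials)))
    rt_ms = cell_rt * noise

    p_err = np.clip(params.base_error_rate + drift
                    + params.low_triplet_error_increment * is_low, 0.0, 0.95)
    correct = rng.random(len(trials)) >= p_err
    # wrong responses land uniformly on one of the other three keys
    offset = rng.integers(1, 4, size=len(trials))
    wrong = (trials["position"].to_numpy() - 1 + offset) % 4 + 1
    response = np.where(correct, trials["position"].to_numpy(), wrong)

    out = trials.assign(
        participant=participant,
        group=group,
        epoch=epoch,
        response=response,
        correct=correct,
        rt_ms=rt_ms,
        sequence=cycle.canonical_string,
    )
    cols = ["participant", "group", "sequence", "block", "epoch", "trial",
            "position", "origin", "triplet_label", "triplet_category",
            "response", "correct", "rt_ms"]
    return out[cols]


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate the full two-group cohort.

    Each participant gets an independent child stream of the master seed
    (keyed by enrollment index), so per-participant data do not depend on
    simulation order.  The seed and a config hash are embedded in the
    output metadata columns.
    """
    roster = [("accuracy", f"acc{i + 1:02d}") for i in range(config.n_accuracy)]
    roster += [("speed", f"spd{i + 1:02d}") for i in range(config.n_speed)]
    children = np.random.SeedSequence(config.seed).spawn(len(roster))
    frames = []
    for (group, pid), child in zip(roster, children):
        frames.append(simulate_participant(config, group,
                                           np.random.default_rng(child), pid))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = config.seed
    out.attrs["config_hash"] = config.config_hash
    return out


def simulate_generation(
    config: SimConfig,
    p: float,
    rng: np.random.Generator,
    cycle: seq.PatternCycle | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> list[GenerationRun]:
    """Generation runs with successor-continuation probability ``p``.

    The first two presses of a run are uniform.  Every later press is
    the pattern successor of the press two back with probability ``p``;
    otherwise it is uniform over the other three positions (so p=0 yields
    0% and p=1 yields 100% high-probability triplets), or over all four
    when ``config.generation.baseline == "uniform"`` (p=0 then sits at
    the 25% chance level).
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    gen = config.generation
    cycle = seq.make_cycle(cycle) if cycle is not None else _participant_cycle(config, rng)
    succ = cycle.successor_array
    runs = []
    for condition in conditions:
        for _ in range(gen.runs_per_condition):
            presses = list(rng.integers(1, 5, size=2))
            for i in range(2, RUN_LENGTH):
                target = succ[presses[i - 2]]
                if rng.random() < p:
                    presses.append(int(target))
                elif gen.baseline == "uniform":
                    presses.append(int(rng.integers(1, 5)))
                else:
                    others = [q for q in (1, 2, 3, 4) if q != target]
                    presses.append(others[rng.integers(0, 3)])
            runs.append(GenerationRun(condition, tuple(presses)))
    return runs
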