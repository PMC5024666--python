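"""The adaptive 1-up–2-down staircase procedure.

Two consecutive correct responses lower the comparison level; one error
raises it. The rule's equilibrium is the level where p² = 0.5, i.e.
p ≈ 0.7071 — the criterion later used to read thresholds off the fitted
psychometric function. Levels are integer nominal ΔE indices into a
comparison series; the step starts at 15 nominal units and shrinks to
10, 5, 3 and finally 1 after each of the first four reversals; a
staircase terminates at its sixth reversal or after 50 trials. Twelve
staircases (three per chromatic direction, with staggered random
starting ranges) run interleaved in random order within a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "new_staircase",
    "update",
    "run_block",
]

#: Starting-level ranges (inclusive) for the three staircases per direction.
START_RANGES = ((11, 20), (21, 30), (31, 40))


@dataclass(frozen=True)
class StaircaseConfig:
    step_schedule: tuple = (15, 10, 5, 3, 1)
    start_ranges: tuple = START_RANGES
    max_trials: int = 50
    reversal_limit: int = 6
    min_level: int = 0  # 1 in the simulated-scene dialect
    max_level: int = 50

    def __post_init__(self):
        if len(self.step_schedule) != 5:
            raise ValueError("step schedule must have 5 entries")
        for lo, hi in self.start_ranges:
            if not (self.min_level <= lo <= hi <= self.max_level):
                raise ValueError("start ranges must lie within the level range")


@dataclass
class StaircaseState:
    level: int
    config: StaircaseConfig
    consec_correct: int = 0
    reversals: int = 0
    trials: int = 0
    last_direction: int = 0  # +1 up, -1 down, 0 none yet
    step_index: int = 0
    done: bool = False
    history: list = field(default_factory=list)  # (level, correct)

    @property
    def step(self) -> int:
        return self.config.step_schedule[self.step_index]


@dataclass(frozen=True)
class TrialRecord:
    direction: str
    staircase_id: int
    trial_index: int
    nominal_de: int
    achieved_de: float
    correct: bool


def new_staircase(
    config: StaircaseConfig, start_range_index: int, rng: np.random.Generator
) -> StaircaseState:
    lo, hi = config.start_ranges[start_range_index % len(config.start_ranges)]
    level = int(rng.integers(lo, hi + 1))
    return StaircaseState(level=level, config=config)


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance one staircase by one response (mutates and returns state).

    Movement: one error moves the level up by the current step; the
    second of two consecutive correct responses moves it down and resets
    the counter. A reversal is logged when the realized movement
    direction flips relative to the previous realized movement (moves
    fully absorbed by clamping at the level bounds count as no
    movement). The step size advances through the schedule at each of
    the first four reversals. Termination: sixth reversal or 50 trials.
    """
    if state.done:
        raise RuntimeError("staircase already terminated")
    cfg = state.config
    state.history.append((state.level, bool(correct)))
    state.trials += 1

    move = 0
    if correct:
        state.consec_correct += 1
        if state.consec_correct >= 2:
            move = -state.step
            state.consec_correct = 0
    else:
        state.consec_correct = 0
        move = +state.step

    if move != 0:
        new_level = int(np.clip(state.level + move, cfg.min_level, cfg.max_level))
        realized = new_level - state.level
        state.level = new_level
        if realized != 0:
            direction = 1 if realized > 0 else -1
            if state.last_direction != 0 and direction != state.last_direction:
                state.reversals += 1
                if state.reversals <= 4:
                    state.step_index = min(state.reversals, 4)
            state.last_direction = direction

    if state.reversals >= cfg.reversal_limit or state.trials >= cfg.max_trials:
        state.done = True
    return state


def run_block(
    series_by_direction: dict,
    observer,
    stimulus_fn,
    rng: np.random.Generator | int,
    config: StaircaseConfig | None = None,
    staircases_per_direction: int = 3,
) -> list:
    """Run one block of interleaved staircases to completion.

    ``series_by_direction`` maps direction name to its ComparisonSeries;
    ``stimulus_fn(direction, level)`` supplies the trial stimulus (see
    :class:`illumdisc.observer.SummaryProvider`). Each trial draws
    uniformly among unfinished staircases. Returns the chronologically
    ordered list of :class:`TrialRecord`; fully reproducible given the
    rng seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if config is None:
        config = StaircaseConfig()

    tracks = []  # (direction, staircase_id, state)
    sid = 0
    for direction in series_by_direction:
        for j in range(staircases_per_direction):
            tracks.append((direction, sid, new_staircase(config, j, rng)))
            sid += 1

    records = []
    trial_index = 0
    while True:
        open_tracks = [t for t in tracks if not t[2].done]
        if not open_tracks:
            break
        direction, sid_, state = open_tracks[int(rng.integers(len(open_tracks)))]
        series = series_by_direction[direction]
        level = int(np.clip(state.level, 0, len(series) - 1))
        stim = stimulus_fn(direction, level)
        correct = observer.respond(stim, rng)
        records.append(
            TrialRecord(
                direction=direction,
                staircase_id=sid_,
                trial_index=trial_index,
                nominal_de=level,
                achieved_de=stim.achieved_de,
                correct=bool(correct),
            )
        )
        update(state, correct)
        trial_index += 1
    return records
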