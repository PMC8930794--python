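"""Stimulus-response-outcome devaluation task.

Six stimuli are deterministically linked to six outcomes (100% contingency);
half of the stimuli require a LEFT press, half a RIGHT press.  Training runs
10 blocks of 12 trials (each stimulus twice per block).  Two test phases
follow: *outcome devaluation*, in which the goal signal of trials whose
outcome is devalued is cancelled, and *stimulus devaluation*, in which the
stimulus drive of devalued-stimulus trials is attenuated.  Each test runs 6
blocks of 12 trials with 2 items devalued per block; every item is devalued
exactly twice across the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEFT, RIGHT, NONE = "LEFT", "RIGHT", "NONE"
TRAIN, OUTCOME_DEVAL, STIMULUS_DEVAL = "train", "outcome_deval", "stimulus_deval"
MODES = (TRAIN, OUTCOME_DEVAL, STIMULUS_DEVAL)


class InputError(ValueError):
    """Unknown stimulus or mode in task encoding."""


@dataclass(frozen=True)
class TaskSpec:
    """The 6x6 task: response map and stimulus->outcome bijection."""

    correct_response: tuple          # per stimulus, LEFT or RIGHT
    outcome_of: tuple                # bijection stimulus -> outcome index
    n_stimuli: int = 6
    n_outcomes: int = 6
    block_size: int = 12
    n_training_blocks: int = 10
    n_deval_blocks: int = 6
    n_devalued_per_block: int = 2

    def __post_init__(self):
        if sorted(self.outcome_of) != list(range(self.n_outcomes)):
            raise InputError("outcome_of must be a bijection")
        if len(self.correct_response) != self.n_stimuli:
            raise InputError("one response per stimulus required")


@dataclass
class TrialRecord:
    """Per-trial log entry."""

    phase: str
    block: int
    trial: int
    stimulus: int
    goal: int
    devalued: bool
    response: str = NONE
    correct: bool = False
    rewarded: bool = False
    rt_ms: float = np.nan

    def as_dict(self) -> dict:
        return dict(phase=self.phase, block=self.block, trial=self.trial,
                    stimulus=self.stimulus, goal=self.goal, devalued=self.devalued,
                    response=self.response, correct=self.correct,
                    rewarded=self.rewarded, rt_ms=self.rt_ms)


@dataclass
class InputDrive:
    """External drive for the stimulus and goal cortical layers."""

    stim: np.ndarray
    goal: np.ndarray


def build_task(seed: int) -> TaskSpec:
    """Random but seed-deterministic 6x6 task (3 LEFT / 3 RIGHT stimuli)."""
    rng = np.random.default_rng(seed)
    sides = np.array([LEFT] * 3 + [RIGHT] * 3, dtype=object)
    rng.shuffle(sides)
    outcomes = rng.permutation(6)
    return TaskSpec(correct_response=tuple(sides), outcome_of=tuple(int(o) for o in outcomes))


def encode_inputs(spec: TaskSpec, stimulus: int, mode: str, devalued: bool,
                  stim_amplitude: float = 1.0, goal_amplitude: float = 1.0,
                  attenuation: float = 0.25) -> InputDrive:
    """One-hot drives for a trial.

    Outcome devaluation cancels the goal drive of devalued trials; stimulus
    devaluation attenuates the stimulus drive (the stimulus is seen but not
    attended).  Non-devalued test trials are encoded exactly as in training.
    """
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}")
    if not (0 <= stimulus < spec.n_stimuli):
        raise InputError(f"unknown stimulus {stimulus!r}")
    stim = np.zeros(spec.n_stimuli)
    goal = np.zeros(spec.n_outcomes)
    s_amp, g_amp = stim_amplitude, goal_amplitude
    if devalued and mode == OUTCOME_DEVAL:
        g_amp = 0.0
    elif devalued and mode == STIMULUS_DEVAL:
        s_amp = attenuation * stim_amplitude
    stim[stimulus] = s_amp
    goal[spec.outcome_of[stimulus]] = g_amp
    return InputDrive(stim=stim, goal=goal)


def block_order(spec: TaskSpec, rng: np.random.Generator) -> np.ndarray:
    """Stimulus order of one block: each stimulus exactly twice, shuffled."""
    order = np.repeat(np.arange(spec.n_stimuli), spec.block_size // spec.n_stimuli)
    rng.shuffle(order)
    return order


def devaluation_schedule(spec: TaskSpec, seed: int) -> list[tuple[int, tuple[int, int]]]:
    """Balanced devaluation design: 6 blocks x 2 devalued items.

    Every item is devalued exactly twice across the test and the two items of
    a block are distinct.  Seed-deterministic (rejection sampling over random
    pairings).
    """
    rng = np.random.default_rng(seed)
    n, k = spec.n_deval_blocks, spec.n_devalued_per_block
    items = np.repeat(np.arange(spec.n_stimuli), n * k // spec.n_stimuli)
    while True:
        perm = rng.permutation(items)
        pairs = perm.reshape(n, k)
        if all(len(set(p)) == k for p in pairs):
            return [(b, (int(p[0]), int(p[1]))) for b, p in enumerate(pairs)]


def score_trial(spec: TaskSpec, stimulus: int, response: str, mode: str,
                devalued: bool) -> tuple[bool, bool]:
    """(correct, rewarded) for a trial.

    ``correct`` is pressing the stimulus's button; reward additionally
    requires the trial not to be devalued.  In the devaluation tests the
    behavioral variable of interest (responding at all) is scored separately
    by the experiment module.
    """
    if not (0 <= stimulus < spec.n_stimuli):
        raise InputError(f"unknown stimulus {stimulus!r}")
    correct = response == spec.correct_response[stimulus]
    rewarded = bool(correct and not devalued)
    return correct, rewarded


def response_name(index: int) -> str:
    return (LEFT, RIGHT)[index]
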