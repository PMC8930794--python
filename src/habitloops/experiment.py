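"""Cohort simulation, behavioral metrics and statistics.

A *subject* is one seeded model instance run through 10 training blocks and
the two devaluation tests (plasticity frozen during tests).  A *cohort* is a
set of subjects with consecutive seeds run under one pathology configuration;
cohorts are the unit of statistical comparison, using an exact (all
combinations) permutation test on per-subject response rates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from . import _kernels
from .model import HierarchicalModel, build_model
from .params import DEFAULT_PARAMS, ModelParams
from .pathology import PathologyConfig
from .task import (NONE, OUTCOME_DEVAL, STIMULUS_DEVAL, TRAIN, TaskSpec,
                   TrialRecord, block_order, build_task, devaluation_schedule,
                   encode_inputs, score_trial)

EXACT_LIMIT = 200_000
MC_RESAMPLES = 100_000


@dataclass
class SubjectResult:
    seed: int
    learning_curve: np.ndarray
    rate_devalued_outcome: float
    rate_valued_outcome: float
    rate_devalued_stimulus: float
    rate_valued_stimulus: float
    shortcut_mean: float
    shortcut_std: float
    unstable_at_block: int | None
    unstable_phase: str | None
    records: list[TrialRecord]
    shortcut_W: np.ndarray


@dataclass
class CohortResult:
    config: PathologyConfig
    seeds: list[int]
    subjects: list[SubjectResult]

    def curve(self) -> np.ndarray:
        return np.array([s.learning_curve for s in self.subjects])

    def rates(self, metric: str) -> np.ndarray:
        return np.array([getattr(s, metric) for s in self.subjects])

    def trials_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for rec in s.records:
                row = rec.as_dict()
                row["seed"] = s.seed
                rows.append(row)
        return pd.DataFrame(rows)

    def subjects_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(dict(
                seed=s.seed,
                final_performance=float(np.mean(s.learning_curve[7:])),
                rate_devalued_outcome=s.rate_devalued_outcome,
                rate_valued_outcome=s.rate_valued_outcome,
                rate_devalued_stimulus=s.rate_devalued_stimulus,
                rate_valued_stimulus=s.rate_valued_stimulus,
                shortcut_mean=s.shortcut_mean,
                shortcut_std=s.shortcut_std,
                unstable_at_block=s.unstable_at_block,
            ))
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        sf = self.subjects_frame()
        unstable = [s.unstable_at_block for s in self.subjects if s.unstable_at_block]
        return {
            "config": asdict(self.config),
            "n_subjects": len(self.subjects),
            "seeds": self.seeds,
            "learning_curve_mean": self.curve().mean(axis=0).round(6).tolist(),
            "rate_devalued_outcome": sf.rate_devalued_outcome.round(6).tolist(),
            "rate_valued_outcome": sf.rate_valued_outcome.round(6).tolist(),
            "rate_devalued_stimulus": sf.rate_devalued_stimulus.round(6).tolist(),
            "rate_valued_stimulus": sf.rate_valued_stimulus.round(6).tolist(),
            "shortcut_mean": sf.shortcut_mean.round(6).tolist(),
            "shortcut_std": sf.shortcut_std.round(6).tolist(),
            "shortcut_mean_cohort": round(float(sf.shortcut_mean.mean()), 6),
            "shortcut_std_cohort": round(float(sf.shortcut_std.mean()), 6),
            "unstable_at_block": unstable,
            "n_unstable": len(unstable),
        }


def _response_rate(records, phase, devalued: bool) -> float:
    sel = [r for r in records if r.phase == phase and r.devalued == devalued]
    if not sel:
        return float("nan")
    return float(np.mean([r.response != NONE for r in sel]))


def run_subject(config: PathologyConfig, seed: int,
                params: ModelParams | None = None,
                freeze_test_plasticity: bool = True) -> SubjectResult:
    """Train one seeded subject and run both devaluation tests.

    On a numerical runaway the subject is not aborted: the block index of the
    first instability is recorded and all remaining trials are marked as
    failed non-responses.
    """
    p = params if params is not None else DEFAULT_PARAMS
    task = build_task(seed)
    model = build_model(task, config, seed, params=p)
    _kernels.seed_noise(int(seed) % (2 ** 31 - 1))
    rng = np.random.default_rng((seed, 0xB10C))

    records: list[TrialRecord] = []
    unstable_at_block: int | None = None
    unstable_phase: str | None = None
    dead = False

    def run_phase_trials(phase: str, n_blocks: int, deval_items, learn: bool):
        nonlocal dead, unstable_at_block, unstable_phase
        for block in range(n_blocks):
            devalued_set = set(deval_items[block]) if deval_items is not None else set()
            for t_idx, stim in enumerate(block_order(task, rng)):
                stim = int(stim)
                goal = task.outcome_of[stim]
                if phase == OUTCOME_DEVAL:
                    devalued = goal in devalued_set
                elif phase == STIMULUS_DEVAL:
                    devalued = stim in devalued_set
                else:
                    devalued = False
                rec = TrialRecord(phase=phase, block=block + 1, trial=t_idx + 1,
                                  stimulus=stim, goal=goal, devalued=devalued)
                if dead:
                    records.append(rec)
                    continue
                drive = encode_inputs(task, stim, phase, devalued,
                                      p.stim_amplitude, p.goal_amplitude,
                                      p.stim_attenuation)
                out = model.run_trial_selection(drive)
                if not out.unstable:
                    rec.response = out.response
                    rec.rt_ms = out.rt_ms
                    rec.correct, rec.rewarded = score_trial(task, stim, out.response,
                                                            phase, devalued)
                    late = model.run_learning_window(drive, rec.rewarded, learn,
                                                     responded=out.response != NONE)
                    if late is not None and late.unstable:
                        out = late
                if out.unstable:
                    dead = True
                    unstable_at_block = block + 1
                    unstable_phase = phase
                    rec.response = NONE
                    rec.correct = rec.rewarded = False
                    rec.rt_ms = float("nan")
                records.append(rec)

    run_phase_trials(TRAIN, task.n_training_blocks, None, learn=True)
    out_sched = [pair for _, pair in devaluation_schedule(task, int(rng.integers(2 ** 31)))]
    stim_sched = [pair for _, pair in devaluation_schedule(task, int(rng.integers(2 ** 31)))]
    learn_tests = not freeze_test_plasticity
    run_phase_trials(OUTCOME_DEVAL, task.n_deval_blocks, out_sched, learn=learn_tests)
    run_phase_trials(STIMULUS_DEVAL, task.n_deval_blocks, stim_sched, learn=learn_tests)

    train_recs = [r for r in records if r.phase == TRAIN]
    curve = np.array([
        np.mean([r.correct for r in train_recs if r.block == b + 1])
        for b in range(task.n_training_blocks)])
    sc_mean, sc_std = shortcut_weight_stats(model)
    return SubjectResult(
        seed=seed,
        learning_curve=curve,
        rate_devalued_outcome=_response_rate(records, OUTCOME_DEVAL, True),
        rate_valued_outcome=_response_rate(records, OUTCOME_DEVAL, False),
        rate_devalued_stimulus=_response_rate(records, STIMULUS_DEVAL, True),
        rate_valued_stimulus=_response_rate(records, STIMULUS_DEVAL, False),
        shortcut_mean=sc_mean,
        shortcut_std=sc_std,
        unstable_at_block=unstable_at_block,
        unstable_phase=unstable_phase,
        records=records,
        shortcut_W=model.shortcut.W.copy(),
    )


def run_cohort(config: PathologyConfig, n_subjects: int, base_seed: int,
               params: ModelParams | None = None) -> CohortResult:
    """Independent subjects with seeds base_seed .. base_seed + n - 1."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    seeds = [int(base_seed) + i for i in range(n_subjects)]
    subjects = [run_subject(config, s, params=params) for s in seeds]
    return CohortResult(config=config, seeds=seeds, subjects=subjects)


def permutation_test(values_a, values_b, n_resamples: int = MC_RESAMPLES,
                     seed: int = 0) -> float:
    """Two-sided permutation test on the difference of means.

    All label reassignments are enumerated when their number is at most
    200,000; otherwise a Monte-Carlo approximation with ``n_resamples``
    resamples and a fixed seed is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pool = np.concatenate([a, b])
    n, na = pool.size, a.size
    obs = abs(a.mean() - b.mean())
    total = pool.sum()
    eps = 1e-12
    n_comb = math.comb(n, na)
    if n_comb <= EXACT_LIMIT:
        count = 0
        for idx in combinations(range(n), na):
            sa = pool[list(idx)].sum()
            diff = sa / na - (total - sa) / (n - na)
            if abs(diff) >= obs - eps:
                count += 1
        return count / n_comb
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pool)
        diff = perm[:na].mean() - perm[na:].mean()
        if abs(diff) >= obs - eps:
            count += 1
    return (count + 1) / (n_resamples + 1)


def shortcut_weight_stats(model_or_W) -> tuple[float, float]:
    """Mean and (population) standard deviation of all shortcut weights."""
    W = model_or_W.shortcut.W if isinstance(model_or_W, HierarchicalModel) else model_or_W
    W = np.asarray(W, dtype=float)
    return float(W.mean()), float(W.std())


# -- output writers -----------------------------------------------------------

def write_outputs(cohort: CohortResult, outdir, figures: bool = True) -> dict:
    """Write trials.csv, subjects.csv, summary.json (+ figures); returns paths."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    trials = outdir / "trials.csv"
    cohort.trials_frame().to_csv(trials, index=False)
    paths["trials"] = trials
    subjects = outdir / "subjects.csv"
    cohort.subjects_frame().to_csv(subjects, index=False)
    paths["subjects"] = subjects
    summary = outdir / "summary.json"
    with open(summary, "w") as fh:
        json.dump(cohort.summary_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = summary
    if figures:
        paths.update(write_figures(cohort, outdir))
    return paths


def write_figures(cohort: CohortResult, outdir) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path
    outdir = Path(outdir)
    paths = {}

    curve = cohort.curve()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    blocks = np.arange(1, curve.shape[1] + 1)
    ax.plot(blocks, curve.mean(axis=0), "-o", color="tab:blue")
    ax.fill_between(blocks, curve.mean(axis=0) - curve.std(axis=0),
                    curve.mean(axis=0) + curve.std(axis=0), alpha=0.25)
    ax.axhline(0.9, ls="--", c="gray", lw=0.8)
    ax.set(xlabel="training block", ylabel="fraction correct", ylim=(0, 1.05),
           title=f"learning curve — {cohort.config.name}")
    fig.tight_layout()
    f1 = outdir / "learning_curve.png"
    fig.savefig(f1, dpi=120)
    plt.close(fig)
    paths["learning_curve"] = f1

    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2), sharey=True)
    for ax, (title, val, dev) in zip(axes, [
            ("outcome devaluation", "rate_valued_outcome", "rate_devalued_outcome"),
            ("stimulus devaluation", "rate_valued_stimulus", "rate_devalued_stimulus")]):
        v, d = cohort.rates(val), cohort.rates(dev)
        ax.bar([0, 1], [np.nanmean(v), np.nanmean(d)],
               yerr=[np.nanstd(v), np.nanstd(d)], color=["tab:green", "tab:red"],
               tick_label=["valued", "devalued"], capsize=4)
        ax.set(title=title, ylim=(0, 1.05))
    axes[0].set_ylabel("response rate")
    fig.suptitle(cohort.config.name)
    fig.tight_layout()
    f2 = outdir / "devaluation_rates.png"
    fig.savefig(f2, dpi=120)
    plt.close(fig)
    paths["devaluation"] = f2
    return paths
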