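"""Behavioural preprocessing and descriptive learning summaries.

Trials are flagged as omission (no response), RT outlier (response faster
than a fast-guess cutoff or slower than the response window), or valid.
Learning is summarised per bin — one bin is a quarter of the run (11 trials
of 44) in presentation order — as accuracy and mean correct RT, and a run
set is judged above chance when accuracy reaches at least 7/11 (63.64 %) in
a minimum number of bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import BehavioralRun

__all__ = [
    "RunSummary",
    "preprocess_run",
    "bin_metrics",
    "above_chance",
    "summary_frame",
]

#: default fast-guess cutoff (s); the slow cutoff defaults to each trial's
#: response window (stimulus duration + ISI), the hard limit of the task
DEFAULT_FAST_CUTOFF = 0.2


@dataclass(frozen=True)
class RunSummary:
    run_id: str
    modality: str
    n_trials: int
    n_valid: int
    n_omissions: int
    n_outliers: int
    bin_accuracy: tuple       # percent per bin; NaN where undefined
    bin_accuracy_defined: tuple
    bin_mean_correct_rt: tuple  # seconds per bin; NaN where no correct trials
    bin_n_omissions: tuple
    bin_n_outliers: tuple
    above_chance_bins: int


def preprocess_run(
    run: BehavioralRun,
    rt_bounds: tuple[float, float | None] = (DEFAULT_FAST_CUTOFF, None),
) -> BehavioralRun:
    """Return a copy of the run with per-trial flags set.

    Each trial receives exactly one of {"valid", "omission", "rt_outlier"}.
    ``rt_bounds = (fast, slow)``; ``slow=None`` uses the per-trial response
    window as the upper limit.
    """
    fast, slow = rt_bounds
    flags = []
    for t, trial in enumerate(run.schedule.trials):
        if run.responses[t] is None:
            flags.append("omission")
            continue
        hi = slow if slow is not None else run.schedule.response_window(trial)
        rt = run.rts[t]
        flags.append("rt_outlier" if (rt < fast or rt > hi) else "valid")
    return replace(run, flags=flags)


def _is_correct(run: BehavioralRun, t: int) -> bool:
    return run.responses[t] == run.schedule.trials[t].correct_side


def bin_metrics(
    run: BehavioralRun,
    n_bins: int = 4,
    include_outliers_in_accuracy: bool = True,
) -> RunSummary:
    """Bin-wise accuracy and mean correct RT for one preprocessed run.

    Accuracy is correct responses divided by answered trials (omissions never
    count; RT outliers count by default, configurable). A bin with an empty
    denominator has *undefined* accuracy — flagged, not zero. Mean RT is
    taken over correct trials in the accuracy denominator.
    """
    if run.flags is None:
        run = preprocess_run(run)
    n = run.n_trials
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    acc, acc_def, rts, n_om, n_out = [], [], [], [], []
    chance_hits = 0
    for b in range(n_bins):
        idx = range(edges[b], edges[b + 1])
        denom = [
            t for t in idx
            if run.flags[t] == "valid"
            or (include_outliers_in_accuracy and run.flags[t] == "rt_outlier")
        ]
        n_om.append(sum(run.flags[t] == "omission" for t in idx))
        n_out.append(sum(run.flags[t] == "rt_outlier" for t in idx))
        if not denom:
            acc.append(float("nan"))
            acc_def.append(False)
            rts.append(float("nan"))
            continue
        correct = [t for t in denom if _is_correct(run, t)]
        a = 100.0 * len(correct) / len(denom)
        acc.append(a)
        acc_def.append(True)
        rts.append(float(np.mean([run.rts[t] for t in correct])) if correct else float("nan"))
        if a >= 100.0 * 7 / 11 - 1e-9:
            chance_hits += 1
    return RunSummary(
        run_id=run.schedule.run_id,
        modality=run.schedule.modality,
        n_trials=n,
        n_valid=sum(f == "valid" for f in run.flags),
        n_omissions=sum(f == "omission" for f in run.flags),
        n_outliers=sum(f == "rt_outlier" for f in run.flags),
        bin_accuracy=tuple(acc),
        bin_accuracy_defined=tuple(acc_def),
        bin_mean_correct_rt=tuple(rts),
        bin_n_omissions=tuple(n_om),
        bin_n_outliers=tuple(n_out),
        above_chance_bins=chance_hits,
    )


def above_chance(
    run_summaries,
    threshold_correct: int = 7,
    min_bins: int = 2,
    bin_size: int = 11,
) -> bool:
    """True if accuracy reaches ``threshold_correct / bin_size`` (inclusive)
    in at least ``min_bins`` bins pooled across the given runs."""
    thr = 100.0 * threshold_correct / bin_size - 1e-9
    hits = 0
    for s in run_summaries:
        for a, defined in zip(s.bin_accuracy, s.bin_accuracy_defined):
            if defined and a >= thr:
                hits += 1
    return hits >= min_bins


def summary_frame(run_summaries) -> pd.DataFrame:
    """Flatten summaries into a cohort-level table (one row per run x bin)."""
    rows = []
    for s in run_summaries:
        for b in range(len(s.bin_accuracy)):
            rows.append(
                {
                    "run_id": s.run_id,
                    "modality": s.modality,
                    "bin": b + 1,
                    "accuracy_pct": s.bin_accuracy[b],
                    "accuracy_defined": s.bin_accuracy_defined[b],
                    "mean_correct_rt_s": s.bin_mean_correct_rt[b],
                    "n_omissions": s.bin_n_omissions[b],
                    "n_outliers": s.bin_n_outliers[b],
                }
            )
    return pd.DataFrame(rows)
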