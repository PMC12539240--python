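"""Synthetic generation of the multisensory 2AFC learning task.

Each run presents 44 trials. On every trial one cue (a sound in audio-visual
runs, a vibration pattern in tactile-visual runs) is played while two visual
symbols appear left and right; exactly one symbol is the cue's matching
partner. Feedback is probabilistic: on a pre-planned subset of trials
(5/10/20 % of the run, spread evenly over the four cues) the valence is
reversed. Inter-trial and inter-stimulus intervals are gamma distributed
within a truncation window.

Everything is generated deterministically from a seed, so downstream stages
(simulation, fitting, event export) run without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StimulusSet",
    "Trial",
    "TrialSchedule",
    "IntervalParams",
    "generate_stimulus_sets",
    "generate_trial_schedule",
    "generate_feedback_plan",
    "sample_intervals",
    "minimum_familiarisation_trials",
    "N_COMBINATIONS",
    "CHANCE_THRESHOLD_PCT",
]

MODALITIES = ("AV", "TV")
N_CUES = 4
N_SYMBOLS = 4
#: cue x symbol combination space per run (4 cues x 4 symbols, 4 matching)
N_COMBINATIONS = N_CUES * N_SYMBOLS
STIM_DURATION = 2.0
FB_DURATION = 1.8
#: per-bin above-chance accuracy criterion: >= 7 of 11 trials correct
CHANCE_THRESHOLD_PCT = round(100.0 * 7 / 11, 2)

# complexity-class multisets; tactile sets use two constant-frequency
# (low-complexity) patterns, one ramp (medium) and one u-shaped (high)
_VISUAL_CLASSES = ("low", "medium", "medium", "high")
_CUE_CLASSES = {"AV": ("low", "medium", "medium", "high"), "TV": ("low", "low", "medium", "high")}


class ConfigurationError(ValueError):
    """Raised for infeasible or out-of-range task configuration."""


@dataclass(frozen=True)
class StimulusSet:
    """Stimuli for one run: 4 cues, 4 visual symbols, and the matching map."""

    modality: str
    cues: tuple[str, ...]
    cue_complexity: tuple[str, ...]
    visual_symbols: tuple[str, ...]
    symbol_complexity: tuple[str, ...]
    matching: Mapping[str, str]  # cue id -> its matching symbol id

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if len(self.cues) != N_CUES or len(self.visual_symbols) != N_SYMBOLS:
            raise ConfigurationError("a stimulus set needs 4 cues and 4 visual symbols")
        if sorted(self.symbol_complexity) != sorted(_VISUAL_CLASSES):
            raise ConfigurationError("visual complexity classes must be {low:1, medium:2, high:1}")
        if sorted(self.cue_complexity) != sorted(_CUE_CLASSES[self.modality]):
            raise ConfigurationError("cue complexity classes do not match the modality")
        if set(self.matching) != set(self.cues) or set(self.matching.values()) != set(self.visual_symbols):
            raise ConfigurationError("matching must be a bijection cues -> symbols")


@dataclass(frozen=True)
class IntervalParams:
    """Truncated-gamma interval parameters (seconds)."""

    iti_mean: float = 1.87
    iti_range: tuple[float, float] = (0.76, 3.45)
    isi_mean: float = 3.45
    isi_range: tuple[float, float] = (2.28, 4.83)


@dataclass(frozen=True)
class Trial:
    index: int  # 1-based
    cue_id: str
    left_symbol: str
    right_symbol: str
    correct_side: str  # side showing the cue's matching symbol
    feedback_reversed: bool
    stim_onset: float
    fb_onset: float
    iti: float
    isi: float


@dataclass
class TrialSchedule:
    run_id: str
    modality: str
    trials: list[Trial]
    reversal_rate: float
    interval_params: IntervalParams
    stimulus_set: StimulusSet
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def response_window(self, trial: Trial) -> float:
        """Seconds from stimulus onset during which a response is accepted."""
        return STIM_DURATION + trial.isi

    def validate(self) -> None:
        seen_cues = set()
        prev_end = -1.0
        for i, tr in enumerate(self.trials):
            if tr.index != i + 1:
                raise ConfigurationError("trial indices must be 1..n in order")
            if tr.left_symbol == tr.right_symbol:
                raise ConfigurationError("left and right symbols must differ")
            match = self.stimulus_set.matching[tr.cue_id]
            shown = {"left": tr.left_symbol, "right": tr.right_symbol}
            if shown[tr.correct_side] != match or shown["left" if tr.correct_side == "right" else "right"] == match:
                raise ConfigurationError("exactly one displayed symbol must match the cue")
            if tr.stim_onset <= prev_end:
                raise ConfigurationError("onsets must be strictly increasing")
            if not np.isclose(tr.fb_onset, tr.stim_onset + STIM_DURATION + tr.isi):
                raise ConfigurationError("feedback onset inconsistent with timeline")
            prev_end = tr.stim_onset
            seen_cues.add(tr.cue_id)
        if seen_cues != set(self.stimulus_set.cues):
            raise ConfigurationError("every cue must appear at least once")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial": t.index,
                "cue": t.cue_id,
                "left_symbol": t.left_symbol,
                "right_symbol": t.right_symbol,
                "correct_side": t.correct_side,
                "reversed": int(t.feedback_reversed),
                "stim_onset": t.stim_onset,
                "fb_onset": t.fb_onset,
                "iti": t.iti,
                "isi": t.isi,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        """Write the schedule as TSV plus a YAML sidecar (``<path>.yaml``)."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
        sidecar = {
            "run_id": self.run_id,
            "modality": self.modality,
            "seed": self.seed,
            "n_trials": self.n_trials,
            "reversal_rate": self.reversal_rate,
            "iti_mean": self.interval_params.iti_mean,
            "iti_range": list(self.interval_params.iti_range),
            "isi_mean": self.interval_params.isi_mean,
            "isi_range": list(self.interval_params.isi_range),
            "cues": list(self.stimulus_set.cues),
            "cue_complexity": list(self.stimulus_set.cue_complexity),
            "visual_symbols": list(self.stimulus_set.visual_symbols),
            "symbol_complexity": list(self.stimulus_set.symbol_complexity),
            "matching": dict(self.stimulus_set.matching),
        }
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "TrialSchedule":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        with open(path.with_suffix(path.suffix + ".yaml")) as fh:
            meta = yaml.safe_load(fh)
        sset = StimulusSet(
            modality=meta["modality"],
            cues=tuple(meta["cues"]),
            cue_complexity=tuple(meta["cue_complexity"]),
            visual_symbols=tuple(meta["visual_symbols"]),
            symbol_complexity=tuple(meta["symbol_complexity"]),
            matching=dict(meta["matching"]),
        )
        trials = [
            Trial(
                index=int(r.trial),
                cue_id=str(r.cue),
                left_symbol=str(r.left_symbol),
                right_symbol=str(r.right_symbol),
                correct_side=str(r.correct_side),
                feedback_reversed=bool(r.reversed),
                stim_onset=float(r.stim_onset),
                fb_onset=float(r.fb_onset),
                iti=float(r.iti),
                isi=float(r.isi),
            )
            for r in df.itertuples()
        ]
        return cls(
            run_id=str(meta["run_id"]),
            modality=meta["modality"],
            trials=trials,
            reversal_rate=float(meta["reversal_rate"]),
            interval_params=IntervalParams(
                iti_mean=meta["iti_mean"],
                iti_range=tuple(meta["iti_range"]),
                isi_mean=meta["isi_mean"],
                isi_range=tuple(meta["isi_range"]),
            ),
            stimulus_set=sset,
            seed=int(meta["seed"]),
        )


def generate_stimulus_sets(seed: int) -> dict[str, StimulusSet]:
    """Build one :class:`StimulusSet` per modality, deterministically per seed.

    Complexity classes are shuffled over the stimulus ids, and the assignment
    of cues to their matching symbols is a seeded random bijection, mirroring
    the pseudo-randomised set construction of the experiment.
    """
    sets: dict[str, StimulusSet] = {}
    for m, modality in enumerate(MODALITIES):
        rng = np.random.default_rng([seed, m])
        prefix = "a" if modality == "AV" else "t"
        cues = tuple(f"{prefix}{i + 1}" for i in range(N_CUES))
        symbols = tuple(f"v{i + 1}" for i in range(N_SYMBOLS))
        cue_cls = tuple(str(x) for x in rng.permutation(_CUE_CLASSES[modality]))
        sym_cls = tuple(str(x) for x in rng.permutation(_VISUAL_CLASSES))
        matching = {c: str(s) for c, s in zip(cues, rng.permutation(symbols))}
        sets[modality] = StimulusSet(
            modality=modality,
            cues=cues,
            cue_complexity=cue_cls,
            visual_symbols=symbols,
            symbol_complexity=sym_cls,
            matching=matching,
        )
    return sets


def _repair_cue_runs(order: np.ndarray, rng: np.random.Generator, max_run: int = 3) -> np.ndarray:
    """Shuffle-and-repair: break runs of more than ``max_run`` equal cues."""
    order = order.copy()
    n = order.size
    for _ in range(200):
        bad = -1
        for i in range(max_run, n):
            if np.all(order[i - max_run : i + 1] == order[i]):
                bad = i
                break
        if bad < 0:
            return order
        # swap the offending trial with a random position that breaks the run
        candidates = [
            j
            for j in range(n)
            if order[j] != order[bad]
            and (j == 0 or order[j - 1] != order[bad])
            and (j == n - 1 or order[j + 1] != order[bad])
        ]
        if not candidates:
            rng.shuffle(order)
            continue
        j = int(rng.choice(candidates))
        order[bad], order[j] = order[j], order[bad]
    raise ConfigurationError("could not build a cue order without long runs")


def generate_feedback_plan(
    cue_sequence: Sequence[str],
    reversal_rate: float,
    seed: int,
) -> np.ndarray:
    """Plan which trials get valence-reversed feedback.

    The total count is ``round(rate * n)`` (half away from zero) and is split
    as evenly as possible over the cues (per-cue counts differ by at most 1);
    the positions within each cue's trials are random per seed.
    """
    if not 0.0 <= reversal_rate < 1.0:
        raise ConfigurationError("reversal_rate must lie in [0, 1)")
    cue_sequence = list(cue_sequence)
    n = len(cue_sequence)
    rng = np.random.default_rng([seed, 101])
    total = int(np.floor(reversal_rate * n + 0.5))
    cues = sorted(set(cue_sequence))
    base, rem = divmod(total, len(cues))
    counts = {c: base for c in cues}
    for c in rng.permutation(cues)[:rem]:
        counts[c] += 1
    flags = np.zeros(n, dtype=bool)
    for c in cues:
        idx = [i for i, q in enumerate(cue_sequence) if q == c]
        k = min(counts[c], len(idx))
        for i in rng.choice(idx, size=k, replace=False):
            flags[i] = True
    return flags


def sample_intervals(
    n: int,
    mean: float,
    rng_bounds: tuple[float, float],
    seed: int,
) -> np.ndarray:
    """Sample ``n`` truncated-gamma intervals (seconds).

    Shape and scale are calibrated so the *untruncated* mean equals ``mean``
    (moment heuristic: sd = (hi - lo) / 4); samples outside [lo, hi] are
    rejected and redrawn. The residual truncation shift of the mean is below
    0.05 s for the task's interval windows.
    """
    lo, hi = rng_bounds
    if not lo < mean < hi or lo <= 0.0:
        raise ConfigurationError("interval bounds must satisfy 0 < lo < mean < hi")
    sd = (hi - lo) / 4.0
    shape = (mean / sd) ** 2
    scale = mean / shape
    rng = np.random.default_rng([seed, 202])
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        draw = rng.gamma(shape, scale, size=max(n - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_trial_schedule(
    stimulus_set: StimulusSet,
    n_trials: int = 44,
    cue_frequencies: Mapping[str, int] | None = None,
    reversal_rate: float = 0.10,
    interval_params: IntervalParams | None = None,
    seed: int = 0,
    run_id: str = "run-01",
) -> TrialSchedule:
    """Generate a pseudo-randomised trial schedule.

    * cue order has no more than 3 consecutive identical cues;
    * the matching symbol's side is counterbalanced within +-1 per cue;
    * distractor symbols rotate over the three non-matching symbols per cue,
      so all 16 cue x symbol pairings occur across a default-length run;
    * the run clock starts at 0 at the first ITI onset and each trial is
      ITI -> stimulus (2.0 s) -> ISI -> feedback (1.8 s).
    """
    if n_trials < N_CUES:
        raise ConfigurationError("need at least one trial per cue")
    interval_params = interval_params or IntervalParams()
    if cue_frequencies is None:
        base, rem = divmod(n_trials, N_CUES)
        cue_frequencies = {c: base + (1 if i < rem else 0) for i, c in enumerate(stimulus_set.cues)}
    if sorted(cue_frequencies) != sorted(stimulus_set.cues):
        raise ConfigurationError("cue_frequencies must cover exactly the set's cues")
    if sum(cue_frequencies.values()) != n_trials:
        raise ConfigurationError(f"cue frequencies sum to {sum(cue_frequencies.values())}, expected {n_trials}")
    if min(cue_frequencies.values()) < 1:
        raise ConfigurationError("every cue must appear at least once")

    rng = np.random.default_rng([seed, 303])
    order = np.repeat(
        [list(stimulus_set.cues).index(c) for c in stimulus_set.cues for _ in range(cue_frequencies[c])], 1
    )
    rng.shuffle(order)
    order = _repair_cue_runs(order, rng)
    cue_seq = [stimulus_set.cues[i] for i in order]

    # per-cue side counterbalancing (+-1) and balanced distractor rotation
    sides: dict[str, list[str]] = {}
    distractors: dict[str, list[str]] = {}
    for c in stimulus_set.cues:
        k = cue_frequencies[c]
        s = ["left"] * (k // 2) + ["right"] * (k - k // 2)
        rng.shuffle(s)
        sides[c] = s
        others = [v for v in stimulus_set.visual_symbols if v != stimulus_set.matching[c]]
        d = (others * (k // len(others) + 1))[:k]
        rng.shuffle(d)
        distractors[c] = d

    reversed_flags = generate_feedback_plan(cue_seq, reversal_rate, seed)
    itis = sample_intervals(n_trials, interval_params.iti_mean, interval_params.iti_range, seed)
    isis = sample_intervals(n_trials, interval_params.isi_mean, interval_params.isi_range, seed + 1)

    trials: list[Trial] = []
    used = {c: 0 for c in stimulus_set.cues}
    clock = 0.0
    for t in range(n_trials):
        c = cue_seq[t]
        i = used[c]
        used[c] += 1
        side = sides[c][i]
        match = stimulus_set.matching[c]
        distract = distractors[c][i]
        left, right = (match, distract) if side == "left" else (distract, match)
        stim_onset = clock + itis[t]
        fb_onset = stim_onset + STIM_DURATION + isis[t]
        clock = fb_onset + FB_DURATION
        trials.append(
            Trial(
                index=t + 1,
                cue_id=c,
                left_symbol=left,
                right_symbol=right,
                correct_side=side,
                feedback_reversed=bool(reversed_flags[t]),
                stim_onset=float(stim_onset),
                fb_onset=float(fb_onset),
                iti=float(itis[t]),
                isi=float(isis[t]),
            )
        )
    schedule = TrialSchedule(
        run_id=run_id,
        modality=stimulus_set.modality,
        trials=trials,
        reversal_rate=reversal_rate,
        interval_params=interval_params,
        stimulus_set=stimulus_set,
        seed=seed,
    )
    schedule.validate()
    return schedule


def minimum_familiarisation_trials(
    instruction_trials: int = 13,
    practice_min: int = 10,
    run_length: int = 44,
) -> int:
    """Minimum number of task trials completed before scanning.

    Familiarisation comprises, per modality, a guided instruction block and a
    full behavioural run; self-paced practice (at least ``practice_min``
    trials) is required before the first behavioural run and again with the
    scanner response box, while practice before the second modality's run is
    repeated only when needed. With the defaults this floor is 134 trials.
    """
    per_modality = instruction_trials + run_length
    return 2 * per_modality + 2 * practice_min
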