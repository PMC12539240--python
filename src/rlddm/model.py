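"""Generative reinforcement-learning drift-diffusion model (RLDDM).

A Rescorla-Wagner learner maintains a reward expectation V in [0, 1] for each
of the 16 cue x symbol combinations (all initialized at 0.5).  On each trial
the values of the two displayed combinations are normalized to sum to 1; the
scaled difference drives a Wiener diffusion whose first passage through the
upper/lower boundary produces the left/right choice and the decision time:

    RPE_t    = R_t - V_t                          (reward prediction error)
    V_t+1    = V_t + eta * RPE_t                  (delta rule, chosen combo only)
    Vbar_l   = V_l / (V_l + V_r),  Vbar_r = 1 - Vbar_l
    v_t      = (Vbar_l - Vbar_r) * vmod           (trial-wise drift rate)
    RT, side ~ WFPT(a, tau, z, v_t)

Rewards are coded 1 (positive feedback) / 0 (negative feedback); omissions
receive neutral feedback, which carries no reward signal: no RPE, no value
update, no likelihood contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import TrialSchedule, Trial
from . import wfpt as _wfpt

__all__ = [
    "RLDDMParams",
    "ValueTable",
    "BehavioralRun",
    "compute_rpe",
    "update_value",
    "normalize_pair",
    "drift_rate",
    "trial_loglik",
    "simulate_run",
    "compute_latents",
]

#: below this floor a value pair is considered degenerate when normalizing
DEGENERATE_EPS = 1e-12


@dataclass(frozen=True)
class RLDDMParams:
    """Free parameters of the model plus the fixed relative start point.

    eta   : learning rate, unitless in [0, 1]
    a     : boundary separation, evidence units, > 0
    tau   : non-decision time, seconds, >= 0
    vmod  : drift weight, evidence/s per unit normalized value difference, >= 0
    z     : relative start point, fixed at 0.5 (unbiased) unless overridden
    """

    eta: float
    a: float
    tau: float
    vmod: float
    z: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("learning rate eta must lie in [0, 1]")
        if self.a <= 0.0:
            raise ValueError("boundary separation a must be > 0")
        if self.tau < 0.0:
            raise ValueError("non-decision time tau must be >= 0")
        if self.vmod < 0.0:
            raise ValueError("drift weight vmod must be >= 0")
        if not 0.0 < self.z < 1.0:
            raise ValueError("relative start point z must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta, self.a, self.tau, self.vmod], dtype=float)


class ValueTable:
    """Reward expectations for every cue x symbol combination, initial 0.5."""

    def __init__(self, cues, symbols, initial: float = 0.5):
        self.cues = tuple(cues)
        self.symbols = tuple(symbols)
        self._ci = {c: i for i, c in enumerate(self.cues)}
        self._si = {s: i for i, s in enumerate(self.symbols)}
        self.v = np.full((len(self.cues), len(self.symbols)), float(initial))

    @classmethod
    def for_schedule(cls, schedule: TrialSchedule) -> "ValueTable":
        s = schedule.stimulus_set
        return cls(s.cues, s.visual_symbols)

    def __getitem__(self, key) -> float:
        cue, sym = key
        return float(self.v[self._ci[cue], self._si[sym]])

    def __setitem__(self, key, value: float) -> None:
        cue, sym = key
        self.v[self._ci[cue], self._si[sym]] = value

    def update(self, cue: str, symbol: str, reward: float, eta: float) -> float:
        """Delta-rule update of one combination; returns the RPE applied."""
        old = self[cue, symbol]
        rpe = compute_rpe(reward, old)
        self[cue, symbol] = update_value(old, reward, eta)
        return rpe


def compute_rpe(reward: float, value: float) -> float:
    """Reward prediction error: delivered reward minus expected reward."""
    if reward is None or (isinstance(reward, float) and np.isnan(reward)):
        raise ValueError("RPE is undefined for neutral feedback (omission)")
    return float(reward) - float(value)


def update_value(value: float, reward: float, eta: float) -> float:
    """Delta rule: ``V' = V + eta * (R - V)``."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    return float(value) + eta * compute_rpe(reward, value)


def normalize_pair(v_left: float, v_right: float) -> tuple[float, float]:
    """Normalize a value pair to sum to 1; (0.5, 0.5) for a degenerate pair."""
    if v_left < 0.0 or v_right < 0.0:
        raise ValueError("values must be nonnegative")
    denom = v_left + v_right
    if denom < DEGENERATE_EPS:
        warnings.warn("degenerate value pair (both ~0); returning (0.5, 0.5)", RuntimeWarning)
        return 0.5, 0.5
    vbl = v_left / denom
    return vbl, 1.0 - vbl


def drift_rate(vbar_left: float, vbar_right: float, vmod: float) -> float:
    """Trial drift rate: normalized value difference scaled by the drift weight."""
    return (vbar_left - vbar_right) * vmod


def trial_loglik(response: str, rt: float, v: float, params: RLDDMParams,
                 tol: float = _wfpt.DEFAULT_TOL) -> float:
    """Log WFPT density of one observed (choice, RT) pair.

    Left responses map to the upper boundary, right responses to the lower
    boundary. An RT at or below the non-decision time is infeasible under the
    model and returns ``-inf`` (a sentinel, never an exception, so optimizers
    can probe freely).
    """
    if response not in ("left", "right"):
        raise ValueError("likelihood is defined only for left/right responses")
    t_dec = rt - params.tau
    if t_dec <= 0.0:
        return -np.inf
    boundary = "upper" if response == "left" else "lower"
    dens = _wfpt.wfpt_density(t_dec, v, params.a, params.z, boundary, tol)
    if dens <= 0.0:
        return -np.inf
    return float(np.log(dens))


@dataclass
class BehavioralRun:
    """A run's schedule plus observed (or simulated) behaviour.

    responses[t] is "left"/"right" or None (omission); rts[t] is seconds from
    stimulus onset (NaN for omissions); rewards[t] is 1.0/0.0 (NaN = neutral
    feedback after an omission). ``flags`` is filled by behavioural
    preprocessing with "valid"/"omission"/"rt_outlier" per trial.
    """

    schedule: TrialSchedule
    responses: list
    rts: np.ndarray
    rewards: np.ndarray
    flags: list | None = None

    def __post_init__(self):
        n = self.schedule.n_trials
        if not (len(self.responses) == len(self.rts) == len(self.rewards) == n):
            raise ValueError("behaviour arrays must match the schedule length")
        for t in range(n):
            omitted = self.responses[t] is None
            if omitted != bool(np.isnan(self.rts[t])) or omitted != bool(np.isnan(self.rewards[t])):
                raise ValueError("rt and reward must be absent exactly for omissions")

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials

    def to_frame(self) -> pd.DataFrame:
        df = self.schedule.to_frame()
        df["response"] = [r if r is not None else "omission" for r in self.responses]
        df["rt"] = self.rts
        df["reward"] = self.rewards
        if self.flags is not None:
            df["flag"] = self.flags
        return df

    def write(self, path: str | Path) -> None:
        """Tab-separated trial log (schedule columns + response, rt, reward)."""
        self.schedule.write(path)  # sidecar carries the schedule metadata
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read(cls, path: str | Path) -> "BehavioralRun":
        schedule = TrialSchedule.read(path)
        df = pd.read_csv(path, sep="\t")
        responses = [None if r == "omission" else str(r) for r in df["response"]]
        run = cls(
            schedule=schedule,
            responses=responses,
            rts=df["rt"].to_numpy(dtype=float),
            rewards=df["reward"].to_numpy(dtype=float),
            flags=list(df["flag"]) if "flag" in df else None,
        )
        return run


def _deliver_feedback(trial: Trial, response: str | None) -> float:
    """Reward under the probabilistic feedback scheme (NaN = neutral)."""
    if response is None:
        return np.nan
    correct = response == trial.correct_side
    if trial.feedback_reversed:
        correct = not correct
    return 1.0 if correct else 0.0


def simulate_run(schedule: TrialSchedule, params: RLDDMParams, seed: int,
                 dt: float = 1e-3) -> BehavioralRun:
    """Forward-simulate a behavioural run from the generative model.

    Per trial: normalize the displayed pair's values, form the drift rate,
    sample the diffusion (omission if the decision does not finish inside the
    response window), deliver probabilistic feedback, and delta-rule-update
    the chosen combination. Deterministic per (schedule, params, seed).
    """
    values = ValueTable.for_schedule(schedule)
    rng = np.random.default_rng([seed, 404])
    responses: list = []
    rts = np.full(schedule.n_trials, np.nan)
    rewards = np.full(schedule.n_trials, np.nan)
    for t, trial in enumerate(schedule.trials):
        vbl, vbr = normalize_pair(values[trial.cue_id, trial.left_symbol],
                                  values[trial.cue_id, trial.right_symbol])
        v = drift_rate(vbl, vbr, params.vmod)
        window = schedule.response_window(trial)
        resp, rt = _wfpt.simulate_trial(
            v, params.a, params.tau, params.z,
            response_window=window,
            seed=int(rng.integers(0, 2**31 - 1)),
            dt=dt,
        )
        reward = _deliver_feedback(trial, resp)
        responses.append(resp)
        if resp is not None:
            rts[t] = rt
            rewards[t] = reward
            chosen_symbol = trial.left_symbol if resp == "left" else trial.right_symbol
            values.update(trial.cue_id, chosen_symbol, reward, params.eta)
    return BehavioralRun(schedule=schedule, responses=responses, rts=rts, rewards=rewards)


def compute_latents(run: BehavioralRun, params: RLDDMParams) -> pd.DataFrame:
    """Replay a run with its observed choices and feedback; return trial latents.

    Columns: trial, vbar_left, vbar_right, drift, rpe, v_chosen_norm.
    Normalized values and the drift rate exist on every trial (they depend
    only on the presented pair); RPE and the chosen value are NaN on
    omissions, which also leave the value table untouched.  Trials flagged as
    RT outliers still update values — the feedback was seen — even though
    they are excluded from the likelihood.
    """
    values = ValueTable.for_schedule(run.schedule)
    rows = []
    for t, trial in enumerate(run.schedule.trials):
        vbl, vbr = normalize_pair(values[trial.cue_id, trial.left_symbol],
                                  values[trial.cue_id, trial.right_symbol])
        v = drift_rate(vbl, vbr, params.vmod)
        resp = run.responses[t]
        if resp is None:
            rpe = np.nan
            v_chosen = np.nan
        else:
            chosen_symbol = trial.left_symbol if resp == "left" else trial.right_symbol
            v_chosen = vbl if resp == "left" else vbr
            rpe = values.update(trial.cue_id, chosen_symbol, run.rewards[t], params.eta)
        rows.append(
            {"trial": trial.index, "vbar_left": vbl, "vbar_right": vbr,
             "drift": v, "rpe": rpe, "v_chosen_norm": v_chosen}
        )
    return pd.DataFrame(rows)
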