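"""First-level fMRI event tables with parametric modulators.

Each trial contributes one stimulus event (2.0 s) and one feedback event
(1.8 s). For valid trials the stimulus event carries the normalized value of
the chosen combination (at stimulus onset, i.e. pre-feedback) as the value
modulator and the feedback event carries the trial's reward prediction
error. Omission and RT-outlier trials contribute unmodulated no-interest
events instead. Tables are written as BIDS-style events TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import BehavioralRun
from .behaviour import preprocess_run
from .task import FB_DURATION, STIM_DURATION

__all__ = ["build_events", "write_bids_events", "read_bids_events", "center_modulators"]

COLUMNS = ["onset", "duration", "trial_type", "pmod_value", "pmod_rpe"]

TRIAL_TYPES = (
    "stimulus", "feedback",
    "stimulus_outlier", "feedback_outlier",
    "stimulus_omission", "feedback_omission",
)


def build_events(run: BehavioralRun, latents: pd.DataFrame,
                 onset_offset: float = 0.0) -> pd.DataFrame:
    """Assemble the event table for one run from its fitted latents.

    ``onset_offset`` shifts onsets into scanner time when importing external
    logs. Raises if the latents table does not align with the run.
    """
    if len(latents) != run.n_trials or list(latents["trial"]) != [t.index for t in run.schedule.trials]:
        raise ValueError("latents do not match the run's trials")
    if run.flags is None:
        run = preprocess_run(run)
    rows = []
    for t, trial in enumerate(run.schedule.trials):
        flag = run.flags[t]
        suffix = {"valid": "", "rt_outlier": "_outlier", "omission": "_omission"}[flag]
        modulated = flag == "valid"
        rows.append({
            "onset": trial.stim_onset + onset_offset,
            "duration": STIM_DURATION,
            "trial_type": "stimulus" + suffix,
            "pmod_value": float(latents["v_chosen_norm"].iloc[t]) if modulated else np.nan,
            "pmod_rpe": np.nan,
        })
        rows.append({
            "onset": trial.fb_onset + onset_offset,
            "duration": FB_DURATION,
            "trial_type": "feedback" + suffix,
            "pmod_value": np.nan,
            "pmod_rpe": float(latents["rpe"].iloc[t]) if modulated else np.nan,
        })
    table = pd.DataFrame(rows, columns=COLUMNS).sort_values("onset", kind="stable")
    return table.reset_index(drop=True)


def center_modulators(table: pd.DataFrame, mode: str = "none") -> pd.DataFrame:
    """Optionally mean-center each modulator over its modulated rows.

    ``mode="none"`` is the identity (the default: SPM demeans modulators
    itself); ``mode="mean"`` subtracts the column mean over non-missing rows.
    """
    if mode not in ("none", "mean"):
        raise ValueError(f"unknown centering mode {mode!r}")
    out = table.copy()
    if mode == "mean":
        for col in ("pmod_value", "pmod_rpe"):
            m = out[col].notna()
            if m.any():
                out.loc[m, col] = out.loc[m, col] - out.loc[m, col].mean()
    return out


def write_bids_events(table: pd.DataFrame, path: str | Path) -> None:
    """Write a BIDS events TSV ('n/a' for missing, >= 6 significant digits)."""
    out = table.copy()
    for col in COLUMNS:
        if col not in out.columns:
            raise ValueError(f"event table is missing column {col!r}")
    out = out[COLUMNS]
    out.to_csv(Path(path), sep="\t", index=False, na_rep="n/a", float_format="%.8g")


def read_bids_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_bids_events`."""
    return pd.read_csv(Path(path), sep="\t", na_values=["n/a"])
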