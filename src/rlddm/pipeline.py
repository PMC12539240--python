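"""End-to-end pipeline: simulate -> fit -> latents -> summary -> events.

Every stage writes a text artifact into the output directory and the run
ends with a manifest recording the configuration, stage seeds, and a
content hash per output, so identical configs yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .behaviour import bin_metrics, preprocess_run, summary_frame
from .config import RunConfig, derive_seed
from .events import build_events, write_bids_events
from .fitting import OptimizerConfig, fit_run
from .model import compute_latents, simulate_run
from .task import IntervalParams, generate_stimulus_sets, generate_trial_schedule

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages for one synthetic run; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_id = f"{config.modality.lower()}-run"
    stage_seeds = {
        s: derive_seed(config.seed, s, run_id)
        for s in ("task", "simulate", "fit")
    }

    sset = generate_stimulus_sets(stage_seeds["task"])[config.modality]
    schedule = generate_trial_schedule(
        sset,
        n_trials=config.n_trials,
        reversal_rate=config.reversal_rate,
        interval_params=IntervalParams(
            iti_mean=config.iti_mean, iti_range=tuple(config.iti_range),
            isi_mean=config.isi_mean, isi_range=tuple(config.isi_range),
        ),
        seed=stage_seeds["task"],
        run_id=run_id,
    )
    from .model import RLDDMParams

    gen_params = RLDDMParams(eta=config.sim_eta, a=config.sim_a,
                             tau=config.sim_tau, vmod=config.sim_vmod)
    run = simulate_run(schedule, gen_params, seed=stage_seeds["simulate"], dt=config.sim_dt)
    run = preprocess_run(run, rt_bounds=(config.rt_fast_cutoff, config.rt_slow_cutoff))

    run_path = out / f"{run_id}_trials.tsv"
    run.write(run_path)

    fit = fit_run(
        run,
        optimizer_config=OptimizerConfig(population=config.population,
                                         generations=config.generations),
        seed=stage_seeds["fit"],
    )
    fit_path = out / f"{run_id}_fit.txt"
    with open(fit_path, "w") as fh:
        for k in ("eta", "a", "tau", "vmod", "z"):
            fh.write(f"{k}\t{getattr(fit.params, k):.8g}\n")
        fh.write(f"nll\t{fit.nll:.8g}\n")
        fh.write(f"n_trials_used\t{fit.n_trials_used}\n")
        fh.write(f"converged\t{int(fit.converged)}\n")

    latents = compute_latents(run, fit.params)
    latents_path = out / f"{run_id}_latents.tsv"
    latents.to_csv(latents_path, sep="\t", index=False, float_format="%.8g")

    summary = bin_metrics(run)
    summary_path = out / f"{run_id}_summary.tsv"
    summary_frame([summary]).to_csv(summary_path, sep="\t", index=False, float_format="%.6g")

    events = build_events(run, latents)
    events_path = out / f"{run_id}_events.tsv"
    write_bids_events(events, events_path)

    outputs = {
        "trials": run_path, "fit": fit_path, "latents": latents_path,
        "summary": summary_path, "events": events_path,
    }
    manifest = {
        "version": __version__,
        "config": config.model_dump(mode="json"),
        "stage_seeds": stage_seeds,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
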