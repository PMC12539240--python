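"""Export fMRI event files with value and RPE parametric modulators.

Simulates a run, fits it, computes trial-wise latents under the fitted
parameters, and writes a BIDS-style events TSV: stimulus events carry the
normalized chosen value, feedback events the reward prediction error.
"""

from pathlib import Path

from rlddm import (
    OptimizerConfig,
    RLDDMParams,
    build_events,
    compute_latents,
    fit_run,
    generate_stimulus_sets,
    generate_trial_schedule,
    preprocess_run,
    simulate_run,
    write_bids_events,
)

schedule = generate_trial_schedule(generate_stimulus_sets(seed=1)["TV"], seed=2)
run = preprocess_run(simulate_run(schedule, RLDDMParams(0.25, 2.5, 1.0, 4.0), seed=3))
fit = fit_run(run, optimizer_config=OptimizerConfig(population=24, generations=40), seed=4)
latents = compute_latents(run, fit.params)
events = build_events(run, latents)

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "tv-run_events.tsv"
write_bids_events(events, path)
print(events.head(8).to_string(index=False))
print(f"\n{len(events)} rows written to {path}: one stimulus and one feedback "
      "event per trial; 'n/a' modulators mark omission/outlier no-interest events.")
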