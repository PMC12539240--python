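"""Generate a synthetic run of the multisensory learning task.

Builds the stimulus sets for both modalities, then a 44-trial pseudo-random
schedule with 10 % reversed feedback, and prints the first trials.
"""

from rlddm import generate_stimulus_sets, generate_trial_schedule

sets = generate_stimulus_sets(seed=1)
for modality, sset in sets.items():
    print(f"{modality}: cues {sset.cues} (complexity {sset.cue_complexity})")
    print(f"    matching map {sset.matching}")

schedule = generate_trial_schedule(sets["AV"], reversal_rate=0.10, seed=2)
df = schedule.to_frame()
print(f"\n{schedule.n_trials} trials, {int(df['reversed'].sum())} with reversed feedback")
print(df.head(6).to_string(index=False))
print("\nEach row is one trial: the cue sounds while two symbols are shown; "
      "'correct_side' marks where the matching symbol sits, 'reversed' flips "
      "the feedback valence, and onsets are seconds on the run clock.")
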