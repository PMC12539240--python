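"""Small parameter-recovery study.

Draws 20 parameter sets from plausible ranges, simulates a 176-trial run for
each, refits, and reports how well each parameter is recovered. (The full
validation uses 100 runs; see scripts/acceptance.py.)
"""

from rlddm import recover_parameters

report = recover_parameters(n_runs=20, trials_per_run=176, seed=5)
print(f"{report.n_runs} runs x {report.trials_per_run} trials")
print(f"{'parameter':>10} {'pearson':>8} {'spearman':>9} {'bias':>8} {'rmse':>8}")
for p in ("eta", "a", "tau", "vmod"):
    print(f"{p:>10} {report.pearson[p]:8.3f} {report.spearman[p]:9.3f} "
          f"{report.bias[p]:8.3f} {report.rmse[p]:8.3f}")
print("\nHigh correlations mean the 44-trial-per-cue design carries enough "
      "information to identify the learning and decision parameters; the "
      "learning rate is intrinsically the hardest.")
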