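"""Validate the estimators by parameter recovery.

For each learner model, simulate a set of sessions with known input
exploration variance, estimate it per session with both methods and
summarize the similarity ratio (mean +/- SD across sessions). Perfect
estimation gives a mean similarity ratio of 1. A reduced set size is
used here so the example runs in seconds; the systematic pattern
matches the full-size study.
"""

from explorevar import Model, aggregate_sr, draw_noise_vectors, run_simulation_set

N_SIMS, N_TRIALS = 300, 500
draws = draw_noise_vectors(N_TRIALS, N_SIMS, seed=0)  # shared across models

print(f"{N_SIMS} simulations x {N_TRIALS} trials, default parameters\n")
print(f"{'model':<12} {'TTC mean SR':>12} {'ATTC mean SR':>13} {'ATTC SD':>8}")
for model in Model:
    simset = run_simulation_set(model, draws=draws, seed=0)
    ttc = aggregate_sr(simset, "ttc")
    attc = aggregate_sr(simset, "attc")
    print(
        f"{model.value:<12} {ttc.mean:>12.2f} {attc.mean:>13.2f} "
        f"{attc.sd:>8.2f}"
    )
print(
    "\nThe TTC method underestimates exploration under the adaptive\n"
    "criterion; the lag-2 ATTC method recovers it much better, at the\n"
    "price of larger per-session spread (it uses fewer changes). The\n"
    "Dhawale19 learner regulates exploration by a full reward history,\n"
    "which a single-variance estimator captures only erratically."
)
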