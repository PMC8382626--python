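"""One-at-a-time parameter sweep (reduced scale).

Varies the learning fraction and the reward criterion while holding
everything else at the defaults, and tabulates the mean similarity
ratio per simulation set. The full study grid (five values for each of
five parameters, 1000 simulations per set) is available via
``explorevar.sweep()`` with no ``grid`` argument or the ``explorevar
sweep`` shell command.
"""

import pandas as pd

from explorevar import Model, sweep

frame = sweep(
    models=[Model.THERRIEN16, Model.CASHABACK19],
    grid={
        "alpha": [0, 0.15, 1],
        "criterion": ["random", "adaptive_mean", "fixed"],
    },
    n_sims=200,
    n_trials=500,
    seed=0,
)

table = frame.pivot_table(
    index=["param", "value"], columns=["model", "method"], values="mean_sr"
)
with pd.option_context("display.width", 120):
    print(table.round(2).to_string())
print(
    "\nMean similarity ratios per set (200 simulations each): the TTC\n"
    "estimate drops sharply at learning fraction 0 and under random\n"
    "reward. The ATTC estimate is unbiased under random reward and much\n"
    "closer to 1 overall, but retains some upward bias when a\n"
    "performance-dependent criterion is combined with little or no\n"
    "learning."
)
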