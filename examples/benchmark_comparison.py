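"""Compare four optimizers on the shifted/rotated Rastrigin benchmark.

Runs 30 independent trials per algorithm (D = 10, population 20, 25
generations) on seeded self-generated instances and prints the mean and
sample std of the per-trial best objective values.  The function's global
optimum is 500, so "mean - 500" is the average residual error; a smaller
mean means a stronger optimizer under this tight evaluation budget.
"""

from quadtune import OptimizerConfig, Strategy, run_trials

for strategy in (Strategy.PSO, Strategy.DE_BEST_1, Strategy.DE_RAND_TO_BEST_1,
                 Strategy.DE_IMPROVED):
    config = OptimizerConfig(D=10, lower=-100.0, upper=100.0, strategy=strategy,
                             N=20, G=25, seed=2024)
    stats = run_trials("F5", config, n_trials=30)
    print(f"{strategy.value:24s} mean {stats.mean:7.2f}  std {stats.std:6.2f}")

print("\nLower is better; 500 is the theoretical optimum of this function.")
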