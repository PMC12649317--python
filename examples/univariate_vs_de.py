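"""Head-to-head: parameter-at-a-time search vs the improved DE.

The instrument couples DP and EP through a rotated covariance, so optimizing
one parameter at a time converges to a ridge point instead of the joint
optimum.  Five paired seeds are run with both methods; the improved DE
consistently reaches a lower fitness (higher peak intensities).
"""

import numpy as np

from quadtune import VirtualInstrument, autotune, univariate_search

print(f"{'seed':>4s} {'univariate':>12s} {'improved DE':>12s} {'gain %':>8s}")
for seed in range(5):
    uni = univariate_search(VirtualInstrument(seed=seed),
                            rng=np.random.default_rng(seed))
    de = autotune(VirtualInstrument(seed=seed), rng=np.random.default_rng(seed))
    gain = 100.0 * (np.mean(de.intensities) / np.mean(uni.intensities) - 1.0)
    print(f"{seed:4d} {uni.fitness:12.4f} {de.fitness:12.4f} {gain:+8.1f}")

print("\nFitness is the weighted reciprocal intensity (lower is better); the "
      "last column is the mean-intensity gain of the evolved tuning.")
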