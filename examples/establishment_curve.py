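"""Establishment probability of a beneficial allele vs its selection coefficient.

A single variant copy is dropped into a panmictic population and followed
until fixation or loss; the Monte Carlo fixation rate is compared with the
closed forms 1 - exp(-2s) and Haldane's 2s. Runs in under a minute.
"""

import numpy as np

from gridpop import (
    SimulationParams,
    establishment_probability,
    estimate_establishment,
    haldane_approximation,
)

N = 4000
TRIALS = 3000

print(f"Panmictic establishment of a single copy (N={N}, {TRIALS} trials/point)")
print(f"{'s':>6} {'simulated':>10} {'95% CI':>19} {'1-e^-2s':>9} {'2s':>7}")
for s in (0.02, 0.05, 0.2, 0.5):
    params = SimulationParams(
        N=N, panmictic=True, s_het=s, s_hom=s, init_copies=1, max_generations=50_000
    )
    res = estimate_establishment(params, TRIALS, master_seed=42)
    print(
        f"{s:6.2f} {res.p_hat:10.4f} [{res.ci_low:8.4f},{res.ci_high:8.4f}] "
        f"{establishment_probability(s):9.4f} {haldane_approximation(s):7.2f}"
    )

print(
    "\nThe simulated rate tracks 2s for small s and bends below it as s grows."
    "\nAt large s the individual-based rate follows the Poisson branching"
    "\nsurvival, a few percent below the exponential interpolation."
)
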