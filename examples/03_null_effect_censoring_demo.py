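"""How significance censoring manufactures an effect out of nothing.

Simulates literatures with a true effect of exactly zero in which only 5%
of non-supportive studies are published, then compares the naive pooled
estimate with the trim-and-fill and PET corrections across replicates.
"""

import numpy as np

from metabias import (
    SimulationConfig,
    excess_significance_test,
    fixed_effect,
    pet,
    simulate_literature,
    trim_and_fill,
)

reps = 50
naive, corrected_tf, corrected_pet, flagged = [], [], [], 0
for seed in range(reps):
    lit = simulate_literature(
        SimulationConfig(delta_true=0.0, k_published=100, publish_prob_nonsig=0.05, seed=seed)
    )
    naive.append(fixed_effect(lit.published).theta)
    corrected_tf.append(trim_and_fill(lit.published).fe_corrected.theta)
    corrected_pet.append(pet(lit.published).b0)
    flagged += excess_significance_test(lit.published, basis="fixed").binom_p < 0.05

print(f"true effect:                 0.00")
print(f"naive fixed-effect estimate: {np.mean(naive):+.3f} (mean over {reps} literatures)")
print(f"trim-and-fill corrected:     {np.mean(corrected_tf):+.3f}")
print(f"PET intercept:               {np.mean(corrected_pet):+.3f}")
print(f"excess-significance flagged: {flagged}/{reps} literatures")
print(
    "\nThe naive estimate is pure selection artifact.  Trim-and-fill removes "
    "part of the bias but under-corrects; PET lands near zero (here slightly "
    "below it — the regression over-corrects when selection is this strong). "
    "The binomial test flags essentially every censored literature."
)
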