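"""Compare estimator bias under directional pleiotropy.

30% of variants carry a positive direct effect on the outcome (independent
of instrument strength, so InSIDE holds).  IVW absorbs that average direct
effect and is biased upward; MR-Egger's free intercept soaks it up and its
slope stays near the truth; the weighted median resists because valid
variants still hold a majority of the weight.
"""

import numpy as np

from summr import (
    SimulationConfig,
    ivw,
    median_estimator,
    mr_egger,
    simulate_summary_data,
)

true_beta = 0.1
n_rep = 100
results = {"ivw": [], "egger_slope": [], "egger_intercept": [], "weighted_median": []}
for rep in range(n_rep):
    data = simulate_summary_data(
        SimulationConfig(
            n_variants=100, true_beta=true_beta, regime="directional_inside",
            invalid_fraction=0.3, pleiotropy_mean=0.01, pleiotropy_sd=0.005,
            seed=1000 + rep,
        )
    )
    results["ivw"].append(ivw(data).estimate)
    fit = mr_egger(data)
    results["egger_slope"].append(fit.slope.estimate)
    results["egger_intercept"].append(fit.intercept.estimate)
    results["weighted_median"].append(
        median_estimator(data, variant="weighted", n_boot=2, seed=rep).estimate
    )

print(f"true causal effect: {true_beta}; mean estimates over {n_rep} replicates:")
for name, vals in results.items():
    target = 0.0 if name == "egger_intercept" else true_beta
    print(f"  {name:17s} {np.mean(vals):+.4f}   (bias {np.mean(vals) - target:+.4f})")
print("\nThe Egger intercept should sit near the average per-variant "
      "pleiotropic effect (0.3 x 0.01 = 0.003), while its slope stays "
      "closest to 0.1; IVW carries the largest bias.")
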