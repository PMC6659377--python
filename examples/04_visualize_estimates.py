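"""Write the two standard summary-MR figures.

The scatter plot shows each variant at (exposure association, outcome
association) with outcome-side error bars and one line per estimator —
the slope of each line is that method's causal estimate.  The density plot
shows the smoothed distribution of per-variant ratio estimates that the
mode estimator maximizes, with the mode marked.
"""

from pathlib import Path

from summr import (
    PlotSpec,
    SimulationConfig,
    ivw,
    median_estimator,
    mode_density_plot,
    mr_egger,
    scatter_plot,
    simulate_summary_data,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

data = simulate_summary_data(SimulationConfig(n_variants=60, true_beta=0.1, seed=11))
estimates = [
    ivw(data),
    mr_egger(data),
    median_estimator(data, variant="weighted", n_boot=200, seed=11),
]

scatter = scatter_plot(
    data, estimates,
    PlotSpec.from_estimates(estimates, output_path=str(out / "scatter.svg")),
)
density = mode_density_plot(data, spec=PlotSpec(output_path=str(out / "density.svg")))
print(f"wrote {scatter} and {density}")
print("In the scatter, all three lines should nearly coincide (no pleiotropy "
      "was simulated); in the density, the marked mode sits near 0.1.")
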