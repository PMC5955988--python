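"""Estimate axon totals by 20% systematic grid sampling.

Simulates treated- and untreated-eye optic-nerve cross-sections as Poisson
axon fields with the study's printed densities and degeneration fractions,
runs the grid-sampling estimator on each, and prints the group comparison.
"""

from onhlab.axons import compare_groups, estimate_totals, grid_sample_counts
from onhlab.synthetic import AxonFieldParams, generate_axon_field

untreated = generate_axon_field(
    AxonFieldParams(density_per_mm2=84_440 / 0.22, degenerating_fraction=0.033, seed=1)
)
treated = generate_axon_field(
    AxonFieldParams(density_per_mm2=80_397 / 0.22, degenerating_fraction=0.094, seed=2)
)

est_u = estimate_totals(grid_sample_counts(untreated, 0.20, seed=10), untreated)
est_t = estimate_totals(grid_sample_counts(treated, 0.20, seed=11), treated)
rep = compare_groups(
    est_t.total_axons, est_u.total_axons, est_t.percent_degenerating, est_u.percent_degenerating
)

print(f"untreated: {est_u.total_axons:9.0f} axons, {est_u.percent_degenerating:4.2f}% degenerating")
print(f"treated  : {est_t.total_axons:9.0f} axons, {est_t.percent_degenerating:4.2f}% degenerating")
print(f"relative axon loss      : {rep['relative_loss_pct']:4.1f} %")
print(f"degeneration ratio      : {rep['degeneration_ratio']:4.1f} x")
print()
print(
    "Totals are mean sampled density x nerve cross-sectional area; with the\n"
    "printed group means the report reads ~5% loss and a ~2.9x ratio."
)
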