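"""Simulate a chromosome polymer and recover its folding parameters.

Generates 1000 traces of a fractional-Brownian polymer calibrated to a
compact-chromosome regime (step size a = 1.03 µm at 1 Mb, scaling
exponent s = 0.198), averages their pairwise distances into a mean
distance matrix, and fits d = a * g**s back.  The printed estimates
should bracket the simulation inputs within their 95% CIs: a is the mean
spatial distance between loci 1 Mb apart (compaction), and s describes
how distance grows with genomic separation (0.5 = random walk; ~0.2 =
strongly intermixed chromosome).
"""

from haplotrace import (
    PolymerParams,
    default_region_coords,
    fit_power_law,
    mean_distance_matrix,
    simulate_traces,
)

params = PolymerParams(a=1.030, s=0.198, region_coords=default_region_coords(21),
                       seed=1)
traces = simulate_traces(params, 1000)
matrix = mean_distance_matrix(traces, params.region_coords)
fit = fit_power_law(matrix, traces=traces)

print(f"simulated {len(traces)} traces over {params.region_coords.size} regions")
print(f"true parameters: a = {params.a} um, s = {params.s}")
print(
    f"fitted: a = {fit.a:.3f} um (95% CI {fit.ci95_a[0]:.3f}-{fit.ci95_a[1]:.3f}), "
    f"s = {fit.s:.3f} (95% CI {fit.ci95_s[0]:.3f}-{fit.ci95_s[1]:.3f})"
)
print(f"fit used {fit.n_pairs} region pairs")
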