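"""Simulation-based comparison of three isolation scenarios.

Simulates the Fst distribution of each candidate scenario (small Ne + low
gene flow; small Ne + high gene flow; moderate Ne + low gene flow) at a
small replicate count and asks: does the 95% interval contain the observed
among-population Fst, what fraction of simulated pairwise distances is
significant, and how many simulations fall within 5-25% of the observation?

A desk-scale illustration (the full analysis uses thousands of replicates;
see scripts/acceptance.py for the calibrated desk-scale run).
"""

from isoscope import default_scenarios, run_scenario

OBSERVED_MT = 0.105  # among-population Fst, mtDNA, three isolates

print(f"observed mtDNA among-population Fst = {OBSERVED_MT}")
print(f"{'scenario':12s} {'median':>7s} {'95% interval':>17s} "
      f"{'sig.frac':>9s} {'within 25%':>11s}")
for spec in default_scenarios(markers=["mtdna"]):
    summary = run_scenario(
        spec, observed_fst=OBSERVED_MT, n_reps=60, n_perm=100, seed=5
    )
    lo, hi = summary.ci95
    contains = lo <= OBSERVED_MT <= hi
    print(
        f"{spec.name:12s} {summary.median_fst():7.3f} "
        f"[{lo:6.3f}, {hi:6.3f}]{'*' if contains else ' '} "
        f"{summary.significant_fraction:9.2f} "
        f"{summary.within_range_proportions[25]:11.2f}"
    )
print(
    "\n* = the observed value lies inside the simulated 95% interval."
    "\nThe isolation scenario (scenario1) produces the strongest and most"
    "\nconsistently significant differentiation; the alternatives leave a"
    "\nlarge share of simulated distances non-significant."
)
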