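"""Per-population diversity and neutrality statistics.

Builds the study-shaped synthetic dataset (four small population samples
with skewed haplotype frequencies) and prints the classical within-
population summary: sample size n, number of distinct haplotypes k,
haplotype diversity HD with its standard error, Fu's Fs with a simulation
p-value, Harpending's raggedness r, and the three theta estimators.
"""

import numpy as np

from isoscope import generate_study_fixture, population_summary

mt, _, manifest = generate_study_fixture(seed=0)

print(f"{'pop':8s} {'n':>3s} {'k':>3s} {'HD (sd)':>15s} {'Fs (p)':>15s} "
      f"{'r':>7s} {'theta_pi':>9s} {'theta_H':>8s}")
ss = np.random.SeedSequence(1)
for pop, seed in zip(mt.populations, ss.spawn(len(mt.populations))):
    div, neut = population_summary(mt, pop, p_reps=200, seed=seed)
    print(
        f"{pop:8s} {div.n:3d} {div.k:3d} "
        f"{div.hd:7.3f} ({div.hd_sd:.3f}) "
        f"{neut.fs:7.3f} ({neut.fs_p:.3f}) "
        f"{neut.raggedness_r:7.3f} {neut.theta_pi:9.3f} {neut.theta_h:8.3f}"
    )

print(
    "\nHD near 1 means almost every individual carries a distinct haplotype;"
    "\nstrongly negative Fs with a small p-value signals a haplotype excess"
    "\n(demographic expansion), while Fs near 0 is the isolation-compatible"
    "\npattern; small raggedness r indicates a smooth mismatch distribution."
)
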