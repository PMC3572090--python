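# isoscope

Detecting genetic isolation in small human populations from uniparental
markers (mtDNA control-region sequences and Y-chromosome STR profiles).

Small, recently founded communities — the motivating case is the
German-speaking "linguistic islands" of the Eastern Alps — may carry
detectable genetic signatures of isolation: reduced within-population
haplotype diversity, unusually high among-population differentiation, and
no signal of demographic expansion. Classical summary statistics alone
cannot separate true long-term isolation from the effects of small sample
size or modest drift, so `isoscope` pairs the classical statistics with a
structured-coalescent simulator: candidate micro-evolutionary scenarios
(founder size, gene flow between villages, split times) are simulated
forward from explicit priors and the *observed* differentiation is
compared against each scenario's simulated Fst distribution.

## What it computes

**Within-population statistics** (per population sample):

- haplotype diversity, Nei's estimator `HD = n/(n-1) (1 - Σ pᵢ²)` with its
  sampling standard error;
- the mismatch distribution and Harpending's raggedness
  `r = Σᵢ (xᵢ - xᵢ₋₁)²` over mismatch-class frequencies;
- θ estimators: θπ (mean pairwise differences), θS (Watterson's `S/a₁`) and
  θH (inversion of expected homozygosity, `θH = 1/F̂ - 1`);
- Tajima's D with the standard 1989 constants;
- Fu's Fs via the Ewens sampling formula,
  `Fs = ln(S′/(1-S′))` with `S′ = P(K ≥ k_obs | θ = θπ)`, the Stirling
  numbers of the first kind computed by exact log-domain recursion, and a
  p-value from neutral coalescent simulation.

**Among-population statistics**: one-level AMOVA on pairwise molecular
distances (sequence differences with pairwise deletion of gaps/ambiguous
sites; summed absolute repeat differences for STRs), Φst with a
permutation test, pairwise Φst matrices, Reynolds `-ln(1-Fst)` and Slatkin
`Fst/(1-Fst)` linearizations, delete-one jackknife intervals, and
nonmetric MDS of distance matrices.

**Scenario testing**: a structured-coalescent simulator for a
source + three-sinks demography (exponential growth, backward migration,
population splits; HKY mutation for sequence, symmetric stepwise mutation
for STRs), uniform priors over sink effective size, sink–sink gene flow
and split times, and the comparison machinery: simulated Fst
distributions, 95% percentile intervals, the fraction of simulated
pairwise distances reaching permutation significance, and the proportion
of simulations falling within 5–25% bands around an observed Fst.

## Worked example

`examples/04_scenario_comparison.py` simulates the three candidate
scenarios at desk scale and compares them with the observed mtDNA
among-population Fst of 0.105:

```
observed mtDNA among-population Fst = 0.105
scenario      median      95% interval  sig.frac  within 25%
scenario1      0.125 [ 0.025,  0.378]*      0.87        0.28
scenario2      0.048 [-0.004,  0.144]*      0.49        0.13
scenario3      0.031 [ 0.003,  0.079]       0.64        0.05
```

Scenario 1 ("small effective size, low gene flow") brackets the observed
value with a median close to it and makes most simulated pairwise
distances significant; the high-gene-flow and moderate-size alternatives
concentrate well below the observation and leave a large share of their
simulated distances non-significant. The other examples cover the
per-population statistics table (`01`), AMOVA/Fst/MDS (`02`), a single
simulator replicate (`03`) and representative subsampling (`05`); each
prints a short interpretation of its numbers.

A thin CLI wraps the same functions
(`isoscope stats|fst|amova|mds|simulate|scenario-test|subsample|validate|convert|make-fixtures`);
every command taking `--seed` is bit-reproducible.

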