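# Methods

This note documents the models, estimators, numerical choices and known
limitations of `isoscope`. Notation: n is a sample size, k a count of
distinct haplotypes, pᵢ haplotype relative frequencies, S the number of
segregating sites, θ a scaled mutation parameter.

## Data model and comparison conventions

Sequence data are pre-aligned haploid haplotypes over {A,C,G,T,-,N} with a
population label per record; STR data are integer repeat counts at an
ordered locus panel. Region labels ("HVR1", "HVR1+HVR2") are metadata
only — nothing indexes by genomic coordinate, because every statistic
operates on aligned columns.

Two comparison conventions are deliberately different:

- **Distances** (θπ, mismatch, AMOVA): sites with `-` or `N` in *either*
  sequence are excluded pairwise, mirroring the pairwise-deletion default
  of the classical population-genetics packages. STR distance is the sum
  over loci of absolute repeat differences; records with missing repeat
  calls (sentinel `NA`, never 0, since 0 is a legal allele label) are
  excluded from distance computations with a warning.
- **Haplotype collapsing** (k, HD, θH, Fs): full-string equality with `N`
  as a literal character, so an ambiguous base never merges two otherwise
  distinct haplotypes. This is conservative: k is reproducible and never
  depends on the order in which sequences are compared.

## Within-population estimators

- HD = n/(n−1)(1 − Σpᵢ²); its standard error is the square root of Nei's
  sampling variance
  2/(n(n−1)) {2(n−2)[Σpᵢ³ − (Σpᵢ²)²] + Σpᵢ² − (Σpᵢ²)²}.
- θπ is the mean of all pairwise differences; θS = S/a₁ with
  a₁ = Σ_{i<n} 1/i; θH inverts the infinite-alleles expectation of
  homozygosity, F̂ = Σpᵢ² = 1/(1+θ), giving θH = 1/F̂ − 1. An alternative
  stepwise-model inversion exists for microsatellites; the infinite-alleles
  convention was chosen because θH here is only used as a similarity
  feature, never as an absolute estimate.
- Tajima's D uses the standard 1989 normalizing constants and is reported
  as *undefined* (an exception, not 0) when S = 0.
- Harpending's raggedness r = Σ_{i=1}^{d+1}(xᵢ − xᵢ₋₁)², where x are the
  relative frequencies of mismatch classes 0..d and x_{d+1} = 0. Only the
  within-observed-range first differences plus the single trailing term
  enter the sum; there is no leading virtual class below zero differences.
- Fu's Fs: S′ = P(K ≥ k_obs | θ = θπ) under the Ewens sampling formula,
  P(K = k) = |s(n,k)| θᵏ / (θ(θ+1)…(θ+n−1)), with unsigned Stirling
  numbers of the first kind computed by the exact recursion
  |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| carried out entirely in the log
  domain (logaddexp), so no overflow occurs for any practical n. The
  p-value simulates neutral constant-size coalescent samples at θ = θπ
  (infinite-sites mutations on a Kingman genealogy) and reports the
  fraction with Fs ≤ the observed value. Degenerate simulated draws
  (monomorphic) count as "not as extreme". Fu's own guidance for a 5%
  test is p < 0.02; the raw p is always reported and any thresholding is
  left to the caller.

## AMOVA / Φst

One-level analysis of molecular variance on squared distances δ² (pairwise
differences are used directly as δ², the standard convention for haplotype
data): SSD(total) = Σδ²/(2N), SSD(within) summed per population,
σ²w = SSD(within)/(N−P), σ²a = (MS(among) − σ²w)/n_c with
n_c = (N − Σnₚ²/N)/(P−1), and Φst = σ²a/(σ²a + σ²w). Negative variance
components are retained in the raw Φst; a clamped-to-zero display value is
exposed separately. Significance is by random reassignment of individuals
to populations with sizes fixed, p = (b+1)/(m+1) where b counts permuted
Φst ≥ observed. Defaults: 1000 permutations for data analysis, 200 inside
simulation replicates (cost-bounded), α = 0.05.

Pairwise Φst matrices apply the same machinery to each pair of
populations, slicing one precomputed distance matrix. The Y-chromosome
AMOVA uses the summed-absolute-repeat-difference distance; a 0/1
haplotype distance can be obtained by collapsing profiles first.

Jackknife intervals are delete-one intervals (min, max of replicate
statistics). The default deletion unit is the individual: with only three
populations, population-level deletion leaves single-pair comparisons and
is degenerate, but it is available by flag for larger panels. Populations
with n ≤ 2 are protected from individual deletion so grouped statistics
remain defined.

## MDS

Nonmetric (monotone-regression) MDS via SMACOF started from the classical
Torgerson configuration, reporting Stress-1 = √(Σ(d̂−d*)²/Σd̂²). The
classical start plus single initialization makes the layout a
deterministic function of the input matrix. An all-zero matrix returns a
degenerate zero embedding with stress 0.

## Structured-coalescent simulator

Demography: a list of demes with sampling-time size ne₀ and forward
exponential growth g, so backward Ne(t) = max(ne₀·e^{−gt}, 1); a backward
migration matrix (m[i][j] = per-generation probability a lineage in i
traces to j); and split events moving all lineages of a child deme into
its parent. Effective sizes are haploid throughout — uniparental markers,
no ×2/×4 ploidy scaling — and all comparisons are internal to the model.

The event loop draws competing waiting times per deme: coalescence under
the time-inhomogeneous rate C(k,2)/Ne(t) by exact inverse-CDF time
rescaling (piecewise: exponential-decay segment, then the constant floor;
no thinning), and migration as homogeneous exponentials. Splits are
deterministic epoch boundaries. The unit floor on Ne guarantees
termination; configurations whose lineages are genuinely stranded
(disconnected demes, no future split) raise an error rather than loop.

The scenario demography is one large source plus three sinks. Fixed
settings: source Ne 10⁵ with growth 0.03, sink growth 0.017, split times
uniform on (32, 48) generations drawn independently per sink (the villages
were founded by separate events), source→sink flow 10⁻⁴ and sink→source
flow 10⁻³ (forward phrasing; converted to backward rates by swapping
direction, with a flag for the literal-backward reading), 50 samples per
sink, 333 bp for mtDNA. The source's backward shrink is capped at a
2000-generation horizon; with the default size and growth the unit floor
binds first (~384 generations), so the horizon is inert and results are
insensitive to it. Scenario priors: sink Ne uniform 100–300 (scenarios 1
and 2) or 700–900 (scenario 3); sink–sink migration uniform 0–0.005
(scenarios 1 and 3) or 0.015–0.02 (scenario 2). Y-chromosome counterparts
reuse the effective sizes with *all* gene flow halved, reflecting
patrilocality.

### Mutation layers

- **HKY** for sequences: rate matrix with transition/transversion ratio κ
  and stationary frequencies π, normalized to one expected substitution
  per site per rate unit; per-branch transition matrices come from the
  eigendecomposition of the π-symmetrized generator, and sites evolve
  independently down the tree from a stationary root draw. The
  whole-region rate (default 5.2023×10⁻⁵ per year, a control-region
  estimate) is converted to per-site, per-generation units with a
  25-year generation time. κ = 40 and π = (0.31, 0.31, 0.13, 0.25) are
  package defaults typical of the mtDNA control region, not externally
  fitted values.
- **Stepwise (SMM)** for STRs: per-locus Poisson mutation counts on each
  branch, each mutation ±1 repeat with equal probability, reflecting at
  the allele floor of 1. The five default locus rates (order DYS19, 390,
  391, 392, 393: 2.2, 2.1, 2.6, 0.5, 1.1 ×10⁻³ per generation) are
  package defaults in the range of published father–son estimates and are
  overridable per run.

A note on validation: the mutation generator is normalized to *realized
substitutions*, whereas matrix-mutation simulators that drop "events"
which may be silent use a slightly different rate convention; the
cross-validation tests therefore compare segregating-site distributions in
the Jukes–Cantor limit (where the conventions coincide) and validate the
κ-biased regime against a direct matrix-exponential closed form.

## Scenario testing

Per replicate: draw (sink Ne, sink–sink m, three split times) from the
priors, simulate a dataset, compute the among-all-sinks Φst and the three
pairwise Φst values with 200-permutation p-values. Summaries: the 95%
percentile interval of the overall Φst values (the paper-style
"distribution interval"; percentile chosen because the object summarized
is a simulated distribution, not an estimator), the fraction of
replicate×pair distances with p < α, and the proportion of overall Φst
values within ±5/10/15/20/25% of an observed value. Modal values for
sensitivity sweeps use a Gaussian KDE with Silverman bandwidth and a
512-point grid. Replicates consume independent child seeds spawned from
one seed sequence, so a summary is bit-reproducible and independent of
execution order; sweep grid points derive their seed from the grid value
itself, so duplicated grid points replay identical simulations.

The full-scale analysis uses 10⁴ replicates per scenario and marker. The
shipped acceptance script and test suite run 300 replicates per scenario
with 200 permutations — distribution quantiles and significance fractions
are stable at that scale (binomial SE on a fraction ≈ 1.7 percentage
points), and a complete run stays within a desk-session minute budget.

## Representative subsampling

The subsample score compares a candidate subset to the full pool on six
statistics (HD, mean Φst to a fixed 3-population synthetic panel, Fs,
Tajima's D, raggedness, θH): score = Σ|stat_sub − stat_full|/scale, where
each scale is the full pool's delete-one jackknife SE — a natural unit
that makes deviations comparable across statistics on different scales.
Undefined components (e.g. Tajima's D on a monomorphic subset, or a
zero-variance scale) are skipped and the sum is renormalized to the
six-component scale. The selection routine draws `n_draws` uniform
subsamples per candidate size and returns the minimum-score draw of the
preferred size plus the full evaluation table, so alternative similarity
criteria can be applied downstream. The combination rule is a package
design choice: the similarity criterion is exposed, not hard-coded into
the returned table.

## Synthetic data

The study-shaped fixture emulates the *shape* of the motivating dataset:
four mtDNA population samples of 40/59/48/46 drawn multinomially from
overlapping windows of a deterministic haplotype pool (pool members are
≥ 2 differences apart, so collapsing is unambiguous) with geometric
frequency skew, rejection-sampled until each realized HD lies in
0.88–0.98, the span observed across comparable small isolates; plus three
Y-STR populations of 50 with shifted repeat profiles. Every generator
parameter is recorded in a JSON-serializable manifest, so tests assert
against the manifest rather than magic numbers.

What the fixture does **not** emulate: real haplogroup composition,
site-specific mutation-rate heterogeneity, sequencing error, or missing
data patterns. Tests passing on these fixtures demonstrate algorithmic
correctness and calibration of the machinery, not conclusions about any
real population; conclusions about real data require running the same
pipeline on real alignments.

## Numerical choices and degenerate inputs

- Ewens/Stirling computations are entirely log-domain; probabilities sum
  to 1 within 10⁻¹⁰ for n ≤ 50 (and remain finite far beyond).
- Statistics undefined on an input raise `UndefinedStatisticError` rather
  than returning 0 (monomorphic Tajima's D and Fs, n < 2 diversity).
- Negative Φst is preserved raw, clamped only for display and before the
  Reynolds/Slatkin transforms; Fst = 1 transforms to infinity.
- AMOVA requires every population to have n ≥ 2; violations raise a
  degenerate-group error rather than producing NaNs.
- Permutation p-values use the (b+1)/(m+1) correction, so p = 0 is never
  reported at finite permutation counts.
- All stochastic entry points accept either a seed or a NumPy Generator;
  seeded runs are bit-reproducible.

## Known limitations

- No recombination, selection, or diploid genotypes in the simulator; no
  multi-level (3-tier) AMOVA; no haplogroup calling.
- The coalescent migration approximation treats per-generation migration
  probabilities as exponential rates; for m approaching 1 this would
  distort timing, but all study values are ≤ 0.02.
- Fu's Fs p-values use constant-size neutral coalescent replicates, the
  classical convention; they are not scenario-conditioned.
- The within-range proportions use the overall (among-all-sinks) Φst;
  pairwise values feed only the significance fraction.
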