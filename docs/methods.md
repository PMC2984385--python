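# Methods

## The mapping problem

One bi-allelic QTL with alleles Q/q and a purely additive substitution
effect segregates in a set of independent half-sib families: each sire
`i` has phased marker haplotypes `h_i = (h_i1, h_i2)`, and each progeny
`ij` (one per dam) contributes its paternally and maternally transmitted
marker haplotypes and a phenotype `y_ij`.  The task is to estimate the
QTL position on a dense cM map.  Both scans test every marker-interval
midpoint and report the argmax; ties break towards the smaller interval
index, and the estimated position is always an interval midpoint (the
unique symmetric choice, since neither method resolves within-interval
position).

## HaploMax

Per interval and per observed window haplotype `h` (windows of 2 or 4
flanking markers; 4-marker windows take two markers each side of the
interval, truncated at chromosome ends), the model
`y = sire + γ·dose_h + e` is fitted by least squares with the sire as a
fixed categorical effect, and γ is tested with the 1-df extra-sum-of-
squares F (numerator df 1, denominator df `n − Ns − 1`).  The sire
effects are absorbed by within-family centering (Frisch–Waugh), which
makes the interval statistic exactly equal to the full OLS fit (verified
against an explicit design-matrix fit to 1e-10) at a fraction of the
cost, and lets permutation nulls evaluate hundreds of permuted phenotype
vectors as one matrix product.  Haplotypes whose centered dose is
numerically zero (absent, universal, or confounded with families) are
skipped; an interval with no testable haplotype scores 0.

## HAPimLDL

The likelihood at a tested position `x` mixes Gaussians over the
unobserved QTL states:

* **Sire diplotypes.**  `P(Z_i = z | h_i)` for the four ordered
  diplotypes (QQ, qq, Qq, qQ) is the Hardy–Weinberg product of
  per-chromosome conditional allele probabilities.
* **Transmission (linkage).**  The probability that the allele a progeny
  received from its sire at `x` descends from each sire chromosome is
  computed exactly from the crossover-pattern probabilities between the
  two nearest sire-heterozygous ("informative") markers flanking `x`,
  under Haldane (no interference).  With one informative flank only that
  flank is used; with none the origins are equiprobable; at an
  informative marker the origin is observed.  Using only the nearest
  informative flanks ignores double crossovers past them — negligible at
  the sub-cM densities this package targets.  Calibration is tested by
  simulation: binned predicted origin probabilities match empirical
  origin frequencies over 10^4 simulated meioses.
* **LD evolution.**  `P(Q | h) = min(1, E[Π_{Q,h}(t)] / E[Π_h(t)])`,
  where expectations follow the Wright–Fisher / no-interference decay of
  Bennett multilocus disequilibria: each coefficient decays per
  generation by the probability of no recombination across its loci, and
  haplotype frequencies decompose over partitions into one block plus
  singletons.  That restricted partition family (all combinatorial
  coefficients equal one) is exact here because the markers are assumed
  to be in equilibrium when the mutation arises, so every marker-only
  coefficient is zero at time 0 and stays zero; the general coefficients
  required when 4+ linked loci carry marker LD are deliberately an
  unimplemented extension point.  The decomposition and its inverse
  round-trip random tables to 1e-12, and the closed-form `t`-generation
  frequencies match a direct deterministic iteration of the recombination
  dynamics on the full haplotype table (an oracle that never touches the
  Bennett algebra) to 1e-12 for 3-locus windows with arbitrary LD and
  5-locus windows with marker-equilibrium starts.
* **Time-0 state.**  `Π_{h,Q}(0) = (1−β) Π_h Π_Q(0) + β Π_Q(0) δ_{h=h*}`
  with β = 1 throughout (a brand-new mutation on founder haplotype h*);
  β < 1 is supported in code but not exercised.  Marker allele
  frequencies at time 0 are estimated from the observed parental
  haplotypes (sire chromosomes plus dam-transmitted haplotypes) — drift
  is frequency-neutral in expectation, so the sample estimate stands in
  for the unobservable founder frequencies.  Sires condition at `t`
  generations, dam-transmitted haplotypes at `t + 1` (one extra meiosis).
  `t` is an input, not estimated.

Degenerate cases: a window haplotype with expected frequency zero (a
monomorphic marker) falls back to the marginal `Π_Q(0)` so the
likelihood stays finite; per-progeny mixture densities are floored at
1e-300 before the log; σ² is floored at 1e-6.

### Maximization

Under the additive constraint the (diplotype, dam allele, origin) sum
collapses exactly to a three-component mixture with per-progeny weights
for effects (+α, 0, −α) — the collapse is tested against the full
enumeration to 1e-12.  For fixed mixture weights, (μ_1..μ_Ns, α, σ²) are
maximized by EM with a closed-form M-step (a two-level weighted least
squares), accelerated by squared extrapolation of consecutive EM steps
(SQUAREM) with a monotonicity safeguard; convergence is declared at
1e-8 on the log-likelihood (configurable).  σ² is extrapolated on the
log scale to stay positive.

The nuisances of the LD model are profiled: `h*` over the window
haplotypes observed in the sample (at most 4 for 2-marker windows, 16
for 4-marker), and `Π_Q(0)` continuously over `(10^-4, Π_{h*}]`.
Because the time-0 model makes every extended-haplotype frequency linear
in `Π_Q(0)`, the conditional probabilities are `min(1, Π_Q(0)·slope_h)`
with slopes computed once per (position, h*): the `Π_Q(0)` profile
(4-point geometric grid plus a bounded Brent refinement, warm-starting
the EM along the way) costs almost nothing beyond the EM itself.  A
candidate `h*` whose grid optimum trails the position's incumbent by
more than 2 log-likelihood units is not refined.  The LRT at each
position is `2(max log L − null log L)` against the null of per-sire
means and a common σ² (fitted once, in closed form); it is non-negative
by construction.

Because `h*` is a *discrete* profiled nuisance, the fixed-position null
LRT is a maximum over up to four correlated 2-parameter likelihood
ratios, not a single χ²₂ variable: its null median (≈2.8 in simulations)
sits above the χ²₂ median but below the median of the maximum of four
independent χ²₂ draws (≈3.68, an upper bound since positive correlation
shrinks a maximum).  Significance is therefore never taken from χ²
asymptotics; it comes from within-family permutation thresholds.

## The simulator

The generator emulates the historical process the LD model assumes, so
that the scans are evaluated under their own model class plus real
finite-population drift:

* Founders: `2 Ne` haplotypes with i.i.d. Bernoulli(1/2) marker alleles
  (linkage equilibrium; symmetric frequencies maximize marker
  informativeness).  `complete_LD` mode places the Q mutation on exactly
  one founder haplotype; `equilibrium` mode draws the QTL as one more
  independent Bernoulli(1/2) locus.
* Evolution: discrete Wright–Fisher generations — `2 Ne` gametes from
  parents drawn uniformly with replacement (or from the truncation-
  selected top `sel` fraction by simulated phenotype), Haldane crossovers
  between adjacent loci, optional marker mutation per meiosis (default
  0), the QTL never mutating after time 0.  Verified properties: allele
  frequencies are martingales, heterozygosity decays as
  `(1 − 1/(2Ne))^t`, and two-locus D decays as `(1 − c)^t` at large Ne.
* Design: `Ns` sires sampled without replacement from the final
  generation; each progeny receives a recombined paternal gamete from
  its sire and a maternal gamete from a dam drawn uniformly from the
  final generation (one progeny per dam).  With `Ns·Np` ≫ `Ne` the dams
  cannot literally be mutually unrelated; drawing maternal gametes from
  the evolved population is the standard gene-dropping resolution and
  matches the model's treatment of dam-transmitted haplotypes as
  generation `t + 1`.  Phenotypes are `y = a·(#Q) + N(0, σ²)`.
  Replicates with the QTL lost or no QTL-heterozygous sire are discarded
  and redrawn; the replicate counter advances only on accepted designs.
* Truncation selection retains the top `⌈sel · Ne⌉` individuals by
  phenotype as the breeding pool each historical generation.

What the generator does **not** emulate: real linkage maps with
interference, varying marker informativeness and allele-frequency
spectra, genotyping/phasing error, unequal family sizes, dam pedigrees,
polygenic background variation, or any demography beyond constant `Ne`.
Passing tests therefore demonstrate correctness of the methods under
their intended model class, not field performance on real livestock
data.

## Evaluation

* Accuracy: `root-MSE = sqrt(Σ_r (ŝ_r − s)² / R)` in cM, with a
  delta-method Monte-Carlo standard error `sd(sq.err)/(2·rmse·√R)`.
* Significance: phenotypes permuted *within* sire families (preserving
  the sire structure under the no-QTL null); the 5% threshold is the
  `⌈0.95·B⌉`-th order statistic of the permutation maxima (B = 1000 by
  default; the permutation unit and count are this package's choices —
  they were not fixed by the original study).  Empirical size under the
  null is ≈5% (tested).  Power is the fraction of replicates whose
  observed maximum exceeds their own threshold.
* Method comparison: paired t-test on per-replicate squared position
  errors, the two methods always scanning the same replicates.
* Reproducibility: every replicate draws its generator from a spawned
  child of one master seed, so tables are bit-reproducible and
  parallelizable.

### Problem sizes

The test suite and `scripts/acceptance.py` use 100–150 replicates per
scenario for HaploMax accuracy and power (200 permutations per
replicate), and 50 replicates for the likelihood scan — sizes chosen so
the Monte-Carlo standard error of a root-MSE near 2 cM is below 0.2 cM
and a full run completes in minutes on one CPU.  The original tables
used 500 replicates; all comparisons are made at 3 Monte-Carlo standard
errors of the reduced-scale estimate.

## Known limitations

* The transmission computation replaces an approximate published
  subroutine (whose internals are not documented) with an exact
  two-flank calculation; fidelity to the original approximation cannot
  be verified, only calibration against simulated meioses.
* Under strong truncation selection this generator reproduces the
  *direction* of the published degradation (selection worsens accuracy
  and inflates swept-haplotype frequencies) but not its magnitude; the
  original populations were simulated with a program whose selection
  internals are not described, and its selected scenarios show a
  near-total power collapse that phenotypic truncation at the stated
  fractions does not produce here.
* The scan evaluates interval midpoints only; a finer within-interval
  grid would change estimates by at most half the marker spacing.
* `Π_Q(0)` profiling at small sample sizes inflates the estimated
  effect magnitude (a winner's-curse effect inherent to maximizing over
  the LD nuisances); at the reference design scale the effect estimate
  at the true interval is well behaved (sign correct, bias under 50%).
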