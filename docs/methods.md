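# Methods

## The model

`gridpop` simulates a single autosomal biallelic locus in a diploid
population of constant census size `N` living on a square torus with one
individual per cell (density `d = 1`, side `L = round(sqrt(N))`, effective
census `L²` used everywhere). Mating is *socially localized*: the two
parents of the individual replacing a given cell are drawn through an
isotropic Gaussian kernel centred on that cell, with per-axis standard
deviation `σ` chosen so that the kernel realizes Wright's neighborhood
(effective community) size

    N_n = 4 π σ² d .

For human populations `N_n` is naturally bounded by Dunbar's number
(~150, range 100–230): the circle of stable social relationships from
which mates are effectively drawn. Distance on the grid is social
proximity, not geography; inbreeding, migration and local genetic drift
are emergent, not parameters.

Each generation is non-overlapping:

1. **Mortality.** An individual of genotype `g` dies with probability
   `p_death(g) = 1 − w_g / w_max`, where `w = (1, 1+s_het, 1+s_hom)` for
   (wild, heterozygote, variant homozygote) and `w_max = max w`.
   Survival-to-mating proportional to fitness realizes the defining
   property of `s` — carriers leave `(1+s)`-fold as many offspring in
   expectation — and the `w_max` normalization keeps all probabilities in
   `[0, 1]` for any `s ≥ −1`, including `s > 1`. The selection coefficient is defined through expected offspring
   counts, which does not fix the death rule; alternative mappings (baseline death rate, fecundity
   weights) preserve expected parentage ratios and could shift absolute
   equilibrium levels only slightly.
2. **Parent sampling.** For every cell of the fresh grid, two *distinct*
   surviving cells are drawn by sampling continuous Gaussian offsets,
   rounding to the nearest cell and wrapping on the torus (no edge
   effects). Draws landing on dead cells, or duplicating the first
   parent, are rejected and redrawn; after 1000 consecutive rejections
   the kernel width doubles (with a logged warning), which guarantees
   termination whenever at least two survivors exist while preserving
   locality in every realistic regime. The focal cell itself may be
   drawn (its previous occupant is a community member); selfing is
   excluded by the distinctness requirement. Fewer than two survivors
   anywhere raises a population-collapse signal, recorded as extinction.
   Sex is not modelled: any two distinct survivors can pair.
3. **Mendelian transmission.** Each parent contributes one allele;
   heterozygotes transmit the variant with probability 1/2.
4. **De novo mutation.** Each *wild* allele of the offspring converts to
   the variant independently with probability `mu` (per transmitted
   allele; 0 by default).

Initialization is either a Bernoulli field of heterozygotes
(`init_het_fraction`) or exactly `init_copies` heterozygous founders at
distinct uniform cells. Terminal states: *extinct* (zero variant
alleles), *fixed* (zero wild alleles), or the generation cap.

## Exact aggregated engine for panmictic runs

When the kernel is at least as wide as the torus (`panmictic`, or
`σ ≥ L`), the parent draw is uniform over survivors and spatial position
carries no information. The per-generation law of the genotype counts is
then exactly: binomial survivorship per genotype class; ordered draws of
two distinct survivors with genotype-pair probability
`c_i (c_j − δ_ij) / (A (A − 1))`; Mendelian mixing; the mutation
transition matrix; and a multinomial draw of `N` offspring. `gridpop`
runs panmictic trajectories through this O(1)-per-generation count
process (and, when a grid object is requested, places the offspring
uniformly at random). This is a distributional identity, not an
approximation — a regression test compares fixation rates of the two
engines on the same scenario — and it is what makes 5000-generation,
`N ≈ 10⁵` panmictic equilibria a matter of seconds.

## Closed forms

* **Establishment.** A single copy of an allele conferring advantage
  `s > 0` escapes loss by drift with probability `P ≈ 1 − e^(−2s)`
  (Haldane's `P ≈ 2s` for small `s`); `P = 0` exactly for `s ≤ 0`.
* **Balancing-selection equilibrium.** With parental selection weights
  `a : b : c = 1+s_hom : 1+s_het : 1` on genotype ratios `P : 2Q : R`,
  the interior equilibrium under random mating is Hardy–Weinberg with
  `p* = (b − c) / (2b − a − c)`; for a lethal homozygote (`a = 0`) this
  is `p = s/(1+2s)` and carrier fraction `2Q = 2s(1+s)/(1+2s)²`, with the
  small-`s` shortcut `2Q ≈ 2s/(1+4s)`. The implementation uses this
  closed form directly (the fixed point of the selection recursion is
  available in closed form for every overdominant case, so no iterative
  solver or tolerance is involved). The inverse problem — the `s`
  sustaining an observed carrier prevalence `T ∈ (0, 1/2)` — is the
  positive root of `(2−4T)s² + (2−4T)s − T = 0`; the round trip is exact
  to 10⁻¹⁰ over the whole domain.
* A known and deliberate property: the simulator's establishment
  probability follows the *branching-process* survival (offspring copies
  of a rare carrier are Poisson with mean `1+s`; survival solves
  `1 − P = e^{−(1+s)P}`), which agrees with `1 − e^(−2s)` to within a
  couple of percent for `s ≲ 0.05` but sits below it by ~5% at `s = 0.2`
  and ~8% at `s = 0.5`. This is intrinsic to any individual-based model
  with near-Poisson offspring variance, not a numerical artefact; the
  diffusion-based exponential form overestimates survival at large `s`.

## Monte Carlo drivers

* `estimate_establishment` — independent trials from `init_copies`
  founders; "established" means fixed, or, when `s_hom < 0` makes
  fixation unreachable, still segregating at the generation cap
  (the natural quasi-stationary reading). Reports a Wilson 95% interval,
  mean survival time of extinct trials, and mean maximum prevalence.
* `estimate_equilibrium` — averages the carrier fraction over the final
  20% of generations (default) and across runs; runs that go extinct
  contribute their zero tails (local die-outs genuinely depress the
  population average, so they are not censored or restarted).
* `sweep` — fills an `(N_n, s_het)` matrix with either estimator;
  per-cell derived seeds, per-cell failures recorded as NaN.
* Reproducibility: one `SeedSequence` per batch; identical master seeds
  give bit-identical trajectories and sweep matrices.

## Scenario presets and desk scales

| preset | parameters | notes |
|---|---|---|
| `cftr_panmictic` | `s_het = 0.02132`, `s_hom = −1`, panmictic, `N = 9×10⁶`, 5000 generations, start at 4% heterozygotes | equilibrates at ~4% carriers, the European CFTR carrier frequency |
| `cftr_dunbar` | `s_het = 0.0295`, `s_hom = −1`, `N_n = 150`, `N = 10⁸`, 3000 generations | the same 4% requires a ~38% larger advantage once mating is local |
| `lactase` | `s_het = s_hom = 0.1`, `N_n = 150`, `N = 5×10⁶`, 100 founders, 600 generations | purely beneficial spread from a rare base |
| `neutral_drift` | `s = 0`, `mu = 0` | drift-only control |

The `scale` knob shrinks `N` and founder counts proportionally (founding
*density* preserved) and is reported on the returned parameter object.
Equilibrium levels depend mainly on `N_n` and `s`, so shrinking `N` is
legitimate for equilibrium questions; establishment probabilities of
beneficial alleles are `N`-insensitive once `N ≫ 1/s`.

Problem sizes used by `scripts/acceptance.py` (chosen once as desk-scale
equivalents and documented here):

* CFTR panmictic equilibrium: `N = 9×10⁴` (from `9×10⁶`), 5000
  generations, 4 runs, final-20% averaging.
* CFTR with `N_n = 150`: `N = 10⁵`, `s_het ∈ {0.022, 0.026, 0.030,
  0.034}`, 1500 generations, 3 runs per point, final-25% averaging,
  linear interpolation of the 4% crossing.
* Lactase: `N = 2×10⁶` with 40 founders (founding density `2×10⁻⁵`
  preserved from the full-scale preset), 2 runs, horizon long enough to
  bracket generation 210 and the heterozygote peak.
* Generation-years conversion: 200 generations × 29 years.

## Lactase timing: what the founding base does

The spread of a purely beneficial allele under a Dunbar-limited kernel is
wave-like: each established founder cluster (a fraction `≈ P(s)` of
founders) expands as a stochastic Fisher wave with front speed of order
`σ √(2s)` cells/generation — measured at ~0.9–1.1 for `σ = 3.45`,
`s = 0.1`, i.e. the theoretical speed reduced by the usual
finite-density front correction. Time to 80% coverage therefore scales
as `sqrt(N / n_clusters) / c` and is controlled by the founding density,
which accounts of this scenario typically leave unspecified ("an initial
low base"). At the documented density of `2×10⁻⁵` the model crosses 80%
carriers at roughly twice the ~210 generations sometimes quoted; a
founding density a few-fold higher reproduces that faster timing. The
preset keeps the documented density; the timing sensitivity is inherent
and the reported quantities state the generation at which they are read.

## Numerical choices

* Genotypes are `int8` codes; the lattice engine is fully vectorized
  (float32 normal draws, int32 torus arithmetic, redraw loops operating
  only on still-pending cells). Throughput is ~10 ms/generation at
  `N = 10⁵` and ~0.4 s/generation at `N = 2×10⁶` on one core.
* `σ` is *not* rescaled after deaths within a generation: the kernel
  width is the controlled variable and `N_n` nominal; mortality-induced
  density fluctuation is part of the stochastic process.
* Discretization inflates the per-axis kernel variance to `σ² + 1/12`
  (rounding noise); negligible for every `N_n ≥ 3` and accounted for in
  the kernel tests.
* Equilibrium averaging windows and run counts trade variance against
  runtime; the defaults (20–25% tails, 3–4 runs) put Monte Carlo error
  well inside the 10% bands used for validation.
* Ties and degenerate inputs: `init_het_fraction = 0` with `mu = 0` is
  immediately extinct; `s_het = s_hom = −1` collapses the population
  (recorded, not raised, at the trajectory level); `n_n > N` is
  rejected; explicit `sigma` overrides `n_n`.

## What the synthetic scenarios do and do not show

All validation inputs are generated internally; there is no external
data. The model omits overlapping generations, age structure, explicit
sexes, multiple loci and linkage, spatially varying selection, and any
direct modelling of consanguinity or migration (the latter two emerge
from the kernel). Passing tests therefore demonstrate the internal
consistency of the model and its agreement with classical population
genetics in the appropriate limits — not that any particular human
population satisfies the model's assumptions. Estimates of `s` from an
observed prevalence inherit the assumptions that the population is at
equilibrium and that the variant is homozygous-lethal.
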