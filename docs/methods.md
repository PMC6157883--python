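# Methods

This note documents the model implemented by `umicorrect`, the numerical
choices behind it, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Amplification model

PCR is treated as a Galton-Watson branching process on single-stranded
molecules: in every cycle each existing copy of a family is duplicated
independently with the reaction efficiency `E ∈ [0, 1]`, perfectly or not
at all; no molecules are destroyed and `E` is constant across cycles.
Substitution errors, partial copies and plateau (late-cycle efficiency
decay) are deliberately outside the model — artifacts they produce are
handled by the read-count threshold instead. A double-stranded template
counts as two molecules; protocols in which both strands amplify under the
same UMI can divide corrected counts by two (`--umis-per-molecule 2`).

Family sizes obey `M₀ = 1`, `Mᵢ = Mᵢ₋₁ + Binom(Mᵢ₋₁, E)` with
`E[Mᵢ] = (1+E)ⁱ` and `V[Mᵢ] = ((1−E)/(1+E)) (1+E)ⁱ ((1+E)ⁱ − 1)`.
The normalized family size `F = lim Mᵢ/(1+E)ⁱ` exists almost surely; it
has mean 1 and variance `(1−E)/(1+E)`, and its distribution is what makes
read counts overdispersed relative to Poisson. The number of PCR cycles
drops out of the model entirely: the variance of `Mᵢ/(1+E)ⁱ` is
`((1−E)/(1+E))(1 − (1+E)⁻ⁱ)`, so the residual cycle dependence decays as
`(1+E)⁻ⁱ`. `E = 0` is rejected rather than special-cased: the family
never grows and the limit construction degenerates (the variance formula's
`E → 0` limit of 1 does not describe the process, whose rescaled variance
is 0).

### Pre-computed density table

`F` has no known closed-form density, so it is estimated by simulation:

* **Convergence criterion.** Each draw runs the branching process until
  `(1+E)ⁱ ≥ 10⁴` (cycle cap 2000), bounding the relative error of the
  variance against its limit by `10⁻⁴`.
* **Size grid.** Histogram bins of width 0.01 on `[0, 2]`, positioned so
  that `x = 1` is a bin *midpoint* (edges 0, 0.005, 0.015, …, 2.005),
  then geometrically widening bins (factor 1.06) up to the support cap of
  50. The midpoint-at-1 arrangement makes the `E = 1` column (all mass
  exactly at 1) reduce every downstream mixture integral to an exact
  Poisson formula, which anchors the degenerate limit of the whole chain.
* **Efficiency grid.** 0.02 to 0.92 in steps of 0.02, then 0.005 steps to
  0.96 and 0.0025 steps to 1.00. The refinement near 1 is needed because
  the density's two modes (families whose first copy succeeded vs failed,
  the latter near `x ≈ ½`) sharpen and shift quickly as `E → 1`, and a
  uniform 0.02 spacing no longer interpolates them to the accuracy target
  below. No extrapolation outside `[0.02, 1]`: below 0.02 convergence is
  pathologically slow and the limit distribution changes character.
* **Replicates.** `build_density_table` defaults to 10⁶ draws per
  efficiency for a production table; the table the package builds lazily
  (and the test suite's shared fixture) uses 10⁵, which keeps the build
  under ~20 s and still satisfies every table invariant (column integrals
  within 1 %, means within 3 %, variances within 5 % of `(1−E)/(1+E)`).
* **Interpolation.** Cubic spline across the efficiency axis (clipped at
  0), piecewise-linear along `x`; values at grid nodes are exact, the
  density is 0 beyond the grid end. Accuracy target: Kolmogorov-Smirnov
  distance below 0.01 between the interpolated CDF at an off-grid
  efficiency and fresh Monte-Carlo draws; this holds across the grid up
  to `E ≈ 0.985` (see Limitations).
* **Persistence and reproducibility.** Tables carry their grids, seed and
  replicate count and round-trip losslessly through a self-describing TSV
  (`save`/`load`, CLI `build-density`). All stochastic routines take an
  explicit seeded `numpy` generator; identical seeds give bit-identical
  tables, libraries and pipeline outputs.

## Read-count model

Sequencing is Poissonian sampling: `C | F ~ Poisson(F·D)` with `D` the
mean reads per molecule, assuming every copy is equally likely to be
sequenced and sampling is sparse. Marginally `P(C = k)` is the mixture
`∫ Poisson(k; xD) f_F(x; E) dx`, integrated by the midpoint rule on
exactly the table's grid (no adaptive quadrature, for reproducibility);
`E(C) = D`, `V(C) = D + D² (1−E)/(1+E)`.

With an error-correction threshold `T` the observable distribution is
censored at `C ≥ T` and the **loss** is `ℓ = P(C < T)` — the expected
fraction of true molecules that are unsequenced or filtered. Censored
moments are computed by rewriting the infinite sums as
`E(C) − Σ_{k<T} k·P(C = k)` (and likewise for the second moment); the
totals entering the rewrite are taken under the same quadrature measure as
the pmf (total mass `Z`, `E(C) = D·m₁` with `m₁` the quadrature mean of
`F`), which keeps the rewrite exact even when the surviving tail mass is
comparable to the table's Monte-Carlo error. Probabilities below 10⁻³⁰⁰
are clamped to 0; censored moments are refused when `P(C ≥ T) < 10⁻¹²`.

A truncated-Poisson baseline (`poisson_loss_baseline`) fits a plain
Poisson rate by matching the T-censored Poisson mean to the observed
censored mean and reports `P(Poisson < T)`. It equals the model at
`E = 1` and is otherwise a lower bound on the loss at the same censored
mean — a quantitative demonstration of why ignoring amplification
stochasticity underestimates lost molecules severely.

## Estimation

Parameters are estimated by the method of moments from the censored
sample mean `m̂` and variance `v̂` (unbiased estimators) of the surviving
read counts:

* `T = 0`: closed form, `D̂ = m̂` and `Ê = (1−v′)/(1+v′)` with
  `v′ = (v̂ − m̂)/m̂²` clamped to `[0, 1]`; clamping (over/under-dispersed
  samples) is flagged (`at_boundary`).
* `T > 0`: nested bracketed root-finding. The censored mean is strictly
  increasing in `D` at fixed `E`, so `D(E)` is solved by Brent's method in
  `log D` over `[10⁻⁴, 10⁶]`; an outer search drives the censored-variance
  residual to zero over the table's efficiency range. The outer search
  first evaluates the residual at every efficiency column of the table:
  under heavy censoring the residual between columns carries the columns'
  independent Monte-Carlo noise and can produce spurious sign changes, so
  refinement is restricted to the bracket with the smallest endpoint
  residual. Inner solves run near machine precision — under deep censoring
  the moment map is badly conditioned (parameter changes of order 0.1 can
  move the censored moments by only ~10⁻⁵) and looser tolerances select
  visibly wrong roots. When no sign change exists the moment pair lies
  outside the model's attainable region; `E` is clamped to the
  better-fitting edge of the domain and the fit is flagged.

The fitted parameters give `ℓ̂` through the loss formula and the corrected
count `n̂ₜₒₜ = n_obs/(1 − ℓ̂)`, reported unrounded (a rounded column is
provided for convenience).

The pipeline always censors estimation at `max(T, 1)` even when the user
filter removes nothing (`T ≤ 1`): molecules with zero reads are never
observable, so the data are intrinsically censored at one read.

## Shrinkage

Raw per-gene losses are noisy for genes with few surviving UMIs. Writing
`s` for the between-gene variance of the true loss and `u/n` for the raw
estimator's variance at `n` observed UMIs, the MSE-optimal combination
with the library-wide estimate is `λ = s/(s + u/n)`. `(s, u)` are fitted
by weighted least squares of `(ℓ̂ᵍʳᵃʷ − ℓ̄)²` on `1/n` with weights
`w(n) = n/(1 + n/100)`, which emphasise moderately observed genes;
non-negativity is enforced by clip-and-refit (negative coordinates are
fixed at zero and the other re-solved), since negative variance components
are meaningless. `ℓ̄` is the unweighted mean of the valid raw losses
(the normalisation is per gene; a per-UMI normalisation would be
dimensionally inconsistent).

Genes with fewer than two surviving UMIs or a failed fit get `λ = 0`
(library-wide loss) and are excluded from the regression. The same `λ` is
applied to `E` and `D` for *reporting* shrunken parameters; the count
correction uses the shrunken loss exclusively.

## Synthetic libraries

The generator draws per-UMI read counts from exactly the model above:
per gene, `n_true` independent `F` draws (inverse-CDF sampling from the
density table, uniform within bins — validated against the direct
branching process at KS < 0.01) and Poisson reads at the gene's depth.
Zero-read UMIs are omitted from the output, as in real data. Phantoms are
injected as an explicit artifact convention, not a mechanistic claim:
Poisson(rate × n_true) extra UMIs per gene with truncated-geometric read
counts (support ≥ 1, mean 1.5 reads), matching the qualitative signature
of phantoms as over-abundant at low read counts; a hidden truth label is
retained for evaluation. UMI identifiers are sequential labels — barcode
sequence space, UMI collisions and sequencing errors on reads are not
simulated, so passing tests say nothing about sequence-level artifact
modes (those are assumed to be handled by upstream UMI merging tools).

The bundled study designs (used by the acceptance tests and
`scripts/acceptance.py`):

* **Multi-tier accuracy.** 7 abundance tiers (10–10 000 molecules) × 30
  genes, `E ~ U(0.25, 0.8)`, `D = 6`, `T = 5`. Because a single 30-gene
  tier gives the per-tier median a sampling SD of several percent, the
  tests pool several seeded replicate libraries of the same design before
  taking medians.
* **Low depth.** The same design with depths rescaled to a mean of one
  read per molecule and `T = 1` (the loss is then the unsequenced
  fraction, ~40–45 % here).
* **Phantom separation.** A deeply sequenced library (`D = 300`,
  `E = 0.65`, phantom rate 0.2, `T = 5`), mirroring protocols with a few
  hundred reads per UMI. Threshold-based phantom removal is only pure
  when the depth is well above the threshold; at shallow depth the
  filtered set necessarily contains many true UMIs, which is a property
  of the method, not of the implementation.

## Known limitations

* **Shrinkage target under strong heterogeneity.** The shrinkage pulls
  gene losses toward the *pooled* library-wide estimate. A single-(E, D)
  fit to a strongly heterogeneous mixture of genes overestimates the
  dispersion, hence the pooled loss exceeds the average per-gene loss,
  and corrected counts of weakly expressed genes inherit that excess
  (about +10 % at the 10-molecule tier of the multi-tier design above,
  vanishing for well-observed genes as `λ → 1`). With realistic, milder
  between-gene variation the discrepancy is at the percent level. The
  pooled target is kept because it is the method's defining convention
  and is robust for sparse libraries; users with very heterogeneous
  libraries should trust per-gene corrections primarily where `λ` is
  close to 1.
* **Efficiencies above ~0.985.** The family-size density approaches a
  point mass as `E → 1` and no fixed grid interpolates the near-delta
  region to the KS < 0.01 target; read-count quantities remain accurate
  there because the Poisson kernel smooths over `x`.
* **Deep censoring.** When `P(C ≥ T)` is tiny the (E, D) moment map is
  nearly non-invertible; fits are still returned (the solver resolves the
  near-flat residual deterministically) but small data perturbations move
  the parameter estimates substantially. The loss estimate — the quantity
  that matters for correction — is far more stable than the individual
  parameters in this regime.
* **Estimator noise floor.** At 10⁵ UMIs, `(E = 0.6, D = 4)`, `T = 5`,
  the censored moment estimator has sampling SDs of ≈0.017 in `Ê` and
  ≈0.07 in `D̂`; these are properties of moment matching at this censoring
  level, not of the implementation.
* The model excludes PCR substitution errors, plateau effects, UMI
  barcode collisions and read-level sequencing errors, and the phantom
  generator is a labelled convention for testing the filter, not a model
  of phantom formation.
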