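# Methods

## Model

`surveylca` fits latent class models to an `n × p` matrix of categorical
responses `y_ij ∈ {1, …, d_j}` — in the motivating application, coded
consumption levels of `p` food groups. Conditional on membership in class
`k` (out of `K`), items are independent multinomials:

    Pr(y_i | θ, π) = Σ_k π_k Π_j θ_{j, y_ij | k}

with class probabilities `π` on the simplex and item-response
probabilities `θ_{j·|k}` on the `d_j`-simplex.

**Overfitting as model selection.** `K` is fixed far above the plausible
number of classes (default 50) and the symmetric Dirichlet prior on `π`
is made sparse (`α = 1/K`). Superfluous classes then empty out during
sampling, approximating a Dirichlet-process mixture, and the number of
occupied classes is read off the posterior instead of being chosen by
repeated fits and information criteria. Item-response distributions get a
flat `Dir(1, …, 1)` prior (`γ = 1`): every level keeps nonzero mass, so
classes stay interpretable even for rarely endorsed levels.

**Survey weighting.** Each subject carries a design weight `w_i`
(inverse inclusion probability, possibly nonresponse/calibration
adjusted). With the normalisation constant `κ = Σ_i w_i / n`, the
pseudo-likelihood raises subject `i`'s contribution to the power
`w̃_i = w_i/κ`. Normalising by `κ` makes the weights average to one, so
posterior spread reflects the sample size `n` while point estimation
targets the population: `π_k` becomes the *population* prevalence of
pattern `k`. The conjugate structure survives: the full conditionals for
`π` and every `θ_{j·|k}` are Dirichlet with weighted counts
`(1/κ) Σ w_i 1(·)` in place of cell counts.

**Class-assignment conditional.** The complete-data conditional implied
by the pseudo-likelihood is tempered,
`P(z_i = k) ∝ [π_k Π_j θ_{j,y_ij|k}]^{w̃_i}`, and this is the default, so
that the three Gibbs updates are the exact conditionals of one coherent
pseudo-posterior (the collapsed form of which is verified against
exhaustive enumeration in the test suite). An untempered variant
(exponent 1) is available via `SamplerConfig(tempered_z=False)` for
sensitivity analysis. All class-mass computations run in the log domain
(`p = 50` probability products underflow otherwise) with Gumbel-max
categorical sampling; probabilities are floored at 1e-300 before logs to
guard against exact zeros from near-degenerate Dirichlet draws.

With unit weights every formula reduces to the ordinary latent class
model, and the weighted and unweighted code paths are identical draw for
draw under a shared seed — this degeneracy is asserted exactly in the
tests.

## Sampler initialisation: the warm start

From uniformly random labels, an overfitted mixture first coalesces into
many small clusters and then grows them; plain Gibbs has no merge move,
so two persistent clusters representing the same true class can only
merge by one losing its members individually. With unequal weights this
barrier can become insurmountable: tempering makes high-weight subjects'
conditionals very sharp (sticky), and in a noisy regime (within-class
modal probability 0.55) weighted chains were observed to hold a true
pattern split in two for 25,000+ iterations. A chain initialised at the
generating partition, by contrast, holds the correct three-class
structure indefinitely — the failure is a mixing barrier, not the
pseudo-posterior's preference.

The default `init="warm"` therefore runs the first
`min(burn_in/2, 1000)` sweeps with unit weights — the well-mixing
unweighted kernel — before the weighted kernel takes over. Retained
draws always come from the configured kernel; unweighted runs are
unaffected (their warm phase *is* the sampler), and the unit-weight
degeneracy above still holds exactly. `init="uniform"` disables the warm
phase.

A random permutation move (`permute_labels=True`) is available to
encourage label-space mixing; it relabels `(π, θ, z)` consistently each
sweep and leaves the likelihood invariant. It is off by default: all
reported summaries are label-free or relabelled in postprocessing.

## Postprocessing

Mixture likelihoods are invariant to relabelling, so raw chains scramble
class-specific summaries. The pipeline is built on the label-free
co-clustering matrix `S_ab` = fraction of retained draws assigning
subjects `a` and `b` to the same class:

1. **How many classes.** A class "exists" in an iteration if it holds at
   least 5% of the sampled subjects (unweighted shares; the boundary is
   inclusive). The reported count is the posterior mode of the
   per-iteration number of existing classes.
2. **Consensus partition.** Complete-linkage hierarchical clustering of
   the dissimilarity `1 − S`, cut to that count. The tree is cut by
   merge order (`cut_tree`, the `cutree` semantics) rather than by a
   height threshold: with finitely many retained draws, many pairs never
   co-cluster, the top of the dendrogram is tied at distance exactly 1,
   and no height threshold produces the requested number of groups.
3. **Relabelling.** Per retained iteration, the sampled classes are
   matched to the consensus groups by maximum-overlap optimal assignment
   (Hungarian algorithm on the contingency table). Unmatched (surplus)
   classes go to a discard bucket whose prevalence mass is recorded.
4. **Summaries.** Posterior median prevalence per class, posterior
   mean/median `θ`, modal patterns (argmax over levels of the posterior
   mean `θ`; ties to the lower level) and consensus assignments. Classes
   whose prevalence median falls below the 5% threshold are dropped and
   their subjects reassigned to the surviving class with the highest
   mean co-clustering affinity.

Every summary is invariant to arbitrary per-iteration relabelling of the
stored draws (property-tested), and relabelling already-aligned draws is
a no-op.

An optional redundancy merge (classes with identical modal patterns
merged, prevalences summed) exists but is off in the main pipeline; see
WFPBB below for where it is needed.

Convergence is assessed with the Gelman–Rubin potential scale reduction
factor, `sqrt(((L−1)/L · W + B/L)/W)` over ≥2 chains of length `L`;
values near 1 (conventionally below 1.05) indicate agreement. Zero
within-chain variance yields NaN with a warning.

## WFPBB comparator

The weighted finite population Bayesian bootstrap "undoes" the design
instead of reweighting the model: a weighted Pólya urn imputes a
synthetic population of size `N ≈ Σw` (selection probability of unit `i`
at urn draw `t` proportional to `w_i − 1 + l_i (N−n)/n`, `l_i` its prior
selections; requires `w_i ≥ 1`, smaller weights are rescaled with a
warning), an SRS of size `m = n` is drawn from it, and the *unweighted*
model is refit. Over `B` such rounds (default 20) the aligned posterior
draws are pooled into a mixture of posteriors. Because urn resamples
duplicate subjects, the overfitted refits tend to split true patterns
into redundant classes; each bootstrap is therefore redundancy-merged
before alignment (alignment is modal-pattern matching against a
reference bootstrap with the modal recovered class count). Without this
merge the pooled prevalences were visibly distorted; with it the method
lands between the unweighted and weighted models in accuracy, as
expected. `B`, `m` and the target population size are configurable since
no authoritative settings are available.

## Synthetic-data generator

The generator emulates a stratified survey of a finite population:
`N = 5,000` subjects hold `K_true = 3` patterns with prevalence
`π_true = (0.1, 0.3, 0.6)`; each pattern fixes a modal level for each of
`p = 50` four-level items, hit with probability 0.85 (case A) or 0.55
(case B), off-modal levels sharing the remainder evenly. Four strata of
sizes `(385, 565, 2190, 1860)` carry deliberately different pattern
mixes — `(0.60, 0.30, 0.10)`, `(0.20, 0.60, 0.20)`, `(0.05, 0.35, 0.60)`,
`(0.025, 0.15, 0.825)` — chosen so that (a) they marginalise exactly to
`π_true` (the sizes are pinned down by this linear constraint given the
mixes, up to one free parameter) and (b) an equal-take sample of 100 per
stratum (`n = 400`, weights `w_i = N_s/100`, `κ = N/n = 12.5`) is
strongly non-representative: its expected unweighted class shares are
`(0.219, 0.350, 0.431)`, making the unweighted prevalence MSE against
truth ≈ 0.015. The within-stratum mixes are configurable.

What the generator does *not* emulate: item dependence within class
beyond the mixture itself, missing responses, measurement error or
informative nonresponse, and multi-stage/clustered designs (weights are
pure stratum-inverse-inclusion). A green benchmark therefore establishes
correct recovery under the model's own assumptions with a textbook
stratified design — not robustness to real-survey complications.

## Benchmark harness

`run_study` replicates: generate a population and sample (replicate seed
= master seed + index), fit each requested method (independent derived
seeds), postprocess, match recovered classes to the generating patterns
by Hamming agreement of modal patterns (ties broken toward closer
prevalence; a missing pattern scores prevalence 0 and a surplus class is
recorded), and report per-replicate prevalence estimates, recovered
class counts and extra-class sizes. The prevalence MSE averages over
replicates *and* the three true components. Reporting protocol in
`scripts/acceptance.py`: 20 replicates, 8,000 iterations (burn-in 4,000,
thinning 5) — a documented reduction of the full 100 × 25,000/15,000/5
protocol chosen purely for run-time; the test suite reduces further
(6 × 3,000) to fit its budget.

With the stand-in strata above, the design-based variance floor of the
weighted prevalence estimator is ≈ 4e-4 (averaged over the three
components), so the weighted model's case-A MSE cannot fall much below
that level regardless of chain length; the headline contrasts are the
orderings (weighted ≪ unweighted; WFPBB between).

## Numerical and policy choices

- Tertile discretisation of nonnegative intake: zeros are level 1;
  positive values split at the linear-interpolation 1/3 and 2/3
  quantiles of the positive subsample; a value exactly on a cut takes
  the lower level; with one distinct positive value both cuts collapse
  onto it and all positives take level 2 (warned).
- `d_j` is per-item; supplied level counts may exceed the observed
  maximum so unobserved top levels stay representable.
- Missing responses are rejected, not imputed.
- `z` draws are stored in 8-bit (or 16-bit for `K > 255`) integers and
  `θ` draws in float32 to keep memory modest; `π` is float64.
- Mode/argmax ties anywhere break to the lowest index; class-count ties
  in the posterior mode break to the smaller count.
- The co-clustering matrix is dense `n × n` (fine up to ~10⁴ subjects).

## Known limitations

- Prevalence uncertainty from the pseudo-posterior is approximate: no
  design-based variance correction is applied, so interval coverage can
  be below nominal under strong designs.
- The warm start removes the observed merge pathology but is a
  heuristic; pathological posteriors with genuinely separated redundant
  modes would still need split–merge moves, which are not implemented.
- WFPBB here serves point-estimate comparison only; bootstrap variance
  estimation is out of scope.
- Weights are treated as fixed constants; calibration uncertainty is
  ignored.
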