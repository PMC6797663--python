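# Methods

## Model

A psychological embedding consists of stimulus coordinates
`Z ∈ R^{n×D}`, a similarity kernel with parameters `θ`, and, when several
participant groups are modeled, a matrix of per-group attention weights
`W ∈ R^{K×D}` with `w_kj ≥ 0` and `Σ_j w_kj = D`. Distance is the
attention-weighted Minkowski distance

    d(z_m, z_n; w) = ( Σ_j w_j |z_mj − z_nj|^ρ )^{1/ρ},

with `ρ = 2` by default (`ρ` is held fixed during fitting; the Student's-t
kernel requires the 2-norm, and training `ρ` adds an unidentifiable degree
of freedom against the kernel's own shape parameters). Four kernel
families map distance to similarity:

| family | form | parameters (lower bounds) |
| --- | --- | --- |
| exponential | `exp(−β d^τ) + γ` | β > 0, τ > 0, γ ≥ 0 |
| student_t | `(1 + d²/α)^{−(α+1)/2}` | α > 0 |
| inverse | `1 / (μ + d^τ)` | μ ≥ 1e−7, τ > 0 |
| heavy_tailed | `(κ + d^τ)^{−α}` | κ ≥ 0, τ > 0, α > 0 |

`μ`'s floor exists purely for numerical stability at `d = 0`. No upper
bound is placed on `τ`; random restarts initialize it in `[1, 2]`, the
psychologically standard (Laplacian–Gaussian) range.

A trial shows a query and 2–8 references; the participant selects the
`n_select` most similar references, optionally ranked. Selection follows
Luce's choice rule: the probability of picking a reference is proportional
to its similarity to the query. Ranked selections use sequential removal —
the j-th pick competes against the not-yet-picked references — and an
unranked selection of a set is the sum of the ranked probabilities over
its orderings. This single sequential-removal implementation covers every
configuration; the textbook single-select, ranked-pair, and unranked-pair
formulas are unit tests of it. The data log-likelihood is the sum of
per-trial log probabilities; a floor of 2.2e−16 is applied inside the log
(with the gradient of floored trials zeroed) because stochastic responses
can hit vanishing model probabilities early in optimization.

## Fitting

`inference.fit` maximizes the mean log-likelihood over `Z`, the trainable
kernel parameters, and (for K > 1) the attention-weight rows. Gradients
are analytic and fully vectorized; positive parameters are optimized
through a shifted-softplus bijection and weight rows through a softmax
scaled by `D`, so all constraints hold at every step. The optimizer is
L-BFGS-B (`ftol = 1e−5`, `maxiter = 5000`), the standard quasi-Newton
choice for smooth medium-dimensional problems; it is deterministic, so a
fit is a pure function of (data, seed).

Restarts: coordinates initialize iid `Normal(0, 0.17²)` and kernel
parameters draw uniformly from documented ranges (β ∈ [1, 30],
τ ∈ [1, 2], α ∈ [1, 10], ...); the best of `n_restart = 10` final losses
wins. When a warm start is supplied it seeds the first restart only; later
restarts draw fresh random kernel parameters even when explicit parameters
were passed. This matters in incremental pipelines: a tiny seed batch can
be interpolated almost perfectly by a degenerate step-function kernel
(τ → 40+), and without restart diversity every warm-started refit stays
trapped there no matter how much data arrive.

`dimension_search` holds out 10% of trials (stratified by trial
configuration), fits candidate dimensionalities in ascending order, and
stops when validation loss stops improving; ties within 1e−6 count as no
improvement. `assess_convergence` refits on cumulative data partitions and
correlates the similarity matrices of consecutive increments (comparison
against the full-data embedding is available as `mode="final"`). Matrix
correlations use only the strictly-upper triangle, since the matrix is
symmetric and the diagonal is self-similarity.

## Posterior sampling

Per-stimulus uncertainty is a posterior `p(z_k | D, Z_¬k, θ) ∝
likelihood × Gaussian prior`, approximated by Gibbs sweeps with one
elliptical-slice update per stimulus per sweep (randomized order), kernel
parameters and weights held at their fitted values. The prior is the
package's choice (the model itself does not pin its hyperparameters): mean
at the current point estimate and isotropic scale equal to the mean
nearest-neighbor distance of the embedding — local enough that samples
describe uncertainty around the MLE, which is how active selection
consumes them. Defaults: 100 retained samples, 100 burn-in sweeps,
thinning 2. A stimulus touched by no trials has constant likelihood, so
its draws come straight from the prior (logged, not an error).

## Active selection

The expected information gain of a candidate trial is the mutual
information between the coordinates and the trial outcome; with posterior
samples it reduces to the entropy of the posterior-predictive outcome
distribution minus the mean per-sample entropy. Trials are generated by a
two-stage heuristic rather than exhaustive scoring: queries are drawn
proportionally to per-stimulus uncertainty, then references proportionally
to similarity with the query, with a cap on query reuse per batch and
maximal stage-1 weight for never-observed stimuli.

The stage-1 uncertainty score fits a moment-matched Gaussian to each
stimulus's samples and sums KL divergences against all other stimuli. The
default direction is `priority_k = Σ_j KL(N_k ‖ N_j)`: the trace term
`tr(Σ_j^{-1} Σ_k)` grows with stimulus k's own spread, while a
low-uncertainty stimulus is not boosted by uncertain neighbors (its
`Σ_k` appears only in the log-determinant). The opposite direction is
available via `direction="to"` but fails the inflated-covariance sanity
check: with tight, far-apart neighbors its Mahalanobis term
`(μ_k − μ_j)ᵀ Σ_k^{-1} (μ_k − μ_j)` explodes for tight stimuli and swamps
any covariance signal. Singular sample covariances are ridge-regularized.

## Synthetic studies

`simulation` provides virtual agents — ground-truth embeddings answering
trials by sampling their own outcome distributions — and two study
harnesses. Worker hours convert trial counts through the median human
response durations per configuration: 3.06 s for 2-choose-1, 8.98 s for
ranked 8-choose-2. Embedding quality is the Pearson
correlation between fitted and ground-truth similarity matrices
(upper triangle).

Two ground-truth generators are provided. The isotropic Gaussian cloud
(`generate_gaussian_ground_truth`, default variance 0.03 per dimension)
matches the two-group attention study's stimulus model. The clustered
generator (`generate_clustered_ground_truth`: cluster centers with
between-cluster variance 0.03, members scattered with variance 0.03/16,
4 clusters by default) emulates domains built from families of look-alike
stimuli, the typical setting for fine-grained similarity work. The
distinction matters for what the strategy study can show: on a homogeneous
cloud, posterior uncertainty is spatially uniform and random references
already include near neighbors, so active selection has nothing to
exploit — we measured its trial content to be statistically
indistinguishable from random content there. Clustered geometry is where
similarity-guided reference selection pays off, because random reference
sets rarely discriminate within a cluster. Passing the strategy-ordering
test on clustered truth therefore demonstrates the mechanism, not a claim
that active selection helps on structureless stimulus sets.

### Collection-strategy comparison

Three strategies are compared on one fixed ground truth across five
collection runs (the truth is drawn once; runs differ only in trial
generation and response sampling): random 2-choose-1 (seeded with 500
random trials), random 8-choose-2 (seeded with 50), and active 8-choose-2
(seeded with 50). Between active rounds the posterior is refreshed with a
short chain (40 samples, 15 burn-in sweeps); kernel parameters are refit
on every fifth round starting with the first, and only the coordinates are
refit (warm-started) in between. Random-strategy increments follow the
same refit schedule so the learning curves differ only through trial
content. Batch sizes scale with the stimulus set: the full-scale design
(208 stimuli) uses 250-trial increments for random strategies and
40-unique-query rounds for active, and a study on n stimuli multiplies
these by n/208 (minimum 8). Without this, hours-to-criterion at small n
is dominated by linear interpolation across one coarse increment rather
than by the strategies themselves. Default study size: 30 stimuli in 2-D,
criterion r = .95.

### Two-group attention study

One hundred (or, scaled down, 30) stimuli in 4-D with iid `Normal(0,
0.03)` coordinates; novices attend `w = [1.8, 1.8, .2, .2]`, experts the
complement. The *independent* condition fits a separate single-group
embedding per group on its own random 8-choose-2 stream until that group's
similarity matrix reaches criterion; the *shared* condition fits one
two-group embedding with trainable weight rows on a mixed stream (novice
trials with probability 0.74) until both groups reach criterion, and a
group stops contributing trials as soon as its own criterion is met — the
cheap-group oversampling exists to speed up shared inference, not to keep
collecting data a converged group no longer needs. Without that stopping
rule the shared condition can cost *more* than independent at small scale,
because the majority group keeps consuming budget long after converging.
The trial configuration is 8-choose-2 ranked — the most efficient
non-active random strategy — since the original design leaves it unstated.
Reported hours interpolate linearly between increments; shared-condition
hours are apportioned to groups by their counts at the crossing point.

## Numerical and design notes

- Stimulus indices are 0-based and contiguous; `n` is inferred as max
  index + 1. CSV files always carry 8 reference columns padded with −1.
- Outcome 0 of every enumeration is the recorded selection ordering, so
  likelihood, simulation, and information gain agree on outcome identity.
- Fitted embeddings are centered (translation is unidentifiable); rotation
  remains unidentified at ρ = 2, which is why all quality measures operate
  on similarity matrices rather than raw coordinates.
- Group-specific likelihoods dispatch on each trial's `group_id`;
  single-group data fix the weights at 1 (the coordinates absorb axis
  scaling, so no expressiveness is lost).
- Floats serialize with 17 significant digits; two runs with the same
  manifest produce byte-identical outputs.

## What the synthetic harness does and does not show

Virtual agents answer exactly according to the model family being fitted;
real judgments include lapses, individual differences beyond per-group
attention weights, context and order effects, and kernel misspecification.
Recovery correlations and cost orderings measured here are therefore
upper bounds on real-data performance, and the worker-hour figures
inherit the response-duration medians measured for one specific pool of
crowdworkers. Scaled-down study sizes (20–30 stimuli) were chosen so that
the full test suite and the acceptance script re-run from scratch in
minutes; the harness accepts larger sizes unchanged.
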