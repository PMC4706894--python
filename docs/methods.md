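# Methods

## Capacities and their operators

A capacity on the classifier set `X = {0,...,k-1}` is stored Möbius-first:
the coefficients `m(B)` over nonempty coalitions, with
`μ(A) = Σ_{B⊆A} m(B)`. This makes `s`-additivity a storage truncation
(coefficients vanish above size `s`), makes the learning problem linear in
the parameters, and gives closed forms for the operators:

- Choquet integral: evaluated by the sorted-level-set formula
  `Σ_i (f_(i) - f_(i-1)) μ(A_i)` with ties in the sort broken by ascending
  element index (the value is tie-rule invariant because equal increments
  contribute zero — asserted by test).
- Shapley value: `v_i = Σ_{B∋i} m(B)/|B|`; efficiency `Σ v_i = μ(X)` holds
  identically in this form.
- Extended interaction index: `I_S = Σ_{B⊇S} m(B)/(|B|-|S|+1)`. The
  rendered source definition of the double-sum form is typographically
  ambiguous, so the Möbius form is taken as primary and the tests certify
  it against the literal double sum and the required identities: `I_{x}`
  equals the Shapley value and `I` of a pair equals the Murofushi–Soneda
  pairwise index.

All three operators are certified against brute-force evaluation of the
textbook definitions over explicit `μ` tables on hundreds of random
capacities with up to 5 elements, at 1e-12 absolute tolerance.

Coalitions are canonical sorted index tuples, ordered by size then
lexicographically; capacities therefore serialize deterministically
(JSON keys `"0,2"` etc.).

## Score normalization

Normalization is per classifier and per classification event: the row of
`n` class scores is min-max mapped onto `[-1, 1]`, then projected by
`x ↦ 1/(1+exp(-λ(x-c)))` with the crossover `c` at the midpoint of the two
highest rescaled values. Centering between the leaders compresses both
toward 0.5 when they are nearly tied, so a classifier's internal ambiguity
survives into the belief space. Defaults: `λ = 2`, capped at `slope_max =
10`; an `optimized` crossover rule is an exposed extension point but
resolves to the midpoint rule, which is the only behavior specified
unconditionally. Degenerate all-equal rows carry no ranking information and
map to 0.5 ("maximal uncertainty") exactly. The map is strictly increasing
(rank-preserving) and invariant to positive affine rescaling of the raw
scores.

## Capacity identification

Because `Choquet(f) = Σ_B m(B) min_{i∈B} f_i`, each training sample
contributes a linear design row (coalition-wise minima of the beliefs).
Fitting minimizes the sum of squared residuals against one-vs-rest targets
(1 for the true class, 0 otherwise — the natural least-squares surrogate
for a class-likelihood score) plus a small ridge (`1e-6`), subject to the
`k·2^(k-1)` monotonicity inequalities and `Σ m = 1`. The ridge guarantees
strict convexity when the design is rank-deficient.

The QP is solved by SLSQP with analytic gradients from the uniform additive
capacity (always feasible); the objective is scaled by `1/T` so the
convergence tolerance (`ftol = 1e-14`) is meaningful at any training-set
size. A trust-constr solve is the fallback if SLSQP reports failure or
infeasibility beyond `1e-8`. The solution is divided by its coefficient sum
— a positive rescale that preserves every monotonicity inequality — so
normalization holds exactly. Learned capacities are verified monotone at
`1e-8` before being returned.

Hierarchy: per class, a 4-additive one-vs-rest capacity on all `k`
classifiers is learned first and drives ensemble selection; the class
capacity used at decision time is then learned on the ensemble members
only, unrestricted (order `|E_i| ≤ 4`, at most 15 coefficients). Learning
ensembles after the global capacities follows the order the procedure is
stated in.

## Ensemble construction

Greedy: start empty, repeatedly append the classifier maximizing the
extended interaction index of the *augmented* coalition `E ∪ {D}`. This is
the only reading under which the first selected member provably equals the
Shapley maximizer (interaction of a singleton = Shapley value). Ties break
toward the lowest classifier index. Ensembles are always filled to `s`
(default 4 of 6) even when the marginal interaction is negative; an
early-stop variant would change the contract and is not enabled. For
additive capacities the construction provably reduces to the top-`s`
Shapley ranking, which the tests check by exhaustive enumeration.

## Decision rule and threshold

Class likelihoods are Choquet integrals of ensemble-member beliefs; the
decision is the argmax unless `top1 - top2 < threshold` (strict), in which
case the system abstains. Strictness makes threshold 0 mean "never abstain"
(exact ties, measure-zero on continuous scores, go to the lowest class
index). The threshold compares the raw likelihood difference, not a
normalized margin. By construction, raising the threshold can only convert
decisions into abstentions: errors are non-increasing and abstentions
non-decreasing in the threshold, exactly, on any fixed dataset.

The threshold is tuned by grid search (default 0 to 1, step 0.01) on
validation data, maximizing efficiency and skipping grid points where it is
ND; if efficiency is ND on the whole grid the tuner falls back to the
information transfer rate. Ties prefer the smallest threshold.

## Metrics

- **Efficiency** is implemented as the net-progress rate `p_c - p_e`, ND
  when `≤ 0`. The metric's originating reference is cited but not
  reproduced in the source text, so this concrete definition — which
  reproduces the ND semantics exactly, lives in `(0, 1]`, and penalizes
  errors as undo operations while abstentions only cost the emission — is
  the package default, behind a small pluggable surface. ND propagates
  through averages by skipping (matching how the benchmark tables handle
  classifiers with undefined efficiency).
- **Nykopp's ITR** is the capacity of the row-normalized confusion channel
  with abstention as the `(n+1)`-th output symbol, computed by
  Blahut–Arimoto alternating maximization with the duality gap
  `max_i c_i - I` as stopping rule at relative tolerance 1e-9. Classes with
  no evaluated samples are dropped from the input alphabet. Treating
  abstention as an output symbol is what lets the metric credit rejections;
  collapsing it would erase the framework's key behavior.

## Synthetic score generator

Scores are Gaussian signal-plus-noise:
`s_{j,i} = α_j·1[i = c_t] + σ(√ρ z_{t,i} + √(1-ρ) ε_{t,j,i})` with `z`
shared across classifiers and `ε` private. The two knobs are the ones the
fusion claims depend on: skill heterogeneity (`α`) and diversity (`ρ`).
The `paper_like` preset uses 6 classes, 6 classifiers, skills
`(0.8, 1.1, 1.5, 1.9, 2.4, 3.0)` spanning chance-adjacent to near-ceiling
(matching the spread seen in practice, where some base classifiers cannot
support communication at all while others approach 90% accuracy), `ρ = 0.3`
and `σ = 1`. The replicate study trains on 500 samples and tests on 500,
sizes at which capacity learning is well-conditioned and a study of 20
replicates completes in well under a minute.

What the generator does *not* emulate: EEG time series and P300 waveform
shape, row/column flash aggregation, non-Gaussian artifact noise,
within-session nonstationarity, and classifier-specific output geometries
(all base classifiers share one score scale before normalization). Passing
tests therefore demonstrate the correctness and the comparative behavior of
the fusion machinery under controllable skill/diversity conditions, not
performance on real EEG.

## Numerical choices

- Oracle comparisons: 1e-12 absolute, on instances with ≤ 5 elements.
- Monotonicity tolerance 1e-8 everywhere a learned capacity is checked.
- Degenerate normalization rows detected at spread < 1e-12.
- Blahut–Arimoto: relative gap 1e-9, iteration cap 2·10^5.
- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; train/test streams in the replicate study are separated by a fixed
  seed offset of 10^4.

## Known limitations

- The slope/crossover "optimized" rule and the original efficiency formula
  come from references that are not reproducible from the source text; both
  are implemented as documented defaults behind extension points, and the
  published per-subject absolute table values are used only for
  internal-consistency checks of the reported improvement ranges, not as
  reproduction targets.
- One-vs-rest indicator targets are a design choice; probability-calibrated
  targets might fit better when base classifiers are well calibrated.
- The greedy ensemble search is not exhaustive over all `C(k, s)`
  coalitions and can be suboptimal when strong three-way synergies exist
  that pairwise growth never reaches.
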