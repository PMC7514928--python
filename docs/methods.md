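# Methods

This note records the model, the algorithmic and numerical choices, and the
limits of what the test suite demonstrates.

## Consensus model

An ensemble of M rank classifiers over K classes is summarized by a K×M rank
matrix R whose column k is classifier k's total order (permutation of 1..K,
rank 1 = most likely; ties and partial orders are rejected at validation).
The consensus ranking minimizes `φ(r) = Σ_k f(r, r^(k))` over the symmetric
group S_K. Both supported metrics admit linear forms in ensemble tallies,
which is what makes exact optimization practical:

* **Disagreement** (Hamming on positions): with the position tally
  `π_ij = #{k : r_ik = j}`, `φ_d(r) = Σ_ij (M − π_ij) x_ij` where x is r's
  permutation matrix. The cost of placing class i at position j is the
  number of classifiers that voted otherwise, `κ_ij = M − π_ij`. Both
  marginals of π equal M (each classifier fills each position exactly once).
* **Condorcet** (Kendall tau): with the pair tally
  `δ_ij = #{k : r_ik < r_jk}`, `φ_C(r) = θ − Σ_ij δ_ij y_ij` where y is r's
  pairwise-preference matrix and `θ = Σ_ij δ_ij = M·K(K−1)/2`. θ is kept in
  exact integer arithmetic; all distances and objectives are integers, so no
  floating-point comparison ever decides an optimum.

The two consensus rankings need not coincide; the built-in digit example
exhibits exactly one swapped adjacent pair between them.

A relation worth stating precisely, because a naive reading gets it wrong:
for any two total orders, `f_d(r,s) ≤ Σ_i |r_i − s_i| ≤ 2·f_C(r,s)` (the
Diaconis–Graham inequality). The unfactored claim `f_d ≤ f_C` is false — an
adjacent transposition has f_d = 2 and f_C = 1 — so only the factor-2 chain
is asserted and tested.

## Solvers

**Disagreement** is a linear assignment problem: the feasible set of the
binary program is the assignment polytope, whose vertices are exactly the
permutation matrices, so the LP relaxation is exact (total unimodularity)
and `scipy.optimize.linear_sum_assignment` returns a certified global
optimum in O(K³). The occasionally repeated claim that this formulation is
NP-hard confuses it with general binary programming. A brute-force oracle
over all K! permutations is kept in the test suite.

**Condorcet** is the linear ordering problem (Kemeny aggregation), NP-hard
in general. Exactness is preserved by restricting scale rather than by
approximating: exhaustive vectorized enumeration for K ≤ 8 (40 320 orders at
K = 8, milliseconds), branch-and-bound over prefix orders for 8 < K ≤ 15
with the admissible bound `Σ_{unresolved pairs} max(δ_ij, δ_ji)`, and a
`CapabilityError` beyond (CLI exit code 3). An ILP route with triangle
transitivity constraints `y_ij + y_jk − y_ik ≤ 1` would extend the ceiling
but is not included; the error contract keeps the omission honest.

**Tie-breaking** is deterministic and layered. Disagreement: the
lexicographically smallest optimal rank vector, found by greedily fixing
each class to the smallest position that preserves the optimal value
(re-solving the residual assignment, K² small LAPs). Condorcet: among all
optimal orders, first the one maximizing the position-vote score
`Σ_i π[i, r_i]` — when a class pair is majority-tied, outright placement
votes decide — then lexicographic. Plain lexicographic order alone would
resolve a majority-tied pair toward the lower class index regardless of
vote support, which is the less defensible choice; the layered rule is also
the one that reproduces the published worked example. Branch-and-bound
collects co-optima up to a cap of 50 000 (`optimum_count` is reported as
None if truncated); within the cap the selection is exact.

## Conjunction coefficients

`I_C = 4·Σ_ij δ_ij(δ_ij−1) / (M(M−1)K(K−1)) − 1` counts, per ordered class
pair, the ordered classifier pairs in agreement, normalized so unanimity
gives 1. `I_d = Σ_ij π_ij(π_ij−1) / (K·M(M−1))` is this package's positional
analogue, built by the same pair-counting construction applied to placements
rather than pairwise preferences: it is 1 iff all rankings are identical, 0
iff no (class, position) cell receives two votes (e.g. cyclic shifts), and
always in [0, 1]. Numerators are exact integers; one division at the end.

Attainable interval of I_C: the per-pair function `δ(δ−1) + (M−δ)(M−δ−1)` is
minimized by the most balanced split, which yields the lower bound
**−1/(M−1) for even M and −1/M for odd M**, valid for every ensemble and
attained by explicit profiles (mutual reversal at M = 2; the cyclic profile
at M = 3, K = 3). Exhaustive enumeration of all (K!)^M profiles for
M ∈ {2,3}, K ∈ {3,4} confirms these extremes exactly. The parity-swapped
version of this interval also circulates; `ic_bounds(..., convention=
"swapped")` exposes it for comparison, and the test suite shows it
disagrees with the enumeration. The coefficient report always carries the
enumeration-backed bounds.

## Pipeline and evaluation

Per-sample combination solves one consensus per observation (no coupling
across samples) and predicts the class with consensus rank 1; with M = 1 the
consensus is the single classifier's own ranking. FPR = FP/N and FNR = FN/P
are computed against an explicitly named positive class — made first-class
because in screening the positive class is rare and the risk asymmetric. A
rate with an empty denominator is NaN, never 0. Confusion-matrix rank
likelihoods `p(ranked k-th | class j) = n_jk / n_j·` and the empirical
independence gap `max |p̂(u1,u2) − p̂(u1)p̂(u2)|` are exposed as diagnostics
only: the likelihoods cannot drive a fusion rule at prediction time (true
classes are unknown), and the gap illustrates why unconditional independence
is the wrong design target — accurate classifiers are necessarily dependent
(identical perfect binary deciders over balanced classes have gap 0.25,
while the output marginal is 1/2 whatever the accuracy).

## Simulator

The generator emulates the screening setting: true classes drawn from an
imbalanced prior — default (0.81, 0.02, 0.17) for normal / atypical / debris,
uniform for other K — and M weak classifiers emitting noisy rankings
centered on "true class first, remaining classes in canonical index order"
(the fixed secondary order makes center-recovery tests well-defined).

* **Mallows model**: exact repeated-insertion sampling; item i+1 contributes
  v inversions with probability ∝ q^v (q = e^−λ), so the sum of the v's has
  the exact Kendall-distance law — no MCMC, no burn-in. λ = 0 is uniform;
  λ → ∞ degenerates to the center. (λ is conventionally called the
  "dispersion" parameter although larger values mean *more* concentration;
  agreement coefficients therefore increase with it.) The default λ = 1.8
  gives an individual top-1 error ≈ 0.16 at K = 3 — a realistically weak
  base learner, comparable to a small neural network on this kind of task.
* **Score model**: class scores are unit-variance Gaussians with location =
  margin for the true class, 0 otherwise, ranked descending; the margin is
  the accuracy parameter.
* **Dependence** ρ ∈ [0,1] induces correlated errors — the mechanism that
  caps ensemble gains in practice: under Mallows each classifier copies a
  per-sample shared draw with probability ρ; under the score model a shared
  per-sample noise vector enters every classifier with weight √ρ. This
  mechanism is this package's own modeling choice.

All randomness flows through `numpy.random.default_rng(seed)`; the same seed
reproduces a batch bit-for-bit across platforms. Ensemble-size sweeps derive
the per-size seed from `SeedSequence([seed, M])`, so any sweep row can be
reproduced as a standalone run.

What the simulator does **not** emulate: real image features and their
segmentation artifacts, classifiers trained on overlapping data (dependence
here is exchangeable, not structured), heterogeneous classifier quality, and
drifting class priors. Passing tests therefore demonstrate correctness of
the combination machinery and its statistical behavior under a clean noise
model — not performance claims about any particular real screening dataset.

## Problem sizes and test design

The suite runs exhaustive oracles where exhaustion is cheap (metric axioms
and inequality chain for K ≤ 4 plus random probes to K = 8; solver-vs-brute
force on 500 random ensembles with K ≤ 7, M ≤ 9; coefficient enumeration
over all profiles for M ∈ {2,3}, K ∈ {3,4}; a K = 9 branch-and-bound check
against a vectorized sweep of all 9! orders) and seeded Monte-Carlo
elsewhere (center recovery: 200 replicates at K = 5, λ = 0.5, M = 101;
ensemble-size benefit: 20 replicates of n = 300 samples at individual error
≈ 0.3). Property tests use hypothesis in derandomized mode. Statistical
assertions use wide margins (3σ binomial bands, strict orderings of means)
so they are stable under the fixed seeds.

## Known limitations

* Total orders only: ties, partial rankings and top-t lists are rejected,
  not modeled.
* The Condorcet solver's exactness ceiling is K = 15 without an ILP backend.
* Classifiers are weighted equally; per-classifier weights would require a
  training signal the method deliberately avoids.
* `I_d` is this package's construction (interval-verified, unanimity-
  calibrated); other positional agreement coefficients exist and do not
  coincide with it.
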