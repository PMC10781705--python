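# Methods

## Model and scope

The package treats link prediction as a sampling problem. Given a
simple, undirected, unweighted graph with adjacency matrix A, a
path-based method induces a score distribution over ordered node pairs,

    P[(i,j) | f] = |f(A)_ij|^q / ‖f(A)‖_q^q ,

with `f(A) = A²` or `A³` under the L₁,₁ norm (q = 1; path counts are
nonnegative, so the absolute value is vacuous) for the classical
samplers, and the pair `cos(At)`, `sin(At)` under the L₂,₂ norm (q = 2,
built into the squaring) for the quantum-walk sampler. Only the
*measurement distribution* of the quantum circuit is modelled:

    p_ij^even(t) = |cos(At)_ij|² / N ,   p_ij^odd(t) = |sin(At)_ij|² / N ,

computed from the symmetric eigendecomposition `A = QΛQᵀ` as
`cos(At) = Q cos(Λt) Qᵀ` (and likewise for sine). No statevector,
gate sequence, or Trotterization is simulated; `e^{±iAt}` is never
formed. The circuit enters only through its size (⌈log₂N⌉ + 2
Hadamards, ⌈log₂N⌉ CNOTs, 2⌈log₂N⌉ + 1 qubits, padding non-power-of-two
N with zero-amplitude basis states) and through the query-cost
calculators. The simulation error ε of a hardware implementation enters
those costs only polylogarithmically and is dropped from the
arithmetic; the d-sparse estimate `n_s · k_max · t / p_G` sets all
hidden constants to 1 and is meant as a comparator across parameter
settings, not an absolute gate count.

## Query accounting

The input is accessed through a general-graph-model oracle with three
unit-cost query types: degree of v, l-th neighbour of v (1-based,
neighbours in ascending node order — any fixed order gives the same
distributions, ascending is deterministic and testable), and the
adjacency entry of a pair. The oracle counts every call, including
repeats; caching of answers is an algorithm-level decision, and the A³
sampler caches (it has necessarily read the whole graph during
preprocessing) while the A² sampler does not, so its per-draw cost is
the literal 2 neighbour + 1 pair query of the complexity accounting.
The i = j coincidence in an A² draw needs no query to detect but the
pair query is issued regardless, keeping every draw at exactly 3
queries. Node selection uses a cumulative array with bisection; ties at
array boundaries resolve to the lower index.

The sampler weights — `p_v ∝ k_v²` for A², `p_uv ∝ k_u k_v` over ordered
adjacent pairs for A³ — follow from the integer identities
`Σ_v k_v² = ‖A²‖₁,₁` and `Σ_{(u,v) adjacent, ordered} k_u k_v = ‖A³‖₁,₁`,
which make the two-stage draw's marginal exactly the target law. Both
identities and the marginals themselves are verified in the test suite
against the brute-force dense distribution, which is kept as an
independent oracle and never used as the sampler.

## Usefulness, correctness, precision

A drawn pair is *good* when `A_ij = 0` and `i ≠ j` (mask
`G = J − (A + I)`) and *correct* when it hits a held-out link
(`A'_ij = 1`). All sums run over ordered pairs; every matrix involved
is symmetric, so ratios are unchanged under unordered reporting. The
conditional precision `p_C|G = p_C / p_G` is reported as missing
(`None`) when the denominator falls below a stability floor of 1e−8,
and fold averages skip missing values while reporting how many were
skipped. Cross-validation folds remove `round(fraction · |E|)` links
uniformly at random, independently per fold (a resample, not a
partition); the default protocol is 10 folds at 10%.

## Spectral curve evaluation

Curves over a walk-time grid need only a few entries of `cos(At)` and
`sin(At)`: since `‖cos(At)‖_F² = Σ_k cos²(λ_k t)`, the total even mass
is known from the spectrum alone, and `p_G` follows by subtracting the
*bad* entries (diagonal + edges), each of which is a cosine series
`C_ij(t) = Σ_k Q_ik Q_jk cos(λ_k t)` assembled for the whole grid with
one matrix product. Correctness curves use the same series over the
held-out pairs. One eigendecomposition therefore serves an entire
curve. The dense route (full matrices per t) is retained and the two
routes agree to 1e−12 in the tests. At t = 0 the walk is the identity
analytically; the implementation returns that limit exactly rather
than leaving eigendecomposition round-off at the degenerate point.
Dense-mode evaluation is capped at N = 5000 (full eigendecomposition);
larger inputs are rejected with guidance rather than silently
subsampled.

## Synthetic networks

Experiments run on synthetic graphs from a small registry:

* **Scale-free** (`sf`): configuration model on an i.i.d. degree
  sequence from the discrete power law `P(k) ∝ k^(−γ)` truncated to
  `[k_min, N−1]` (inverse-CDF sampling; the sequence sum is forced even
  by incrementing one random node). Self-loops and multi-edges from the
  stub matching are repaired by bounded random edge swaps, which
  preserve degrees when a swap is found; irreparable offenders are
  dropped, so the realized minimum degree can fall below `k_min` while
  the tail — the part that matters for `k_max` — is preserved.
  Defaults γ = 2.5, k_min = 2, matching the 2 < γ ≤ 4 range typical of
  real complex networks.
* **Erdős–Rényi** (`er`): `G(N, p)` with `p = k_av/(N−1)`, as a
  homogeneous control (default k_av = 6).

All randomness derives from a master seed through counter-based child
seeds (`SeedSequence((seed, key...))`), so each fold and each ensemble
replicate is individually reproducible.

These generators emulate the degree heterogeneity of real networks but
not their community structure, degree correlations, or clustering.
Passing tests therefore show that the samplers, metrics, and scaling
estimates behave as derived on degree-driven topology; they do not
certify prediction precision on any particular real dataset, where the
relative merit of even- versus odd-path scores is domain-dependent
(the walk time t remains a free hyper-parameter and no single default
is endorsed — the CLI requires it explicitly).

## Ensemble sizes and statistical choices

* The hub-scaling check regresses `log(mean k_max)` on `log N`. The
  maximum of N power-law degrees is heavy-tailed (Fréchet with shape
  γ − 1), so its sample mean converges slowly; the check uses sizes
  500–8000 with 60 replicates per size, at which the estimator's
  dispersion (±≈0.05) is small against the ±0.15 agreement band around
  the expected exponent 1/(γ−1). The finite-size expectation of the
  mean-based slope sits slightly above 1/(γ−1) (≈0.75 vs 2/3 at γ = 2.5
  at these sizes), a property of the estimator, not of the generator.
* Sampler–distribution equivalence is tested at 10⁵ draws with a total
  variation bound of 0.02 plus a chi-square goodness-of-fit at
  α = 0.001 restricted to the support. The expected TV of a *correct*
  multinomial sample grows with the size of the support, so the random
  fixture used for this check is a sparse ER(30) (k_av = 2), where the
  expected TV (≈0.013–0.016) leaves comfortable headroom; for the
  quantum-walk distribution (support up to 2N² cells) the test compares
  the observed TV against its analytic multinomial expectation instead
  of a fixed constant.
* Saturation experiments evaluate `p_G(t)` on a 50-point grid over
  t ∈ [0, 5]; precision curves start at t = 0.1 to avoid the small-p_G
  region where the conditional ratio is unstable.
* Degenerate inputs are guarded rather than looped over: requesting
  useful samples from a distribution with zero good mass (e.g. A³ on a
  path of length 2, whose odd-path scores live entirely on existing
  links) is detected by an exact p_G precheck and reported, since the
  rejection-sampling cost 1/p_G diverges.

## Known limitations

* Weighted, directed, and multi-graphs are out of scope, as are
  coherent (superposed) oracle queries — the quantum oracles appear
  only inside the resource formulas.
* The configuration-model simplification can shave a few edges off the
  sampled degree sequence (quantified above); exact-degree generators
  (e.g. edge-swap MCMC to stationarity) were not needed at the accuracy
  the scaling checks require.
* The d-sparse resource estimate ignores constants and polylog factors;
  comparisons across methods are meaningful, absolute numbers are not.
* Ranking-based evaluation metrics (AUC, precision@k) are deliberately
  absent: the sampling-conditional precision is the quantity of
  interest here.
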