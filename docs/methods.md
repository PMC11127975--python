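# Methods

This note records the models implemented in `graphdyn`, the estimators and
their numerical choices, and the design decisions taken where the problem
left room. Information is measured in bits (base-2 logarithms) throughout.

## Generative model

A graph `g` is drawn from a prior `P(G)`; a binary time series
`X = (X_{i,t})`, `i < N`, `t < T`, is then generated by a Markov chain
`P(X|G) = P(X_1) ∏_t P(X_{t+1} | X_t, G)` with synchronous (parallel)
vertex updates. Each vertex flips according to an activation probability
`α(n, m)` (inactive → active) or deactivation probability `β(n, m)`
(active → inactive), where `m` and `n` count its active and inactive
neighbors (`n + m = k_i`). Multiedges count with multiplicity; a self-loop
feeds a vertex's own state back with multiplicity 2, consistent with the
degree identity `k_i = Σ_{j≠i} M_ij + 2 M_ii`. The initial condition is
iid Bernoulli(1/2) per vertex by default (configurable), and is always
independent of `G` — which is why estimators may drop its entropy term and
restore it analytically.

### Dynamics

| model | α(n, m) | β(n, m) | coupling | defaults |
| --- | --- | --- | --- | --- |
| Glauber | σ(2J(m−n)) | σ(2J(n−m)) | J | ferromagnetic sign |
| SIS | ε + (1−ε)(1−(1−q)^m), q = clip(λ/β, 0, 1) | β | λ | β = 0.5, ε = 10⁻³ |
| Cowan | σ(a(νm−μ)) | β | ν | β = 0.5, a = 7, μ = 1 |

with `σ(x) = 1/(1+e^{−x})`. Two conventions needed a decision:

* **Glauber sign.** The convention in which spins preferentially *align*
  with neighbors is the default (`α = σ(2J(m−n))`); the opposite sign is
  available via `ferromagnetic=False`. Alignment is the physically
  standard heat-bath rule whose stationary law is the ferromagnetic Ising
  model.
* **SIS coupling.** The per-contact transmission probability is
  parameterized as `q = clip(λ/β, 0, 1)`; `q` can also be set directly.
  The raw form `1 − (1 − λ/β)^m` exits [0, 1] when λ > β, so the sweep
  axis remains λ but the dynamics saturates at λ = β. The spontaneous
  activation ε is composed so that `α(·, 0) = ε` *exactly* and α is
  monotone in `m`; ε prevents the epidemic from being absorbed at zero
  prevalence.

### Graph priors

* **Erdős–Rényi, fixed edge count**: uniform over all simple graphs with
  `N` vertices and `E` edges; `H(G) = log2 C(C(N,2), E)`.
* **Configuration model**: the stub-matching law over loopy multigraphs
  with degree sequence `k`,
  `P(g) = (2E)!!/(2E)! · ∏ k_i! / (∏_{i<j} M_ij! ∏_i (2M_ii)!!)`,
  evaluated in log-factorial space (no overflow up to E ~ 10⁵). The
  self-loop factor is read as `(2M_ii)!! = 2^{M_ii} M_ii!`; this is the
  reading under which the law normalizes on exhaustively enumerated
  supports (e.g. the three pairings of k = (2,2)), and it is what stub
  counting gives.
* **Geometric degree sequences**: iid draws from ρ(k) = (1−p)p^k (mean
  p/(1−p); the default p = 5/6 gives mean degree 5), redrawn until the sum
  is within 5% of 2E, then repaired by unit increments/decrements at
  random entries. The conditioning procedure is a choice; any scheme that
  lands exactly on 2E with small distortion of ρ would do. Real-network
  degree sequences enter through plain edge-list files (whitespace
  separated, `#` comments, 0- or 1-based).

## Computing the information measures

Three routes, in decreasing exactness and increasing reach:

1. **Finite tables** (`discrete_joint_info`): direct summation over an
   explicit prior vector and likelihood matrix. Exact; doubles as the
   oracle for everything else. The two-graph/three-outcome toy model and
   its closed forms (`U(G|X) = 1` when the graphs' outcome sets are
   disjoint; `U(X|G) = 1 − pH(r)/H(pr)` in the fully overlapping case)
   are checked against this route to 10⁻¹².
2. **Trajectory enumeration** (`exact_joint_measures`): for tiny systems,
   every trajectory is enumerated with a vectorized prefix recursion
   (arrays of `2^{N(t−1)} × |support|` likelihoods; a guard caps the
   largest intermediate at ~6·10⁷ elements, i.e. N = 4, T ≤ 6 with a
   20-graph support). `H(X|G)` from this route is cross-checked against an
   independent chain-rule evaluation `H(X_1) + Σ_t H(X_{t+1}|X_t)` on the
   2^N-state transition matrix.
3. **Monte Carlo with exact evidence** (`exact_mc_mi`): sample M pairs
   (g, x) from the generative model and average
   `log P(x|g) − log P(x)`, with the evidence `P(x) = Σ_g P(g)P(x|g)`
   summed over the *whole enumerated support* (stacked adjacency tensors,
   one vectorized pass per sample). The only error is Monte Carlo:
   SE = sample SD / √M. Uncertainty-coefficient SEs use delta-method
   influence values for the correlated ratio of means. T-sweeps reuse one
   set of trajectories simulated at max(T) and evaluate all prefixes
   (cumulative per-step log-likelihoods), which strongly reduces the
   variance of successive differences.

Past-conditioned measures use `I(X_future; G | X_past) = I(X;G) −
I(X_past;G)` with both terms estimated from the same samples, so the
identity `I_cond = I` at τ = 1 holds sample by sample; the normalizers are
`H(X_future|X_past) = H(X) − H(X_past)` and `H(G|X_past) = H(G) −
I(X_past;G)`.

### Posterior MCMC and the mean-field bound

`P(G|X)` is sampled by Metropolis–Hastings with
`min(1, Δ · proposal-ratio)`, `Δ = P(g')P(x|g') / P(g)P(x|g)` — the
standard rule, validated here by the prior-recovery and
enumerated-posterior tests. A move touches at most four vertices, so Δ is recomputed from
O(T) likelihood terms using cached per-vertex neighbor-count histories;
cache coherence against from-scratch recomputation is fuzz-tested.

* **Hinge flip** (ER): rewire one endpoint (chosen w.p. 1/2) of a uniform
  edge to a uniform vertex; both directions have proposal probability
  1/(EN), so the ratio is 1. Moves creating self-loops or multiedges are
  rejected; rejected and invalid proposals count toward the `N·δ`
  sampling gap (δ = 5, Q = 1000 by default; burn-in 10·N·δ moves).
* **Double-edge swap** (configuration model): the chain state is the
  sequence of E *ordered* edge instances, which is the lumped projection
  of a symmetric chain on labeled stub matchings (pick two matched stub
  pairs uniformly, choose one of the two re-pairings). On matchings the
  proposal is exactly symmetric — including every self-loop and
  parallel-edge corner case — and uniform-over-matchings induces exactly
  the stub-matching multigraph law, so the acceptance probability reduces
  to the likelihood ratio alone. A flat-likelihood chain reproduces the
  enumerated k = (2,2,2) ensemble (chi-square).

The **mean-field estimator** draws M outer pairs (g, x), runs the sampler
on each x, estimates edge marginals π_ij (simple graphs) or multiplicity
histograms π_ij(m) (multigraphs) from the Q posterior samples, and
averages `log P_MF(g|x) − log P(g)`. Smoothing prevents −∞ when the outer
graph contains an edge unseen among the samples: simple-graph frequencies
are clamped to [1/(Q+1), 1 − 1/(Q+1)]; multigraph histograms get add-one
smoothing over the observed multiplicity range plus one unseen bin. The
estimate is a lower bound on I(X;G) up to Monte Carlo error and **can be
negative**: the factorized family cannot represent edge dependence, and
under the fixed-edge-count ER prior even a perfectly estimated posterior
pays the factorization gap (at J = 0, exactly `log2 C(C(N,2),E) − C(N,2)`
bits). One chain is run per outer draw.

### Duality detection

`duality_scan` applies the sign criterion to finite differences of the two
U curves on a sorted grid: a segment is flagged dual when both slopes are
significant (|slope| > z·SE of the difference; z = 1 by default, and exact
curves with zero SE need only a nonzero slope) and of opposite sign;
maximal runs of flagged segments are reported as dual intervals.

## What the tests show — and at what scale

All test inputs are generated programmatically (the priors and dynamics
*are* the data generator; there are no bundled datasets). Scales were
chosen for a single-CPU budget:

* exact/oracle agreement on ER(3,1) and ER(4,3) supports (3–20 graphs),
  trajectory enumeration up to N = 4, T = 6;
* posterior correctness on ER(4,3), Glauber J = 2, T = 50 with Q = 5000
  samples (total-variation < 0.05 against the enumerated posterior);
* the T-duality on exact curves for T = 2…6 (I strictly increasing,
  U(G|X) rising, U(X|G) falling past its crossover at T = 4);
* a coupling sweep on ER(5,5), Glauber, T = 80, M = 1200 over
  J ∈ [0.25, 9]: both U curves peak in the interior and a dual region is
  detected between the maxima. The U(G|X) peak and the dual region are
  many standard errors strong; the post-peak decline of U(X|G) is within
  about one standard error — on systems this small the predictability
  curve saturates rather than visibly turning over, which is the main
  caveat when extrapolating these desk-scale checks to large networks;
* baseline scorers on ER(20,40), Glauber, T = 500: all three are
  informative (AUC > 0.6) near the ordering transition
  (J_c ≈ atanh(1/⟨k⟩) ≈ 0.26) and indistinguishable from chance at J = 0.
  Deep in the ordered phase (J = 1) the global magnetization mode swamps
  pairwise signal and the correlation scorer drops back to chance — a
  real property of the method, not an implementation artifact.

## Known limitations

* Exact routes require enumerable supports (ER with ≾ 10⁶ graphs,
  configuration models with ≾ 10⁶ stub matchings) and tiny N·T for
  trajectory enumeration.
* The mean-field bound degrades (strongly negative values) when the
  posterior chain is under-sampled relative to the posterior's
  concentration; at desk scales this limits MF coupling sweeps past the
  phase transition. Diagnostics (acceptance rate, per-draw terms) are
  reported so such runs are visible.
* Only binary-state, discrete-time, synchronous Markov dynamics are
  implemented; continuous-state and asynchronous processes are out of
  scope, as are directed or weighted graphs beyond multiedges.
* The upper-bound companion estimator for I(X;G) is not provided; only
  the exact estimator and the mean-field lower bound are.
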