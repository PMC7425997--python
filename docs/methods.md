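# Methods

## The model

A neuron with `K` synaptic partners occupies a point `J = (J_1, ..., J_K)`,
`J_i >= 0`, in synaptic-weight space. Two physiological constraints on the
net weight are considered:

* **bounded** — a resource limit `sum_i J_i <= Jbar`. The allowed
  configurations fill the volume under a regular `K-1` simplex,
  `V(K, Jbar) = Jbar^K / K!`.
* **fixed** — homeostasis holds `sum_i J_i = Jbar`. The allowed
  configurations are the simplex surface. Its `K-1`-dimensional measure
  depends on how distances between weight configurations are costed: under
  the Euclidean norm (weights can trade off jointly)
  `A(K, Jbar) = Jbar^{K-1} sqrt(K) / (K-1)!`; under the 1-norm (weights
  change one at a time) the `sqrt(K)` becomes `K`, because the simplex's
  inner radius is `Jbar/K` instead of `Jbar/sqrt(K)`.

The *flexibility hypothesis* is that the probability a neuron has `K`
partners is proportional to this measure. Normalizing `V` over `K >= 1`
gives a zero-truncated Poisson; normalizing `A` gives a distinct family
whose normalizer `Z_A(x) = sum_{K>=1} x^{K-1} K^w / (K-1)!` (`w = 1/2` or
`1`) has no closed form for `w = 1/2` and equals `(1+x) e^x` for `w = 1`.
Degrees are zero-truncated because a neuron with no retained partner does
not appear in a wiring diagram.

Connectomes measure synapse counts, not physiological weights, so the net
weight is taken proportional to the neuron's total synapse count:
`Jbar = alpha * Sbar` with one unknown `alpha >= 0` (weight per synapse) per
cell population. Each neuron's degree is then conditioned on its own
`Sbar_i` — this is what lets heterogeneous synapse counts discriminate the
constraint models from a null in which every potential partner connects
independently: a zero-truncated binomial with `N` potential partners and
connection probability `q`. `N` is an anatomical input (the size of the
potential-partner pool), `q` is fitted.

The budget may also scale with degree, `Jbar * K^p`, `p` in [0, 1]
(`p = 0`: order-1/K weights; `p = 1`: order-1 weights; `p = 1/2`: balanced
scaling). With the identification `K^p Jbar = alpha Sbar` — the synapse
count absorbs the scaling — the conditional pmfs and all fits are unchanged,
so `p` matters only for the optimal-degree theory.

## Fitting and model comparison

Maximum likelihood. The zero-truncated-Poisson score
`sum_i [K_i/alpha - Sbar_i e^{x_i}/(e^{x_i}-1)] = 0` (`x_i = alpha Sbar_i`)
and the truncated-binomial moment condition
`q / (1-(1-q)^N) = mean(K)/N` are solved by bracketed Brent root finding
(relative tolerance at float resolution, well below 1e-10). For the fixed
family the score uses the tilted mean `E[K-1]` under `Z_A`'s weights; the
identity `Sbar Z < dZ/dalpha < 2 Sbar Z` confines the MLE to
`[sum(K_i-1)/(2 sum Sbar_i), sum(K_i-1)/sum(Sbar_i)]`, which is used as the
root bracket and reported with the fit. All-`K=1` datasets drive the MLE to
the `alpha = 0` boundary and are flagged degenerate rather than raised, so
a pipeline run can still tabulate them.

Evidence. The marginal likelihood under each prior is approximated by
Laplace's method around the MLE with variance
`sigma^2 = 1 / sum_i c_i`, `c_i` the per-record observed information
(per-record precisions add). The truncated-Gaussian integrals are exact:

* flat prior: `sqrt(pi sigma^2 / 2) (1 + erf(theta/sqrt(2 sigma^2)))` on
  `[0, inf)`; for `q` the integral is truncated at both ends of `[0, 1]`.
  The flat prior on `alpha` is improper, so only evidence *differences*
  (log odds) are meaningful; the constant cancels between the two
  `alpha`-models, and the `alpha`-vs-`q` comparison inherits the same
  convention.
* Jeffreys prior `p(theta) ∝ theta^{-1/2}` (the Poisson-rate Jeffreys
  prior — the `1/theta` alternative makes the marginal diverge at the
  origin):
  `int_0^inf theta^{-1/2} e^{-(theta-that)^2/(2 s^2)} dtheta
   = (pi/2) sqrt(that) e^{-z} [I_{-1/4}(z) + I_{1/4}(z)]`, `z = that^2/(4s^2)`,
  verified against adaptive quadrature to six digits and evaluated with
  exponentially scaled Bessel functions (`ive`) so `z` up to 1e6 cannot
  overflow. For `q` the prior singularity and the unit interval are handled
  by an explicit one-dimensional quadrature after `q = u^2`.

Fixed-family variance bounds. `Z_A` is summed numerically (range
`1..2*max(Sbar)` by default, doubled until a geometric tail bound is below
1e-12), so the exact observed information is available. In addition the
curvature of `ln Z_A` in `x` is bounded analytically:
it is non-positive for all `x > 0`, bounded below by
`-min(2 - sqrt(3), 1/x^2)` (Euclidean; `2 - sqrt(3)` is the exact `x -> 0`
limit and the curvature approaches `-1/(2x^2)` from above as `x -> inf`),
and equals `-1/(1+x)^2` exactly in the 1-norm. Both envelope facts are
asserted by a test on a dense grid. Dropping the (non-positive) `ln Z`
curvature gives a certified *lower* bound on `sigma^2`,
`alpha^2 / sum(K_i - 1)`; the envelope gives the upper bound. Because the
evidence is monotone increasing in `sigma^2` under both priors, these
variance bounds yield an evidence interval, and the headline log odds for
the fixed model are quoted conservatively: its lower bound minus the
opponent's upper bound. Reported intervals always satisfy lower <= upper;
in the (degenerate) case where the envelope sum is non-positive the upper
variance bound is infinite and the evidence upper bound is reported as such
rather than clamped.

A quadrature oracle integrates the exact marginal likelihood adaptively in
log space (peak-rescaled; relative tolerance 1e-8) and is used only in
tests: at n = 100 the Laplace point evidences agree with it to well under
0.5 log units and the fixed-family interval brackets it.

Multiple comparisons are reported raw (no correction), matching how log
odds are normally read; both priors can be tabulated side by side as a
robustness check.

## Optimal degrees

Maximizing the measure over `K` gives the optimally flexible degree. By
analytic continuation of the factorial (`K! -> Gamma(K+1)`, harmonic
numbers by Euler's expansion) the critical points are, to `O(1/K*)`:

* bounded: `K*_V = alpha e^p Sbar - 1/2` (ratio route: `alpha e^p Sbar + p - 1`)
* fixed:   `K*_A = alpha e^p Sbar + 2 - p` (ratio route: `alpha e^p Sbar - p + 1/2`)

The two derivation routes differ at `O(1)`; both are reported and neither is
silently preferred. `K*_A > K*_V` at matched budget: the homeostatic
constraint favors more partners. The bounded form requires `K* >= 1` and
the fixed form `K* >= 2` (harmonic numbers are defined for positive
integers).

The discrete optimum — treated as ground truth — is found from the ratio
criterion: successive measure ratios with `K^p Jbar = alpha Sbar`
substituted locally form a single log-concave sequence
(`ln m(K+1) - ln m(K) = ln b + p(K+1) ln(1+1/K) - ln(K+1)` for the volume,
analogously with the `K^w` factor for the area), whose argmax is located by
exhaustive search over `1..max(10, ceil(4 b e^p))` with exact tie reporting
at relative tolerance 1e-12. At `p = 0` the sequence telescopes to the
exact log measure. This formulation is used because maximizing the raw
measure at fixed `Jbar` is ill-posed at `p = 1`: `ln V` becomes convex in
`K` (the continuum critical point is a minimum) and `ln A` linear to
`O(1/K^2)`, so no stable argmax exists there, while the ratio criterion
remains well-conditioned across `p` in [0, 1]. Over budgets 5–200 and
`p` in {0, 1/2, 1} the discrete optimum stays within 1.5 (bounded) and 2
(fixed) of the closed forms. Exact ties occur at integer budgets (e.g.
`V(9) = V(10)` at `b = 10`) and are reported as ties.

## Synthetic data

The generator emulates what the fits assume: per-neuron `(K, Sbar)` pairs
with `Sbar` drawn from a configurable law (default: discretized lognormal,
log-mean 4.5, log-sd 0.5 — median ~90 synapses, heterogeneity comparable
to larval Kenyon-cell synapse counts) and `K` sampled by exact inverse-CDF
from the chosen family at `alpha = 0.25` (inside the range of fitted values
for larval populations), or `(N, q)` for the binomial null with `Sbar`
independent of `K`. The default population size is 110 neurons, a larval
per-side Kenyon-cell count. One master seed is spawned into per-neuron
substreams, so draws are independent of iteration order and a prefix of a
larger run equals a smaller run.

`generate_edge_list` additionally materializes records as an edge list:
each neuron's `Sbar` synapses are spread over `K` distinct partners from a
shared pool, every connection receiving at least `min_synapses` (remainder
multinomial), plus optional decoy edges onto an excludable cell type. A
`(K, Sbar)` pair infeasible for the synapse floor (`Sbar < K *
min_synapses`) is redrawn by default (vanishingly rare at the default
conditions) or raised under the `error` policy.

What the generator does **not** emulate: spatial structure, morphology and
claw geometry, reciprocal or community wiring, left/right correlations, or
any dependence of `alpha` on neuron age. Passing tests therefore certify
the statistical machinery — estimator consistency, calibration of the
evidence approximations, filter correctness — not any claim about real
mushroom-body data, which must be supplied as edge lists.

Model discriminability at the default conditions is asymmetric, and the
test expectations reflect it: either constraint family separates from the
binomial null overwhelmingly (log odds of several hundred at n = 200,
because the null cannot use the per-neuron synapse counts), while the two
constraint families nearly coincide at these budgets (`x ~ 22`; per-record
KL ~ 0.013 nats), so at n = 200 the generating one wins the conservative
log odds in the clear majority but not near-certainty of replicates; full
separation appears by n ~ 2000. This mirrors the small
fixed-versus-bounded odds the method yields on real data.

## Connectome ingestion

Edge lists are aggregated by (pre, post) pair; connections below the
synapse threshold (default 2) are dropped, as are connections whose
partner belongs to an excluded class; `K` and `Sbar` are then computed on
the retained set, so `Sbar >= min_synapses * K` by construction. Whether
`Sbar` should also count synapses in excluded or sub-threshold connections
is ambiguous in principle; this package counts retained synapses only, and
both the threshold and the exclusion list are exposed as options so the
alternative conventions can be run as robustness variants. Neurons on the
two sides of the brain are kept as separate records. The binomial `N` is
taken from configuration; if absent it is inferred as the number of
non-excluded neurons in the metadata (a potential-partner census), falling
back to twice the maximum observed degree when no metadata accompany a bare
record table.

## Numerical conventions

* All factorial/Gamma and normalizer arithmetic in log space (`gammaln`,
  `logsumexp`); probabilities exponentiated at interfaces only.
* `ln(e^x - 1)` via `expm1`/`log1p` branches; the zero-truncated-Poisson
  information term `(Sbar/2 csch(x/2))^2` as `Sbar^2 e^{-x}/(1-e^{-x})^2`.
* Degenerate budgets (`alpha Sbar = 0`) are the analytic limit: a point
  mass at `K = 1`.
* Root finding: Brent with analytic brackets; ties in discrete argmaxes
  reported, not broken.
* Monte-Carlo measures use hit-or-miss in the bounding cube; the fixed
  constraint estimates the projected `K-1` volume and applies the exact
  norm-dependent projection factor (`sqrt(K)` or `K`), so the estimator is
  independent of the closed-form area.

## Known limitations

* The Laplace evidence is an asymptotic approximation; its error is O(1/n)
  and tested only down to n = 20.
* The fixed-family evidence interval derives from global curvature
  envelopes; for datasets dominated by records with `x < 1` the upper
  variance bound can widen substantially (and in the extreme becomes
  infinite).
* The optimal-degree closed forms are meaningless below `K* ~ 1-2` and the
  `p = 1` case is intrinsically ill-conditioned for the raw-measure
  formulation (see above).
* No joint fitting of `(alpha, p)` and no modeling of synaptic-weight
  values themselves — the models describe partner counts only.
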