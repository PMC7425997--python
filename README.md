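# flexdegree

Degree-distribution models for neural connectivity under constraints on a
neuron's total synaptic weight, with Bayesian model comparison — built for
synapse-resolution wiring diagrams such as the *Drosophila* mushroom body,
where a neuron's connection strengths are proxied by synapse counts.

## The idea

A neuron with `K` partners and weights `J_1..J_K >= 0` can satisfy a
physiological constraint in many ways. The size of that solution space —
the neuron's *flexibility* — depends on `K`:

| constraint | solution space | measure |
|---|---|---|
| bounded net weight, `ΣJ_i ≤ J̄` | volume under a regular simplex | `V(K) = J̄^K / K!` |
| fixed net weight, `ΣJ_i = J̄` (homeostasis) | simplex surface | `A(K) = J̄^{K-1}√K / (K-1)!` |

Setting `p(K) ∝ measure(K)` and writing `J̄ = αS̄` (total synapse count
times an unknown weight-per-synapse `α`) yields degree distributions
conditioned on each neuron's synapse count: a zero-truncated Poisson for
the bounded constraint and a distinct simplex-area family for the fixed
one (a 1-norm variant replaces `√K` by `K`). These are tested against a
zero-truncated binomial random-wiring null `p(K) ∝ C(N,K) q^K (1-q)^{N-K}`
by the log evidence ratio (log odds)

```
L = ln p_A(K | S̄) − ln p_X(K | S̄),
```

with parameters marginalized by Laplace approximation under flat or
Jeffreys priors. The fixed-weight normalizer has no closed form, so its
evidence is reported as a certified interval and headline odds are
conservative lower bounds. The package also provides the optimal-degree
theory (`K*_V ≈ αe^p S̄ − ½`, `K*_A ≈ αe^p S̄ + 2 − p` for budgets scaling
as `J̄K^p`), exact configuration counting for discrete synaptic-weight
units, Monte-Carlo oracles for the geometry, a reproducible synthetic-data
generator, and edge-list ingestion with the standard connection filters.

## Worked example

```python
import numpy as np
from flexdegree import (larva_like_config, generate_records,
                        fit_alpha_fixed, fit_q_binomial,
                        log_evidence_flat, log_odds, pearson_r)

# 200 neurons with lognormal synapse counts, degrees from the fixed-net-
# weight family at alpha = 0.25
recs = generate_records(larva_like_config(n_neurons=200, seed=0))

fit_a = fit_alpha_fixed(recs)
fit_b = fit_q_binomial(recs, N=400)
print(f"alpha_hat = {fit_a.point_estimate:.4f}  bracket = "
      f"({fit_a.bracket[0]:.4f}, {fit_a.bracket[1]:.4f})")
print(f"q_hat     = {fit_b.point_estimate:.4f}")
print(f"pearson r(Sbar, K) = {pearson_r(recs):.3f}")

L = log_odds(log_evidence_flat(fit_a, recs), log_evidence_flat(fit_b, recs))
print(f"log odds fixed-vs-binomial: lower bound = {L.lower:.1f}")
```

prints

```
alpha_hat = 0.2489  bracket = (0.1268, 0.2537)
q_hat     = 0.0671
pearson r(Sbar, K) = 0.923
log odds fixed-vs-binomial: lower bound = 559.0
```

`alpha_hat` recovers the generating value 0.25 inside its analytic bracket;
the strongly positive lower-bound log odds say the data are at least
`e^559` times more likely under the fixed-net-weight model than under
random wiring — the null cannot exploit the per-neuron synapse counts.

On real data, the same analysis runs from the shell on a pair of CSVs
(`pre_id,post_id,synapse_count` and `neuron_id,cell_type,side,claw_count`):

```
flexdegree run --edges edges.csv --metadata metadata.csv \
    --direction out --min-synapses 2 --exclude-types APL,dopaminergic \
    --prior both --out results/
```

writing `report.json`, `report.tsv` and `marginals.tsv` with per-cell-type
fits, evidence intervals, pairwise log odds and maximum-likelihood marginal
degree distributions. `flexdegree simulate` writes synthetic edge lists;
`flexdegree compare` runs on a pre-built `(K, S̄)` table.

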