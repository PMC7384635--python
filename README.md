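# fusedggm

Joint Bayesian estimation of multiple sparse Gaussian graphical models with
an optional mixture layer for unknown sub-populations — aimed at settings
where several related datasets (e.g. documents from consecutive time
periods, patient cohorts, experimental batches) each carry a
conditional-independence network that partly persists and partly evolves,
and where a single period may hide more than one sub-network.

## Model

For groups t = 1..T, observations follow Y_i ~ N_p(μ_t, Ω_t⁻¹).  The prior
on the precision matrices is a Bayesian fused graphical lasso:

* off-diagonals ω_{j₁j₂}^t: double-exponential with rate λ_t (sparsity);
* diagonals: exponential;
* differences ω^t − ω^{t'} for every group pair: double-exponential with
  rate λ_{t',t} (shrinkage toward a shared structure);
* all penalties: Gamma(r, s) hyperpriors (defaults r = 0.001, s = 1).

A scale-mixture-of-normals representation yields a column-wise block Gibbs
sampler whose every draw is positive definite by construction.  Edges are
reported when the 95% equal-tailed credible interval of ω_{j₁j₂} excludes
zero; networks are exported as partial correlations
ρ_{j₁j₂} = −ω_{j₁j₂}/√(ω_{j₁j₁}ω_{j₂j₂}).

The mixture layer allocates observations within each group to an unknown
number of components via a Chinese restaurant process, optionally
data-integrative (DI-CRP): external pairwise similarities s_{ii'} rescale an
existing component's weight by a majority count n*₋ᵢ,ₖ (members similar to i
above i's third-quartile threshold) and a cohesion score
h_i(k) = 1 + Σ s_{ii'} over k's members.  Precisions are then updated
stage-wise per component (BSM) or jointly fused across all components of
all groups (BFM).  A tf-idf front end maps term-document counts to the
continuous features the model consumes, with a posting-date similarity
(1/(1+Δdays)) as the DI-CRP side information.

See `docs/methods.md` for the full model, sampler and design choices.

## Worked example

```python
import numpy as np
from fusedggm import (GeneratorConfig, Hyperparameters, simulate_mixture_dataset,
                      run_fused_chain, summarize_chain, f_score, frobenius_loss)

cfg = GeneratorConfig(p=10, T=3, n_t=100, structure="shared", shared_frac=0.8)
sim = simulate_mixture_dataset(cfg, np.random.default_rng(0))

hyper = Hyperparameters(n_iter=600, burn_in=100, seed=1)
chain = run_fused_chain(sim.dataset, hyper)

for t, summ in enumerate(summarize_chain(chain, 0.95)):
    print(f"group {t+1}: F-score "
          f"{f_score(summ.adjacency, sim.adjacencies[t][0]):.2f}, "
          f"Frobenius {frobenius_loss(summ.omega_mean, sim.precisions[t][0]):.2f}")
```

Output (seeds as above):

```
group 1: F-score 0.93, Frobenius 0.98
group 2: F-score 0.92, Frobenius 0.99
group 3: F-score 0.88, Frobenius 1.15
```

Each line compares one group's estimated network against its generating
truth: the F-score is the harmonic mean of edge precision and recall after
credible-interval sparsification, and the Frobenius number is the distance
between the posterior-mean precision matrix and the true one (the true
matrices here have 14 edges of magnitude 0.4 on 10 nodes).

The same pipeline is scriptable from the shell:

```sh
fusedggm simulate --out-dir sim --p 10 --t 3 --n 100 --seed 0
fusedggm fit --data sim/data.csv --method bf --out-dir fit --seed 1 --n-iter 600
fusedggm evaluate --est-adjacency fit/g1_adjacency.csv \
    --true-adjacency sim/adjacency_true_g1_c1.csv --out report.json
```

Subcommands: `simulate`, `featurize` (tf-idf + date similarity), `fit`
(`nonmixture`/`bf`/`bsm`/`bfm`, allocation `crp`/`dicrp`), `summarize`
(recompute summaries from a stored trace), `evaluate`, `cv` (k-fold
predictive comparison of all five estimation variants).

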