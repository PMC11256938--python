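# scvic

Deep generative clustering of single-cell RNA-seq counts.

Single-cell RNA-seq count matrices mix the biological signal of interest —
which cell states exist and which cell belongs to which — with two strong
technical distortions: dropout (transcripts that were present but never
captured, producing excess zeros) and batch effects (systematic shifts
between sequencing runs). `scvic` is for analysts who want cluster
assignments that come from a single probabilistic model of the raw counts,
rather than from a pipeline of normalization, correction and clustering
steps that each ignore the uncertainty of the previous one.

## Model

Each count `x_ng` for cell *n* and gene *g* is generated as

```
z_n  ~  Σ_c π_c N(μ_c, I)            cell state: Gaussian mixture, C components
log t_n ~ N(μ̄_b, σ̄²_b)              scaling factor; per-batch empirical prior
ρ_n  =  f_ρ(z_n, s_n)                softmax decoder; Σ_g ρ_ng = 1
α_n  =  f_α(z_n, s_n)                dropout probabilities
x_ng ~  ZINB(t_n ρ_ng, θ_g, α_ng)    zero-inflated negative binomial
```

where `s_n` is the one-hot batch label, `θ_g` gene-wise inverse dispersions
and the ZINB density is `α·1{x=0} + (1−α)·NB(x; μ, θ)`. Two encoder
networks amortize the variational posteriors `q(z|x,s)` and `q(log t|x,s)`.

Inference is coordinate descent: Adam on a reparameterized Monte-Carlo
estimator of the mixture-aware evidence lower bound updates the networks
and dispersions while the mixture `(π, μ)` is frozen; after every epoch one
EM iteration on the epoch's latent draws updates the mixture while the
networks are frozen. Cluster labels come either from the posterior
component memberships `argmax_c q(c|μ_z)` (built-in) or from Louvain
community detection on a KNN graph of the encodings (the `-Louvain`
variant). With `n_components=1` the model reduces to a scVI-style
non-mixture VAE, which doubles as the ablation baseline.

The package ships a splat-style count simulator (grouped cells, lognormal
DE factors, per-batch multiplicative effects, logistic dropout calibrated
to a 5–25 % capture-loss axis) and the matching evaluation metrics: ARI,
NMI, and the KNN-region KL divergence of batch mixing.

## Worked example

```python
from scvic import (SimulationScenario, simulate, TrainingConfig, fit,
                   assign_builtin, assign_louvain, ari)

data = simulate(SimulationScenario(n_groups=3, n_cells=500, n_genes=300,
                                   dropout_mid=-0.5, seed=1))
state = fit(data, TrainingConfig(n_components=3, max_epochs=100, seed=1))
builtin = assign_builtin(state, data)
louvain = assign_louvain(state, data, seed=1)
print("built-in ARI", round(ari(data.true_labels, builtin.labels), 3))
print("Louvain  ARI", round(ari(data.true_labels, louvain.labels), 3))
```

prints

```
built-in ARI 0.994
Louvain  ARI 0.743
```

— the built-in mixture labels recover the three simulated groups (15 %
capture loss) essentially perfectly from the raw counts; on this run the
Louvain variant splits one tight group into sub-communities (each community
stays nested inside a single true group), the usual behavior of modularity
clustering on compact latent blobs. The same flow is available from the shell:

```bash
scvic simulate --groups 3 --cells 500 --genes 300 --seed 1 --out sim/
scvic fit --counts sim/counts.mtx --components 3 --epochs 100 --seed 1 --out run/
scvic cluster --checkpoint run/checkpoint.npz --counts sim/counts.mtx --out run/
scvic evaluate --labels run/labels_builtin.tsv --truth sim/labels.tsv --out run/metrics.json
```

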