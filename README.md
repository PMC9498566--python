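# tgdrsurv

Threshold gradient descent regularized Cox models for censored survival
data with high-dimensional omics measurements.

## The problem

Studies of complex disease routinely collect a censored survival
response (overall survival, progression-free survival, ...) together
with thousands of omics measurements per patient, of which only a small
subset is expected to be survival-associated. Two things are therefore
needed at once: a model flexible enough to capture nonlinear effects,
and regularized estimation that selects variables.

`tgdrsurv` implements a one-hidden-layer neural network with a Cox
partial-likelihood loss whose weights are estimated by **threshold
gradient descent regularization (TGDR)** rather than penalization. For
sample *i* with covariates *z_i*, observed time *Y_i = min(T_i, C_i)*
and event indicator *δ_i = I(T_i ≤ C_i)*, the network produces a log
hazard ratio

    θ_i = W2ᵀ tanh(W1 z_i + b),

and training maximizes the log partial likelihood

    l = Σ_{δ_i=1} [ θ_i − log Σ_{t_j ≥ t_i} exp(θ_j) ].

TGDR starts all weights at exactly zero and, at each of *K* iterations,
updates only the entries whose gradient magnitude reaches a fraction
*τ ∈ [0, 1]* of the maximum gradient — globally for the output weights
W2, row-wise per hidden node for the input weights W1. A weight that
never passes the threshold ends the fit bit-exactly zero, so variable
selection falls out of the estimate itself: a variable is selected iff
its entry of the composite importance vector **W12 = W2ᵀ W1** is
nonzero. The same machinery applied to plain Cox regression gives a
sparse linear baseline. The two tuning parameters (τ, K) are chosen by
stratified cross-validation.

The package also ships the simulation designs used to benchmark the
method (multivariate normal covariates with AR(1) or identity
correlation; hazards with linear, quadratic and interaction effects;
Weibull baseline hazard; exponential censoring calibrated to a target
censoring rate) and the evaluation metrics (Harrell's C-index;
selection precision/recall/F1; selection ROC/AUC across a tuning grid).

## Worked example

```python
import numpy as np
import tgdrsurv as tg

# one synthetic replicate: 500 samples, 50 covariates, the first 5
# carrying unit linear effects, AR(1) correlation, 30% censoring
design = tg.SimulationDesign(setting=1, scenario=1, p=50, N=500, up=5,
                             corr="ar1", seed=7)
rep = tg.generate_replicate(design)

# sparse linear Cox fit via TGDR
fit = tg.fit_ct(rep.data, tg.TGDRConfig(tau=0.9, K=300))
imp = tg.importance(fit.params)
print("selected:", (1 + np.flatnonzero(imp.selected)).tolist())

# evaluate against an independent test replicate
test = tg.generate_replicate(tg.simulate.with_seed(design, 8))
scores = tg.predict_scores(fit, test.data.Z)
print("test C-index:", round(tg.concordance_index(scores, test.data), 3))
m = tg.selection_f1(imp.selected, rep.truth)
print("selection F1:", m.f1)
```

prints

```
selected: [1, 2, 3, 4, 5]
test C-index: 0.883
selection F1: 1.0
```

i.e. the fit recovers exactly the five true variables and ranks
test-set risks with C-index 0.88 (1.0 would be perfect, 0.5 random).
The neural-network estimator is `tg.fit_cnt` with the same interface;
`tg.cross_validate` tunes (τ, K), and `tg.run_experiment` runs the full
generate/tune/fit/evaluate loop over replicates.

A command-line interface mirrors the library:

```sh
tgdrsurv simulate --p 50 --n 500 --up 5 --seed 7 --out data.csv
tgdrsurv fit --data data.csv --method ct --tau 0.9 --k 300 --importance-out imp.csv
tgdrsurv cv --data data.csv --method cnt --folds 5
tgdrsurv experiment --p 100 --n 500 --up 10 --replicates 10 --out report.csv
```

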