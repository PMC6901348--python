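# fjwnn — fuzzy jump wavelet neural networks for nonlinear system identification

`fjwnn` identifies nonlinear dynamic systems — chaotic time series, benchmark
difference-equation plants, and physiological signal maps such as surface-EMG
envelopes → elbow torque — with a Takagi–Sugeno–Kang fuzzy model whose rule
consequents are *jump* wavelet networks: each rule blends all linear input
regressors with a group of Mexican-hat wavelet neurons sharing one dyadic
scale. The linear part captures global, extrapolating structure; the wavelets
capture local nonlinearity; the fuzzy layer switches smoothly between scale
regimes.

## Model

Given regressors u ∈ ℝᵐ, the mother wavelet is φ(z) = (m − ‖z‖²)·exp(−‖z‖²/2)
and a candidate basis function at integer scale a and shift B responds as
2^(−am/2)·φ(2ᵃu − B). Rule l (one per distinct scale among the selected
wavelets) computes the consequent

    η_l(u) = Σ_j w_lj · φ_{a_l, B_lj}(u)  +  Σ_j w_ulj · u_j ,

fires at the geometric mean μ_l of its participating inputs' Gaussian
memberships (antecedent codes c ∈ {0..n_a} choose a pool member per input, 0
excludes the input), and the prediction is the rule-weighted blend

    ŷ = Σ_l v_l · μ̄_l · η_l ,     μ̄_l = μ_l / Σ_j μ_j ,

over the rules surviving the weight threshold (v_l < 0.05 is pruned).

Fitting is a three-stage pipeline:

1. **Dictionary and selection** — a lattice of scaled/shifted wavelets is
   built on the (min–max normalised) training inputs; forward orthogonal
   least squares ranks candidates by error-reduction ratio with the linear
   regressors forced into the model; the wavelet count is chosen by
   validation RMSE over nested prefixes; an integer-chromosome genetic
   algorithm refines the subset.
2. **Hybrid training** — membership means/std-devs, rule weights and
   antecedent codes are optimised by the imperialist competitive algorithm
   (ICA); at every candidate, all consequent weights are re-solved exactly by
   one joint linear least squares (the output is linear in them once firings
   are fixed).
3. **Rule induction** — rules with weight below 0.05 (or with no supporting
   firings on the training data) are removed and the consequents re-solved.

## Worked example

```python
import numpy as np
from fjwnn import FJWNN, SelectionConfig, GAConfig, ICAConfig
from fjwnn.experiment import benchmark_splits

train, test = benchmark_splits("mackey-glass", seed=0, tau=17.0)
model = FJWNN(
    train,
    selection=SelectionConfig(ga=GAConfig(population_size=150, generations=12)),
    ica=ICAConfig(population=150, max_iterations=50),
)
res = model.fit(seed=0)
print(res.summary())
print("test:", res.evaluate(test))
```

prints (chaotic Mackey–Glass prediction, x(t) from x(t−6), …, x(t−24)):

```
Fuzzy Jump Wavelet Neural Network Results
=========================================================
No. observations:                  500
No. regressors:                      4
Prediction horizon:                  0
Rules (after pruning):               8
Model parameters:                  126
Selected wavelets:                  39
Training RMSE:               2.470e-03
Final ICA cost:              2.259e-03
---------------------------------------------------------
rule  scale  wavelets  weight v  antecedent codes
   1     -3         3    0.2920  [9,4,1,3]
   2     -2         2    0.1531  [3,1,4,1]
...
   8      4         5    0.4818  [0,3,1,0]
=========================================================
test: {'rmse': 0.0025206..., 'rrse': 0.0111021..., 'rel_err_pct': 0.2634...,
       'vaf_pct': 99.9876..., 'n': 500}
```

i.e. the one-step prediction error on the 500 held-out points is ≈0.0025 on a
signal of unit scale — 0.26 % of the output RMS, 99.99 % of output variance
explained — using 8 fuzzy rules. A `fjwnn` command-line tool wraps the same
library (`fjwnn benchmark`, `fjwnn fit`, `fjwnn predict`,
`fjwnn benchmark-run`).

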