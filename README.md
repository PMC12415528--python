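# thetanet

Theta-band directed cortical network analysis for EEG frequency-tagging
studies of action–effect binding, built as a fully testable pipeline:
every stage can be driven by synthetic inputs with known ground truth,
so the whole chain — spectral tagging contrast, data-driven ROI
selection, nonlinear directed-connectivity estimation, and group
statistics — is verifiable without access to raw recordings.

## The problem

When people learn that a keypress produces a flickering stimulus, the
flicker frequency "tags" the neural representation of that action
effect: power at the tag frequency (4.5 Hz, inside the theta band)
rises relative to an out-of-band control flicker (8 Hz), and the
regions carrying that activity form a directed network. The scientific
questions are *which* cortical regions carry the tagged theta activity
in each task phase (action planning, standby, perception), and *how*
those regions drive one another — linearly and nonlinearly, and
asymmetrically between directions and between groups.

## The core model

Directed connectivity is estimated with a nonlinear multivariate
autoregressive (nMVAR) model: with M regional time series, the current
sample is a function of the p previous samples of all regions,

    x_n = f(x_p) + σ_n ,   x_p = [x_1(n−1) … x_M(n−1), …, x_M(n−p)]ᵀ

with f realised by a single-hidden-layer perceptron (6 tanh hidden
units, linear outputs) trained by incremental error back-propagation
with momentum, an adaptive learning rate, early stopping, and 5-fold
permuted cross-validation (80/10/10 splits). First-order Taylor
expansion of the hidden activations at the origin splits the fitted map
as f = fLin + fNonLin, giving two directed measures:

* **lC(i→j)** — linear connectivity: the aggregated magnitude of the
  effective linear coefficients of region i's lags into region j
  (output weights × activation slopes × input weights);
* **NC(i→j)** — nonlinear connectivity: the log error ratio
  `ln(ε²_{j,i-linear} / ε²_j)`, where the numerator error restricts
  region i's influence to its linear pathway and the denominator is the
  full network's error. NC ≈ 0 when i influences j only linearly.

Edge significance comes from 100 time-shifted surrogates (independent
circular shifts per channel, identical network settings). Model order is
selected by the Schwarz Bayesian Criterion over linear VAR least-squares
fits. Group inference uses paired/pooled t-tests with Cohen's d
(paired d = t/√n; independent d = t·√(1/n₁+1/n₂)), Benjamini–Hochberg
FDR, and default JZS Bayes factors (Cauchy prior, scale √2/2) labelled
by Lee–Wagenmakers evidence bands.

## Worked example

`analysis/04_fit_connectivity.py` simulates a 3-channel system with a
planted linear edge (channel 1 → 0, coefficient 0.45) and a planted
square nonlinearity (channel 0 → 2, gain 0.35), then runs the full
estimator. Its output:

```
SBC selects order p = 2 (true generating order 2)
fit quality: train R2 0.509, test R2 0.487 (train/test MSE 0.492/0.505)
linear connectivity (row -> column):
[[0.581 0.053 0.14 ]
 [0.434 0.669 0.04 ]
 [0.05  0.023 0.648]]
nonlinear connectivity:
[[ 0.008  0.003  0.911]
 [ 0.009  0.014  0.008]
 [ 0.005  0.005 -0.013]]
planted linear edge IC->ATL significant: True
planted nonlinear edge ATL->IFC significant: True
```

The linear matrix recovers the planted coefficient (entry [1,0] ≈ 0.43
against a true 0.45, off-diagonal noise an order of magnitude smaller),
the nonlinear matrix isolates the square edge (entry [0,2] ≈ 0.91, all
other off-diagonals near 0), and both planted edges survive the
surrogate test. Matched train/test R² indicates the network
generalizes rather than memorizes.

The other numbered scripts under `analysis/` demonstrate the remaining
stages: input simulation (01), the 4.5-vs-8 Hz tagging contrast and
phase segmentation (02), hotspot → DBSCAN → labelled-ROI recovery (03),
and two-group asymmetry/group-difference tables (05). Each writes its
tables under `results/`.

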