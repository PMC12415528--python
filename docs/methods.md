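# Methods

This note documents the models, parameters, numerical choices and known
limitations of each pipeline stage, and what the synthetic generators
do and do not emulate.

## Synthetic data

The generators provide every input class with known ground truth.

**Linear VAR.** A stationary VAR(p) with user-supplied coefficient
matrices `A[lag][j, i]` (source i → target j) and Gaussian innovations.
Stationarity is enforced at construction via the companion-matrix
spectral radius (< 1), and a burn-in of `10·p·M` samples is discarded to
remove initialization transients. The generated lagged covariances
match the Yule–Walker relations (checked against a fixed-point solution
of the discrete Lyapunov equation at n = 20 000).

**Nonlinear MVAR.** The same simulator plus explicit cross-lag terms,
each a (target, source, lag, form, gain) tuple with form ∈ {square,
tanh, pairwise product} — smooth, zero-preserving terms whose Taylor
expansion at 0 has no linear leakage in the square/product cases, so a
planted "nonlinear edge" really is nonlinear. With no terms the output
is bit-identical to the linear generator at equal seed. Trajectories
exceeding |x| > 10⁶ abort with an instability error naming the first
nonlinear term.

**Flicker epochs.** Each trial is a sinusoid at the flicker frequency
inside the flicker interval (raised-cosine ramps of 50 ms), plus 1/f
noise (spectral shaping of white noise, exponent 1) and white noise.
Defaults mirror the task structure: 4.5 or 8 Hz flicker, 256 Hz
sampling, epochs −2 to 4 s around the lock, flicker from 0 to 2 s, and
optional uniform onset-latency jitter. The 1/f-plus-white model is a
generic EEG noise stand-in, not a claim about any particular dataset;
no topographies, blinks or line noise are simulated, so passing tests
say nothing about artifact robustness.

**Voxel fields.** A regular 5 mm grid with an exponential background
(scale 0.2) plus Gaussian hotspots (power `peak·exp(−d²/r²)`,
overlapping hotspots add) and an integer label field (default: every
voxel generic cortex; the demo label fields plant anatomical patches of
15 mm radius). A background-only field is the null fixture for the ROI
pipeline's false-positive behaviour.

**Subject connectivity samples.** For each ROI pair the a→b direction
exceeds b→a by a configurable offset; `subject_sd` parametrizes the
standard deviation of the within-subject *directional difference*
(each direction gets independent noise with sd `subject_sd/√2`), so an
offset of one `subject_sd` is a paired effect size of exactly d = 1.

## Spectral stage

Morlet decomposition uses 5 cycles; the Gaussian envelope is treated as
supported on ±3 standard deviations, which defines the edge-invalid
zone (half-support `3·n_cycles/(2πf)` per frequency). Edge-invalid
samples are excluded from downstream statistics rather than zero-padded.
Power is averaged over trials (evoked and induced together). Baseline
normalization is `(P − mean_base)/mean_base` over −350 to −150 ms; the
baseline may be computed on a different lock's decomposition
(`baseline_source`) for response-locked epochs whose own pre-stimulus
interval is unavailable — the cross-lock bookkeeping under variable
reaction times is the caller's choice, exposed rather than hard-coded.
The tagging contrast subtracts the control-flicker power from the
tag-flicker power at matched measured frequencies and is antisymmetric
by construction. Phase windows are half-open [start, end): the sample
at exactly 1.0 s belongs to standby, not action planning.

## ROI stage

Thresholding supports two semantics, since both appear in practice: the
default keeps the top fraction (default 3%) of in-brain voxels with
full tie inclusion at the cut; an alternative keeps voxels within a
given proximity of the maximum power. Clustering is DBSCAN with
eps = 2 × grid edge (10 mm at 5 mm resolution, connecting face, edge
and corner grid neighbours) and min_pts = 4, a conventional choice for
3-D point data. Voxels in excluded tissue (white matter, cerebellum,
subcortical nuclei; outside-brain voxels never enter) and voxels left
unclustered are dropped. ROIs are assembled deterministically by an
explicit label → ROI mapping (anterior temporal, insular, inferior
frontal, lingual label groups); this replaces any manual segmentation
step with a reproducible rule. The rolandic operculum's membership in
the inferior frontal ROI is phase- and group-configurable, defaulting
to included except for the adult perception phase. Hemisphere
restriction is a sign filter on the x coordinate with a configurable
convention. On null (background-only) fields with an anatomically
labelled parcellation the pipeline produces a named ROI of ≥ 5 voxels
in ≤ 5% of seeds; note this false-positive rate depends on the label
geometry — with large unlabelled cortical expanses retained before
clustering, chance clusters of ≥ 5 *unnamed* voxels are common, which
is why ROI assembly (not raw clustering) is the unit of inference.

## Connectivity stage

Order selection fits VAR(p) by least squares for p = 1…p_max on a
common effective sample and minimizes
`SBC(p) = ln det Σ̂(p) + (ln N / N)·p·M²`, ties toward the smaller p.

The network is a single hidden layer of 6 tanh units with linear
outputs. tanh is the activation because it is odd, zero-preserving and
Taylor-expandable at 0 with a closed-form derivative; since channels
are z-scored, 0 is the operating point and the activation slopes at the
hidden biases are the linearization gains. Training is per-sample
("incremental") gradient descent with momentum 0.9 and initial rate
0.01, adapted per epoch on the validation error: ×1.05 on improvement,
×0.7 on worsening, and outright rejection (weights restored, momentum
reset) of an epoch whose validation error grows by more than 4% — the
classical adaptive back-propagation recipe; the constants are
conventions, as is early-stopping patience 20 within at most 500
epochs. Weights start uniform in (−0.5, 0.5); training restarts from a
fresh init up to 3 times on divergence. Each of the (default 5)
permuted folds splits samples 80/10/10 into train/validation/test and
keeps the best-validation weights; reported connectivity is the mean
over the folds' best networks, a declared convention where no canonical
aggregation exists.

lC aggregates the absolute effective linear coefficients across lags
(L1 by default; max and L2 available) — magnitudes, matching tables
that print only positive connectivities. NC uses the error-ratio
definition with the numerator computed by *restricting* a fitted
network: predict `f(x with channel i's lags zeroed) + fLin(i's lags)`.
An alternative reading — retraining a reduced network with i forced
linear — is available (`nc_mode="retrain"`) but is not the default: it
is an order of magnitude costlier and, on linear nulls, agrees with
the restriction reading. Diagonals are reported but excluded from
asymmetry inference.

Surrogates circularly shift each channel independently by an offset
uniform on [0.1 n, 0.9 n] samples (never 0), preserving marginals and
autocorrelation while destroying cross-channel alignment; the full fit
is repeated with identical settings, and an edge is significant when
its observed value exceeds the empirical 95th percentile of its 100
surrogate values. On independent white-noise channels the empirical
edge-wise type-I error is statistically indistinguishable from the
nominal 5% (the observed statistic is exchangeable with its
surrogates, giving ≈ 5/101 by rank symmetry).

## Statistics stage

Paired t-tests (df = n−1) compare bidirectional connection pairs;
pooled-variance independent t-tests (df = n₁+n₂−2, matching printed
df = 58 for groups of 31 and 29) compare groups, restricted to ROIs
defined in both groups. Effect sizes are exact algebraic conversions
from t. Bayes factors are default two-sided JZS: a Cauchy prior with
scale √2/2 on the effect size, integrated by adaptive quadrature with
the Cauchy written as an inverse-gamma mixture; evidence labels follow
the Lee–Wagenmakers bands with boundary values assigned to the weaker
band (BF₁₀ = 1 is anecdotal evidence for H0). BH-FDR families are
within phase × measure for asymmetry tables and across all compared
connections per measure for group tables; the family definition is a
configuration choice, not a mathematical necessity. The point-wise map
test applies a paired t at every (channel, time) point with BH-FDR over
the whole map. The mixed ANOVA (within: flicker frequency, between:
group) reports F, dfs, p and partial η²; perfectly flat data return
F = 0 by convention rather than 0/0.

## Problem sizes

The simulation-based checks use sizes chosen to make Monte-Carlo
margins comfortable at desk scale: directed-edge recovery uses
2-channel systems at n = 1200 over 100 seeds with 2-fold training;
surrogate calibration uses 3-channel white noise at n = 400 with 100
surrogates per dataset (204 edge tests); order recovery uses VAR(3) at
n = 5000; linear-null NC uses n = 4000 with the full 5-fold protocol.
The pipeline demo runs 12 subjects per group at n = 1500. All measured
properties passed with wide margins at these sizes (e.g., 100/100
directed recoveries where ≥ 90 is required).

## Known limitations

* Training is exactly reproducible only under a fixed seed; different
  BLAS builds may flip ties in `argsort`-free code paths but none are
  relied on.
* The estimator is undefined for constant channels (z-scoring) and
  degenerate for perfect fits (zero denominator in NC); both abort with
  explicit errors rather than returning sentinel values.
* NC is a ratio of in-sample errors; with very short series it inherits
  overfitting noise and can go slightly negative. Inference should rely
  on the surrogate test, not on NC's sign alone.
* The synthetic flicker data contain no volume conduction or source
  mixing, so spectral-stage tests validate the arithmetic, not source
  separation. Beamforming is out of scope; the pipeline starts at voxel
  activity maps and ROI time series.
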