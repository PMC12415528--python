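"""Nonlinear MVAR effective connectivity via a single-hidden-layer network.

Each channel's current sample is modelled as a function of all channels'
``p`` previous samples, x_n = f(x_p) + noise, with f realised by a
multilayer perceptron (tanh hidden layer, linear outputs). The fitted
map splits as f = fLin + fNonLin by first-order Taylor expansion of the
hidden activations around the origin (inputs are z-scored, so the origin
is the operating point and the activation slopes at the hidden biases
are the "scaling parameters" of the hidden units).

Two directed measures follow:

* linear connectivity lC(i->j): aggregated magnitude of the effective
  linear coefficients of channel i's lags into channel j
  (output weights x activation slopes x input weights);
* nonlinear connectivity NC(i->j): the log ratio of the one-step squared
  prediction error when channel i is restricted to its linear pathway
  versus the full network's error.

Significance is assessed against time-shifted surrogates: each channel
is independently circularly shifted, destroying cross-channel temporal
alignment while preserving marginals, and the whole fit is repeated with
identical settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._ebp import train_fold
from .containers import ConnectivityResult, EpochedSeries

__all__ = [
    "TrainConfig",
    "NMVARNet",
    "NCREANNFit",
    "select_order_sbc",
    "fit_ncreann",
    "extract_linear_part",
    "linear_connectivity",
    "nonlinear_connectivity",
    "evaluate_model",
    "surrogate_test",
    "connectivity_result",
    "lagged_design",
]


@dataclass
class TrainConfig:
    """Training protocol for the nonlinear MVAR network.

    Defaults follow the classical adaptive incremental back-propagation
    recipe: momentum 0.9, initial rate 0.01 grown 5% on validation
    improvement and shrunk 30% on worsening, epochs rejected when the
    validation error grows more than 4%, early stopping with patience 20,
    5 permuted folds with an 80/10/10 train/validation/test split, and
    weights initialised uniformly in (-0.5, 0.5).
    """

    hidden: int = 6
    momentum: float = 0.9
    learning_rate: float = 0.01
    max_epochs: int = 500
    patience: int = 20
    folds: int = 5
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1)
    init_range: float = 0.5
    max_err_growth: float = 0.04
    restarts: int = 3
    nc_mode: str = "restrict"  # or "retrain"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.folds < 1:
            raise ValueError("folds must be >= 1")
        if self.nc_mode not in ("restrict", "retrain"):
            raise ValueError("nc_mode must be 'restrict' or 'retrain'")


@dataclass
class NMVARNet:
    """A fitted single-hidden-layer nonlinear MVAR network.

    Input ordering is lag-major: input index (lag-1)*M + i holds channel
    i at that lag, matching x_p = [x_1(n-1) ... x_M(n-1), ..., x_M(n-p)].
    """

    M: int
    p: int
    W1: np.ndarray  # (H, M*p)
    b1: np.ndarray  # (H,)
    W2: np.ndarray  # (M, H)
    b2: np.ndarray  # (M,)
    val_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def H(self) -> int:
        return self.b1.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """One-step predictions for lagged inputs X of shape (N, M*p)."""
        return np.tanh(X @ self.W1.T + self.b1) @ self.W2.T + self.b2

    def predict_linear(self, X: np.ndarray) -> np.ndarray:
        """Predictions of the affine part fLin (Taylor expansion at 0)."""
        L = self.linear_map()
        const = self.W2 @ np.tanh(self.b1) + self.b2
        return X @ L.T + const

    def linear_map(self) -> np.ndarray:
        """Effective linear map (M, M*p): W2 . diag(tanh'(b1)) . W1."""
        slopes = 1.0 - np.tanh(self.b1) ** 2
        return self.W2 @ (slopes[:, None] * self.W1)


def lagged_design(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Build lagged inputs X (N, M*p) and targets Y (N, M) from (M, n) data."""
    data = np.asarray(data, dtype=float)
    M, n = data.shape
    if n <= p:
        raise ValueError("series shorter than the model order")
    N = n - p
    X = np.empty((N, M * p))
    for lag in range(1, p + 1):
        X[:, (lag - 1) * M : lag * M] = data[:, p - lag : n - lag].T
    Y = data[:, p:].T
    return X, Y


def _as_array(data: np.ndarray | EpochedSeries) -> np.ndarray:
    if isinstance(data, EpochedSeries):
        # concatenate trials along time
        return data.data.transpose(0, 2, 1).reshape(data.n_channels, -1)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("data must be a (channels, samples) array")
    return arr


def select_order_sbc(data: np.ndarray | EpochedSeries, p_max: int) -> int:
    """Model order by the Schwarz Bayesian Criterion over VAR least squares.

    For p = 1..p_max a linear VAR(p) is fitted by least squares on a
    common effective sample (rows from p_max on) and
    SBC(p) = ln det(residual covariance) + (ln N / N) * p * M^2 is
    minimised; ties break toward the smaller order.
    """
    arr = _as_array(data)
    if not np.all(np.isfinite(arr)):
        raise ValueError("series must be finite")
    M, n = arr.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if p_max > n / (2 * M):
        raise ValueError(
            f"series too short for p_max={p_max}: need at least n = {2 * M * p_max} samples"
        )
    arr = arr - arr.mean(axis=1, keepdims=True)
    N = n - p_max
    Y = arr[:, p_max:].T
    best_p, best_sbc = 1, np.inf
    for p in range(1, p_max + 1):
        X = np.empty((N, M * p))
        for lag in range(1, p + 1):
            X[:, (lag - 1) * M : lag * M] = arr[:, p_max - lag : n - lag].T
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ B
        sigma = resid.T @ resid / N
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        sbc = logdet + (np.log(N) / N) * (p * M * M)
        if sbc < best_sbc - 1e-12:
            best_sbc, best_p = sbc, p
    return best_p


@dataclass
class NCREANNFit:
    """Cross-validated fit: one fold-best network per permuted fold.

    Reported connectivity is the mean over folds; per-fold MSE and R^2
    for train and test splits are kept for generalization checks.
    """

    nets: list[NMVARNet]
    fold_metrics: list[dict]
    p: int
    config: TrainConfig
    channel_means: np.ndarray
    channel_sds: np.ndarray

    @property
    def M(self) -> int:
        return self.nets[0].M

    def mean_metric(self, key: str) -> float:
        return float(np.mean([m[key] for m in self.fold_metrics]))


def _zscore(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"channel {flat[0]} has zero variance; z-scoring undefined")
    return (arr - mu) / sd, mu.ravel(), sd.ravel()


def evaluate_model(net: NMVARNet, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """(MSE, R^2): error pooled over channels, R^2 averaged over channels."""
    pred = net.predict(X)
    resid = pred - Y
    mse = float(np.mean(resid**2))
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    if np.any(sst == 0):
        raise ValueError("zero-variance target channel; R^2 undefined")
    r2 = float(np.mean(1.0 - np.sum(resid**2, axis=0) / sst))
    return mse, r2


def fit_ncreann(
    data: np.ndarray | EpochedSeries, p: int, config: TrainConfig | None = None
) -> NCREANNFit:
    """Fit the nonlinear MVAR network with permuted cross-validation.

    Channels are z-scored; for each fold the lagged samples are permuted
    and split train/validation/test, the network is trained by
    incremental back-propagation (restarting from a fresh init up to
    ``config.restarts`` times on divergence), and the fold-best
    (validation) weights are kept. Fully reproducible given
    ``config.seed``.
    """
    if config is None:
        config = TrainConfig()
    arr = _as_array(data)
    arr, mu, sd = _zscore(arr)
    M, n = arr.shape
    if n - p < 10 * M * p:
        raise ValueError(f"series too short: need well over M*p = {M * p} lagged samples")
    X, Y = lagged_design(arr, p)
    N = X.shape[0]
    n_train = int(round(config.splits[0] * N))
    n_val = int(round(config.splits[1] * N))
    rng = np.random.default_rng(config.seed)
    nets: list[NMVARNet] = []
    metrics: list[dict] = []
    H, D = config.hidden, M * p
    for fold in range(config.folds):
        perm = rng.permutation(N)
        Xp, Yp = np.ascontiguousarray(X[perm]), np.ascontiguousarray(Y[perm])
        for attempt in range(config.restarts + 1):
            r = config.init_range
            W1 = rng.uniform(-r, r, (H, D))
            b1 = rng.uniform(-r, r, H)
            W2 = rng.uniform(-r, r, (M, H))
            b2 = rng.uniform(-r, r, M)
            bW1, bb1, bW2, bb2, best_val, n_epochs, trace = train_fold(
                Xp,
                Yp,
                n_train,
                n_val,
                W1,
                b1,
                W2,
                b2,
                config.learning_rate,
                config.momentum,
                config.max_epochs,
                config.patience,
                config.max_err_growth,
            )
            finite = (
                np.isfinite(best_val)
                and np.all(np.isfinite(bW1))
                and np.all(np.isfinite(bW2))
            )
            if finite:
                break
        else:  # pragma: no cover - requires repeated divergence
            raise RuntimeError(
                f"training diverged in fold {fold} after {config.restarts + 1} initialisations"
            )
        if not finite:
            raise RuntimeError(
                f"training diverged in fold {fold} after {config.restarts + 1} initialisations"
            )
        net = NMVARNet(M=M, p=p, W1=bW1, b1=bb1, W2=bW2, b2=bb2, val_trace=trace)
        tr_mse, tr_r2 = evaluate_model(net, Xp[:n_train], Yp[:n_train])
        te_mse, te_r2 = evaluate_model(net, Xp[n_train + n_val :], Yp[n_train + n_val :])
        nets.append(net)
        metrics.append(
            {
                "fold": fold,
                "mse_train": tr_mse,
                "mse_test": te_mse,
                "r2_train": tr_r2,
                "r2_test": te_r2,
                "val_error": float(best_val),
                "epochs": int(n_epochs),
            }
        )
    return NCREANNFit(
        nets=nets, fold_metrics=metrics, p=p, config=config, channel_means=mu, channel_sds=sd
    )


def extract_linear_part(net: NMVARNet) -> np.ndarray:
    """Linear coefficient tensor (p, M, M): first-order Taylor at x = 0.

    ``A[lag][j, i]`` is the effective linear coefficient of channel i at
    lag+1 into channel j. fLin is the corresponding affine map; fNonLin
    is the remainder f - fLin.
    """
    L = net.linear_map()  # (M, M*p)
    return np.stack(
        [L[:, lag * net.M : (lag + 1) * net.M] for lag in range(net.p)], axis=0
    )


def linear_connectivity(
    net_or_fit: NMVARNet | NCREANNFit,
    aggregate: str = "l1",
    route: str = "lags",
) -> np.ndarray:
    """Linear directed connectivity lC, entry (i, j) = influence i -> j.

    Aggregation over lags: ``l1`` (default, sum of absolute
    coefficients), ``max`` or ``l2``. ``route='weights'`` computes the
    same quantity directly from the weight products without forming the
    lag tensor (algebraically identical).
    """
    if isinstance(net_or_fit, NCREANNFit):
        mats = [linear_connectivity(net, aggregate, route) for net in net_or_fit.nets]
        return np.mean(mats, axis=0)
    net = net_or_fit
    if route == "lags":
        A = extract_linear_part(net)  # (p, M, M) with [lag, j, i]
        stacked = np.abs(A)
    elif route == "weights":
        slopes = 1.0 - np.tanh(net.b1) ** 2
        coef = np.empty((net.p, net.M, net.M))
        for lag in range(net.p):
            for j in range(net.M):
                for i in range(net.M):
                    coef[lag, j, i] = np.sum(
                        net.W2[j] * slopes * net.W1[:, lag * net.M + i]
                    )
        stacked = np.abs(coef)
    else:
        raise ValueError(f"unknown route {route!r}")
    if aggregate == "l1":
        agg = stacked.sum(axis=0)
    elif aggregate == "max":
        agg = stacked.max(axis=0)
    elif aggregate == "l2":
        agg = np.sqrt((stacked**2).sum(axis=0))
    else:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    return agg.T  # [j, i] -> [i, j]


def _lag_columns(M: int, p: int, i: int) -> np.ndarray:
    return np.array([lag * M + i for lag in range(p)])


def nonlinear_connectivity(
    net_or_fit: NMVARNet | NCREANNFit,
    data: np.ndarray | EpochedSeries | None = None,
    X: np.ndarray | None = None,
    Y: np.ndarray | None = None,
) -> np.ndarray:
    """Nonlinear directed connectivity NC, entry (i, j) = influence i -> j.

    NC(i->j) = ln(e^2_{j, i linear} / e^2_j) where e^2_j is the full
    network's mean squared one-step error on channel j and the numerator
    restricts channel i's lags to the linear pathway: the prediction is
    f(x with x_i lags zeroed) + fLin applied to x_i's lags only.
    """
    if isinstance(net_or_fit, NCREANNFit):
        fit = net_or_fit
        if X is None or Y is None:
            if data is None:
                raise ValueError("need the fitted data (or X, Y) to compute NC")
            arr = _as_array(data)
            arr = (arr - fit.channel_means[:, None]) / fit.channel_sds[:, None]
            X, Y = lagged_design(arr, fit.p)
        mats = [nonlinear_connectivity(net, X=X, Y=Y) for net in fit.nets]
        return np.mean(mats, axis=0)
    net = net_or_fit
    if X is None or Y is None:
        if data is None:
            raise ValueError("need the fitted data (or X, Y) to compute NC")
        arr = _as_array(data)
        X, Y = lagged_design(arr, net.p)
    full_err = np.mean((net.predict(X) - Y) ** 2, axis=0)  # per target channel j
    if np.any(full_err == 0):
        raise ZeroDivisionError("degenerate perfect fit: zero full-model error")
    L = net.linear_map()
    NC = np.empty((net.M, net.M))
    for i in range(net.M):
        cols = _lag_columns(net.M, net.p, i)
        Xz = X.copy()
        Xz[:, cols] = 0.0
        pred = net.predict(Xz) + X[:, cols] @ L[:, cols].T
        lin_err = np.mean((pred - Y) ** 2, axis=0)
        NC[i] = np.log(lin_err / full_err)
    return NC


def nonlinear_connectivity_retrain(
    data: np.ndarray | EpochedSeries, p: int, config: TrainConfig | None = None
) -> np.ndarray:
    """NC under the constrained-retraining reading of the error ratio.

    Instead of restricting a fitted network's pathway for channel i, a
    reduced network is retrained with identical settings on inputs where
    channel i's lags are removed (zeroed), and i's purely linear
    contribution is refit by least squares on the reduced network's
    residual. Much costlier than the default restriction; exposed for
    sensitivity analyses.
    """
    if config is None:
        config = TrainConfig()
    arr = _as_array(data)
    arr, _, _ = _zscore(arr)
    M, _ = arr.shape
    X, Y = lagged_design(arr, p)
    full = fit_ncreann(arr, p, config)
    full_err = np.mean(
        [np.mean((net.predict(X) - Y) ** 2, axis=0) for net in full.nets], axis=0
    )
    if np.any(full_err == 0):
        raise ZeroDivisionError("degenerate perfect fit: zero full-model error")
    NC = np.empty((M, M))
    for i in range(M):
        cols = _lag_columns(M, p, i)
        Xz = X.copy()
        Xz[:, cols] = 0.0
        lin_errs = []
        for net in full.nets:
            resid = Y - net.predict(Xz)
            B, *_ = np.linalg.lstsq(X[:, cols], resid, rcond=None)
            lin_errs.append(np.mean((resid - X[:, cols] @ B) ** 2, axis=0))
        NC[i] = np.log(np.mean(lin_errs, axis=0) / full_err)
    return NC


def connectivity_result(
    fit: NCREANNFit,
    data: np.ndarray | EpochedSeries,
    roi_names: list[str] | None = None,
) -> ConnectivityResult:
    """Bundle mean-over-folds lC/NC and fit metrics for one subject."""
    lC = linear_connectivity(fit)
    if fit.config.nc_mode == "retrain":
        NC = nonlinear_connectivity_retrain(data, fit.p, fit.config)
    else:
        NC = nonlinear_connectivity(fit, data=data)
    return ConnectivityResult(
        lC=lC,
        NC=NC,
        roi_names=roi_names or [f"roi{i}" for i in range(fit.M)],
        mse_train=fit.mean_metric("mse_train"),
        mse_test=fit.mean_metric("mse_test"),
        r2_train=fit.mean_metric("r2_train"),
        r2_test=fit.mean_metric("r2_test"),
        fold_metrics=fit.fold_metrics,
        order=fit.p,
    )


def surrogate_test(
    data: np.ndarray | EpochedSeries,
    p: int,
    config: TrainConfig | None = None,
    n_surr: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ConnectivityResult:
    """Significance of each directed edge against time-shifted surrogates.

    Each surrogate shifts every channel circularly by an independent
    offset drawn uniformly from [0.1 n, 0.9 n] samples (never 0), then
    the entire fit is repeated with identical network settings. An edge
    is significant when its observed value exceeds the (1 - alpha)
    empirical quantile of its surrogate values; diagonals are never
    flagged.
    """
    if n_surr < 1:
        raise ValueError("n_surr must be >= 1")
    if config is None:
        config = TrainConfig()
    arr = _as_array(data)
    M, n = arr.shape
    fit = fit_ncreann(arr, p, config)
    result = connectivity_result(fit, arr)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = max(1, int(0.1 * n)), int(0.9 * n)
    surr_lC = np.empty((n_surr, M, M))
    surr_NC = np.empty((n_surr, M, M))
    for s in range(n_surr):
        shifts = rng.integers(lo, hi + 1, size=M)
        shifted = np.stack([np.roll(arr[ch], shifts[ch]) for ch in range(M)])
        sfit = fit_ncreann(shifted, p, config)
        surr_lC[s] = linear_connectivity(sfit)
        surr_NC[s] = nonlinear_connectivity(sfit, data=shifted)
    q_lC = np.quantile(surr_lC, 1.0 - alpha, axis=0)
    q_NC = np.quantile(surr_NC, 1.0 - alpha, axis=0)
    off_diag = ~np.eye(M, dtype=bool)
    result.sig_lC = (result.lC > q_lC) & off_diag
    result.sig_NC = (result.NC > q_NC) & off_diag
    return result
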