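"""Incremental error-back-propagation kernel for the nonlinear MVAR net.

A single-hidden-layer perceptron (tanh hidden units, linear outputs) is
trained sample-by-sample ("incremental mode") with momentum and an
adaptive learning rate: after each epoch the validation error is
compared with the previous epoch's — improvement grows the rate by 5%,
worsening shrinks it by 30%, and an epoch whose error grows by more than
4% is rejected outright (weights restored). Early stopping keeps the
weights with the best validation error.

The loop is JIT-compiled with numba; everything is float64.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["train_fold"]


@njit(cache=True)
def _forward_mse(X, Y, W1, b1, W2, b2, start, stop):  # pragma: no cover - jitted
    H = b1.shape[0]
    M = b2.shape[0]
    err = 0.0
    count = 0
    for n in range(start, stop):
        for j in range(M):
            acc = b2[j]
            for h in range(H):
                pre = b1[h]
                for d in range(X.shape[1]):
                    pre += W1[h, d] * X[n, d]
                acc += W2[j, h] * np.tanh(pre)
            diff = acc - Y[n, j]
            err += diff * diff
            count += 1
    return err / count if count > 0 else 0.0


@njit(cache=True)
def train_fold(
    X,
    Y,
    n_train,
    n_val,
    W1,
    b1,
    W2,
    b2,
    lr,
    momentum,
    max_epochs,
    patience,
    max_err_growth,
):  # pragma: no cover - jitted
    """Train one fold in place; returns best-validation weights.

    X is (N, D) lagged inputs, Y is (N, M) targets; the first ``n_train``
    rows train, the next ``n_val`` validate (callers permute rows
    beforehand). Returns (W1, b1, W2, b2, best_val, n_epochs, val_trace).
    """
    D = X.shape[1]
    H = b1.shape[0]
    M = b2.shape[0]

    vW1 = np.zeros((H, D))
    vb1 = np.zeros(H)
    vW2 = np.zeros((M, H))
    vb2 = np.zeros(M)

    hid = np.empty(H)
    out_err = np.empty(M)
    dh = np.empty(H)

    best_W1 = W1.copy()
    best_b1 = b1.copy()
    best_W2 = W2.copy()
    best_b2 = b2.copy()
    best_val = _forward_mse(X, Y, W1, b1, W2, b2, n_train, n_train + n_val)
    prev_val = best_val
    val_trace = np.empty(max_epochs)
    wait = 0
    n_epochs = 0

    for epoch in range(max_epochs):
        # snapshot for possible rejection of this epoch
        sW1 = W1.copy()
        sb1 = b1.copy()
        sW2 = W2.copy()
        sb2 = b2.copy()
        svW1 = vW1.copy()
        svb1 = vb1.copy()
        svW2 = vW2.copy()
        svb2 = vb2.copy()

        for n in range(n_train):
            # forward
            for h in range(H):
                pre = b1[h]
                for d in range(D):
                    pre += W1[h, d] * X[n, d]
                hid[h] = np.tanh(pre)
            for j in range(M):
                acc = b2[j]
                for h in range(H):
                    acc += W2[j, h] * hid[h]
                out_err[j] = acc - Y[n, j]
            # backward
            for h in range(H):
                s = 0.0
                for j in range(M):
                    s += W2[j, h] * out_err[j]
                dh[h] = s * (1.0 - hid[h] * hid[h])
            # update with momentum
            for j in range(M):
                for h in range(H):
                    vW2[j, h] = momentum * vW2[j, h] - lr * out_err[j] * hid[h]
                    W2[j, h] += vW2[j, h]
                vb2[j] = momentum * vb2[j] - lr * out_err[j]
                b2[j] += vb2[j]
            for h in range(H):
                for d in range(D):
                    vW1[h, d] = momentum * vW1[h, d] - lr * dh[h] * X[n, d]
                    W1[h, d] += vW1[h, d]
                vb1[h] = momentum * vb1[h] - lr * dh[h]
                b1[h] += vb1[h]

        val_err = _forward_mse(X, Y, W1, b1, W2, b2, n_train, n_train + n_val)
        n_epochs = epoch + 1

        if not np.isfinite(val_err) or val_err > (1.0 + max_err_growth) * prev_val:
            # reject the epoch: restore weights, damp the rate, reset momentum
            W1[:] = sW1
            b1[:] = sb1
            W2[:] = sW2
            b2[:] = sb2
            vW1[:] = 0.0
            vb1[:] = 0.0
            vW2[:] = 0.0
            vb2[:] = 0.0
            lr *= 0.7
            val_trace[epoch] = prev_val
            if lr < 1e-12:
                break
        else:
            if val_err < prev_val:
                lr *= 1.05
            else:
                lr *= 0.7
                vW1[:] = svW1 * 0.0
                vb1[:] = svb1 * 0.0
                vW2[:] = svW2 * 0.0
                vb2[:] = svb2 * 0.0
            prev_val = val_err
            val_trace[epoch] = val_err

        if prev_val < best_val - 1e-12:
            best_val = prev_val
            best_W1[:] = W1
            best_b1[:] = b1
            best_W2[:] = W2
            best_b2[:] = b2
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break

    return best_W1, best_b1, best_W2, best_b2, best_val, n_epochs, val_trace[:n_epochs]
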