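"""Synthetic inputs with known ground truth for every pipeline stage.

Generators cover: stationary linear VAR(p) systems with known coefficient
matrices, nonlinear MVAR systems with specified cross-lag terms,
flicker-entrained oscillatory epochs (SSVEP-style frequency tagging),
clustered voxel hotspots on a regular grid, and subject-level directed
connectivity samples with stated asymmetries. Every generator is
bit-reproducible given its spec (the seed lives in the spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import EpochedSeries, VoxelActivityMap

__all__ = [
    "LinearVARSpec",
    "NonlinearVARSpec",
    "NLTerm",
    "FlickerSpec",
    "Hotspot",
    "VoxelFieldSpec",
    "StabilityError",
    "gen_linear_var",
    "gen_nonlinear_var",
    "gen_ssvep_epochs",
    "gen_voxel_field",
    "gen_subject_connectivity",
    "companion_spectral_radius",
    "one_over_f_noise",
]


class StabilityError(ValueError):
    """Raised for non-stationary coefficient sets or divergent trajectories."""


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix for coefficients A (p, M, M)."""
    p, M, _ = A.shape
    comp = np.zeros((M * p, M * p))
    for lag in range(p):
        comp[:M, lag * M : (lag + 1) * M] = A[lag]
    if p > 1:
        comp[M:, : M * (p - 1)] = np.eye(M * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class LinearVARSpec:
    """Stationary linear VAR(p) generating process.

    ``A[lag][j, i]`` is the coefficient of channel i (source) at that lag
    in the update of channel j (target) — the generating counterpart of
    the autoregressive map the connectivity stage estimates.
    """

    M: int
    p_true: int
    A: np.ndarray  # (p_true, M, M)
    noise_sd: float | np.ndarray = 1.0
    n_samples: int = 4000
    n_trials: int = 1
    seed: int = 0
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.p_true, self.M, self.M):
            raise ValueError(
                f"A must have shape (p_true, M, M) = ({self.p_true}, {self.M}, {self.M})"
            )
        rho = companion_spectral_radius(self.A)
        if rho >= 1.0:
            raise StabilityError(
                f"coefficient matrices are non-stationary: companion spectral radius {rho:.3f} >= 1"
            )
        if self.n_samples <= 10 * self.M * self.p_true:
            raise ValueError(
                f"n_samples must exceed 10*M*p_true = {10 * self.M * self.p_true}"
            )
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.M,)
        ).copy()

    @property
    def burn_in(self) -> int:
        # discard initialization transients; paper-silent convention
        return 10 * self.p_true * self.M


@dataclass(frozen=True)
class NLTerm:
    """One nonlinear cross-lag term added to a target channel's update.

    ``form`` is one of ``square``, ``tanh``, ``product``; ``product``
    multiplies the lagged samples of ``source`` and ``source2``
    (``source2`` defaults to ``source``, reducing to a square).
    All forms are smooth and zero-preserving.
    """

    target: int
    source: int
    lag: int
    form: str = "square"
    gain: float = 0.3
    source2: int | None = None


@dataclass
class NonlinearVARSpec:
    """A linear VAR base plus explicit nonlinear cross-lag terms."""

    base: LinearVARSpec
    nl_terms: Sequence[NLTerm] = ()
    divergence_bound: float = 1e6

    def __post_init__(self) -> None:
        for term in self.nl_terms:
            if not (1 <= term.lag <= self.base.p_true):
                raise ValueError(f"nl_term lag {term.lag} exceeds model order {self.base.p_true}")
            if not np.isfinite(term.gain):
                raise ValueError("nl_term gain must be finite")
            if term.form not in ("square", "tanh", "product"):
                raise ValueError(f"unknown nonlinear form {term.form!r}")
            for ch in (term.target, term.source, term.source2 or 0):
                if not (0 <= ch < self.base.M):
                    raise ValueError(f"channel index {ch} out of range")


def _simulate_nmvar(
    spec: LinearVARSpec,
    nl_terms: Sequence[NLTerm],
    divergence_bound: float,
) -> np.ndarray:
    """Shared simulator; empty nl_terms reproduces the linear process bit-for-bit."""
    M, p = spec.M, spec.p_true
    n_total = spec.n_samples + spec.burn_in
    rng = np.random.default_rng(spec.seed)
    out = np.empty((M, spec.n_samples, spec.n_trials))
    for trial in range(spec.n_trials):
        eps = rng.standard_normal((n_total, M)) * spec.noise_sd
        x = np.zeros((n_total, M))
        x[:p] = eps[:p]
        for n in range(p, n_total):
            xn = eps[n].copy()
            for lag in range(p):
                xn += spec.A[lag] @ x[n - 1 - lag]
            for term in nl_terms:
                u = x[n - term.lag, term.source]
                if term.form == "square":
                    contrib = u * u
                elif term.form == "tanh":
                    contrib = np.tanh(u)
                else:  # product
                    v = x[n - term.lag, term.source2 if term.source2 is not None else term.source]
                    contrib = u * v
                xn[term.target] += term.gain * contrib
            if np.any(np.abs(xn) > divergence_bound):
                culprit = nl_terms[0] if nl_terms else None
                detail = (
                    f" (first nonlinear term: target {culprit.target}, source {culprit.source}, "
                    f"form {culprit.form}, gain {culprit.gain})"
                    if culprit is not None
                    else ""
                )
                raise StabilityError(
                    f"trajectory diverged beyond |x| > {divergence_bound:g} at sample {n}{detail}"
                )
            x[n] = xn
        out[:, :, trial] = x[spec.burn_in :].T
    return out


def _to_epochs(spec: LinearVARSpec, data: np.ndarray) -> EpochedSeries:
    times = np.arange(spec.n_samples) / spec.sampling_rate
    return EpochedSeries(data=data, sampling_rate=spec.sampling_rate, times=times, lock="cue")


def gen_linear_var(spec: LinearVARSpec) -> tuple[EpochedSeries, np.ndarray]:
    """Simulate a stationary linear VAR(p).

    Returns the epoched series (after burn-in removal) and the
    ground-truth adjacency: ``adj[i, j]`` is True iff any lag carries a
    nonzero coefficient from channel i into channel j.
    """
    data = _simulate_nmvar(spec, (), np.inf)
    adj = np.any(spec.A != 0, axis=0).T  # A[lag][j, i] -> adj[i, j]
    return _to_epochs(spec, data), adj


def gen_nonlinear_var(
    spec: NonlinearVARSpec,
) -> tuple[EpochedSeries, np.ndarray, np.ndarray]:
    """Simulate a nonlinear MVAR: linear VAR base plus nonlinear terms.

    Returns (series, linear adjacency, nonlinear adjacency). With no
    nonlinear terms the output is sample-identical to
    :func:`gen_linear_var` at equal seed.
    """
    base = spec.base
    data = _simulate_nmvar(base, spec.nl_terms, spec.divergence_bound)
    adj_lin = np.any(base.A != 0, axis=0).T
    adj_nl = np.zeros((base.M, base.M), dtype=bool)
    for term in spec.nl_terms:
        adj_nl[term.source, term.target] = True
        if term.source2 is not None:
            adj_nl[term.source2, term.target] = True
    return _to_epochs(base, data), adj_lin, adj_nl


def one_over_f_noise(
    n_samples: int, exponent: float, rng: np.random.Generator, n_series: int = 1
) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, unit variance."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


@dataclass
class FlickerSpec:
    """Flicker-entrained oscillatory epochs (frequency-tagging emulation).

    One channel per entry in ``channel_names``; each trial is a sinusoid
    at ``flicker_freq`` inside the flicker interval (raised-cosine
    ramped) on top of 1/f plus white noise.
    """

    flicker_freq: float = 4.5
    sampling_rate: float = 256.0
    epoch_window: tuple[float, float] = (-2.0, 4.0)
    flicker_interval: tuple[float, float] = (0.0, 2.0)
    amplitude: float = 1.0
    onset_latency_jitter: float = 0.0
    pink_exponent: float = 1.0
    pink_sd: float = 1.0
    white_sd: float = 0.5
    ramp: float = 0.05
    n_trials: int = 50
    n_channels: int = 1
    lock: str = "cue"
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window
        f0, f1 = self.flicker_interval
        if not (t0 <= f0 < f1 <= t1):
            raise ValueError("flicker interval must lie within the epoch window")
        if self.sampling_rate <= 4 * self.flicker_freq:
            raise ValueError("sampling_rate must exceed 4x the flicker frequency")


def gen_ssvep_epochs(spec: FlickerSpec) -> EpochedSeries:
    """Generate flicker-entrained epochs per :class:`FlickerSpec`."""
    fs = spec.sampling_rate
    times = np.arange(round((spec.epoch_window[1] - spec.epoch_window[0]) * fs)) / fs + spec.epoch_window[0]
    n_times = times.size
    rng = np.random.default_rng(spec.seed)
    data = np.zeros((spec.n_channels, n_times, spec.n_trials))
    for trial in range(spec.n_trials):
        jitter = rng.uniform(0.0, spec.onset_latency_jitter) if spec.onset_latency_jitter > 0 else 0.0
        onset = spec.flicker_interval[0] + jitter
        offset = spec.flicker_interval[1]
        envelope = np.zeros(n_times)
        inside = (times >= onset) & (times < offset)
        envelope[inside] = 1.0
        if spec.ramp > 0:
            rise = (times >= onset) & (times < onset + spec.ramp)
            envelope[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - onset) / spec.ramp))
            fall = (times >= offset - spec.ramp) & (times < offset)
            envelope[fall] = 0.5 * (1 - np.cos(np.pi * (offset - times[fall]) / spec.ramp))
        tone = spec.amplitude * envelope * np.sin(2 * np.pi * spec.flicker_freq * (times - onset))
        for ch in range(spec.n_channels):
            noise = np.zeros(n_times)
            if spec.pink_sd > 0:
                noise += spec.pink_sd * one_over_f_noise(n_times, spec.pink_exponent, rng)[0]
            if spec.white_sd > 0:
                noise += spec.white_sd * rng.standard_normal(n_times)
            data[ch, :, trial] = tone + noise
    return EpochedSeries(
        data=data, sampling_rate=fs, times=times, lock=spec.lock,
        channel_names=[f"ch{i}" for i in range(spec.n_channels)],
    )


@dataclass(frozen=True)
class Hotspot:
    center: tuple[float, float, float]
    radius: float = 10.0
    peak: float = 5.0


@dataclass
class VoxelFieldSpec:
    """Regular voxel grid with Gaussian power hotspots and a label field.

    ``label_fn`` maps an (N, 3) coordinate array to integer labels; the
    default labels every voxel 1 (generic grey matter). Overlapping
    hotspots add.
    """

    extent: tuple[tuple[float, float], ...] = ((-40.0, 40.0), (-40.0, 40.0), (-40.0, 40.0))
    edge_length: float = 5.0
    hotspots: Sequence[Hotspot] = ()
    background_scale: float = 0.2
    label_fn: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_length <= 0:
            raise ValueError("edge length must be positive")


def gen_voxel_field(spec: VoxelFieldSpec) -> VoxelActivityMap:
    """Generate a gridded activity map: exponential background + hotspots."""
    axes = [
        np.arange(lo, hi + 0.5 * spec.edge_length, spec.edge_length)
        for lo, hi in spec.extent
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rng = np.random.default_rng(spec.seed)
    power = rng.exponential(spec.background_scale, size=grid.shape[0])
    for hs in spec.hotspots:
        d2 = np.sum((grid - np.asarray(hs.center)) ** 2, axis=1)
        power += hs.peak * np.exp(-d2 / hs.radius**2)
    if spec.label_fn is not None:
        labels = np.asarray(spec.label_fn(grid), dtype=int)
        if labels.shape != (grid.shape[0],):
            raise ValueError("label_fn must return one integer label per voxel")
    else:
        labels = np.ones(grid.shape[0], dtype=int)
    return VoxelActivityMap(grid, power, labels, spec.edge_length)


def gen_subject_connectivity(
    n_subjects: int,
    pairs: Sequence[tuple[str, str]],
    mean_offsets: Sequence[float] | float = 0.0,
    subject_sd: float = 0.2,
    seed: int = 0,
    base_level: float = 0.5,
    phase: str = "action_planning",
    measure: str = "linear",
) -> pd.DataFrame:
    """Per-subject directed connectivity values with known asymmetries.

    For each ROI pair (a, b) the a->b direction exceeds b->a by the
    pair's ``mean_offset`` in expectation. ``subject_sd`` is the standard
    deviation of the within-subject directional difference (each
    direction receives independent noise with sd ``subject_sd/sqrt(2)``),
    so an offset of ``subject_sd`` is a paired effect size of d = 1.

    Returns tidy long-format records: subject, phase, measure, a, b,
    direction, value.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    offsets = np.broadcast_to(np.asarray(mean_offsets, dtype=float), (len(pairs),))
    rng = np.random.default_rng(seed)
    rows = []
    dir_sd = subject_sd / np.sqrt(2.0)
    for (a, b), off in zip(pairs, offsets):
        fwd = base_level + off + rng.normal(0.0, dir_sd, n_subjects)
        bwd = base_level + rng.normal(0.0, dir_sd, n_subjects)
        for s in range(n_subjects):
            rows.append((s, phase, measure, a, b, "a->b", fwd[s]))
            rows.append((s, phase, measure, a, b, "b->a", bwd[s]))
    return pd.DataFrame(
        rows, columns=["subject", "phase", "measure", "a", "b", "direction", "value"]
    )
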