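"""Time-frequency decomposition and the frequency-tagging contrast.

The stage mirrors the study design: Morlet wavelet power (5 cycles,
Gaussian envelope truncated at +/-3 SD) averaged over trials, relative
change against a pre-stimulus baseline window (default -350 to -150 ms),
the theta-tag contrast (power under 4.5 Hz flicker minus power under the
8 Hz control flicker, both measured at the tag frequency), and the
segmentation of the time course into the three canonical analysis phases.
"""

from __future__ import annotations

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .containers import CANONICAL_PHASES, EpochedSeries, PhaseWindow, TFPower

__all__ = [
    "morlet_tfr",
    "baseline_normalize",
    "frequency_contrast",
    "segment_phases",
    "wavelet_half_support",
]

#: Gaussian envelope truncation, in standard deviations of the envelope.
SUPPORT_SD = 3.0


def wavelet_half_support(freq: float, n_cycles: float) -> float:
    """Half-length (s) of the truncated Morlet wavelet at one frequency.

    The envelope SD is ``n_cycles / (2*pi*f)``; the wavelet is treated as
    supported on +/- SUPPORT_SD standard deviations.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    return SUPPORT_SD * sigma_t


def morlet_tfr(
    epochs: EpochedSeries,
    freqs: np.ndarray,
    n_cycles: float = 5.0,
) -> TFPower:
    """Morlet wavelet power, averaged over trials.

    Edge samples closer to an epoch boundary than the wavelet
    half-support at each frequency are flagged invalid and excluded from
    downstream statistics (they are contaminated by zero-padding).

    Raises
    ------
    ValueError
        If a requested frequency reaches the Nyquist rate or its wavelet
        is longer than the epoch.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    fs = epochs.sampling_rate
    if freqs.max() >= fs / 2:
        raise ValueError(f"max frequency {freqs.max()} Hz >= Nyquist ({fs / 2} Hz)")
    duration = epochs.times[-1] - epochs.times[0]
    for f in freqs:
        if 2 * wavelet_half_support(f, n_cycles) > duration:
            raise ValueError(
                f"wavelet support at {f} Hz ({2 * wavelet_half_support(f, n_cycles):.2f} s) "
                f"exceeds the epoch duration ({duration:.2f} s)"
            )
    # mne expects (n_epochs, n_channels, n_times)
    arr = np.transpose(epochs.data, (2, 0, 1))
    power = tfr_array_morlet(
        arr, sfreq=fs, freqs=freqs, n_cycles=n_cycles, output="power", zero_mean=True
    )
    power = power.mean(axis=0)  # (channels, freqs, times)
    valid = np.ones((freqs.size, epochs.times.size), dtype=bool)
    for k, f in enumerate(freqs):
        half = wavelet_half_support(f, n_cycles)
        valid[k] = (epochs.times - epochs.times[0] >= half) & (
            epochs.times[-1] - epochs.times >= half
        )
    return TFPower(
        power=power,
        freqs=freqs,
        times=epochs.times.copy(),
        sampling_rate=fs,
        lock=epochs.lock,
        channel_names=list(epochs.channel_names),
        state="raw",
        valid=valid,
    )


def baseline_normalize(
    tfr: TFPower,
    baseline: tuple[float, float] = (-0.350, -0.150),
    baseline_source: TFPower | None = None,
) -> TFPower:
    """Relative power change against a baseline window.

    Per channel and frequency: ``(P(t) - mean_baseline) / mean_baseline``.
    ``baseline_source`` lets the baseline be computed on a different
    (e.g., cue-locked) decomposition and applied to the present
    (e.g., effect-locked) one, matching designs where the pre-stimulus
    interval does not exist in the response-locked epoch.
    """
    if tfr.state != "raw":
        raise ValueError(f"input must be raw power, got state {tfr.state!r}")
    src = baseline_source if baseline_source is not None else tfr
    if src.state != "raw":
        raise ValueError("baseline source must be raw power")
    mask = (src.times >= baseline[0]) & (src.times < baseline[1])
    if not mask.any():
        raise ValueError(f"baseline window {baseline} contains no samples")
    if not src.valid[:, mask].all():
        raise ValueError("baseline window overlaps wavelet edge-invalid samples")
    base = src.power[:, :, mask].mean(axis=2)  # (channels, freqs)
    bad = np.argwhere(base == 0)
    if bad.size:
        ch, fr = bad[0]
        raise ZeroDivisionError(
            f"mean baseline power is zero for channel {src.channel_names[ch]!r} "
            f"at {src.freqs[fr]} Hz"
        )
    norm = (tfr.power - base[:, :, None]) / base[:, :, None]
    return TFPower(
        power=norm,
        freqs=tfr.freqs.copy(),
        times=tfr.times.copy(),
        sampling_rate=tfr.sampling_rate,
        lock=tfr.lock,
        channel_names=list(tfr.channel_names),
        state="baseline_normalized",
        valid=tfr.valid.copy(),
        baseline=baseline,
    )


def frequency_contrast(tfr_tag: TFPower, tfr_ctrl: TFPower) -> TFPower:
    """Tag-minus-control contrast of baseline-normalized power.

    Both inputs are evaluated at the same measured frequencies (the tag
    frequency); they differ in which flicker drove the recording. The
    contrast is antisymmetric in its arguments.
    """
    for t in (tfr_tag, tfr_ctrl):
        if t.state != "baseline_normalized":
            raise ValueError("contrast inputs must be baseline-normalized")
    if (
        tfr_tag.power.shape != tfr_ctrl.power.shape
        or not np.allclose(tfr_tag.times, tfr_ctrl.times)
        or not np.allclose(tfr_tag.freqs, tfr_ctrl.freqs)
        or tfr_tag.channel_names != tfr_ctrl.channel_names
    ):
        raise ValueError("contrast inputs must share channel, frequency and time axes")
    return TFPower(
        power=tfr_tag.power - tfr_ctrl.power,
        freqs=tfr_tag.freqs.copy(),
        times=tfr_tag.times.copy(),
        sampling_rate=tfr_tag.sampling_rate,
        lock=tfr_tag.lock,
        channel_names=list(tfr_tag.channel_names),
        state="contrasted",
        valid=tfr_tag.valid & tfr_ctrl.valid,
        baseline=tfr_tag.baseline,
    )


def _slice(tfr: TFPower, window: PhaseWindow) -> TFPower:
    mask = (tfr.times >= window.interval[0]) & (tfr.times < window.interval[1])
    return TFPower(
        power=tfr.power[:, :, mask],
        freqs=tfr.freqs.copy(),
        times=tfr.times[mask],
        sampling_rate=tfr.sampling_rate,
        lock=tfr.lock,
        channel_names=list(tfr.channel_names),
        state=tfr.state,
        valid=tfr.valid[:, mask],
        baseline=tfr.baseline,
    )


def segment_phases(
    tfrs: dict[str, TFPower],
    phases: tuple[PhaseWindow, ...] = CANONICAL_PHASES,
) -> dict[PhaseWindow, TFPower]:
    """Slice lock-specific decompositions into the analysis phases.

    ``tfrs`` maps lock name ("cue", "action_effect") to a TFPower.
    Intervals are half-open [start, end): the sample at exactly 1.0 s
    belongs to the standby phase, not action planning.
    """
    out: dict[PhaseWindow, TFPower] = {}
    for window in phases:
        if window.lock not in tfrs:
            raise KeyError(
                f"phase {window.name!r} needs a {window.lock!r}-locked decomposition"
            )
        out[window] = _slice(tfrs[window.lock], window)
    return out
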