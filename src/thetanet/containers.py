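"""Core in-memory containers shared across pipeline stages.

The pipeline operates on event-locked multichannel trials
(:class:`EpochedSeries`), their time-frequency power (:class:`TFPower`),
gridded source-power maps (:class:`VoxelActivityMap`), density-clustered
regions of interest (:class:`ROICluster`), and fitted directed-connectivity
results (:class:`ConnectivityResult`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EpochedSeries",
    "TFPower",
    "PhaseWindow",
    "VoxelActivityMap",
    "ROICluster",
    "ConnectivityResult",
]


@dataclass
class EpochedSeries:
    """Event-locked multichannel trials.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_times, n_trials)
        Signal in arbitrary units.
    sampling_rate : float
        Samples per second.
    times : ndarray, shape (n_times,)
        Time axis in seconds relative to the lock event; strictly
        increasing and uniformly spaced.
    lock : str
        Event the epoch is locked to, ``"cue"`` or ``"action_effect"``.
    channel_names : list of str
    """

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    lock: str = "cue"
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (channels, times, trials); got shape {self.data.shape}"
            )
        if self.data.shape[1] != self.times.size:
            raise ValueError("time axis length does not match data")
        dt = np.diff(self.times)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time axis must be strictly increasing and uniform")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def save(self, path: str | Path) -> None:
        """Write the array container plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), data=self.data, times=self.times)
        meta = {
            "sampling_rate": self.sampling_rate,
            "lock": self.lock,
            "channel_names": self.channel_names,
            "units": "arbitrary",
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EpochedSeries":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=arrs["data"],
            times=arrs["times"],
            sampling_rate=meta["sampling_rate"],
            lock=meta["lock"],
            channel_names=meta["channel_names"],
        )


@dataclass
class TFPower:
    """Channels x frequencies x time power with processing-state flags.

    ``state`` is one of ``raw`` (trial-averaged wavelet power,
    non-negative), ``baseline_normalized`` (relative change versus a
    baseline window) or ``contrasted`` (tag-minus-control difference of
    normalized power). ``valid`` marks samples outside the wavelet
    edge-effect zone.
    """

    power: np.ndarray  # (n_channels, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    sampling_rate: float
    lock: str = "cue"
    channel_names: list[str] = field(default_factory=list)
    state: str = "raw"
    valid: np.ndarray | None = None  # (n_freqs, n_times) bool
    baseline: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be (channels, freqs, times)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency axis must be increasing")
        if self.state == "raw" and np.any(self.power < -1e-12):
            raise ValueError("raw power must be non-negative")
        if self.valid is None:
            self.valid = np.ones((self.freqs.size, self.times.size), dtype=bool)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.power.shape[0])]


@dataclass(frozen=True)
class PhaseWindow:
    """A named analysis phase: a half-open time interval on one lock.

    The three canonical phases are action_planning (cue-locked, 0-1 s),
    standby (cue-locked, 1-2 s) and perception (effect-locked, 0-1 s).
    """

    name: str
    lock: str
    interval: tuple[float, float]

    def contains(self, t: float) -> bool:
        """Half-open membership: start <= t < end."""
        return self.interval[0] <= t < self.interval[1]


#: The three canonical analysis phases.
CANONICAL_PHASES = (
    PhaseWindow("action_planning", "cue", (0.0, 1.0)),
    PhaseWindow("standby", "cue", (1.0, 2.0)),
    PhaseWindow("perception", "action_effect", (0.0, 1.0)),
)


@dataclass
class VoxelActivityMap:
    """Source power on a regular grid with anatomical labels.

    ``labels`` are integer atlas codes; 0 means outside the brain.
    """

    coordinates: np.ndarray  # (N, 3) mm
    power: np.ndarray  # (N,)
    labels: np.ndarray  # (N,) int
    edge_length: float = 5.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.coordinates.shape[0]
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (N, 3)")
        if self.power.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("power and labels must match coordinates")
        if self.edge_length <= 0:
            raise ValueError("edge length must be positive")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        # coordinates must be unique grid points
        scaled = np.round(self.coordinates / self.edge_length).astype(int)
        if np.unique(scaled, axis=0).shape[0] != n:
            raise ValueError("coordinates must be unique grid points")

    def to_table(self, path: str | Path) -> None:
        """Write as a delimited table (x, y, z, power, label)."""
        arr = np.column_stack([self.coordinates, self.power, self.labels])
        header = "x\ty\tz\tpower\tlabel"
        np.savetxt(path, arr, delimiter="\t", header=header, comments="")

    @classmethod
    def from_table(cls, path: str | Path, edge_length: float = 5.0) -> "VoxelActivityMap":
        arr = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(arr[:, :3], arr[:, 3], arr[:, 4].astype(int), edge_length)


@dataclass
class ROICluster:
    """A named region of interest assembled from clustered voxels."""

    members: np.ndarray  # voxel indices into the parent map
    cluster_id: int
    roi_name: str
    centroid: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int)
        if self.members.size == 0:
            raise ValueError("ROI cluster must have at least one member voxel")
        self.centroid = np.asarray(self.centroid, dtype=float)


@dataclass
class ConnectivityResult:
    """Directed connectivity estimates for one subject/condition.

    ``lC[i, j]`` is the linear influence of channel i on channel j
    (non-negative under the default absolute-coefficient aggregation);
    ``NC[i, j]`` is the nonlinear influence, a natural-log error ratio.
    Diagonals are reported but excluded from asymmetry inference.
    """

    lC: np.ndarray
    NC: np.ndarray
    roi_names: list[str]
    mse_train: float = np.nan
    mse_test: float = np.nan
    r2_train: float = np.nan
    r2_test: float = np.nan
    fold_metrics: list[dict] = field(default_factory=list)
    sig_lC: np.ndarray | None = None
    sig_NC: np.ndarray | None = None
    order: int | None = None

    def __post_init__(self) -> None:
        self.lC = np.asarray(self.lC, dtype=float)
        self.NC = np.asarray(self.NC, dtype=float)
        if self.lC.shape != self.NC.shape or self.lC.ndim != 2:
            raise ValueError("lC and NC must be square matrices of equal shape")
        if not np.all(np.isfinite(self.NC)):
            raise ValueError("NC must be finite")

    def to_json(self, path: str | Path) -> None:
        out = {
            "roi_names": self.roi_names,
            "lC": self.lC.tolist(),
            "NC": self.NC.tolist(),
            "mse_train": self.mse_train,
            "mse_test": self.mse_test,
            "r2_train": self.r2_train,
            "r2_test": self.r2_test,
            "order": self.order,
            "fold_metrics": self.fold_metrics,
            "sig_lC": None if self.sig_lC is None else self.sig_lC.tolist(),
            "sig_NC": None if self.sig_NC is None else self.sig_NC.tolist(),
        }
        Path(path).write_text(json.dumps(out, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConnectivityResult":
        d = json.loads(Path(path).read_text())
        return cls(
            lC=np.array(d["lC"]),
            NC=np.array(d["NC"]),
            roi_names=d["roi_names"],
            mse_train=d["mse_train"],
            mse_test=d["mse_test"],
            r2_train=d["r2_train"],
            r2_test=d["r2_test"],
            fold_metrics=d.get("fold_metrics", []),
            sig_lC=None if d["sig_lC"] is None else np.array(d["sig_lC"], dtype=bool),
            sig_NC=None if d["sig_NC"] is None else np.array(d["sig_NC"], dtype=bool),
            order=d.get("order"),
        )
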