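"""Shared data containers for the envelope-tracking pipeline.

Everything downstream operates on a handful of small, validated containers:
waveforms and their slow amplitude envelopes, sparse acoustic-landmark event
tables, the impulse series that drives the two response models, evoked-response
kernels, continuous (multi-)channel response series, oscillator trajectories,
and band-resolved phase maps.  Containers are plain frozen-ish dataclasses with
numpy payloads plus light CSV / WAV / HDF5 round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "EnvelopeSeries",
    "LandmarkEvents",
    "EventInputSeries",
    "Kernel",
    "ResponseSeries",
    "OscillatorTrajectory",
    "BandSpec",
    "TFPhaseMap",
    "EpochedPhases",
    "NoiseConfig",
]


def _as_float_array(x, name: str, ndim: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class Waveform:
    """A sampled acoustic pressure signal (arbitrary units)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def to_wav(self, path: str | Path) -> None:
        wavfile.write(str(path), int(round(self.fs)), self.samples.astype(np.float32))

    @classmethod
    def from_wav(cls, path: str | Path) -> "Waveform":
        fs, data = wavfile.read(str(path))
        data = np.asarray(data)
        if data.ndim == 2:  # average channels of stereo input
            data = data.mean(axis=1)
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return cls(samples=np.asarray(data, dtype=float), fs=float(fs))


@dataclass
class EnvelopeSeries:
    """Amplitude envelope (a.u.) or its temporal derivative (a.u./s)."""

    values: np.ndarray
    fs: float
    kind: Literal["envelope", "derivative"] = "envelope"

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.kind not in ("envelope", "derivative"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "envelope" and self.values.size and self.values.min() < -1e-9:
            raise ValueError("envelope values must be non-negative")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


@dataclass
class LandmarkEvents:
    """Sparse acoustic-edge events: times (s) and magnitudes.

    ``kind`` distinguishes peaks of the envelope derivative (``peakRate``,
    acoustic edges) from peaks of the envelope itself (``peakEnv``).
    """

    times: np.ndarray
    magnitudes: np.ndarray
    kind: Literal["peakRate", "peakEnv"] = "peakRate"

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.magnitudes = _as_float_array(self.magnitudes, "magnitudes")
        if self.times.shape != self.magnitudes.shape:
            raise ValueError("times and magnitudes must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if self.magnitudes.size and self.magnitudes.min() <= 0:
            raise ValueError("event magnitudes must be positive")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "magnitude": self.magnitudes, "kind": self.kind}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkEvents":
        df = pd.read_csv(path)
        kind = str(df["kind"].iloc[0]) if len(df) else "peakRate"
        return cls(
            times=df["time_s"].to_numpy(float),
            magnitudes=df["magnitude"].to_numpy(float),
            kind=kind,  # type: ignore[arg-type]
        )


@dataclass
class EventInputSeries:
    """Model input s(t): scaled impulses at event samples, zeros elsewhere."""

    s: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.s = _as_float_array(self.s, "s")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.s.size and self.s.min() < 0:
            raise ValueError("s must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.s.size


@dataclass
class Kernel:
    """Evoked-response waveform over a lag window relative to the event.

    ``lag_window`` follows the encoding-model convention: (-0.15, 0.45) means
    the kernel starts 150 ms *before* the event sample.
    """

    values: np.ndarray
    fs: float
    lag_window: tuple[float, float] = (-0.15, 0.45)

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values")
        start, end = self.lag_window
        if end <= start:
            raise ValueError("lag_window end must exceed start")
        expected = int(round((end - start) * self.fs)) + 1
        if self.values.size != expected:
            raise ValueError(
                f"kernel length {self.values.size} does not match lag window "
                f"{self.lag_window} at fs={self.fs} (expected {expected})"
            )

    @property
    def lags(self) -> np.ndarray:
        return self.lag_window[0] + np.arange(self.values.size) / self.fs

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"lag_s": self.lags, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, fs: float | None = None) -> "Kernel":
        df = pd.read_csv(path)
        lags = df["lag_s"].to_numpy(float)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(lags)))
        return cls(
            values=df["value"].to_numpy(float),
            fs=float(fs),
            lag_window=(float(lags[0]), float(lags[-1])),
        )


@dataclass
class ResponseSeries:
    """Continuous response time series, channels x samples."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError("data must be 1-D or 2-D (channels x samples)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("data contains non-finite values")
        self.data = arr
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, idx: int = 0) -> np.ndarray:
        return self.data[idx]

    def to_hdf5(self, path: str | Path, event_times: np.ndarray | None = None) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["fs"] = self.fs
            if event_times is not None:
                f.create_dataset("event_times", data=np.asarray(event_times, float))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "ResponseSeries":
        with h5py.File(path, "r") as f:
            return cls(data=f["data"][...], fs=float(f.attrs["fs"]))


@dataclass
class OscillatorTrajectory:
    """Phase/amplitude trajectory of the entrainment model plus its readout.

    ``pred`` is the reconstructed predicted response cos(theta) * r.
    """

    theta: np.ndarray
    r: np.ndarray
    pred: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.theta = _as_float_array(self.theta, "theta")
        self.r = _as_float_array(self.r, "r")
        self.pred = _as_float_array(self.pred, "pred")
        if not (self.theta.size == self.r.size == self.pred.size):
            raise ValueError("theta, r, pred must have equal length")
        if self.r.size and self.r.min() < 0:
            raise ValueError("r must stay non-negative")

    def to_hdf5(self, path: str | Path, **attrs) -> None:
        with h5py.File(path, "w") as f:
            for name in ("theta", "r", "pred"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["fs"] = self.fs
            for k, v in attrs.items():
                f.attrs[k] = v


@dataclass
class BandSpec:
    """Logarithmically spaced analysis bands with a common octave half-width."""

    centers: np.ndarray
    half_width: float

    def __post_init__(self) -> None:
        self.centers = _as_float_array(self.centers, "centers")
        if self.centers.size < 1 or np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be non-empty and strictly increasing")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    @property
    def n_bands(self) -> int:
        return self.centers.size

    def edges(self, index: int) -> tuple[float, float]:
        """Passband edges (Hz) of one band: center * 2**(+-half_width)."""
        c = self.centers[index]
        return c * 2.0 ** (-self.half_width), c * 2.0**self.half_width


@dataclass
class TFPhaseMap:
    """Analytic-signal phase and amplitude per band over time."""

    phase: np.ndarray  # bands x samples, radians in (-pi, pi]
    amplitude: np.ndarray  # bands x samples, >= 0
    fs: float
    band_spec: BandSpec

    def __post_init__(self) -> None:
        self.phase = _as_float_array(self.phase, "phase", ndim=2)
        self.amplitude = _as_float_array(self.amplitude, "amplitude", ndim=2)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude shapes differ")
        if self.phase.shape[0] != self.band_spec.n_bands:
            raise ValueError("band dimension does not match band_spec")

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]


@dataclass
class EpochedPhases:
    """Event-locked phase epochs: events x bands x time."""

    phase: np.ndarray
    window: tuple[float, float]
    fs: float
    band_spec: BandSpec
    event_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 3:
            raise ValueError("phase must be events x bands x time")
        self.event_index = np.asarray(self.event_index, dtype=int)

    @property
    def n_events(self) -> int:
        return self.phase.shape[0]

    @property
    def times(self) -> np.ndarray:
        start = self.window[0]
        return start + np.arange(self.phase.shape[2]) / self.fs


@dataclass
class NoiseConfig:
    """Randomisation settings for the model ensembles.

    snr is the signal-to-noise ratio of the added 1/f noise; by default it is
    a power ratio (the conventional reading of SNR; 0.1 means ten times the
    signal's power, i.e. ~3.2x its RMS amplitude), configurable to an
    amplitude (RMS) ratio via snr_domain.
    """

    snr: float = 0.1
    spectral_exponent: float = 1.0
    jitter_sd: float = 0.010
    n_temporal_iters: int = 64
    n_amplitude_iters: int = 40
    seed: int = 0
    snr_domain: Literal["amplitude", "power"] = "power"

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.n_temporal_iters < 1 or self.n_amplitude_iters < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.snr_domain not in ("amplitude", "power"):
            raise ValueError("snr_domain must be 'amplitude' or 'power'")

    @property
    def n_total_iters(self) -> int:
        return self.n_temporal_iters * self.n_amplitude_iters

    def with_(self, **kwargs) -> "NoiseConfig":
        return replace(self, **kwargs)
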