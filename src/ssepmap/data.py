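"""Core containers: continuous recordings, epoch tensors, evoked potentials,
and the analysis configuration.

Conventions used throughout the package:

* voltages are microvolts (uV);
* time is milliseconds relative to stimulus onset (onset = 0);
* sample windows are half-open ``[t0, t1)``; frame 0 is the first sample
  of an epoch;
* every randomised operation takes a seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .montage import Montage

__all__ = ["Event", "Recording", "EpochSet", "Evoked", "AnalysisConfig"]

UNLABELED = -1


@dataclass(frozen=True)
class Event:
    """Stimulus marker: sample index plus nerve/side tags."""

    sample: int
    nerve: str = "median"   # "median" | "tibial"
    side: str = "left"      # "left" | "right"


@dataclass
class Recording:
    """Continuous multichannel EEG, vertex-referenced.

    data : (n_channels, n_samples) uV, channels ordered as
        ``montage.recorded_ids`` (the reference is implicit, identically 0).
    """

    data: np.ndarray
    rate: float
    events: list[Event]
    montage: Montage

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.data.shape[0] != self.montage.n_recorded:
            raise ValueError(
                f"channel count {self.data.shape[0]} != montage recorded "
                f"count {self.montage.n_recorded}"
            )
        self.events = sorted(self.events, key=lambda e: e.sample)
        for ev in self.events:
            if not (0 <= ev.sample < self.data.shape[1]):
                raise ValueError(f"event at sample {ev.sample} outside data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


def _window_frames(window_ms, rate) -> tuple[int, int]:
    """Half-open frame range [i0, i1) for a ms window at ``rate`` Hz."""
    t0, t1 = window_ms
    i0 = int(round(t0 * rate / 1000.0))
    i1 = int(round(t1 * rate / 1000.0))
    return i0, i1


@dataclass
class EpochSet:
    """Trials x channels x samples tensor sharing one peri-stimulus window.

    ``window`` is (t_min, t_max) in ms relative to stimulus onset; the
    half-open sample range means the epoch holds ``(t_max - t_min) / dt``
    frames, frame 0 at ``t_min``.
    """

    data: np.ndarray
    rate: float
    window: tuple[float, float]
    montage: Montage
    kept_mask: np.ndarray | None = None
    baseline_applied: bool = False
    reference_mode: str = "vertex"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if not (self.window[0] <= 0.0 <= self.window[1]):
            raise ValueError("epoch window must contain stimulus onset (0 ms)")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.shape != (self.data.shape[0],):
            raise ValueError("kept_mask must be per-trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def times(self) -> np.ndarray:
        """Frame times in ms (frame 0 = window start).

        Times sit on the global sample grid (integer multiples of the
        sample period), so identical instants compare bit-identically
        across containers.
        """
        n = self.data.shape[2]
        i0 = int(round(self.window[0] * self.rate / 1000.0))
        return (i0 + np.arange(n)) * 1000.0 / self.rate


@dataclass
class Evoked:
    """Averaged SSEP: channels x samples, with averaging metadata.

    In ``"vertex"`` reference mode the rows are the recorded channels; in
    ``"average"`` mode the reference has been recovered as an explicit
    channel (33rd for the built-in cap) and every frame is zero-mean.
    """

    data: np.ndarray
    rate: float
    window: tuple[float, float]
    montage: Montage
    n_sweeps: int = 0
    reference_mode: str = "vertex"
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if not self.channel_ids:
            if self.reference_mode == "vertex":
                self.channel_ids = list(self.montage.recorded_ids)
            else:
                self.channel_ids = list(self.montage.electrode_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ms, on the global sample grid (see EpochSet)."""
        n = self.data.shape[1]
        i0 = int(round(self.window[0] * self.rate / 1000.0))
        return (i0 + np.arange(n)) * 1000.0 / self.rate

    def frame_of(self, t_ms: float) -> int:
        """Frame index of time ``t_ms`` (nearest-sample, half-open window)."""
        i0 = int(round(self.window[0] * self.rate / 1000.0))
        return int(round(t_ms * self.rate / 1000.0)) - i0

    def crop_frames(self, window_ms) -> tuple[np.ndarray, np.ndarray]:
        """(data, times) restricted to the half-open ms window."""
        i0 = self.frame_of(window_ms[0])
        i1 = self.frame_of(window_ms[1])
        i0 = max(i0, 0)
        i1 = min(i1, self.data.shape[1])
        return self.data[:, i0:i1], self.times[i0:i1]

    def copy(self) -> "Evoked":
        return replace(self, data=self.data.copy(),
                       channel_ids=list(self.channel_ids))


@dataclass
class AnalysisConfig:
    """All tunable analysis constants, defaulting to the study settings.

    Defaults: 8-300 Hz band-pass, optional 50 Hz notch, 100 uV rejection
    threshold, -80..-30 ms baseline, segmentation windows 6-50 ms (median)
    and 10.8-60 ms (tibial), template merge at SC > 0.92, minimum segment
    length 2 frames, 13 Tikhonov regularisation levels, significance levels
    0.01 (scalp) and 0.05 (source).
    """

    filter_lo: float = 8.0
    filter_hi: float = 300.0
    notch50: bool = False
    rejection_threshold: float = 100.0
    epoch_window: tuple[float, float] = (-100.0, 200.0)
    baseline_window: tuple[float, float] = (-80.0, -30.0)
    segmentation_window_median: tuple[float, float] = (6.0, 50.0)
    segmentation_window_tibial: tuple[float, float] = (10.8, 60.0)
    k_range: tuple[int, int] = (1, 10)
    merge_sc: float = 0.92
    min_duration_frames: int = 2
    n_alphas: int = 13
    alpha_scalp: float = 0.01
    alpha_source: float = 0.05
    n_electrodes_bonferroni: int = 33
    restarts: int = 100
    seed: int = 0

    def segmentation_window(self, nerve: str) -> tuple[float, float]:
        if nerve == "median":
            return self.segmentation_window_median
        if nerve == "tibial":
            return self.segmentation_window_tibial
        raise ValueError(f"unknown nerve {nerve!r}")

    @classmethod
    def from_toml(cls, path) -> "AnalysisConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known - {"stages", "inputs", "output_dir", "nerve", "side"}
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        kw = {}
        for f in fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kw[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kw)

    def to_toml_str(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(repr(x) for x in v)}]")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v!r}")
        return "\n".join(lines) + "\n"
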