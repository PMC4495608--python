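"""Forward simulator: SSEP sessions with known microstate ground truth.

The generator emulates the acquisition protocol the pipeline targets:
5 kHz sampling, 0.5 Hz stimulus trains of 3 min (90 stimuli), a scripted
succession of quasi-stable scalp topographies driven by dipoles in a
three-shell spherical head, trial-level latency/amplitude jitter, sensor
and spatially-correlated background noise, optional 50 Hz line
contamination, planted high-amplitude artifact trials, and per-session
cap-placement perturbation (small random rotation of the electrode
positions).

The default median-nerve script has four states with boundaries at 6,
12.8, 15.2, 25.6 and 50 ms; the tibial script has three states from
10.8 ms.  Templates are built from stylised dipole placements (deep
posterior for the earliest, brainstem-like state; contralateral
parietal/frontal for the later, cortical states; the last state is a
near-inversion of the preceding one).  They are plausible, not
anatomically validated.  Single-trial noise levels are likewise a
documented package choice, not a measured quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .data import Event, Evoked, Recording, UNLABELED
from .forward import DipoleSource, HeadModel, forward_topography
from .montage import Montage
from .topography import gfp

__all__ = ["NoiseSpec", "TemplateScript", "GroundTruth", "make_default_script",
           "synthesize_session", "synthesize_sessions", "synthesize_evoked"]


@dataclass
class NoiseSpec:
    """Trial-level noise model (all amplitudes in uV).

    sensor_sd : white sensor noise SD per channel.
    background_amp : total RMS of spatially correlated background activity
        (random dipole topographies x band-limited time courses).
    jitter_sd_ms : per-trial latency jitter SD.
    amp_jitter : per-trial multiplicative amplitude jitter SD.
    line50_amp : 50 Hz line amplitude (0 = off).
    artifact_fraction : fraction of trials carrying a planted artifact.
    artifact_amp : artifact square-pulse amplitude; must exceed the
        rejection threshold to be detectable.
    """

    sensor_sd: float = 4.0
    background_amp: float = 4.0
    background_modes: int = 4
    jitter_sd_ms: float = 0.3
    amp_jitter: float = 0.1
    line50_amp: float = 0.0
    artifact_fraction: float = 0.0
    artifact_amp: float = 150.0


@dataclass
class TemplateScript:
    """K quasi-stable states: templates, time extents and GFP envelopes.

    templates : (K, n_electrodes) average-referenced, unit-GFP maps.
    onsets/offsets : ms, contiguous and non-overlapping, ordered.
    peak_times / peak_gfp : per-state envelope peak latency (ms) and
        target GFP amplitude (uV).
    """

    templates: np.ndarray
    onsets: np.ndarray
    offsets: np.ndarray
    peak_times: np.ndarray
    peak_gfp: np.ndarray
    dipoles: list[DipoleSource] = field(default_factory=list)
    kind: str = "median"
    #: envelope floor as a fraction of the state's peak GFP (keeps the
    #: topography defined right up to the state boundaries)
    env_floor: float = 0.1

    def __post_init__(self):
        self.templates = np.asarray(self.templates, float)
        self.onsets = np.asarray(self.onsets, float)
        self.offsets = np.asarray(self.offsets, float)
        self.peak_times = np.asarray(self.peak_times, float)
        self.peak_gfp = np.asarray(self.peak_gfp, float)
        if not np.all(self.onsets[1:] >= self.offsets[:-1] - 1e-9):
            raise ValueError("states must be ordered and non-overlapping")
        # enforce zero-mean, unit-GFP templates
        self.templates = self.templates - self.templates.mean(axis=1, keepdims=True)
        self.templates = self.templates / gfp(self.templates, axis=1)[:, None]

    @property
    def K(self) -> int:
        return self.templates.shape[0]

    def labels(self, times_ms: np.ndarray) -> np.ndarray:
        """Ground-truth state index per frame (UNLABELED outside states)."""
        t = np.asarray(times_ms, float)
        lab = np.full(t.shape, UNLABELED, dtype=int)
        for k in range(self.K):
            lab[(t >= self.onsets[k]) & (t < self.offsets[k])] = k
        return lab

    def gfp_envelope(self, times_ms: np.ndarray) -> np.ndarray:
        """Per-frame target GFP (uV): piecewise raised-cosine bumps."""
        t = np.asarray(times_ms, float)
        env = np.zeros(t.shape)
        for k in range(self.K):
            on, off, pk, amp = (self.onsets[k], self.offsets[k],
                                self.peak_times[k], self.peak_gfp[k])
            sel = (t >= on) & (t < off)
            tk = t[sel]
            bump = np.where(
                tk <= pk,
                0.5 * (1.0 - np.cos(np.pi * (tk - on) / max(pk - on, 1e-9))),
                0.5 * (1.0 + np.cos(np.pi * (tk - pk) / max(off - pk, 1e-9))),
            )
            env[sel] = amp * np.maximum(bump, self.env_floor)
        return env

    def signal(self, times_ms: np.ndarray) -> np.ndarray:
        """Noise-free average-referenced signal, (n_electrodes, n_frames)."""
        t = np.asarray(times_ms, float)
        lab = self.labels(t)
        env = self.gfp_envelope(t)
        out = np.zeros((self.templates.shape[1], t.shape[0]))
        for k in range(self.K):
            sel = lab == k
            out[:, sel] = self.templates[k][:, None] * env[sel][None, :]
        return out


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream validation."""

    script: TemplateScript
    label_per_frame: np.ndarray
    epoch_window: tuple[float, float]
    rate: float
    dipoles: list[DipoleSource]
    snr_db_per_trial: np.ndarray
    artifact_trials: np.ndarray
    montage_rotation: np.ndarray | None = None
    rotation_deg: float = 0.0


# stylised dipole placements per nerve/state, in brain-radius units for a
# LEFT-side stimulation (contralateral = right hemisphere, x > 0);
# (position, moment direction, sign-anchor electrode, anchor sign)
_MEDIAN_PLACEMENTS = [
    (( 0.12, -0.55, -0.45), (0.2, -0.3, 1.0), "e32", -1.0),   # brainstem-like
    (( 0.50, -0.30,  0.30), (0.2,  0.9, 0.3), "e4",  +1.0),   # parietal, tangential
    (( 0.35,  0.15,  0.50), (0.3, -0.1, 1.0), "e12", +1.0),   # sensorimotor
    (( 0.30,  0.02,  0.52), (-0.3, 0.1, -1.0), "e12", -1.0),  # inversion of 3
]
_TIBIAL_PLACEMENTS = [
    ((0.05,  0.05,  0.55), (0.1, 0.9, -0.5), "e16", -1.0),    # central negativity
    ((0.02,  0.12,  0.58), (0.0, 0.2, 1.0),  "e15", +1.0),    # midline positivity
    ((0.05,  0.02,  0.55), (0.0, -0.2, -1.0), "e15", -1.0),   # inversion of 2
]
_MEDIAN_BOUNDS = (6.0, 12.8, 15.2, 25.6, 50.0)
_MEDIAN_PEAKS = ((6.9, 2.0), (14.0, 3.0), (17.9, 5.0), (32.0, 4.0))
_TIBIAL_BOUNDS = (10.8, 16.5, 29.3, 60.0)
_TIBIAL_PEAKS = ((12.7, 2.0), (22.0, 4.0), (40.0, 3.0))


def make_default_script(kind: str, montage: Montage,
                        head: HeadModel | None = None,
                        side: str = "left") -> TemplateScript:
    """Default median (K=4) or tibial (K=3) component-map script.

    ``side`` is the stimulated side; dipoles sit contralaterally (mirrored
    in x for right-side stimulation).
    """
    head = head or HeadModel()
    if kind == "median":
        placements, bounds, peaks = _MEDIAN_PLACEMENTS, _MEDIAN_BOUNDS, _MEDIAN_PEAKS
    elif kind == "tibial":
        placements, bounds, peaks = _TIBIAL_PLACEMENTS, _TIBIAL_BOUNDS, _TIBIAL_PEAKS
    else:
        raise ValueError(f"unknown nerve kind {kind!r}")
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")
    mirror = -1.0 if side == "right" else 1.0
    rb = head.brain_radius
    templates, dipoles = [], []
    for pos, mom, anchor, sign in placements:
        p = np.array(pos) * rb
        m = np.array(mom, float)
        p[0] *= mirror
        m[0] *= mirror
        dip = DipoleSource(p, m / np.linalg.norm(m))
        v = forward_topography(head, montage, dip)
        # mirror the anchor electrode together with the geometry
        anchor_lab = montage.mirror_map.get(anchor, anchor) if mirror < 0 else anchor
        if sign * v[montage.index(anchor_lab)] < 0:
            dip = DipoleSource(p, -dip.moment)
            v = -v
        templates.append(v / gfp(v))
        dipoles.append(dip)
    return TemplateScript(
        templates=np.array(templates),
        onsets=np.array(bounds[:-1]),
        offsets=np.array(bounds[1:]),
        peak_times=np.array([p[0] for p in peaks]),
        peak_gfp=np.array([p[1] for p in peaks]),
        dipoles=dipoles,
        kind=kind,
    )


def _vertex_referenced(maps_33: np.ndarray, montage: Montage) -> np.ndarray:
    """Full-montage maps -> recorded channels against the vertex reference."""
    rec = maps_33[montage.recorded_indices]
    return rec - maps_33[montage.reference_index]


def _background_noise(rng, montage, head, n_samples, rate, spec: NoiseSpec):
    """Spatially correlated background: random dipole maps x slow noise."""
    if spec.background_amp <= 0 or spec.background_modes <= 0:
        return 0.0
    rb = head.brain_radius
    maps = []
    for _ in range(spec.background_modes):
        pos = rng.normal(size=3)
        pos = pos / np.linalg.norm(pos) * rng.uniform(0.2, 0.7) * rb
        mom = rng.normal(size=3)
        v = forward_topography(head, montage, DipoleSource(pos, mom))
        maps.append(v / gfp(v))
    maps = np.array(maps)                                  # (modes, 33)
    vr_maps = _vertex_referenced(maps.T, montage)          # (32, modes)
    sos = _sig.butter(2, 30.0, btype="lowpass", fs=rate, output="sos")
    tc = rng.standard_normal((spec.background_modes, n_samples))
    tc = _sig.sosfilt(sos, tc, axis=1)
    tc = tc / np.sqrt(np.mean(tc ** 2))                    # unit total RMS
    return (vr_maps @ tc) * spec.background_amp / np.sqrt(spec.background_modes)


def synthesize_session(script: TemplateScript, montage: Montage,
                       head: HeadModel | None = None,
                       noise: NoiseSpec | None = None,
                       duration_min: float = 3.0, rate: float = 5000.0,
                       stim_hz: float = 0.5, seed: int = 0,
                       epoch_window: tuple[float, float] = (-100.0, 200.0),
                       montage_rotation: np.ndarray | None = None,
                       rejection_threshold: float = 100.0,
                       ) -> tuple[Recording, GroundTruth]:
    """One continuous recording session with ground truth.

    Stimulus onsets are at t = 0, 2, 4, ... s of the stimulation train
    (exactly 90 for 3 min at 0.5 Hz); one second of pre/post-roll is added
    around the train so every peri-stimulus window fits.  The recording is
    vertex-referenced (32 channels for the built-in cap) and carries the
    *nominal* montage; any cap-placement rotation only affects the
    simulated physics and is reported in the ground truth.
    """
    head = head or HeadModel()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    if noise.artifact_fraction > 0 and noise.artifact_amp <= rejection_threshold:
        warnings.warn("planted artifact amplitude does not exceed the "
                      "rejection threshold; artifacts will be undetectable")

    sim_montage = montage if montage_rotation is None \
        else montage.rotated(montage_rotation)
    # script templates were built on the nominal montage; rebuild the
    # physical maps from the planted dipoles on the (possibly rotated) cap
    phys_templates = []
    for k, dip in enumerate(script.dipoles):
        v = forward_topography(head, sim_montage, dip)
        phys_templates.append(v / gfp(v))
    phys_templates = np.array(phys_templates) if phys_templates else script.templates
    phys_script = TemplateScript(
        phys_templates, script.onsets, script.offsets,
        script.peak_times, script.peak_gfp, script.dipoles, script.kind,
        script.env_floor)

    pre_roll = 1.0
    n_events = int(round(duration_min * 60.0 * stim_hz))
    train_span = (n_events - 1) / stim_hz
    n_samples = int(round((pre_roll + train_span + 1.0) * rate))
    event_samples = (pre_roll + np.arange(n_events) / stim_hz) * rate
    event_samples = np.round(event_samples).astype(int)

    n_ch = montage.n_recorded
    data = rng.normal(0.0, noise.sensor_sd, size=(n_ch, n_samples)) \
        if noise.sensor_sd > 0 else np.zeros((n_ch, n_samples))
    bg = _background_noise(rng, sim_montage, head, n_samples, rate, noise)
    data = data + bg
    if noise.line50_amp > 0:
        t = np.arange(n_samples) / rate
        gains = 1.0 + 0.3 * rng.standard_normal(n_ch)
        data += noise.line50_amp * gains[:, None] * \
            np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))[None, :]
    noise_rms = np.sqrt(np.mean(data ** 2)) if np.any(data) else 0.0

    # evoked signal per trial, with latency and amplitude jitter
    i0 = int(round(epoch_window[0] * rate / 1000.0))
    i1 = int(round(epoch_window[1] * rate / 1000.0))
    frame_times = np.arange(i0, i1) * 1000.0 / rate
    jit = rng.normal(0.0, noise.jitter_sd_ms, size=n_events) \
        if noise.jitter_sd_ms > 0 else np.zeros(n_events)
    amps = 1.0 + (rng.normal(0.0, noise.amp_jitter, size=n_events)
                  if noise.amp_jitter > 0 else np.zeros(n_events))
    snr_db = np.zeros(n_events)
    for j, es in enumerate(event_samples):
        sig33 = phys_script.signal(frame_times - jit[j]) * amps[j]
        sig = _vertex_referenced(sig33, montage)
        data[:, es + i0:es + i1] += sig
        srms = np.sqrt(np.mean(sig ** 2))
        snr_db[j] = 20 * np.log10(srms / noise_rms) if noise_rms > 0 else np.inf

    # planted artifact trials: alternating-polarity square pulses (a 25 Hz
    # square-wave burst) on 3 random channels; alternation keeps the burst
    # inside the analysis band so the band-pass filter cannot erode it
    # below the rejection threshold
    n_art = int(round(noise.artifact_fraction * n_events))
    art_idx = rng.choice(n_events, size=n_art, replace=False) if n_art else \
        np.array([], dtype=int)
    pulse_len = int(round(0.08 * rate))
    tp = np.arange(pulse_len) / rate
    burst = np.sign(np.sin(2 * np.pi * 25.0 * tp + 1e-9))
    for j in np.sort(art_idx):
        es = event_samples[j] + int(round(0.02 * rate))
        chans = rng.choice(n_ch, size=3, replace=False)
        sign = rng.choice([-1.0, 1.0])
        data[chans[:, None], np.arange(es, es + pulse_len)[None, :]] += \
            sign * noise.artifact_amp * burst[None, :]

    events = [Event(int(s), nerve=script.kind, side="left") for s in event_samples]
    rec = Recording(data, rate, events, montage)
    gt = GroundTruth(
        script=script,
        label_per_frame=script.labels(frame_times),
        epoch_window=epoch_window,
        rate=rate,
        dipoles=list(script.dipoles),
        snr_db_per_trial=snr_db,
        artifact_trials=np.sort(art_idx),
        montage_rotation=montage_rotation,
    )
    return rec, gt


def _random_rotation(rng, max_deg: float) -> tuple[np.ndarray, float]:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(0.0, max_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    return R, np.rad2deg(ang)


def synthesize_sessions(script: TemplateScript, montage: Montage,
                        n_sessions: int, head: HeadModel | None = None,
                        noise: NoiseSpec | None = None, seed: int = 0,
                        rotation_deg_max: float = 3.0,
                        **session_kwargs):
    """Multiple sessions with re-drawn noise and cap-placement perturbation.

    Each session applies an independent random rotation (< 3 degrees by
    default, seeded) to the electrode positions used by the physics,
    mimicking the impossibility of re-positioning the cap identically.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_sessions):
        R, ang = _random_rotation(rng, rotation_deg_max)
        rec, gt = synthesize_session(
            script, montage, head=head, noise=noise,
            seed=int(rng.integers(2 ** 31)), montage_rotation=R,
            **session_kwargs)
        gt.rotation_deg = ang
        out.append((rec, gt))
    return out


def synthesize_evoked(script: TemplateScript, montage: Montage,
                      snr: float = np.inf, seed: int = 0,
                      rate: float = 5000.0,
                      window: tuple[float, float] = (-100.0, 200.0),
                      latency_shift_ms: float = 0.0,
                      n_sweeps: int = 80) -> Evoked:
    """Average-referenced evoked directly at a given script-window SNR.

    Bypasses the continuous simulation for tests and calibration runs that
    work at the evoked level.  ``snr`` is the ratio of RMS signal GFP to
    RMS noise GFP inside the script's time span (``inf`` = noise-free);
    ``latency_shift_ms`` shifts the whole script (session-level latency
    variability).
    """
    rng = np.random.default_rng(seed)
    i0 = int(round(window[0] * rate / 1000.0))
    i1 = int(round(window[1] * rate / 1000.0))
    times = np.arange(i0, i1) * 1000.0 / rate
    sig = script.signal(times - latency_shift_ms)
    if np.isfinite(snr):
        span = (times >= script.onsets[0]) & (times < script.offsets[-1])
        sig_rms = np.sqrt(np.mean(gfp(sig[:, span]) ** 2))
        n_e = sig.shape[0]
        noise = rng.standard_normal(sig.shape)
        noise = noise - noise.mean(axis=0, keepdims=True)
        noise_rms = np.sqrt(np.mean(gfp(noise) ** 2))
        sig = sig + noise * (sig_rms / (snr * noise_rms))
    return Evoked(sig, rate, window, montage, n_sweeps=n_sweeps,
                  reference_mode="average",
                  channel_ids=list(montage.electrode_ids))
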