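# ssepmap

Whole-scalp EEG mapping of somatosensory evoked potentials (SSEPs) in
anaesthetized macaques, as a tested, reusable Python pipeline.

Peripheral-nerve SSEPs recorded from a 33-channel scalp cap are a
candidate tool for the non-invasive, repeatable follow-up of sensorimotor
reorganisation after cortical lesions in non-human primates.  Making that
work requires an analysis chain whose every stage is validated: evoked
-potential preprocessing and averaging, reference-independent topographic
analysis (microstate segmentation and back-fitting), classical waveform
component measures, pre/post-surgery comparisons, and distributed source
imaging.  `ssepmap` implements that chain end-to-end and ships a forward
simulator that generates recordings with *known* component maps, dipole
sources and noise, so each stage can be checked against planted ground
truth — no animal data are required to exercise the pipeline.

## The core quantities

For average-referenced scalp maps `u`, `v` over `n` electrodes:

* **GFP** (global field power): the spatial standard deviation of the map
  at each time frame, `GFP(t) = sqrt(mean_i v_i(t)^2)` — a
  reference-independent response-strength waveform.
* **SC** (spatial correlation):
  `SC = Σ u_i v_i / (sqrt(Σ u_i²) · sqrt(Σ v_i²))`, the cosine similarity
  of two maps.  Identical topographies give SC = 1, unrelated ones SC = 0.
  SC is *signed* here: a polarity inversion (SC = −1) counts as a distinct
  component map.
* **GEV** (global explained variance): the GFP²-weighted fraction of data
  variance explained by the template assigned at each frame,
  `GEV = Σ_t (GFP(t)·SC(v_t, T_L(t)))² / Σ_t GFP(t)²`.

Segmentation uses a modified K-means (assignment by highest signed SC,
templates re-estimated as GFP-weighted means) with Krzanowski–Lai and
cross-validation criteria to choose the number of maps; back-fitting
labels each session frame-wise and derives eight per-map parameters
(onset latency, duration, GEV, latency at best SC, mean SC, max/mean GFP
and GFP-peak latency).  Source imaging solves a Laplacian-weighted
minimum-norm (LORETA) inverse `T(α) = W⁻¹Kᵀ(KW⁻¹Kᵀ + αH)⁺` on a ~3,000
-point grid inside a three-shell spherical head (shell radii 100 / 78 /
68 %, relative skull conductivity 0.05), with 13 pre-computed Tikhonov
levels and paired-t statistics of post-stimulus current density against
the 100 ms pre-stimulus baseline.

## Worked example

```python
import numpy as np
from ssepmap import (builtin_macaque33, make_default_script,
                     synthesize_evoked, select_k, fit_sessions)

montage = builtin_macaque33()
script = make_default_script("median", montage)          # left median nerve

# grand average of synthetic sessions (analysis-window SNR 10)
ga = synthesize_evoked(script, montage, snr=10.0, seed=1)
best, curve, results = select_k(ga, (6.0, 50.0), k_range=range(1, 9),
                                restarts=50, seed=1)
templates, labeling = results[best["kl"]]
print(f"selected K (KL) = {best['kl']}, total GEV = {templates.gev_total:.4f}")

rng = np.random.default_rng(2)
sessions = [synthesize_evoked(script, montage, snr=5.0,
                              seed=int(rng.integers(2**31)),
                              latency_shift_ms=rng.normal(0, 0.5))
            for _ in range(9)]
fits = fit_sessions(sessions, templates)
print(fits.groupby("map").agg(onset_ms=("latency_first_onset", "mean"),
                              onset_sd=("latency_first_onset", "std"),
                              mean_sc=("mean_sc", "mean")).round(2))
```

prints

```
selected K (KL) = 4, total GEV = 0.9907
     onset_ms  onset_sd  mean_sc
map
0        6.38      0.42     0.82
1       13.04      0.44     0.84
2       15.42      0.42     0.91
3       25.84      0.43     0.89
```

The model-selection criterion recovers the four planted component maps
(boundaries 6 / 12.8 / 15.2 / 25.6 / 50 ms) and explains 99 % of the
grand-average variance; back-fitting the templates to nine noisy sessions
with 0.5 ms planted latency jitter reproduces the map onsets with
sub-millisecond spread and high spatial correlation — the stability
signature the method is designed to demonstrate.

A full file-based run (simulation → preprocessing → segmentation →
fitting → statistics → source imaging) is driven by a flat TOML config:

```sh
ssepmap run --config analysis.toml      # or: ssepmap simulate / preprocess / ...
```

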