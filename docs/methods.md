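# Methods

This note documents the models, conventions, numerical choices and known
limitations of `ssepmap`.  Everything quantitative stated here is either
a definition or a property the test suite computes.

## Conventions

* Voltages are microvolts throughout; current density is nominal
  mA/mm³ (the forward gain carries relative conductivities, so absolute
  source units are not physical).
* Time is milliseconds relative to stimulus onset; windows are half-open
  `[t0, t1)`; frame times sit on the global sample grid (integer
  multiples of the sample period), so identical instants compare
  bit-identically across containers — this matters at state boundaries.
* All randomised operations take a seed and are bit-reproducible.
* GFP uses the population (divide-by-n) convention; it equals the
  per-frame population standard deviation across electrodes.
* SC is signed and polarity-sensitive everywhere.  Evoked component
  sequences contain genuine polarity inversions (the last median-nerve
  map inverts the preceding one), so the polarity-ignoring convention of
  resting-state microstate analysis would merge distinct components.
* GEV is normalised by the summed squared GFP of the analysis window.

## Montage

The built-in `macaque33` cap has 32 recorded electrodes (2 midline + 15
per hemisphere) referenced at the vertex; positions are a 10-10-inspired
stylised layout on the unit sphere, symmetric about the midsagittal
plane.  No published coordinates exist for the original caps, so the
layout is an approximation; electrode *roles* ("brainstem"-like deep
posterior site, "cortical"-like right sensorimotor site) are montage
metadata, not anatomical claims, and component-analysis defaults resolve
channels through these roles.

## Forward model

Three concentric spherical shells (brain/skull/scalp at 68/78/100 % of a
40 mm scalp radius; relative conductivities 1 / 0.05 / 1).  For each
Legendre order the shell interface conditions form a 5×5 linear system
solved once per geometry and cached; scalp potentials follow from
Legendre recursions over electrode–source angle cosines, truncated at
N = 60 terms (tail ratio (b/r_brain)^N; sources are kept at ≤ 0.92 of
the brain radius so the truncation error is far below the quantities
asserted anywhere).  The derivative recursion `P'_{n+1} = P'_{n-1} +
(2n+1) P_n` avoids the 1/sin γ singularity for electrodes aligned with a
source.  A central dipole is handled by the direction-independent n = 1
limit.  The "locally adapted spheres" refinement of the original
workflow is simplified to per-electrode radial scaling of one best-fit
sphere (identity for the built-in unit-sphere montage); full
locally-adapted geometry is undocumented upstream and out of scope.

Verification is by independent derivations: the equal-conductivity limit
against the hand-derived homogeneous-sphere factor (2n+1)/n, the angular
machinery against the exact Coulomb dipole potential, per-harmonic
boundary-condition residuals, superposition, and mirror symmetry.

## Synthetic data

The simulator emulates the target acquisition: 5 kHz sampling, 0.5 Hz
stimulus trains of 3 min (exactly 90 stimuli; one second of pre/post-roll
surrounds the train so every peri-stimulus window fits), 32 recorded
channels against the vertex reference.

The default median-nerve script has K = 4 states with boundaries at 6,
12.8, 15.2, 25.6 and 50 ms; the tibial script K = 3 from 10.8 to 60 ms.
Templates come from stylised dipole placements in the spherical head
(deep posterior for the earliest, brainstem-like state, peaking near
6.9 ms; contralateral parietal/frontal sources for later states, the
cortical one peaking near 17.9 ms; the final state a near-inversion of
its predecessor).  Per-state GFP envelopes are piecewise raised cosines
with a floor of 10 % of the state's peak, so the topography stays
defined up to the state boundaries.  Anchor electrodes fix component
polarities (negative on the deep posterior channel, positive on the
sensorimotor channel).

Noise defaults are a package choice, not a measured quantity: 4 uV white
sensor noise, 4 uV spatially correlated background (random dipole
topographies × band-limited time courses), 0.3 ms per-trial latency
jitter, 10 % amplitude jitter, optional 50 Hz line.  These values give a
single-trial SNR near −13 dB, so a grand average of nine 80-sweep
sessions lands at a window SNR around 6 and a 4-map GEV in the mid-90 %
range — the regime the method is meant for.  Planted artifact trials are
alternating-polarity square pulses (a 25 Hz square-wave burst, 150 uV,
three random channels): a *single* square pulse is attenuated below the
100 uV rejection threshold by the 8–300 Hz zero-phase band-pass, which
would make planted artifacts undetectable by construction; keeping the
burst inside the analysis band preserves its amplitude (~190 uV after
filtering).  Multi-session generation re-draws all noise and rotates the
electrode positions by a random ≤ 3° rotation per session
(cap-placement variability); recordings always carry the nominal
montage, the rotation being ground-truth metadata.

What the simulator does **not** emulate: realistic macaque head
geometry, skull-defect conductivity changes (pre/post-surgery
comparisons are exercised as two synthetic session groups), ocular or
muscular artifact morphology, inter-animal anatomical variability, or
non-stationary anaesthesia effects.  Passing tests therefore validate
the *analysis machinery* under controlled conditions, not the
physiological claims one could make on real recordings.

## Preprocessing

Order: band-pass → epoch/reject → average → baseline → average
reference.  The band-pass is a 4th-order Butterworth (8–300 Hz) applied
forward-backward; the optional 50 Hz notch is a 2nd-order IIR (Q = 35),
also forward-backward.  Zero-phase filtering preserves the latency of
symmetric in-band transients exactly (asserted within one sample with a
gaussian probe); note that strongly *asymmetric* slow envelopes can
still shift peaks by a few samples through the magnitude response of the
8 Hz high-pass — an effect of the stated band itself, not of the filter
realisation.  Rejection marks any trial whose absolute amplitude exceeds
100 uV (strictly greater; ties kept) anywhere in the −100..+200 ms
window; the original workflow's manual visual selection is replaced by
an optional user-supplied trial mask.  Averaging uses kept trials only;
baseline is the per-channel mean over −80..−30 ms.  Average referencing
appends the reference as an explicit zero channel before centering
(32 → 33 channels), after which every frame is zero-mean.

## Segmentation

Modified K-means on the grand-average window (6–50 ms median, 10.8–60 ms
tibial): frames are assigned to the template with the highest signed SC
and templates re-estimated as GFP-weighted means of their frames,
renormalised to unit GFP, until the labelling is a fixed point (500
iteration cap; empty clusters re-seed from the worst-explained frame).
100 random restarts by default (templates initialised from K distinct
random frames); the restart with the highest total GEV wins, ties to the
lower restart index.

Post-processing: (1) contiguous runs shorter than 2 frames (0.4 ms at
5 kHz) are absorbed frame-wise into the neighbouring run whose template
correlates better; (2) template pairs with signed SC > 0.92 are merged
(GFP-weighted, renormalised) until no pair qualifies; (3) one more
absorption pass.  The two rules do not come with a prescribed order;
this order is fixed here.  Surviving templates are renumbered by first
labelled frame, so map 1 is always the earliest component.

Model selection computes, per K, the within-cluster dispersion of
unit-normalised maps `W(K) = Σ_t (1 − SC_t²)`, then
`KL(K) = |DIFF(K)| / |DIFF(K+1)|` with
`DIFF(K) = (K−1)^{2/p} W(K−1) − K^{2/p} W(K)` (p = electrode count), and
`CV(K) = σ̂²_K ((p−1)/(p−1−K))²` with σ̂²_K the mean residual variance.
KL is maximised only where dispersion is still genuinely dropping
(DIFF > 0); CV is minimised.  W(K) is computed after post-processing, so
beyond the true K the merge rule collapses redundant clusters and the
curve plateaus — which is precisely what makes the KL peak sharp at the
planted K.  Whether the upstream implementation normalises W by cluster
size is unknown; on well-separated synthetic data both variants give the
same argmax, and the unnormalised form is the committed choice.

## Back-fitting and statistics

Fitting assigns each frame of an individual session the template with
the highest signed SC — no temporal smoothing — and rejects (sets
UNLABELED, without reassignment) contiguous segments of ≤ 2 frames; this
differs deliberately from segmentation's absorption rule, matching the
"rejected" semantics of the fitting stage.  Zero-GFP frames are
unlabelled.  Eight parameters per map: latency at first onset, duration
(total labelled time, not the longest run — the convention is otherwise
unspecified), GEV, latency at best SC, mean (signed) SC, max GFP,
latency at max GFP, mean GFP.  Maps with no labelled frames yield NaN
rows with a warning.

Successive-map latency comparisons use an unpaired t-test when both
groups pass Shapiro–Wilk at 0.05 (the normality gate is otherwise
unnamed upstream), else a Mann–Whitney U test — with scipy's *exact*
null distribution for groups of ≤ 25, because window-edge ties (the
first map's onset is often pinned at the window start, with SD ≈ 0)
make the asymptotic approximation needlessly conservative.  The
significance threshold is 0.01 divided by the electrode count (33) — a
literal reading of the upstream protocol's Bonferroni rule, odd as an
electrode correction on latency tests, kept with a config override.
Group comparisons (e.g. pre/post-craniotomy) run two-tailed unpaired
t-tests on all 8 parameters × maps at the same adjusted threshold;
zero-variance cells are flagged, never significant.

Classical component analysis measures signed peaks in fixed windows
(brainstem: negative peak on the "brainstem"-role electrode and GFP
peak, 4–10 ms; cortical: positive peak on the "cortical"-role electrode
and GFP peak, 12–25 ms) and compares groups per component × {amplitude,
latency} at p < 0.01.  The electrode × time group comparison tests each
(electrode, frame) cell with an unpaired two-tailed t-test at
0.01/n_electrodes.

## Source imaging

Solution space: regular cubic grid intersected with the brain sphere,
spacing searched deterministically so the count lands closest to the
target (3,000 by default; 2,969 at the default head), sources kept at
≤ 0.92 of the brain radius (series accuracy margin), 6-connectivity
neighbours.  The lead field shares the forward code path with the
simulator (asserted column-identical) and is average-referenced (every
gain column sums to zero).

Inverse: `T(α) = W⁻¹Kᵀ(KW⁻¹Kᵀ + αH)⁺`, `W = (BᵀB) ⊗ I₃`, `B = I − A/6`
the 6-neighbour grid Laplacian (boundary rows simply lose missing
neighbours, keeping W invertible), H the average-reference centering
matrix.  The pseudo-inverse is an explicit symmetric eigen-inverse that
removes only the known average-reference kernel (relative cutoff 1e−12);
library default pseudo-inverse truncation proved far too aggressive on
these ill-conditioned gain products.  13 regularisation levels,
log-spaced over [1e−4, 1e2] × the mean eigenvalue of KW⁻¹Kᵀ (the
original 13 values are unpublished; this grid is a committed package
choice).  Per-dataset selection is by generalised cross-validation over
the grid, with a fixed-index override.  Orientations are free (3
components per source); CD magnitude is the Euclidean norm.

Source statistics follow the single-epoch reading of the upstream
protocol: for each source and post-stimulus frame (0–200 ms), a paired
t-test across epochs between that frame's CD and the epoch's mean CD
over the 100 ms pre-stimulus baseline, two-tailed, at p < 0.05
*uncorrected*.  t values are averaged over each component map's frames;
the masked output keeps only sources with at least one significant frame
in the map's window, so an all-NaN row is the "statistically
non-significant" case.

## Problem sizes in the validation suites

The test suites run at sizes chosen to exercise every code path while
staying desk-scale: segmentation recovery over 20 seeded grand averages
at window SNR 10; back-fitting stability over 9 sessions with 0.5 ms
planted session jitter; null calibration over 100 seeded identical-group
runs (plus a 1,500-replicate vectorised t-test calibration); inverse
validation on a ~700-point grid (localisation of 10 noise-free dipoles;
false-positive calibration on 200 signal-free epochs); preprocessing on
one full 3-minute 90-stimulus session.  The forward/inverse geometry is
scale-free, so grid-spacing-denominated results carry over to the
3,000-point default space (also built and checked once in the suite).

## Known limitations

* The spherical head and stylised montage make source locations
  qualitative; localisation accuracy is asserted in grid spacings, not
  millimetres of anatomy.
* EDF files are read (via MNE, annotations or a trigger channel) but not
  written; the text + JSON sidecar dialect is the canonical round-trip
  format.
* GCV is one defensible operationalisation of "regularisation chosen by
  noise level"; the upstream rule is unspecified.
* The per-trial SNR of real anaesthetized-macaque recordings is unknown;
  all noise defaults are package choices documented above.
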