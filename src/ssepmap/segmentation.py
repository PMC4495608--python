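"""Microstate segmentation of grand-average SSEPs.

A modified K-means identifies the succession of quasi-stable component
maps in an analysis window: each frame is assigned to the template with
the highest *signed* spatial correlation, and each template is recomputed
as the GFP-weighted mean of its frames (renormalised to unit GFP), until
the labelling reaches a fixed point.  The objective maximised across
random restarts is the total global explained variance.

Post-processing applies two rules: contiguous labelled runs shorter than
the minimum duration (2 frames, i.e. 0.4 ms at 5 kHz) are absorbed
frame-wise into the neighbouring run whose template correlates better,
and template pairs with signed SC above the merge threshold (0.92) are
merged.  Absorption runs first, then merging, then a final absorption
pass; the rules themselves do not prescribe an order, so this one is
fixed here.

Model selection over a K range uses the Krzanowski-Lai (KL) criterion
(argmax) and a cross-validation (CV) criterion (argmin), both computed
from the within-cluster dispersion of the normalised maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Evoked, UNLABELED
from .topography import gev, gfp, sc_matrix

__all__ = ["TemplateSet", "Labeling", "CriterionCurve", "kmeans_segment",
           "postprocess_clusters", "select_k"]

_MAX_ITER = 500


@dataclass
class TemplateSet:
    """K cluster topographies (zero-mean, unit-GFP) with provenance."""

    templates: np.ndarray               # (K, n_channels)
    window: tuple[float, float]         # ms
    seed: int | None = None
    restarts: int = 0
    best_restart: int | None = None
    gev_total: float = np.nan

    def __post_init__(self):
        self.templates = np.atleast_2d(np.asarray(self.templates, float))
        self.templates = self.templates - self.templates.mean(axis=1, keepdims=True)
        g = gfp(self.templates, axis=1)
        if np.any(g == 0):
            raise ValueError("zero template map")
        self.templates = self.templates / g[:, None]

    @property
    def K(self) -> int:
        return self.templates.shape[0]


@dataclass
class Labeling:
    """Per-frame template assignment over an analysis window."""

    labels: np.ndarray                  # (n_frames,) int, UNLABELED allowed
    window: tuple[float, float]
    rate: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def times(self) -> np.ndarray:
        i0 = int(round(self.window[0] * self.rate / 1000.0))
        return (i0 + np.arange(self.labels.shape[0])) * 1000.0 / self.rate

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.rate

    def runs(self):
        """Contiguous runs as (start, stop, label) with stop exclusive."""
        lab = self.labels
        out = []
        i = 0
        while i < lab.shape[0]:
            j = i
            while j < lab.shape[0] and lab[j] == lab[i]:
                j += 1
            out.append((i, j, int(lab[i])))
            i = j
        return out


@dataclass
class CriterionCurve:
    """Per-K dispersion and model-selection criteria."""

    ks: np.ndarray
    W: np.ndarray                       # within-cluster dispersion
    KL: np.ndarray                      # Krzanowski-Lai (NaN at the edges)
    CV: np.ndarray
    best_k_kl: int = 0
    best_k_cv: int = 0


def _window_data(evoked: Evoked, window) -> tuple[np.ndarray, np.ndarray]:
    if evoked.reference_mode != "average":
        raise ValueError("segmentation requires average-referenced data")
    data, times = evoked.crop_frames(window)
    if data.shape[1] == 0:
        raise ValueError("analysis window outside the evoked data")
    return data, times


def _kmeans_once(V, g, K, rng):
    """One restart of the modified K-means; V is (n_ch, n_frames)."""
    n_frames = V.shape[1]
    idx = rng.choice(n_frames, size=K, replace=False)
    T = V[:, idx].T.copy()
    T = T - T.mean(axis=1, keepdims=True)
    norms = gfp(T, axis=1)
    if np.any(norms == 0):  # degenerate zero frame picked; nudge
        T[norms == 0] = rng.standard_normal((int((norms == 0).sum()), V.shape[0]))
        T = T - T.mean(axis=1, keepdims=True)
        norms = gfp(T, axis=1)
    T /= norms[:, None]
    labels = np.full(n_frames, -2)
    for _ in range(_MAX_ITER):
        sc = sc_matrix(V, T)
        new_labels = np.argmax(sc, axis=0)
        # re-seed empty clusters from the worst-explained frame
        for k in range(K):
            if not np.any(new_labels == k):
                worst = np.argmin(np.max(sc, axis=0) * g)
                new_labels[worst] = k
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(K):
            sel = labels == k
            t = (V[:, sel] * g[sel][None, :]).sum(axis=1)
            nrm = gfp(t)
            if nrm > 0:
                T[k] = t / nrm
    return T, labels


def kmeans_segment(evoked: Evoked, window, K: int, restarts: int = 100,
                   seed: int = 0) -> tuple[TemplateSet, Labeling]:
    """Best-of-restarts modified K-means segmentation of one window.

    Restarts initialise templates from K distinct random frames; the
    restart with the highest total GEV wins (ties break toward the lower
    restart index).  Deterministic given the seed.
    """
    V, _ = _window_data(evoked, window)
    n_frames = V.shape[1]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_frames:
        raise ValueError("K exceeds the number of frames in the window")
    g = gfp(V)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(restarts):
        T, labels = _kmeans_once(V, g, K, rng)
        _, total = gev(V, T, labels)
        if best is None or total > best[0] + 1e-15:
            best = (total, r, T, labels)
    total, r, T, labels = best
    win = (window[0], window[1])
    ts = TemplateSet(T, win, seed=seed, restarts=restarts, best_restart=r,
                     gev_total=total)
    return ts, Labeling(labels, win, evoked.rate)


def _absorb_short_runs(templates, labels, V, min_frames):
    """Reassign runs shorter than min_frames to the better-correlated
    neighbouring run's template, frame by frame."""
    lab = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        i = 0
        n = lab.shape[0]
        while i < n:
            j = i
            while j < n and lab[j] == lab[i]:
                j += 1
            runs.append([i, j, lab[i]])
            i = j
        for ridx, (a, b, l) in enumerate(runs):
            if l == UNLABELED or (b - a) >= min_frames:
                continue
            prev_l = runs[ridx - 1][2] if ridx > 0 else None
            next_l = runs[ridx + 1][2] if ridx + 1 < len(runs) else None
            cand = [c for c in (prev_l, next_l) if c is not None and c != UNLABELED]
            if not cand:
                continue
            for f in range(a, b):
                scs = sc_matrix(V[:, f:f + 1], templates[cand])[:, 0]
                lab[f] = cand[int(np.argmax(scs))]
            changed = True
            break  # run list is stale; rebuild
    return lab


def _merge_templates(templates, labels, V, g, merge_sc):
    """Merge template pairs with signed SC above the threshold."""
    T = templates.copy()
    lab = labels.copy()
    while T.shape[0] > 1:
        scs = sc_matrix(T.T, T)
        np.fill_diagonal(scs, -np.inf)
        i, j = np.unravel_index(np.argmax(scs), scs.shape)
        if scs[i, j] <= merge_sc:
            break
        keep, drop = min(i, j), max(i, j)
        sel = (lab == keep) | (lab == drop)
        if np.any(sel):
            t = (V[:, sel] * g[sel][None, :]).sum(axis=1)
        else:
            t = T[keep] + T[drop]
        t = t - t.mean()
        nrm = gfp(t)
        T[keep] = t / nrm if nrm > 0 else T[keep]
        T = np.delete(T, drop, axis=0)
        lab[lab == drop] = keep
        lab[lab > drop] -= 1
    return T, lab


def postprocess_clusters(templates: TemplateSet, labeling: Labeling,
                         evoked: Evoked, min_frames: int = 2,
                         merge_sc: float = 0.92) -> tuple[TemplateSet, Labeling]:
    """Short-run absorption, template merging, and a re-absorption pass.

    Any contiguous labelled run shorter than ``min_frames`` is reassigned
    frame-wise to the preceding or following run's template (whichever has
    the higher signed SC with that frame); template pairs with signed
    SC > ``merge_sc`` are merged (GFP-weighted mean of their frames,
    renormalised) until no pair qualifies.  Unused templates are dropped
    and labels compacted.
    """
    V, _ = _window_data(evoked, templates.window)
    g = gfp(V)
    T = templates.templates
    lab = _absorb_short_runs(T, labeling.labels, V, min_frames)
    T, lab = _merge_templates(T, lab, V, g, merge_sc)
    lab = _absorb_short_runs(T, lab, V, min_frames)
    # drop templates with no frames left; renumber by first labelled frame
    # so map 1 is the earliest component (presentation convention)
    used = [k for k in range(T.shape[0]) if np.any(lab == k)]
    used.sort(key=lambda k: int(np.argmax(lab == k)))
    remap = {old: new for new, old in enumerate(used)}
    lab = np.array([remap.get(l, UNLABELED) for l in lab])
    T = T[used]
    _, total = gev(V, T, lab)
    ts = TemplateSet(T, templates.window, seed=templates.seed,
                     restarts=templates.restarts,
                     best_restart=templates.best_restart, gev_total=total)
    return ts, Labeling(lab, labeling.window, labeling.rate)


def _dispersion(V, T, labels) -> float:
    """Within-cluster dispersion of unit-normalised maps.

    Frames and templates are L2-normalised; W(K) sums the squared residual
    of each frame after projection on its assigned template (polarity
    handled by the square), i.e. sum_t (1 - SC_t^2).
    """
    sc = sc_matrix(V, T)
    picked = sc[labels.clip(min=0), np.arange(V.shape[1])]
    picked = np.where(labels == UNLABELED, 0.0, picked)
    return float(np.sum(1.0 - picked ** 2))


def select_k(evoked: Evoked, window, k_range=range(1, 11), restarts: int = 100,
             seed: int = 0, min_frames: int = 2, merge_sc: float = 0.92):
    """Segment at each K and score with the KL and CV criteria.

    Returns ``(best, curve, results)`` where ``best`` is a dict with the
    KL-optimal and CV-optimal K, ``curve`` a :class:`CriterionCurve`, and
    ``results`` maps each K to its post-processed (TemplateSet, Labeling).

    KL(K) = \\|DIFF(K)\\| / \\|DIFF(K+1)\\| with
    DIFF(K) = (K-1)^(2/p) W(K-1) - K^(2/p) W(K), p = electrode count
    (evaluated at interior K only); CV(K) = sigma2_K ((p-1)/(p-1-K))^2
    with sigma2_K the mean residual variance of the normalised maps.
    """
    ks = np.array(sorted(k_range))
    if ks.size < 3:
        raise ValueError("k_range too small to evaluate the KL criterion")
    V, _ = _window_data(evoked, window)
    p, n_frames = V.shape
    W = np.full(ks.size, np.nan)
    CV = np.full(ks.size, np.nan)
    results = {}
    for i, K in enumerate(ks):
        ts, lb = kmeans_segment(evoked, window, int(K), restarts=restarts,
                                seed=seed + int(K))
        ts, lb = postprocess_clusters(ts, lb, evoked, min_frames=min_frames,
                                      merge_sc=merge_sc)
        results[int(K)] = (ts, lb)
        W[i] = _dispersion(V, ts.templates, lb.labels)
        sigma2 = W[i] / (n_frames * (p - 1))
        denom = p - 1 - K
        CV[i] = sigma2 * ((p - 1) / denom) ** 2 if denom > 0 else np.inf
    diff = np.full(ks.size, np.nan)
    for i, K in enumerate(ks):
        if i == 0:
            continue
        diff[i] = (ks[i - 1]) ** (2.0 / p) * W[i - 1] - K ** (2.0 / p) * W[i]
    KL = np.full(ks.size, np.nan)
    for i in range(1, ks.size - 1):
        if abs(diff[i + 1]) > 0:
            KL[i] = abs(diff[i]) / abs(diff[i + 1])
    # a KL peak is only meaningful where dispersion is still dropping
    kl_valid = np.where(np.isfinite(KL) & (diff > 0))[0]
    best_kl = int(ks[kl_valid[np.argmax(KL[kl_valid])]]) if kl_valid.size \
        else int(ks[np.nanargmax(KL)])
    best_cv = int(ks[np.nanargmin(CV)])
    curve = CriterionCurve(ks, W, KL, CV, best_k_kl=best_kl, best_k_cv=best_cv)
    return {"kl": best_kl, "cv": best_cv}, curve, results
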