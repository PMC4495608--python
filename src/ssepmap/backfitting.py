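"""Back-fitting of component-map templates to individual recordings.

The templates derived from a grand-average segmentation are fitted back
to each session's evoked potential: every frame in the analysis window is
assigned the template with the highest signed spatial correlation, with
no temporal smoothing; contiguous segments of 0.4 ms or less (2 frames at
5 kHz) are rejected, i.e. left unlabelled rather than reassigned — the
fitting stage, unlike segmentation, does not absorb them.

Eight topographic parameters are then computed per map and session:
latency at first onset, total duration, GEV, latency at best SC, mean SC,
maximum GFP, latency at maximum GFP, and mean GFP.  Session-level
statistics compare successive map latencies (unpaired t-test, falling
back to Mann-Whitney U when either group fails a Shapiro-Wilk normality
test) and compare all parameters between two session groups (e.g.
pre/post-craniotomy) with two-tailed unpaired t-tests.  Significance
thresholds are Bonferroni-adjusted by the electrode count (divisor 33 by
default) — a literal reading of the source protocol, overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import Evoked, UNLABELED
from .segmentation import Labeling, TemplateSet
from .topography import gev, gfp, sc_matrix

__all__ = ["PARAMETERS", "fit_templates", "map_parameters", "fit_sessions",
           "compare_successive_map_latencies", "compare_groups"]

PARAMETERS = (
    "latency_first_onset", "duration", "gev", "latency_best_sc",
    "mean_sc", "max_gfp", "latency_max_gfp", "mean_gfp",
)


def fit_templates(evoked: Evoked, templates: TemplateSet,
                  window=None, min_frames: int = 2) -> Labeling:
    """Frame-wise template assignment by highest signed SC.

    Runs of length <= ``min_frames`` become UNLABELED (rejected, not
    reassigned); zero-GFP frames are UNLABELED.  No smoothing.
    """
    if evoked.reference_mode != "average":
        raise ValueError("back-fitting requires average-referenced data")
    window = window or templates.window
    V, times = evoked.crop_frames(window)
    fnorm = np.linalg.norm(V, axis=0)
    sc = sc_matrix(V, templates.templates)
    labels = np.argmax(sc, axis=0)
    labels[fnorm == 0] = UNLABELED
    # reject short segments
    lab = labels.copy()
    n = lab.shape[0]
    i = 0
    while i < n:
        j = i
        while j < n and lab[j] == lab[i]:
            j += 1
        if lab[i] != UNLABELED and (j - i) <= min_frames:
            lab[i:j] = UNLABELED
        i = j
    return Labeling(lab, (window[0], window[1]), evoked.rate)


def map_parameters(evoked: Evoked, templates: TemplateSet,
                   labeling: Labeling) -> pd.DataFrame:
    """The eight topographic parameters for each map.

    Returns a DataFrame indexed by map (0-based) with one column per
    parameter; maps with no labelled frames get NaN rows (with a warning).
    Latencies are in ms, GFP in uV, duration = total labelled time in ms
    (not the longest run).
    """
    V, times = evoked.crop_frames(labeling.window)
    if V.shape[1] != labeling.labels.shape[0]:
        raise ValueError("labeling does not match the evoked window")
    g = gfp(V)
    sc = sc_matrix(V, templates.templates)
    per_map_gev, _ = gev(V, templates.templates, labeling.labels)
    frame_ms = 1000.0 / evoked.rate
    rows = []
    for k in range(templates.K):
        sel = labeling.labels == k
        if not np.any(sel):
            warnings.warn(f"map {k} has no labelled frames in this recording")
            rows.append({p: np.nan for p in PARAMETERS})
            continue
        t_k = times[sel]
        sc_k = sc[k, sel]
        g_k = g[sel]
        rows.append({
            "latency_first_onset": float(t_k[0]),
            "duration": float(sel.sum() * frame_ms),
            "gev": float(per_map_gev[k]),
            "latency_best_sc": float(t_k[np.argmax(sc_k)]),
            "mean_sc": float(np.mean(sc_k)),
            "max_gfp": float(np.max(g_k)),
            "latency_max_gfp": float(t_k[np.argmax(g_k)]),
            "mean_gfp": float(np.mean(g_k)),
        })
    df = pd.DataFrame(rows)
    df.index.name = "map"
    return df


def fit_sessions(evokeds, templates: TemplateSet, window=None,
                 min_frames: int = 2) -> pd.DataFrame:
    """Back-fit several sessions; tidy frame (session, map, parameters)."""
    frames = []
    for s, ev in enumerate(evokeds):
        lb = fit_templates(ev, templates, window=window, min_frames=min_frames)
        df = map_parameters(ev, templates, lb).reset_index()
        df.insert(0, "session", s)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _normal(x, alpha=0.05) -> bool:
    """Shapiro-Wilk gate; degenerate samples count as non-normal."""
    x = np.asarray(x, float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return stats.shapiro(x).pvalue >= alpha
        except ValueError:
            return False


def compare_successive_map_latencies(fits: pd.DataFrame, alpha: float = 0.01,
                                     n_electrodes: int = 33) -> pd.DataFrame:
    """Latency differences between successive maps across sessions.

    For each successive map pair and each of the two latency parameters
    (first onset, best SC): unpaired t-test when both groups pass
    Shapiro-Wilk normality (alpha 0.05), otherwise Mann-Whitney U;
    significance at ``alpha / n_electrodes``.
    """
    fits = fits.dropna(subset=["latency_first_onset"])
    maps = sorted(fits["map"].unique())
    thr = alpha / n_electrodes
    rows = []
    for a, b in zip(maps[:-1], maps[1:]):
        for param in ("latency_first_onset", "latency_best_sc"):
            ga = fits.loc[fits["map"] == a, param].dropna().to_numpy()
            gb = fits.loc[fits["map"] == b, param].dropna().to_numpy()
            row = {"map_a": a, "map_b": b, "parameter": param,
                   "n_a": ga.size, "n_b": gb.size,
                   "adjusted_threshold": thr}
            if ga.size < 3 or gb.size < 3:
                row.update(test="skipped", statistic=np.nan, p=np.nan,
                           significant=False, skipped=True)
                rows.append(row)
                continue
            if _normal(ga) and _normal(gb):
                res = stats.ttest_ind(ga, gb)
                row.update(test="t", statistic=float(res.statistic),
                           p=float(res.pvalue))
            else:
                # exact null distribution for small samples (ties make the
                # asymptotic approximation needlessly conservative here)
                method = "exact" if max(ga.size, gb.size) <= 25 else "auto"
                res = stats.mannwhitneyu(ga, gb, alternative="two-sided",
                                         method=method)
                row.update(test="mannwhitneyu", statistic=float(res.statistic),
                           p=float(res.pvalue))
            row.update(significant=bool(row["p"] < thr), skipped=False)
            rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(fits_a: pd.DataFrame, fits_b: pd.DataFrame,
                   alpha: float = 0.01, n_electrodes: int = 33) -> pd.DataFrame:
    """Two-tailed unpaired t-tests on all 8 parameters x maps.

    Compares two groups of back-fitted sessions (e.g. pre- vs
    post-craniotomy); Bonferroni-adjusted threshold ``alpha/n_electrodes``.
    Zero-variance cells yield NaN statistics and are never significant.
    """
    maps = sorted(set(fits_a["map"]).union(fits_b["map"]))
    thr = alpha / n_electrodes
    rows = []
    for k in maps:
        for param in PARAMETERS:
            ga = fits_a.loc[fits_a["map"] == k, param].dropna().to_numpy()
            gb = fits_b.loc[fits_b["map"] == k, param].dropna().to_numpy()
            row = {"map": k, "parameter": param, "n_a": ga.size, "n_b": gb.size,
                   "mean_a": ga.mean() if ga.size else np.nan,
                   "mean_b": gb.mean() if gb.size else np.nan,
                   "se_a": stats.sem(ga) if ga.size > 1 else np.nan,
                   "se_b": stats.sem(gb) if gb.size > 1 else np.nan,
                   "adjusted_threshold": thr}
            if ga.size < 2 or gb.size < 2:
                row.update(t=np.nan, p=np.nan, significant=False, skipped=True)
                rows.append(row)
                continue
            if np.ptp(ga) == 0 and np.ptp(gb) == 0:
                identical = ga.mean() == gb.mean()
                row.update(t=0.0 if identical else np.nan,
                           p=1.0 if identical else np.nan,
                           significant=False, skipped=False,
                           zero_variance=True)
                rows.append(row)
                continue
            with warnings.catch_warnings():
                # near-constant groups trip scipy's precision-loss warning
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(ga, gb)
            p = float(res.pvalue)
            row.update(t=float(res.statistic), p=p,
                       significant=bool(p < thr), skipped=False)
            rows.append(row)
    return pd.DataFrame(rows)
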