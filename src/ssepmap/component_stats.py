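"""Classical waveform component analysis.

Peak amplitude and latency of the early brainstem-like component and the
main cortical component, measured on single electrodes of interest and on
the GFP waveform, plus electrode x time group comparisons.

Default component specifications mirror the evoked-potential convention
for median-nerve stimulation: the brainstem component is a negative peak
on a deep posterior electrode (montage role "brainstem") and a GFP peak,
searched 4-10 ms post-stimulus; the main cortical component is a positive
peak on the contralateral sensorimotor electrode (role "cortical") and a
GFP peak, searched 12-25 ms.  Electrode roles are montage metadata since
the physical channels these roles map onto vary between caps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import Evoked
from .topography import gfp

__all__ = ["ComponentMeasure", "ComponentSpec", "default_component_specs",
           "detect_component", "electrodewise_ttest",
           "compare_component_measures"]


@dataclass(frozen=True)
class ComponentSpec:
    """What to measure: (component name, channel or "GFP", window, polarity)."""

    component: str
    channel: str            # electrode label or "GFP"
    window: tuple[float, float]
    polarity: str           # "neg" | "pos" | "max"


@dataclass
class ComponentMeasure:
    """One detected component peak."""

    component: str
    channel: str
    latency: float          # ms
    amplitude: float        # uV
    polarity: str
    window: tuple[float, float]
    boundary_hit: bool = False
    missing: bool = False


def default_component_specs(montage) -> list[ComponentSpec]:
    """Brainstem (4-10 ms) and cortical (12-25 ms) specs for a montage."""
    bs = montage.roles.get("brainstem", "e32")
    cx = montage.roles.get("cortical", "e12")
    return [
        ComponentSpec("brainstem", bs, (4.0, 10.0), "neg"),
        ComponentSpec("brainstem", "GFP", (4.0, 10.0), "max"),
        ComponentSpec("cortical", cx, (12.0, 25.0), "pos"),
        ComponentSpec("cortical", "GFP", (12.0, 25.0), "max"),
    ]


def detect_component(evoked: Evoked, channel: str, window,
                     polarity: str = "max",
                     component: str = "") -> ComponentMeasure:
    """Peak of the chosen polarity within the search window.

    ``channel`` is an electrode label or ``"GFP"`` (which forces
    ``polarity="max"``).  The amplitude is the signed value at the peak
    and the latency the peak frame's time.  A flat window is flagged
    ``missing``; a peak on the first or last frame of the window is
    flagged ``boundary_hit``.
    """
    V, times = evoked.crop_frames(window)
    if times.size == 0:
        raise ValueError("search window outside the evoked data")
    if channel == "GFP":
        x = gfp(V)
        polarity = "max"
    else:
        x = V[evoked.channel_ids.index(channel)]
    if np.ptp(x) == 0:
        return ComponentMeasure(component, channel, np.nan, np.nan, polarity,
                                tuple(window), missing=True)
    if polarity == "neg":
        idx = int(np.argmin(x))
    elif polarity == "pos":
        idx = int(np.argmax(x))
    elif polarity == "max":
        idx = int(np.argmax(np.abs(x)))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return ComponentMeasure(component, channel, float(times[idx]),
                            float(x[idx]), polarity, tuple(window),
                            boundary_hit=idx in (0, x.size - 1))


def electrodewise_ttest(group_a, group_b, alpha: float = 0.01,
                        n_electrodes: int | None = None):
    """Per-(electrode, frame) two-tailed unpaired t-tests between groups.

    Returns ``(mask, t, p)`` arrays of shape (channels, frames); a cell is
    significant iff ``p < alpha / n_electrodes``.  Cells with zero
    variance in both groups are never significant (t = 0 when the group
    means are identical, NaN otherwise).
    """
    A = np.stack([ev.data for ev in group_a])
    B = np.stack([ev.data for ev in group_b])
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("groups must share montage and window")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 evokeds per group")
    n_e = n_electrodes or A.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0)
    degenerate = ~np.isfinite(t)
    same_mean = np.isclose(A.mean(axis=0), B.mean(axis=0))
    t = np.where(degenerate & same_mean, 0.0, t)
    p = np.where(degenerate & same_mean, 1.0, p)
    mask = np.where(np.isfinite(p), p < alpha / n_e, False)
    return mask, t, p


def compare_component_measures(group_a, group_b, specs=None,
                               alpha: float = 0.01) -> pd.DataFrame:
    """Detect components per evoked, then t-test amplitude and latency.

    Each spec yields two tests (amplitude, latency) comparing the groups
    with two-tailed unpaired t-tests at ``alpha``; missing components are
    excluded observations.
    """
    if specs is None:
        specs = default_component_specs(group_a[0].montage)
    rows = []
    for spec in specs:
        meas = {}
        for gname, group in (("a", group_a), ("b", group_b)):
            ms = [detect_component(ev, spec.channel, spec.window,
                                   spec.polarity, spec.component)
                  for ev in group]
            meas[gname] = [m for m in ms if not m.missing]
        for attr in ("amplitude", "latency"):
            xa = np.array([getattr(m, attr) for m in meas["a"]])
            xb = np.array([getattr(m, attr) for m in meas["b"]])
            row = {"component": spec.component, "channel": spec.channel,
                   "measure": attr, "n_a": xa.size, "n_b": xb.size,
                   "mean_a": xa.mean() if xa.size else np.nan,
                   "mean_b": xb.mean() if xb.size else np.nan,
                   "sd_a": xa.std(ddof=1) if xa.size > 1 else np.nan,
                   "sd_b": xb.std(ddof=1) if xb.size > 1 else np.nan}
            if xa.size < 2 or xb.size < 2:
                row.update(t=np.nan, p=np.nan, significant=False)
            elif np.ptp(xa) == 0 and np.ptp(xb) == 0:
                same = xa.mean() == xb.mean()
                row.update(t=0.0 if same else np.nan,
                           p=1.0 if same else np.nan, significant=False)
            else:
                res = stats.ttest_ind(xa, xb)
                row.update(t=float(res.statistic), p=float(res.pvalue),
                           significant=bool(res.pvalue < alpha))
            rows.append(row)
    return pd.DataFrame(rows)
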