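"""Reference-independent topographic primitives: GFP, SC and GEV.

These three quantities underlie every topographic stage of the pipeline:

* **GFP** (global field power): per-frame spatial standard deviation of the
  average-referenced map, using the population (divide-by-n) convention.
* **SC** (spatial correlation): cosine similarity between two
  average-referenced maps,
  ``SC = sum(u_i v_i) / (sqrt(sum u_i^2) sqrt(sum v_i^2))``.
  SC is *signed* here: a polarity inversion of the same topography gives
  SC = -1, and is treated as a distinct component map (evoked-potential
  convention, unlike the polarity-ignoring resting-state microstate one).
* **GEV** (global explained variance): the GFP^2-weighted fraction of data
  variance explained by the template assigned at each frame.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gfp", "spatial_correlation", "gev", "ZeroNormMapError"]

from .data import UNLABELED


class ZeroNormMapError(ValueError):
    """Spatial correlation is undefined for an all-zero map."""


def gfp(maps: np.ndarray, axis: int = 0) -> np.ndarray:
    """Global field power: RMS across electrodes of the zero-mean map.

    Parameters
    ----------
    maps : (n_channels,) single map or (n_channels, n_frames) series.
    axis : channel axis.

    Maps are centred across channels before the RMS, so the result is
    reference-independent (equals the per-frame population standard
    deviation across electrodes).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[axis] < 2:
        raise ValueError("GFP needs at least 2 channels")
    centred = maps - maps.mean(axis=axis, keepdims=True)
    return np.sqrt(np.mean(centred ** 2, axis=axis))


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Signed spatial correlation between two average-referenced maps."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("maps must share the montage")
    nu = np.sqrt(np.sum(u ** 2))
    nv = np.sqrt(np.sum(v ** 2))
    if nu == 0.0 or nv == 0.0:
        raise ZeroNormMapError("spatial correlation undefined for a zero map")
    return float(np.dot(u, v) / (nu * nv))


def sc_matrix(series: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Signed SC of every frame against every template.

    series : (n_channels, n_frames); templates : (n_templates, n_channels).
    Returns (n_templates, n_frames); zero-norm frames give SC 0 rows.
    """
    series = np.asarray(series, float)
    templates = np.asarray(templates, float)
    fn = np.linalg.norm(series, axis=0)
    tn = np.linalg.norm(templates, axis=1)
    if np.any(tn == 0):
        raise ZeroNormMapError("zero-norm template")
    denom = np.where(fn == 0, 1.0, fn)
    return (templates @ series) / (tn[:, None] * denom[None, :])


def gev(series: np.ndarray, templates: np.ndarray,
        labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-map and total global explained variance.

    Parameters
    ----------
    series : (n_channels, n_frames) average-referenced window.
    templates : (n_templates, n_channels).
    labels : (n_frames,) template index per frame, ``UNLABELED`` allowed
        (contributes zero explained variance).

    Returns
    -------
    per_map : (n_templates,) GEV restricted to frames labelled with each map.
    total : float, ``sum(per_map)``.

    Notes
    -----
    ``total = sum_t (GFP_t * SC(v_t, T_L(t)))^2 / sum_t GFP_t^2`` over the
    window; the denominator uses *all* frames of the window.
    """
    series = np.asarray(series, float)
    templates = np.atleast_2d(np.asarray(templates, float))
    labels = np.asarray(labels)
    if labels.shape[0] != series.shape[1]:
        raise ValueError("labels must cover the window")
    g = gfp(series)
    denom = float(np.sum(g ** 2))
    if denom == 0.0:
        raise ValueError("all-zero GFP window")
    sc = sc_matrix(series - series.mean(axis=0, keepdims=True), templates)
    per_map = np.zeros(templates.shape[0])
    for k in range(templates.shape[0]):
        sel = labels == k
        if np.any(sel):
            per_map[k] = np.sum((g[sel] * sc[k, sel]) ** 2) / denom
    return per_map, float(per_map.sum())
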