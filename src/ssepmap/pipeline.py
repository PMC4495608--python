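"""End-to-end pipeline orchestration.

``run_pipeline`` executes a stage list described by a flat TOML config
and leaves every stage's outputs as delimited-text tables (plus a JSON
log of all parameters and seeds actually used).  Stages:

``simulate``    synthetic sessions (recordings + ground truth)
``preprocess``  filter/epoch/reject/average -> evoked tables + reports
``segment``     grand-average microstate segmentation (K selection)
``fit``         back-fit templates to each session -> fit table
``stats``       successive-map latency statistics + component measures
``inverse``     LORETA current density of the grand average
``report``      summary JSON of the headline quantities

Later stages consume the outputs of earlier ones from the output
directory, so a stage can also run on files produced by a previous
invocation; a missing dependency is an error.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .backfitting import compare_successive_map_latencies, fit_sessions
from .component_stats import default_component_specs, detect_component
from .data import AnalysisConfig, Evoked
from .forward import HeadModel
from .montage import builtin_macaque33, load_montage
from .preprocess import preprocess_recording
from .segmentation import select_k
from .simulate import NoiseSpec, make_default_script, synthesize_sessions
from .source_imaging import (build_source_space, compute_leadfield,
                             estimate_cd, loreta_operator)

__all__ = ["run_pipeline", "PIPELINE_KEYS"]

PIPELINE_KEYS = {
    "stages", "nerve", "side", "n_sessions", "duration_min", "output_dir",
    "montage", "inputs", "n_sources", "snr", "noise_sensor_sd",
    "noise_background_amp", "noise_jitter_sd_ms", "noise_artifact_fraction",
    "segmentation_window",
}
_STAGES = ("simulate", "preprocess", "segment", "fit", "stats", "inverse",
           "report")


def _load_config(config_path):
    with open(config_path, "rb") as fh:
        raw = tomllib.load(fh)
    from dataclasses import fields

    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known - PIPELINE_KEYS
    if unknown:
        raise ValueError(f"invalid config keys: {sorted(unknown)}")
    cfg_kw = {}
    for f in fields(AnalysisConfig):
        if f.name in raw:
            v = raw[f.name]
            cfg_kw[f.name] = tuple(v) if isinstance(v, list) else v
    return raw, AnalysisConfig(**cfg_kw)


def _session_evokeds(out: Path, montage):
    paths = sorted(out.glob("evoked_*.tsv"))
    if not paths:
        raise FileNotFoundError(
            "missing stage dependency: no evoked files (run 'preprocess')")
    return [sio.read_evoked(p, montage) for p in paths]


def run_pipeline(config_path) -> dict:
    """Run the configured stages; returns a dict of written paths."""
    raw, cfg = _load_config(config_path)
    stages = raw.get("stages", list(_STAGES))
    bad = [s for s in stages if s not in _STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    out = Path(raw.get("output_dir", "ssepmap_out"))
    out.mkdir(parents=True, exist_ok=True)
    nerve = raw.get("nerve", "median")
    side = raw.get("side", "left")
    montage_spec = raw.get("montage", "macaque33")
    montage = load_montage(montage_spec)
    head = HeadModel()
    seed = int(cfg.seed)
    written: dict[str, str] = {}
    log: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(cfg).items()},
                 "pipeline": {k: raw.get(k) for k in sorted(PIPELINE_KEYS)
                              if k in raw},
                 "stages": list(stages), "seed": seed, "nerve": nerve,
                 "side": side}

    if "simulate" in stages:
        script = make_default_script(nerve, montage, head, side=side)
        noise = NoiseSpec(
            sensor_sd=float(raw.get("noise_sensor_sd", NoiseSpec.sensor_sd)),
            background_amp=float(raw.get("noise_background_amp",
                                         NoiseSpec.background_amp)),
            jitter_sd_ms=float(raw.get("noise_jitter_sd_ms",
                                       NoiseSpec.jitter_sd_ms)),
            artifact_fraction=float(raw.get("noise_artifact_fraction", 0.0)),
        )
        sessions = synthesize_sessions(
            script, montage, int(raw.get("n_sessions", 2)), head=head,
            noise=noise, seed=seed,
            duration_min=float(raw.get("duration_min", 3.0)))
        gt_meta = []
        for i, (rec, gt) in enumerate(sessions):
            p = out / f"session_{i:02d}.tsv"
            sio.write_recording(rec, p)
            written[f"session_{i:02d}"] = str(p)
            gt_meta.append({"session": i, "rotation_deg": gt.rotation_deg,
                            "artifact_trials": gt.artifact_trials.tolist(),
                            "mean_trial_snr_db":
                                float(np.mean(gt.snr_db_per_trial))})
        truth = {
            "onsets_ms": script.onsets.tolist(),
            "offsets_ms": script.offsets.tolist(),
            "K": script.K,
            "sessions": gt_meta,
        }
        (out / "ground_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True))
        written["ground_truth"] = str(out / "ground_truth.json")

    if "preprocess" in stages:
        rec_paths = sorted(out.glob("session_*.tsv"))
        if raw.get("inputs"):
            rec_paths = [Path(p) for p in raw["inputs"]]
        if not rec_paths:
            raise FileNotFoundError(
                "missing stage dependency: no recordings (run 'simulate' "
                "or list 'inputs')")
        reports = []
        for i, p in enumerate(rec_paths):
            rec = sio.read_recording(p, montage)
            evoked, _, report = preprocess_recording(rec, cfg)
            ep = out / f"evoked_{i:02d}.tsv"
            sio.write_evoked(evoked, ep)
            written[f"evoked_{i:02d}"] = str(ep)
            report["source"] = str(p)
            reports.append(report)
        (out / "rejection_report.json").write_text(
            json.dumps(reports, indent=1, sort_keys=True))
        written["rejection_report"] = str(out / "rejection_report.json")

    seg_window = tuple(raw["segmentation_window"]) if \
        "segmentation_window" in raw else cfg.segmentation_window(nerve)
    log["segmentation_window_ms"] = list(seg_window)
    log["segmentation_window_source"] = (
        "config" if "segmentation_window" in raw else f"default ({nerve})")

    if "segment" in stages:
        evokeds = _session_evokeds(out, montage)
        ga = Evoked(np.mean([e.data for e in evokeds], axis=0),
                    evokeds[0].rate, evokeds[0].window, montage,
                    n_sweeps=len(evokeds), reference_mode="average",
                    channel_ids=evokeds[0].channel_ids)
        sio.write_evoked(ga, out / "grand_average.tsv")
        best, curve, results = select_k(
            ga, seg_window, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            restarts=cfg.restarts, seed=seed, min_frames=cfg.min_duration_frames,
            merge_sc=cfg.merge_sc)
        ts, lb = results[best["kl"]]
        sio.write_templates(ts, ga.channel_ids, out / "templates.tsv")
        sio.write_labels(lb, out / "labels.tsv")
        sio.write_table(pd.DataFrame({
            "K": curve.ks, "W": curve.W, "KL": curve.KL, "CV": curve.CV}),
            out / "criterion_curve.tsv",
            meta={"best_k_kl": best["kl"], "best_k_cv": best["cv"]})
        log["selected_K"] = best
        log["gev_total"] = ts.gev_total
        written.update(templates=str(out / "templates.tsv"),
                       labels=str(out / "labels.tsv"),
                       criterion_curve=str(out / "criterion_curve.tsv"))

    if "fit" in stages:
        evokeds = _session_evokeds(out, montage)
        tpath = out / "templates.tsv"
        if not tpath.exists():
            raise FileNotFoundError(
                "missing stage dependency: no templates (run 'segment')")
        ts = sio.read_templates(tpath)
        fits = fit_sessions(evokeds, ts, min_frames=cfg.min_duration_frames)
        sio.write_table(fits, out / "fit_table.tsv",
                        meta={"window": f"{ts.window[0]} {ts.window[1]}"})
        written["fit_table"] = str(out / "fit_table.tsv")

    if "stats" in stages:
        fpath = out / "fit_table.tsv"
        if not fpath.exists():
            raise FileNotFoundError(
                "missing stage dependency: no fit table (run 'fit')")
        fits = sio.read_table(fpath)
        lat = compare_successive_map_latencies(
            fits, alpha=cfg.alpha_scalp,
            n_electrodes=cfg.n_electrodes_bonferroni)
        sio.write_table(lat, out / "latency_stats.tsv")
        evokeds = _session_evokeds(out, montage)
        rows = []
        for s, ev in enumerate(evokeds):
            for spec in default_component_specs(montage):
                mres = detect_component(ev, spec.channel, spec.window,
                                        spec.polarity, spec.component)
                rows.append({"session": s, "component": spec.component,
                             "channel": spec.channel,
                             "latency_ms": mres.latency,
                             "amplitude_uV": mres.amplitude})
        sio.write_table(pd.DataFrame(rows), out / "component_measures.tsv")
        written.update(latency_stats=str(out / "latency_stats.tsv"),
                       component_measures=str(out / "component_measures.tsv"))

    if "inverse" in stages:
        gpath = out / "grand_average.tsv"
        if not gpath.exists():
            raise FileNotFoundError(
                "missing stage dependency: no grand average (run 'segment')")
        ga = sio.read_evoked(gpath, montage)
        space = build_source_space(head, int(raw.get("n_sources", 3000)))
        lf = compute_leadfield(head, montage, space)
        op = loreta_operator(lf, n_alphas=cfg.n_alphas)
        cds = estimate_cd(op, ga, alpha_select="gcv")
        # per-map mean CD if labels exist, else the CD at the GFP peak
        lpath = out / "labels.tsv"
        from .topography import gfp as _gfp

        cols = {"x_mm": space.points[:, 0], "y_mm": space.points[:, 1],
                "z_mm": space.points[:, 2]}
        if lpath.exists():
            lb = sio.read_labels(lpath)
            for k in range(int(lb.labels.max()) + 1):
                tsel = lb.times[lb.labels == k]
                fsel = np.isin(np.round(cds.times, 6), np.round(tsel, 6))
                cols[f"cd_map{k + 1}"] = cds.cd[:, fsel].mean(axis=1) \
                    if fsel.any() else np.nan
        else:
            peak = int(np.argmax(_gfp(ga.data)))
            cols["cd_peak_gfp"] = cds.cd[:, peak]
        sio.write_table(pd.DataFrame(cols), out / "cd_maps.tsv",
                        meta={"alpha_index": cds.alpha_index,
                              "alpha": _fmt(cds.alpha),
                              "n_sources": space.n_sources,
                              "spacing_mm": _fmt(space.spacing)})
        log["inverse"] = {"alpha_index": cds.alpha_index,
                          "n_sources": space.n_sources}
        written["cd_maps"] = str(out / "cd_maps.tsv")

    if "report" in stages:
        summary = {}
        if (out / "fit_table.tsv").exists():
            fits = sio.read_table(out / "fit_table.tsv")
            summary["mean_total_gev"] = float(
                fits.groupby("session")["gev"].sum().mean())
            summary["onset_latency_ms"] = {
                f"map{int(k) + 1}": round(float(v), 3) for k, v in
                fits.groupby("map")["latency_first_onset"].mean().items()}
        if "selected_K" in log:
            summary["selected_K"] = log["selected_K"]
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        written["summary"] = str(out / "summary.json")

    (out / "pipeline_log.json").write_text(
        json.dumps(log, indent=1, sort_keys=True, default=str))
    written["log"] = str(out / "pipeline_log.json")
    return written


def _fmt(x) -> str:
    return "%.10g" % x
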