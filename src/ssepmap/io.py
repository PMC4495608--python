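"""Readers and writers for recordings, evoked data and result tables.

Continuous recordings travel either as EDF (read-only, through MNE, which
is an optional dependency) or as the package's delimited-text dialect: a
TSV matrix of samples x channels next to a JSON sidecar holding the
sampling rate, stimulus events and an inline montage.  The text dialect
is lossless to the printed precision (%.10g) and is what the simulator
writes.

Evoked potentials, template sets, labellings and fit tables are delimited
text with ``# key: value`` header metadata lines, so every reader/writer
pair round-trips and the outputs diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Event, Evoked, Recording
from .montage import Montage
from .segmentation import Labeling, TemplateSet

__all__ = ["write_recording", "read_recording", "write_evoked", "read_evoked",
           "write_templates", "read_templates", "write_labels", "read_labels",
           "write_table", "read_table"]

_FMT = "%.10g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> None:
    """Write the text dialect: TSV samples x channels + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data.T, fmt=_FMT, delimiter="\t",
               header="\t".join(rec.montage.recorded_ids), comments="")
    meta = {
        "rate": rec.rate,
        "unit": "uV",
        "events": [{"sample": int(e.sample), "nerve": e.nerve, "side": e.side}
                   for e in rec.events],
        "montage": {
            "labels": list(rec.montage.electrode_ids),
            "positions": rec.montage.positions.tolist(),
            "reference": rec.montage.reference_id,
            "roles": rec.montage.roles,
        },
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_recording_text(path: Path) -> Recording:
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"sidecar {side} missing for {path}")
    meta = json.loads(side.read_text())
    data = np.loadtxt(path, delimiter="\t", skiprows=1).T
    if data.ndim == 1:
        data = data[None, :]
    mm = meta["montage"]
    montage = Montage(mm["labels"], np.array(mm["positions"]),
                      mm["reference"], roles=mm.get("roles", {}))
    events = [Event(int(e["sample"]), e.get("nerve", "median"),
                    e.get("side", "left")) for e in meta["events"]]
    return Recording(data, float(meta["rate"]), events, montage)


def _read_recording_edf(path: Path, montage: Montage | None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    rate = float(raw.info["sfreq"])
    events = []
    for ann in raw.annotations:
        desc = str(ann["description"]).lower()
        nerve = "tibial" if "tibial" in desc else "median"
        side = "right" if "right" in desc else "left"
        sample = int(round(ann["onset"] * rate))
        events.append(Event(sample, nerve, side))
    # classic EDF: fall back to a trigger channel (rising edges = stimuli)
    trig_idx = [i for i, ch in enumerate(raw.ch_names)
                if ch.lower().startswith(("trig", "stim", "status"))]
    if trig_idx:
        trig = data[trig_idx[0]]
        keep = [i for i in range(data.shape[0]) if i not in trig_idx]
        data = data[keep]
        if not events:
            half = 0.5 * (trig.max() + trig.min())
            onsets = np.nonzero((trig[1:] > half) & (trig[:-1] <= half))[0] + 1
            if trig[0] > half:
                onsets = np.concatenate([[0], onsets])
            events = [Event(int(s)) for s in onsets]
    if montage is None:
        from .montage import builtin_macaque33

        montage = builtin_macaque33()
    if data.shape[0] != montage.n_recorded:
        raise ValueError("EDF channel count does not match the montage")
    return Recording(data, rate, events, montage)


def read_recording(path, montage: Montage | None = None) -> Recording:
    """Read EDF (``.edf``) or the delimited-text dialect (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_recording_edf(path, montage)
    return _read_recording_text(path)


def _write_header(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}: {v}\n")


def _read_header(path: Path) -> tuple[dict, int]:
    meta, skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, v = line[1:].split(":", 1)
            meta[k.strip()] = v.strip()
            skip += 1
    return meta, skip


def write_evoked(ev: Evoked, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, {
            "rate": ev.rate,
            "window": f"{ev.window[0]} {ev.window[1]}",
            "n_sweeps": ev.n_sweeps,
            "reference_mode": ev.reference_mode,
            "unit": "uV",
        })
        fh.write("time_ms\t" + "\t".join(ev.channel_ids) + "\n")
        times = ev.times
        for i in range(ev.data.shape[1]):
            vals = "\t".join(_FMT % v for v in ev.data[:, i])
            fh.write((_FMT % times[i]) + "\t" + vals + "\n")


def read_evoked(path, montage: Montage) -> Evoked:
    path = Path(path)
    meta, skip = _read_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    chans = list(df.columns[1:])
    data = df[chans].to_numpy().T
    w = meta["window"].split()
    return Evoked(data, float(meta["rate"]), (float(w[0]), float(w[1])),
                  montage, n_sweeps=int(meta.get("n_sweeps", 0)),
                  reference_mode=meta.get("reference_mode", "average"),
                  channel_ids=chans)


def write_templates(ts: TemplateSet, channel_ids, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, {
            "window": f"{ts.window[0]} {ts.window[1]}",
            "seed": ts.seed,
            "restarts": ts.restarts,
            "best_restart": ts.best_restart,
            "gev_total": _FMT % ts.gev_total,
        })
        fh.write("template\t" + "\t".join(channel_ids) + "\n")
        for k in range(ts.K):
            fh.write(str(k) + "\t" +
                     "\t".join(_FMT % v for v in ts.templates[k]) + "\n")


def read_templates(path) -> TemplateSet:
    path = Path(path)
    meta, skip = _read_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    T = df[df.columns[1:]].to_numpy()
    w = meta["window"].split()
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    ts = TemplateSet(T, (float(w[0]), float(w[1])), seed=seed,
                     restarts=int(meta.get("restarts", 0)))
    ts.gev_total = float(meta.get("gev_total", "nan"))
    return ts


def write_labels(lb: Labeling, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, {"window": f"{lb.window[0]} {lb.window[1]}",
                           "rate": lb.rate})
        fh.write("frame\ttime_ms\tlabel\n")
        times = lb.times
        for i, l in enumerate(lb.labels):
            fh.write(f"{i}\t{_FMT % times[i]}\t{l}\n")


def read_labels(path) -> Labeling:
    path = Path(path)
    meta, skip = _read_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    w = meta["window"].split()
    return Labeling(df["label"].to_numpy(), (float(w[0]), float(w[1])),
                    float(meta["rate"]))


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Tidy delimited table with optional header metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            _write_header(fh, meta)
        df.to_csv(fh, sep="\t", index=False, float_format=_FMT,
                  lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    _, skip = _read_header(path)
    return pd.read_csv(path, sep="\t", skiprows=skip)
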