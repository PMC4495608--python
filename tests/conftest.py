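"""Shared fixtures: montage, head model, scripts and a small source setup."""

from __future__ import annotations

import numpy as np
import pytest

from ssepmap import (HeadModel, builtin_macaque33, make_default_script)
from ssepmap.source_imaging import (build_source_space, compute_leadfield,
                                    loreta_operator)


@pytest.fixture(scope="session")
def montage():
    return builtin_macaque33()


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def median_script(montage, head):
    return make_default_script("median", montage, head)


@pytest.fixture(scope="session")
def tibial_script(montage, head):
    return make_default_script("tibial", montage, head)


@pytest.fixture(scope="session")
def small_space(head):
    """Reduced source space (~700 points) for inverse tests."""
    return build_source_space(head, n_target=700)


@pytest.fixture(scope="session")
def small_leadfield(head, montage, small_space):
    return compute_leadfield(head, montage, small_space)


@pytest.fixture(scope="session")
def small_operator(small_leadfield):
    return loreta_operator(small_leadfield)


def write_minimal_edf(path, data_uV, rate, trigger=None, labels=None):
    """Write a minimal classic EDF file (synthetic test fixture).

    ``data_uV`` is (channels, samples); an optional ``trigger`` channel
    (0/1) is appended under the label "Trigger".  One data record per
    second; samples must divide evenly.
    """
    data = np.asarray(data_uV, float)
    if trigger is not None:
        data = np.vstack([data, np.asarray(trigger, float) * 100.0])
    n_ch, n_samp = data.shape
    if labels is None:
        labels = [f"ch{i + 1}" for i in range(n_ch - (trigger is not None))]
    if trigger is not None:
        labels = list(labels) + ["Trigger"]
    rec_dur = 1.0
    spr = int(round(rate * rec_dur))
    assert n_samp % spr == 0, "samples must fill whole records"
    n_rec = n_samp // spr

    pmin, pmax = -3200.0, 3200.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)

    def pad(s, n):
        return s.ljust(n)[:n].encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2020", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad(str(rec_dur), 8), pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(pad(l, 16) for l in labels),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(str(pmin), 8) for _ in range(n_ch)),
        b"".join(pad(str(pmax), 8) for _ in range(n_ch)),
        b"".join(pad(str(dmin), 8) for _ in range(n_ch)),
        b"".join(pad(str(dmax), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ])
    dig = np.clip(np.round((data - pmin) * scale) + dmin, dmin, dmax
                  ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            chunk = dig[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())
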