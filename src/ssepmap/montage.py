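"""Electrode montages for whole-scalp macaque SSEP recordings.

A montage is an ordered set of labelled electrode positions on the unit
sphere (head-centred; scaled to the scalp radius in mm only when a head
model needs physical coordinates), with exactly one designated reference
electrode.  The built-in ``macaque33`` layout reproduces the geometry of a
33-channel cap: 32 recorded electrodes (2 midline sites and 15 sites over
each hemisphere) referenced to a vertex electrode.

The built-in coordinates are a 10-10-inspired approximation: no published
coordinates exist for the original caps, so the layout is symmetric about
the midsagittal plane and spans the whole scalp, but individual positions
are stylised, not digitised.  Electrode *roles* ("brainstem-like" deep
posterior site, "cortical-like" right sensorimotor site) are montage
metadata rather than anatomical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "load_montage", "builtin_macaque33"]

#: (label, theta_deg from vertex, phi_deg azimuth from anterior midline,
#:  positive toward the RIGHT ear)
#: Right-hemisphere sites have phi > 0; left-hemisphere mirrors are listed
#: with the same theta and negated phi.
_MACAQUE33_RIGHT = [
    ("e1", 22.0, 45.0),
    ("e2", 22.0, 135.0),
    ("e3", 45.0, 25.0),
    ("e4", 45.0, 55.0),
    ("e5", 45.0, 120.0),
    ("e6", 45.0, 150.0),
    ("e7", 68.0, 20.0),
    ("e8", 68.0, 50.0),
    ("e9", 68.0, 80.0),
    ("e10", 68.0, 110.0),
    ("e11", 68.0, 140.0),
    ("e12", 45.0, 88.0),       # right central, "cortical-like" role
    ("e13", 68.0, 163.0),
    ("e14", 92.0, 30.0),
    ("e32", 98.0, 155.0),      # right posterior-inferior, "brainstem-like"
]
_MACAQUE33_MIDLINE = [
    ("e15", 45.0, 0.0),        # frontal midline
    ("e16", 45.0, 180.0),      # parieto-occipital midline
]
#: left-hemisphere labels mirroring _MACAQUE33_RIGHT, in order
_MACAQUE33_LEFT_LABELS = [
    "e17", "e18", "e19", "e20", "e21", "e22", "e23", "e24",
    "e25", "e26", "e27", "e28", "e29", "e30", "e31",
]

_MIDLINE_TOL = 1e-9


def _sph(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector; x toward right ear, y anterior, z up (vertex)."""
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


@dataclass
class Montage:
    """Ordered electrode layout on the unit sphere with one reference.

    Parameters
    ----------
    electrode_ids : list of str
        Ordered labels; recorded channels first, reference included.
    positions : ndarray, shape (n, 3)
        Unit-norm positions, head-centred (x right, y anterior, z up).
    reference_id : str
        Label of the reference electrode (a vertex electrode for the
        built-in cap).
    roles : dict
        Optional semantic roles, e.g. ``{"brainstem": "e32",
        "cortical": "e12"}``.
    mirror_map : dict
        Label -> label of the left/right mirror site (midline sites map to
        themselves).  Only populated for the built-in layout.
    """

    electrode_ids: list[str]
    positions: np.ndarray
    reference_id: str
    roles: dict = field(default_factory=dict)
    mirror_map: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.electrode_ids) != len(set(self.electrode_ids)):
            raise ValueError("duplicate electrode labels")
        if self.positions.shape != (len(self.electrode_ids), 3):
            raise ValueError("positions must be (n_electrodes, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite electrode coordinates")
        if self.reference_id not in self.electrode_ids:
            raise ValueError(f"reference {self.reference_id!r} not in montage")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms <= 0):
            raise ValueError("electrode at the origin")
        # normalise to the unit sphere; callers scale to mm via a HeadModel
        self.positions = self.positions / norms[:, None]

    # -- derived views ----------------------------------------------------
    @property
    def n_electrodes(self) -> int:
        """All electrodes, reference included (33 for the built-in cap)."""
        return len(self.electrode_ids)

    @property
    def n_recorded(self) -> int:
        return self.n_electrodes - 1

    @property
    def reference_index(self) -> int:
        return self.electrode_ids.index(self.reference_id)

    @property
    def recorded_ids(self) -> list[str]:
        return [e for e in self.electrode_ids if e != self.reference_id]

    @property
    def recorded_indices(self) -> np.ndarray:
        return np.array(
            [i for i, e in enumerate(self.electrode_ids) if e != self.reference_id]
        )

    @property
    def midline_flags(self) -> np.ndarray:
        """Boolean per electrode: |x| ~ 0 (on the midsagittal plane)."""
        return np.abs(self.positions[:, 0]) < 1e-6

    def index(self, label: str) -> int:
        return self.electrode_ids.index(label)

    def with_positions(self, positions: np.ndarray) -> "Montage":
        return Montage(
            list(self.electrode_ids),
            np.asarray(positions, float),
            self.reference_id,
            dict(self.roles),
            dict(self.mirror_map),
        )

    def rotated(self, rotation: np.ndarray) -> "Montage":
        """Apply a 3x3 rotation matrix to all positions (cap placement)."""
        return self.with_positions(self.positions @ np.asarray(rotation).T)


def builtin_macaque33() -> Montage:
    """The built-in 33-channel macaque cap layout.

    32 recorded electrodes (2 midline + 15 per hemisphere) plus the vertex
    reference.  Symmetric about the midsagittal plane by construction.
    """
    labels: list[str] = []
    pos: list[np.ndarray] = []
    mirror: dict[str, str] = {}
    for (rl, th, ph), ll in zip(_MACAQUE33_RIGHT, _MACAQUE33_LEFT_LABELS):
        labels.append(rl)
        pos.append(_sph(th, ph))
        labels.append(ll)
        pos.append(_sph(th, -ph))
        mirror[rl] = ll
        mirror[ll] = rl
    for ml, th, ph in _MACAQUE33_MIDLINE:
        labels.append(ml)
        pos.append(_sph(th, ph))
        mirror[ml] = ml
    labels.append("ref")
    pos.append(_sph(0.0, 0.0))
    mirror["ref"] = "ref"
    # order channels e1..e32 then ref, for readable tables
    order = sorted(
        range(len(labels)),
        key=lambda i: (labels[i] == "ref", int(labels[i][1:]) if labels[i] != "ref" else 0),
    )
    labels = [labels[i] for i in order]
    pos_arr = np.array([pos[i] for i in order])
    return Montage(
        labels,
        pos_arr,
        reference_id="ref",
        roles={"brainstem": "e32", "cortical": "e12"},
        mirror_map=mirror,
    )


def load_montage(path_or_token) -> Montage:
    """Load a montage from a delimited electrode file or a builtin token.

    The file format is whitespace/comma-delimited ``label x y z`` rows;
    lines starting with ``#`` are comments.  A ``# reference: LABEL``
    header selects the reference; otherwise a row labelled ``ref`` is
    required.
    """
    if str(path_or_token) == "macaque33":
        return builtin_macaque33()
    labels, rows = [], []
    reference = None
    roles: dict[str, str] = {}
    with open(path_or_token) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("reference:"):
                    reference = body.split(":", 1)[1].strip()
                elif body.lower().startswith("role "):
                    # "# role brainstem: e32"
                    k, v = body[5:].split(":", 1)
                    roles[k.strip()] = v.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 4:
                raise ValueError(f"expected 'label x y z', got: {line!r}")
            labels.append(parts[0])
            rows.append([float(p) for p in parts[1:]])
    if reference is None:
        if "ref" not in labels:
            raise ValueError("no reference row ('ref') and no '# reference:' header")
        reference = "ref"
    return Montage(labels, np.array(rows), reference_id=reference, roles=roles)


def save_montage(montage: Montage, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference: {montage.reference_id}\n")
        for k, v in montage.roles.items():
            fh.write(f"# role {k}: {v}\n")
        for lab, p in zip(montage.electrode_ids, montage.positions):
            fh.write(f"{lab}\t{p[0]:.12g}\t{p[1]:.12g}\t{p[2]:.12g}\n")
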