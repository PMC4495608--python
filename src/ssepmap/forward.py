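"""Analytic three-shell spherical forward model.

Scalp potentials generated by a current dipole inside a piecewise-
homogeneous head made of three concentric spherical shells (brain, skull,
scalp) are expanded in Legendre series.  For each harmonic order ``n`` the
radial solution in each shell is ``A r^n + B r^-(n+1)``; the coefficients
follow from continuity of potential and radial current at the two inner
interfaces and a zero-current (Neumann) condition at the scalp surface.
The per-order 5x5 linear systems are solved once per head geometry and
cached; evaluation then reduces to Legendre recursions over the
electrode-source angle cosines, vectorised over all pairs.

The "locally adapted spheres" idea of fitting the sphere to each electrode
is simplified to per-electrode radial scaling of a single best-fit sphere:
each electrode sees shell radii scaled so the scalp surface passes exactly
through it.  For montages constrained to the unit sphere this is the
identity, but it keeps lead fields well defined for slightly off-sphere
electrode files.

Units are nominal: with relative conductivities (brain = scalp = 1,
skull = 0.05) and radii in mm, the returned potentials are "uV per unit
dipole moment"; all downstream topographic quantities are either
normalised or compared within the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["HeadModel", "DipoleSource", "forward_potentials", "forward_topography",
           "dipole_gain"]

_N_TERMS_DEFAULT = 60


@dataclass(frozen=True)
class HeadModel:
    """Three concentric spherical shells.

    scalp_radius : outer (scalp) radius in mm.
    shell_fractions : (scalp, outer skull, inner skull/brain) as fractions
        of the scalp radius; defaults (1.00, 0.78, 0.68).
    conductivities : relative (brain, skull, scalp); skull defaults 0.05.
    """

    scalp_radius: float = 40.0
    shell_fractions: tuple[float, float, float] = (1.00, 0.78, 0.68)
    conductivities: tuple[float, float, float] = (1.0, 0.05, 1.0)
    n_terms: int = _N_TERMS_DEFAULT

    def __post_init__(self):
        scalp_f, skull_f, brain_f = self.shell_fractions
        if not (0.0 < brain_f < skull_f < scalp_f <= 1.0):
            raise ValueError("need 0 < brain < skull < scalp <= 1 shell fractions")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.scalp_radius <= 0:
            raise ValueError("scalp radius must be positive")

    @property
    def brain_radius(self) -> float:
        return self.scalp_radius * self.shell_fractions[2]

    @property
    def skull_radius(self) -> float:
        return self.scalp_radius * self.shell_fractions[1]


@dataclass
class DipoleSource:
    """Point current dipole strictly inside the brain shell.

    position : 3-vector, mm, head-centred.
    moment : 3-vector, nominal nA*m.
    timecourse : optional per-frame amplitude envelope (simulator use).
    """

    position: np.ndarray
    moment: np.ndarray
    timecourse: np.ndarray | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if self.position.shape != (3,) or self.moment.shape != (3,):
            raise ValueError("position and moment must be 3-vectors")


@lru_cache(maxsize=32)
def _shell_coeffs(shell_fractions, conductivities, n_terms) -> np.ndarray:
    """Scalp-surface radial coefficients F_n, n = 1..n_terms.

    Radii in units of the scalp radius.  For order n the unknowns are
    (A1, A2, B2, A3, B3) of the secondary potentials; the dipole's primary
    potential contributes r^-(n+1) inside the brain (the b^(n-1) factor is
    applied at evaluation time).  F_n = A3 + B3 is the radial factor of
    the scalp-surface potential.
    """
    scalp_f, skull_f, brain_f = shell_fractions
    s1, s2, s3 = conductivities  # brain, skull, scalp
    r1 = brain_f / scalp_f
    r2 = skull_f / scalp_f
    F = np.empty(n_terms + 1)
    F[0] = 0.0
    for n in range(1, n_terms + 1):
        np1 = n + 1
        M = np.array([
            # V continuity at r1:  A1 r1^n - A2 r1^n - B2 r1^-(n+1) = -r1^-(n+1)
            [r1 ** n, -(r1 ** n), -(r1 ** -np1), 0.0, 0.0],
            # current continuity at r1
            [s1 * n * r1 ** (n - 1), -s2 * n * r1 ** (n - 1),
             s2 * np1 * r1 ** -(n + 2), 0.0, 0.0],
            # V continuity at r2
            [0.0, r2 ** n, r2 ** -np1, -(r2 ** n), -(r2 ** -np1)],
            # current continuity at r2
            [0.0, s2 * n * r2 ** (n - 1), -s2 * np1 * r2 ** -(n + 2),
             -s3 * n * r2 ** (n - 1), s3 * np1 * r2 ** -(n + 2)],
            # outer Neumann at the scalp surface (radius 1)
            [0.0, 0.0, 0.0, n, -np1],
        ])
        rhs = np.array([
            -(r1 ** -np1),
            s1 * np1 * r1 ** -(n + 2),
            0.0,
            0.0,
            0.0,
        ])
        A1, A2, B2, A3, B3 = np.linalg.solve(M, rhs)
        F[n] = A3 + B3
    return F


def _legendre_sums(cosg: np.ndarray, bpow_weight: np.ndarray,
                   F: np.ndarray, n_terms: int):
    """Accumulate sum_n w_n [n F_n P_n(c)] and sum_n w_n [F_n P'_n(c)].

    ``bpow_weight[..., n]`` would be too large to materialise; instead the
    caller passes ``bratio`` (b/R per pair) and the powers are built up in
    the recursion.  Returns (accA, accB) with the same shape as cosg.
    """
    c = cosg
    bratio = bpow_weight
    P_prev = np.ones_like(c)       # P_0
    P_cur = c.copy()               # P_1
    dP_prev = np.zeros_like(c)     # P'_0
    dP_cur = np.ones_like(c)       # P'_1
    bpow = np.ones_like(c)         # (b/R)^(n-1), n = 1
    accA = np.zeros_like(c)
    accB = np.zeros_like(c)
    for n in range(1, n_terms + 1):
        w = F[n] * bpow
        accA += w * n * P_cur
        accB += w * dP_cur
        if n == n_terms:
            break
        # advance recursions to order n+1
        P_next = ((2 * n + 1) * c * P_cur - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P_cur
        P_prev, P_cur = P_cur, P_next
        dP_prev, dP_cur = dP_cur, dP_next
        bpow = bpow * bratio
    return accA, accB


def dipole_gain(head: HeadModel, electrode_positions: np.ndarray,
                source_positions: np.ndarray) -> np.ndarray:
    """Gain tensor: potentials per unit moment component.

    Parameters
    ----------
    electrode_positions : (n_e, 3) mm; projected radially onto the scalp
        sphere of each electrode's own radius (locally-adapted scaling).
    source_positions : (n_s, 3) mm, strictly inside the brain shell.

    Returns
    -------
    gain : (n_e, n_s, 3) such that ``V[e] = gain[e, s] @ moment_s`` summed
        over sources.  Not average-referenced.
    """
    epos = np.atleast_2d(np.asarray(electrode_positions, float))
    spos = np.atleast_2d(np.asarray(source_positions, float))
    n_e, n_s = epos.shape[0], spos.shape[0]

    r_e = np.linalg.norm(epos, axis=1)                       # per-electrode scalp radius
    if np.any(r_e <= 0):
        raise ValueError("electrode at the head centre")
    ehat = epos / r_e[:, None]

    b = np.linalg.norm(spos, axis=1)                         # dipole eccentricities
    brain_r = head.brain_radius * (r_e[:, None] / head.scalp_radius)
    if np.any(b[None, :] >= brain_r - 1e-9):
        raise ValueError("dipole on or outside the brain shell")
    # radial unit vectors; arbitrary axis for a central dipole (the n=1
    # term is then direction-independent, see the series limit)
    r0hat = np.zeros_like(spos)
    nz = b > 0
    r0hat[nz] = spos[nz] / b[nz, None]
    r0hat[~nz] = [0.0, 0.0, 1.0]

    F = _shell_coeffs(head.shell_fractions, head.conductivities, head.n_terms)

    cosg = np.clip(ehat @ r0hat.T, -1.0, 1.0)                # (n_e, n_s)
    bratio = b[None, :] / r_e[:, None]                        # (b/R_e)
    accA, accB = _legendre_sums(cosg, bratio, F, head.n_terms)

    s_brain = head.conductivities[0]
    pref = 1.0 / (4.0 * np.pi * s_brain * r_e ** 2)           # (n_e,)

    # G[e,s,:] = pref_e * (accA[e,s] - cosg[e,s]*accB[e,s]) r0hat_s
    #            + pref_e * accB[e,s] ehat_e
    radial_w = (accA - cosg * accB) * pref[:, None]
    tang_w = accB * pref[:, None]
    gain = radial_w[:, :, None] * r0hat[None, :, :] + \
        tang_w[:, :, None] * ehat[:, None, :]
    return gain


def forward_potentials(head: HeadModel, electrode_positions: np.ndarray,
                       dipole: DipoleSource) -> np.ndarray:
    """Raw (not re-referenced) scalp potentials of one dipole, uV/unit moment."""
    g = dipole_gain(head, electrode_positions, dipole.position[None, :])
    return g[:, 0, :] @ dipole.moment


def forward_topography(head: HeadModel, montage, dipole: DipoleSource) -> np.ndarray:
    """Average-referenced scalp map of one dipole on all montage electrodes.

    Montage positions (unit sphere) are scaled to the scalp radius.  The
    returned vector is ordered like ``montage.electrode_ids`` and is
    zero-mean across electrodes.
    """
    epos = montage.positions * head.scalp_radius
    v = forward_potentials(head, epos, dipole)
    return v - v.mean()
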