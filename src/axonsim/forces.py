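"""Deterministic force field of the cross-section model.

Three central force laws act between particle surfaces:

* soft excluded-volume repulsion ``−ε(L_r/d − 1)`` for gaps ``0 < d ≤ L_r``,
  diverging at contact and vanishing continuously at the range ``L_r``;
* motor-spring attraction ``κ d`` between a bonded cargo and its microtubule,
  active for gaps up to the capture radius ``R_b``;
* the same soft repulsion between each particle and the axonal membrane
  (disk domain only), with the gap ``d_B = R0 − |x| − r``.

An organelle whose cross-sectional radius is growing (axial position
``z < 0``, pushing axoplasm ahead of itself) has the repulsion prefactors of
all its pairs doubled — a heuristic stand-in for the fluid flow it drives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .params import ModelParams
from .state import BondSet, ParticleState

__all__ = [
    "repulsion_pair",
    "boundary_force",
    "spring_pair",
    "total_forces",
    "ForceAccumulator",
    "ContactError",
]


class ContactError(RuntimeError):
    """Two particle surfaces touched or overlapped; the step must be
    rejected and retried with a smaller time step."""


def repulsion_pair(d: float, eps: float, L_r: float) -> float:
    """Signed magnitude of the excluded-volume repulsion at surface gap ``d``.

    Positive values push the pair apart. Exactly zero for ``d >= L_r``.

    Raises
    ------
    ContactError
        If ``d <= 0``: the force diverges at contact, so an overlap marks an
        integration failure rather than a physical configuration.
    """
    if d <= 0:
        raise ContactError(f"surface contact (d={d:g} nm)")
    if d >= L_r:
        return 0.0
    return eps * (L_r / d - 1.0)


def spring_pair(d: float, kappa: float, R_b: float) -> float:
    """Attractive motor-spring magnitude ``κ·d`` for a bonded pair at gap
    ``d``; exactly zero beyond the capture radius ``R_b`` (the bond persists
    but the cross-bridge exerts no force)."""
    if d <= 0 or d > R_b:
        return 0.0
    return kappa * d


def boundary_force(x, r: float, R0: float, eps: float, L_r: float) -> np.ndarray:
    """Inward membrane repulsion on a disk of radius ``r`` centred at ``x``
    inside a disk domain of radius ``R0``. Returns a 2-vector (pN)."""
    x = np.asarray(x, dtype=float)
    rc = float(np.hypot(x[0], x[1]))
    d = R0 - rc - r
    if d <= 0:
        raise ContactError(f"particle outside the membrane (d_B={d:g} nm)")
    if d >= L_r or rc == 0.0:
        return np.zeros(2)
    return -eps * (L_r / d - 1.0) * x / rc


@dataclass
class ForceAccumulator:
    """Per-particle force vectors (pN), split by species but indexed
    identically to the owning ``ParticleState``."""

    mt: np.ndarray
    nf: np.ndarray
    org: np.ndarray

    @property
    def packed(self) -> np.ndarray:
        return np.concatenate([self.mt, self.nf, self.org], axis=0)


def _packed_arrays(state: ParticleState, bonds: BondSet, params: ModelParams):
    pos = state.packed_positions()
    radius = state.packed_radii()
    n = state.n_total
    factor = np.ones(n)
    for k, o in enumerate(state.organelles):
        if o.incoming:
            factor[state.n_mt + state.n_nf + k] = 2.0
    org_po, org_pm = bonds.org_pairs()
    org_po = org_po + state.n_mt + state.n_nf  # to global particle index
    return pos, radius, factor, org_po, org_pm


def total_forces(state: ParticleState, bonds: BondSet,
                 params: ModelParams) -> ForceAccumulator:
    """Sum of repulsions, membrane force and motor-spring forces on every
    particle. The internal pair forces obey Newton's third law, so they sum
    to zero over the system; only the membrane force breaks that balance.

    Raises :class:`ContactError` if any surface gap is non-positive.
    """
    pos, radius, factor, org_po, org_pm = _packed_arrays(state, bonds, params)
    dom = state.domain
    out = np.zeros((state.n_total, 2))
    status = kernels.compute_forces(
        pos, radius, factor, bonds.nf_bond, org_po, org_pm,
        state.n_mt, state.n_nf,
        params.eps_r, params.L_r, params.kappa_N, params.kappa_O, params.R_b,
        dom.periodic, dom.side if dom.periodic else 0.0,
        0.0 if dom.periodic else dom.radius,
        out,
    )
    if status != kernels.OK:
        raise ContactError("overlapping surfaces in force evaluation")
    nm, nn = state.n_mt, state.n_nf
    return ForceAccumulator(out[:nm], out[nm:nm + nn], out[nm + nn:])
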