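"""Deterministic fixtures and brute-force oracles.

Everything here is implemented independently of the production force path —
literal double loops over the published force laws, no shared kernels — so
the test suite can use it as a ground truth for the optimized implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .domain import Domain, PeriodicBox
from .params import ModelParams
from .state import BondSet, ParticleState

__all__ = ["Fixture", "make_bonded_pair", "make_poisson_pattern",
           "brute_force_forces", "bonded_pair_equilibrium_gap"]


@dataclass
class Fixture:
    name: str
    state: ParticleState
    bonds: BondSet
    expected: dict = field(default_factory=dict)


def bonded_pair_equilibrium_gap(kappa: float, eps: float, L_r: float) -> float:
    """Gap d* at which the motor spring balances the repulsion for a bonded
    pair: the positive root of ``κ d² + ε d − ε L_r = 0`` (closed form,
    independent of any force code)."""
    return (-eps + math.sqrt(eps * eps + 4.0 * kappa * eps * L_r)) / (2.0 * kappa)


def make_bonded_pair(gap: float, params: ModelParams | None = None,
                     domain_radius: float = 1000.0) -> Fixture:
    """One MT and one NF at the given surface gap, bonded, centred in a disk
    domain far from the membrane. Expected net scalar force on the NF along
    the pair axis (positive = toward the MT) is computed by direct scalar
    evaluation of the spring and repulsion laws."""
    if gap <= 0:
        raise ValueError("gap must be positive")
    p = params or ModelParams()
    from .domain import DiskDomain
    sep = gap + p.r_M + p.r_N
    state = ParticleState(
        mt_pos=[[-sep / 2.0, 0.0]], nf_pos=[[sep / 2.0, 0.0]],
        domain=DiskDomain(domain_radius), mt_radius=p.r_M, nf_radius=p.r_N)
    bonds = BondSet(1, 0)
    bonds.nf_bond[0] = 0
    spring = p.kappa_N * gap if gap <= p.R_b else 0.0
    repulsion = p.eps_r * (p.L_r / gap - 1.0) if gap < p.L_r else 0.0
    return Fixture(
        name=f"bonded_pair_gap{gap:g}", state=state, bonds=bonds,
        expected={"net_attraction_on_nf": spring - repulsion,
                  "equilibrium_gap": bonded_pair_equilibrium_gap(
                      p.kappa_N, p.eps_r, p.L_r)})


def make_poisson_pattern(density: float, domain: Domain,
                         rng: np.random.Generator) -> Fixture:
    """Uniform independent points at ``density`` per μm² — the null model
    for RDF (g ≡ 1) and OPD (Poisson with mean ρπR_w²)."""
    if density <= 0:
        raise ValueError("density must be positive")
    n = rng.poisson(density * domain.area / 1e6)
    if isinstance(domain, PeriodicBox):
        pts = rng.uniform(0.0, domain.side, size=(n, 2))
    else:
        r = domain.radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    state = ParticleState(np.empty((0, 2)), pts, domain)
    return Fixture(name=f"poisson_{density:g}", state=state,
                   bonds=BondSet(n, 0),
                   expected={"g_r": 1.0, "opd_mean_per_Rw":
                             lambda Rw: density * math.pi * (Rw / 1e3) ** 2})


def _min_image(dx: float, dy: float, side: float) -> tuple[float, float]:
    dx -= side * round(dx / side)
    dy -= side * round(dy / side)
    return dx, dy


def brute_force_forces(state: ParticleState, bonds: BondSet,
                       params: ModelParams) -> np.ndarray:
    """Literal O(N²) evaluation of every force law; returns packed (n, 2)
    forces in pN. Raises ValueError on surface contact."""
    pos = state.packed_positions()
    rad = state.packed_radii()
    n = state.n_total
    nm, nn = state.n_mt, state.n_nf
    periodic = state.domain.periodic
    side = state.domain.side if periodic else 0.0
    eps, L_r = params.eps_r, params.L_r

    # per-particle epsilon multiplier: ×2 for organelles pushing in (z < 0)
    fac = [1.0] * n
    for k, o in enumerate(state.organelles):
        if o.z < 0.0:
            fac[nm + nn + k] = 2.0

    F = np.zeros((n, 2))
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if periodic:
                dx, dy = _min_image(dx, dy, side)
            r = math.hypot(dx, dy)
            d = r - rad[i] - rad[j]
            if d <= 0.0:
                raise ValueError(f"contact between {i} and {j}")
            if d < L_r:
                mag = eps * fac[i] * fac[j] * (L_r / d - 1.0)
                F[i, 0] -= mag * dx / r       # repulsion: i pushed away from j
                F[i, 1] -= mag * dy / r

    def spring(i_mt: int, j_global: int, kappa: float) -> None:
        dx = pos[j_global, 0] - pos[i_mt, 0]
        dy = pos[j_global, 1] - pos[i_mt, 1]
        if periodic:
            dx, dy = _min_image(dx, dy, side)
        r = math.hypot(dx, dy)
        d = r - rad[i_mt] - rad[j_global]
        if d <= 0.0 or d > params.R_b or r == 0.0:
            return
        mag = kappa * d
        F[i_mt, 0] += mag * dx / r
        F[i_mt, 1] += mag * dy / r
        F[j_global, 0] -= mag * dx / r
        F[j_global, 1] -= mag * dy / r

    for j_nf, m in enumerate(bonds.nf_bond):
        if m >= 0:
            spring(int(m), nm + j_nf, params.kappa_N)
    for k, engaged in enumerate(bonds.org_bonds):
        for m in engaged:
            spring(int(m), nm + nn + k, params.kappa_O)

    if not periodic:
        R0 = state.domain.radius
        for i in range(n):
            rc = math.hypot(pos[i, 0], pos[i, 1])
            dB = R0 - rc - rad[i]
            if dB <= 0.0:
                raise ValueError(f"particle {i} outside the membrane")
            if dB < L_r and rc > 0.0:
                mag = eps * (L_r / dB - 1.0)
                F[i, 0] -= mag * pos[i, 0] / rc
                F[i, 1] -= mag * pos[i, 1] / rc
    return F
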