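"""Particle configuration and motor-engagement state.

The cross-section holds three particle species, all modelled as disks:
microtubules (MT, fixed radius), neurofilaments (NF, fixed radius) and
transiting organelles, whose cross-sectional radius grows and shrinks as the
spindle-shaped body crosses the plane. ``BondSet`` records which cargoes are
currently engaged with which microtubule through motor cross-bridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import Domain
from .params import KIND_MT, KIND_NF, KIND_ORG, ModelParams

__all__ = [
    "OrganelleInstance",
    "ParticleState",
    "BondSet",
    "surface_distance",
    "organelle_radius",
]


def organelle_radius(z: float, a: float, b: float) -> float:
    """Cross-sectional radius ``b·(1 − z²/a²)`` of a spindle-shaped organelle
    whose centre sits an axial distance ``z`` from the plane.

    Raises
    ------
    ValueError
        If ``|z| > a`` (the organelle does not intersect the plane).
    """
    if abs(z) > a:
        raise ValueError(f"axial offset |z|={abs(z):g} exceeds half-length a={a:g}")
    return b * (1.0 - (z / a) ** 2)


def surface_distance(xi, ri: float, xj, rj: float, domain: Domain) -> float:
    """Gap between two particle surfaces: ``|x_i − x_j| − r_i − r_j``.

    Uses the domain metric (Euclidean in the disk, minimum-image in the
    periodic box). May be negative, which means the disks overlap; callers
    decide how to react.
    """
    d = domain.displacement(np.asarray(xi, float), np.asarray(xj, float))
    return float(np.hypot(d[..., 0], d[..., 1])) - ri - rj


@dataclass
class OrganelleInstance:
    """One organelle currently crossing the plane.

    ``z`` runs from ``−a`` (just touching, entering) to ``+a`` (leaving);
    the in-plane radius is derived from ``z`` via :func:`organelle_radius`.
    """

    center: np.ndarray
    z: float
    a: float
    b: float
    entry_time: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)

    @property
    def radius(self) -> float:
        if self.z >= self.a:
            return 0.0
        return organelle_radius(self.z, self.a, self.b)

    @property
    def incoming(self) -> bool:
        """Radius currently increasing (pushing axoplasm outward)."""
        return self.z < 0.0

    def copy(self) -> "OrganelleInstance":
        return OrganelleInstance(self.center.copy(), self.z, self.a, self.b,
                                 self.entry_time)


@dataclass
class ParticleState:
    """Positions and radii of every particle at one instant."""

    mt_pos: np.ndarray
    nf_pos: np.ndarray
    domain: Domain
    mt_radius: float = 12.5
    nf_radius: float = 5.0
    organelles: list[OrganelleInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mt_pos = np.asarray(self.mt_pos, dtype=float).reshape(-1, 2)
        self.nf_pos = np.asarray(self.nf_pos, dtype=float).reshape(-1, 2)

    @property
    def n_mt(self) -> int:
        return len(self.mt_pos)

    @property
    def n_nf(self) -> int:
        return len(self.nf_pos)

    @property
    def n_org(self) -> int:
        return len(self.organelles)

    @property
    def n_total(self) -> int:
        return self.n_mt + self.n_nf + self.n_org

    def copy(self) -> "ParticleState":
        return ParticleState(
            self.mt_pos.copy(), self.nf_pos.copy(), self.domain,
            self.mt_radius, self.nf_radius,
            [o.copy() for o in self.organelles],
        )

    # ------------------------------------------------------------------
    # packed views used by the force/integration kernels.
    # Layout: microtubules [0, n_mt), neurofilaments [n_mt, n_mt+n_nf),
    # organelles at the tail.
    def packed_positions(self) -> np.ndarray:
        parts = [self.mt_pos, self.nf_pos]
        if self.organelles:
            parts.append(np.array([o.center for o in self.organelles]))
        return np.concatenate(parts, axis=0) if parts else np.empty((0, 2))

    def packed_radii(self) -> np.ndarray:
        r = np.empty(self.n_total)
        r[: self.n_mt] = self.mt_radius
        r[self.n_mt : self.n_mt + self.n_nf] = self.nf_radius
        for k, o in enumerate(self.organelles):
            r[self.n_mt + self.n_nf + k] = o.radius
        return r

    def packed_kinds(self) -> np.ndarray:
        k = np.empty(self.n_total, dtype=np.int8)
        k[: self.n_mt] = KIND_MT
        k[self.n_mt : self.n_mt + self.n_nf] = KIND_NF
        k[self.n_mt + self.n_nf :] = KIND_ORG
        return k

    # ------------------------------------------------------------------
    def surface_distances_to_mts(self, points: np.ndarray,
                                 radii) -> np.ndarray:
        """Surface-distance matrix from arbitrary disks to all MTs.

        ``points`` is (n, 2); ``radii`` a scalar or (n,) array. Returns an
        (n, n_mt) array. Used by the binding kinetics.
        """
        points = np.atleast_2d(points)
        disp = self.domain.displacement(points[:, None, :], self.mt_pos[None, :, :])
        dist = np.hypot(disp[..., 0], disp[..., 1])
        return dist - np.atleast_1d(radii)[:, None] - self.mt_radius

    def check_no_overlap(self) -> None:
        """Raise if any pair of surfaces overlaps (d <= 0) or a particle sits
        outside the disk. Overlap after an accepted step indicates an
        integration failure, since the repulsion diverges at contact."""
        pos = self.packed_positions()
        rad = self.packed_radii()
        n = len(pos)
        for i in range(n):
            for j in range(i + 1, n):
                disp = self.domain.displacement(pos[i], pos[j])
                if float(np.hypot(*disp)) - rad[i] - rad[j] <= 0.0:
                    raise ValueError(f"particles {i} and {j} overlap")
        if not self.domain.periodic:
            gap = self.domain.radius - np.hypot(pos[:, 0], pos[:, 1]) - rad
            if np.any(gap <= 0.0):
                raise ValueError("particle outside the disk domain")


class BondSet:
    """Motor-engagement graph.

    Neurofilaments form a partial matching onto microtubules (each NF engages
    at most one MT at a time); organelles hold a set of MT engagements,
    optionally capped at ``m_max``.
    """

    def __init__(self, n_nf: int, n_org: int = 0):
        self.nf_bond = np.full(n_nf, -1, dtype=np.int64)
        self.org_bonds: list[set[int]] = [set() for _ in range(n_org)]

    @classmethod
    def empty_for(cls, state: ParticleState) -> "BondSet":
        return cls(state.n_nf, state.n_org)

    # ------------------------------------------------------------------
    @property
    def n_nf_bound(self) -> int:
        return int(np.sum(self.nf_bond >= 0))

    def add_organelle(self) -> int:
        self.org_bonds.append(set())
        return len(self.org_bonds) - 1

    def remove_organelle(self, idx: int) -> None:
        """Drop organelle ``idx`` and its bonds (list stays index-aligned
        with ``ParticleState.organelles``)."""
        del self.org_bonds[idx]

    def org_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (organelle index, MT index) arrays of all organelle bonds."""
        oo, mm = [], []
        for k, s in enumerate(self.org_bonds):
            for m in sorted(s):
                oo.append(k)
                mm.append(m)
        return np.asarray(oo, dtype=np.int64), np.asarray(mm, dtype=np.int64)

    def copy(self) -> "BondSet":
        out = BondSet(len(self.nf_bond), 0)
        out.nf_bond = self.nf_bond.copy()
        out.org_bonds = [set(s) for s in self.org_bonds]
        return out

    def validate(self, state: ParticleState, params: ModelParams | None = None) -> None:
        if len(self.nf_bond) != state.n_nf or len(self.org_bonds) != state.n_org:
            raise ValueError("BondSet shape does not match ParticleState")
        if np.any(self.nf_bond >= state.n_mt):
            raise ValueError("NF bond references a dead microtubule")
        for s in self.org_bonds:
            if any(m >= state.n_mt or m < 0 for m in s):
                raise ValueError("organelle bond references a dead microtubule")
            if params is not None and params.m_max is not None and len(s) > params.m_max:
                raise ValueError("m_max cap violated")
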