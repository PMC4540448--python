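"""Model parameters, unit conventions, and timed parameter schedules.

Internal unit system
--------------------
All geometry is in nanometres, time in seconds, forces in piconewtons.
Drag coefficients are entered in the conventional pN·s/μm (as measured)
and converted to pN·s/nm once, at access time, through :meth:`ModelParams.drag`.
Thermal energy ``kT`` is entered in pN·μm. Diffusion coefficients follow from
the Einstein relation ``D = kT / μ`` and are never set independently, so the
fluctuation–dissipation balance of the Langevin equations holds by
construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator

import yaml

__all__ = [
    "ModelParams",
    "EventSchedule",
    "einstein_diffusion",
    "counts_from_density",
    "KT_298K",
]

#: Thermal energy at ~298 K in pN·μm. Reproduces the measured diffusion
#: coefficients of all three particle species from their drag coefficients
#: to three significant figures.
KT_298K = 4.11e-3

# particle kind codes used by packed arrays and kernels
KIND_MT = 0
KIND_NF = 1
KIND_ORG = 2


def einstein_diffusion(mu: float, kT: float = KT_298K) -> float:
    """Diffusion coefficient ``D = kT / μ`` in μm²/s.

    Parameters
    ----------
    mu : float
        Drag coefficient in pN·s/μm.
    kT : float
        Thermal energy in pN·μm.
    """
    if mu <= 0 or kT <= 0:
        raise ValueError("Einstein relation requires mu > 0 and kT > 0")
    return kT / mu


def counts_from_density(density: float, R0: float) -> int:
    """Number of particles in a disk of radius ``R0`` (μm) at an areal
    density (per μm²): ``floor(density · π · R0²)``."""
    if density <= 0 or R0 <= 0:
        raise ValueError("density and R0 must be positive")
    return math.floor(density * math.pi * R0 * R0)


@dataclass
class ModelParams:
    """Every physical parameter of the cross-section model.

    Lengths in nm, rates in 1/s, stiffnesses in pN/nm, drags in pN·s/μm
    (converted internally), organelle speed in μm/s, ``kT`` in pN·μm.
    """

    # particle geometry
    r_N: float = 5.0          # neurofilament backbone radius, nm
    r_M: float = 12.5         # microtubule backbone radius, nm
    org_b: float = 140.0      # organelle maximum cross-sectional radius, nm
    org_aspect: float = 10.0  # organelle half-length over max radius, a/b

    # motor-mediated binding
    R_b: float = 80.0         # capture radius for cargo-microtubule binding, nm
    k_on_N: float = 1.0e-2    # NF binding rate, /s
    k_off_N: float = 6.5e-2   # NF unbinding rate, /s
    k_out_N: float = 0.1      # bound-NF departure rate, /s
    k_on_O: float = 2.0       # organelle binding rate, /s
    k_off_O: float = 2.0      # organelle unbinding rate, /s
    k_in_O: float = 0.105     # organelle arrival rate, /s
    s_O: float = 1.0          # organelle transit speed, μm/s

    # volume exclusion
    L_r: float = 121.2        # repulsion range, nm
    eps_r: float = 0.5        # repulsion scale ε (all species pairs), pN

    # motor springs
    kappa_N: float = 0.18     # NF-MT spring constant, pN/nm
    kappa_O: float = 0.9      # organelle-MT spring constant, pN/nm

    # drag coefficients, pN·s/μm
    mu_N: float = 73.5
    mu_M: float = 512.0
    mu_O: float = 40.3

    kT: float = KT_298K       # thermal energy, pN·μm

    # zippering cap: maximum microtubules one organelle may engage; None = unlimited
    m_max: int | None = None

    # integrator steps, s
    h_slow: float = 1.0 / 50.0
    h_fast: float = 1.0 / 1600.0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        positive = [
            "r_N", "r_M", "org_b", "org_aspect", "R_b", "s_O", "L_r",
            "eps_r", "kappa_N", "kappa_O", "mu_N", "mu_M", "mu_O", "kT",
            "h_slow", "h_fast",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        nonnegative = ["k_on_N", "k_off_N", "k_out_N", "k_on_O", "k_off_O", "k_in_O"]
        for name in nonnegative:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.org_aspect <= 1:
            raise ValueError("organelle half-length a must exceed max radius b")
        if self.m_max is not None and self.m_max < 1:
            raise ValueError("m_max must be a positive integer or None")
        if self.h_fast > self.h_slow:
            raise ValueError("h_fast must not exceed h_slow")

    # ------------------------------------------------------------------
    @property
    def org_a(self) -> float:
        """Organelle half-length a = (a/b)·b, nm."""
        return self.org_aspect * self.org_b

    def drag(self, kind: int) -> float:
        """Drag coefficient in internal units, pN·s/nm."""
        mu = (self.mu_M, self.mu_N, self.mu_O)[kind]
        return mu * 1e-3

    def diffusion(self, kind: int) -> float:
        """Diffusion coefficient in internal units, nm²/s."""
        # kT [pN·μm] → pN·nm is ×1e3; D = kT/μ with μ in pN·s/nm
        return self.kT * 1e3 / self.drag(kind)

    def radius(self, kind: int) -> float:
        return (self.r_M, self.r_N, self.org_b)[kind]

    @property
    def D_N(self) -> float:
        """NF diffusion coefficient, μm²/s."""
        return einstein_diffusion(self.mu_N, self.kT)

    @property
    def D_M(self) -> float:
        """MT diffusion coefficient, μm²/s."""
        return einstein_diffusion(self.mu_M, self.kT)

    @property
    def D_O(self) -> float:
        """Organelle diffusion coefficient, μm²/s."""
        return einstein_diffusion(self.mu_O, self.kT)

    @property
    def s_O_nm(self) -> float:
        """Organelle speed in nm/s."""
        return self.s_O * 1e3

    # ------------------------------------------------------------------
    def copy(self, **overrides) -> "ModelParams":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParams)}


@dataclass
class EventSchedule:
    """Timed parameter changes, e.g. blocking NF transport at t = 1 h.

    Each event is ``(time_s, field, value)``; events are applied to the
    run's working copy of :class:`ModelParams` at the first integrator tick
    whose start time is >= the event time.
    """

    events: list[tuple[float, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.events]
        if times != sorted(times):
            raise ValueError("event times must be non-decreasing")
        for _, name, _ in self.events:
            if name not in _FIELD_NAMES:
                raise ValueError(f"{name!r} is not a ModelParams field")

    def __iter__(self) -> Iterator[tuple[float, str, float]]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def due(self, t_prev: float, t: float) -> list[tuple[str, float]]:
        """Events with time in ``(t_prev, t]`` (``t_prev < 0`` catches t=0)."""
        return [(name, v) for ev_t, name, v in self.events if t_prev < ev_t <= t]
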