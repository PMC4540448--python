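"""Simulation domains: a bounded disk (axon cross-section) and a periodic
square box (boundary-free reference geometry for pure neurofilament runs)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiskDomain", "PeriodicBox", "Domain"]


@dataclass(frozen=True)
class DiskDomain:
    """Disk of radius ``radius`` (nm) centred at the origin, bounded by a
    soft repulsive membrane."""

    radius: float

    kind = "disk"
    periodic = False

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Vector(s) from ``a`` to ``b``."""
        return np.asarray(b, dtype=float) - np.asarray(a, dtype=float)

    def wrap(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def contains(self, x: np.ndarray, r: float = 0.0) -> np.ndarray:
        """Whether a particle of radius ``r`` centred at ``x`` lies strictly
        inside the membrane."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.hypot(x[..., 0], x[..., 1]) + r < self.radius

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)


@dataclass(frozen=True)
class PeriodicBox:
    """Square box ``[0, side)²`` (nm) with periodic boundary conditions;
    distances use the minimum-image convention."""

    side: float

    kind = "periodic"
    periodic = True

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        return d - self.side * np.round(d / self.side)

    def wrap(self, x: np.ndarray) -> np.ndarray:
        return np.mod(np.asarray(x, dtype=float), self.side)

    def contains(self, x: np.ndarray, r: float = 0.0) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.ones(x.shape[:-1], dtype=bool)

    @property
    def area(self) -> float:
        return float(self.side**2)


Domain = DiskDomain | PeriodicBox
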