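"""Morphometric statistics: radial distribution function (RDF), occupancy
probability distribution (OPD) and pairwise microtubule distances (PDMT).

The RDF g(r) is the density of particles at distance r from a reference
particle relative to a uniform pattern of the same mean density: 1 for
complete spatial randomness, sharp peaks for a lattice. The OPD p_n is the
distribution of counts in randomly placed circular observation windows and is
Poisson for a uniform pattern; for interacting filament patterns it is well
approximated by a Gaussian. The per-frame mean of the PDMT is the order
parameter for microtubule-neurofilament segregation: it drops as the
microtubules condense into a central cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .domain import DiskDomain, Domain, PeriodicBox
from .state import ParticleState

__all__ = ["rdf", "opd", "pdmt", "pdmt_series",
           "RDFResult", "OPDResult", "PDMTResult"]


@dataclass
class RDFResult:
    r: np.ndarray          # bin centres, nm
    g: np.ndarray
    n_frames: int
    bin_width: float


@dataclass
class OPDResult:
    n: np.ndarray          # occupancy values
    p: np.ndarray          # probabilities, sum to 1
    mean: float            # Gaussian-fit mean
    sd: float              # Gaussian-fit standard deviation
    sample_mean: float
    sample_var: float
    window_radius: float
    n_frames: int


@dataclass
class PDMTResult:
    distances: list[np.ndarray]   # per frame, nm
    mean_per_frame: np.ndarray    # nm

    @property
    def mean(self) -> float:
        return float(np.mean(np.concatenate(self.distances)))


def _as_frames(points) -> list[np.ndarray]:
    if isinstance(points, np.ndarray) and points.ndim == 2:
        return [points]
    return [np.asarray(p, dtype=float) for p in points]


def _pair_distances(pts: np.ndarray, domain: Domain) -> np.ndarray:
    if isinstance(domain, PeriodicBox):
        d = pts[:, None, :] - pts[None, :, :]
        d -= domain.side * np.round(d / domain.side)
        dist = np.hypot(d[..., 0], d[..., 1])
        iu = np.triu_indices(len(pts), k=1)
        return dist[iu]
    return pdist(pts)


def rdf(points, domain: Domain, bin_width: float = 5.0,
        r_max: float | None = None) -> RDFResult:
    """Radial distribution function averaged over frames.

    ``points`` is one (n, 2) array or a sequence of them (frames). In the
    periodic box all minimum-image pair distances are histogrammed and
    normalised by the exact expected pair count of a uniform pattern
    (annulus area over box area). In the bounded disk, reference particles
    are restricted to those at least ``r_max`` from the membrane so every
    annulus lies fully inside the domain (a simple unbiased edge
    correction); neighbours are taken from the full pattern.
    """
    frames = _as_frames(points)
    if any(len(f) < 2 for f in frames):
        raise ValueError("rdf needs at least two points per frame")
    if r_max is None:
        r_max = (domain.side / 2.0 if isinstance(domain, PeriodicBox)
                 else domain.radius / 2.0)
    if isinstance(domain, PeriodicBox) and r_max > domain.side / 2.0:
        raise ValueError("r_max exceeds half the periodic box side")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    r_mid = 0.5 * (edges[1:] + edges[:-1])
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)

    g_acc = np.zeros(len(r_mid))
    for pts in frames:
        n = len(pts)
        rho = n / domain.area
        if isinstance(domain, PeriodicBox):
            dists = _pair_distances(pts, domain)
            hist, _ = np.histogram(dists, bins=edges)
            expected = 0.5 * n * (n - 1) / domain.area * annulus
        else:
            rc = np.hypot(pts[:, 0], pts[:, 1])
            ref = np.flatnonzero(rc <= domain.radius - r_max)
            if len(ref) == 0:
                raise ValueError("no reference particles away from the "
                                 "membrane; reduce r_max")
            d = pts[None, :, :] - pts[ref, None, :]
            dist = np.hypot(d[..., 0], d[..., 1])
            dist[np.arange(len(ref)), ref] = np.inf  # drop self-pairs
            hist, _ = np.histogram(dist.ravel(), bins=edges)
            expected = len(ref) * rho * annulus
        g_acc += hist / expected
    return RDFResult(r=r_mid, g=g_acc / len(frames), n_frames=len(frames),
                     bin_width=bin_width)


def _gaussian_pdf(n, mean, sd):
    return np.exp(-0.5 * ((n - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def opd(points, domain: Domain, window_radius: float = 60.0,
        windows_per_frame: int = 2000,
        rng: np.random.Generator | int | None = None) -> OPDResult:
    """Occupancy probability distribution from randomly placed circular
    windows, pooled over frames, with an unweighted least-squares Gaussian
    fit to the normalised histogram.

    In the disk domain window centres are sampled so the whole window lies
    inside the membrane; in the periodic box they are uniform over the cell.
    """
    frames = _as_frames(points)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(domain, DiskDomain):
        r_allow = domain.radius - window_radius
        if r_allow <= 0:
            raise ValueError("observation window does not fit in the domain")
    counts = []
    for pts in frames:
        if isinstance(domain, PeriodicBox):
            if window_radius >= domain.side / 2.0:
                raise ValueError("window radius must be below half the box")
            tree = cKDTree(np.mod(pts, domain.side), boxsize=domain.side)
            centers = rng.uniform(0.0, domain.side, size=(windows_per_frame, 2))
        else:
            tree = cKDTree(pts)
            # uniform over the allowed disk of centre positions
            u = rng.random(windows_per_frame)
            th = rng.uniform(0, 2 * np.pi, windows_per_frame)
            rr = r_allow * np.sqrt(u)
            centers = np.stack([rr * np.cos(th), rr * np.sin(th)], axis=1)
        counts.append(tree.query_ball_point(centers, window_radius,
                                            return_length=True))
    counts = np.concatenate(counts)
    n_max = int(counts.max())
    n_vals = np.arange(n_max + 1)
    p = np.bincount(counts, minlength=n_max + 1) / len(counts)
    sample_mean = float(counts.mean())
    sample_var = float(counts.var())
    try:
        if len(n_vals) < 3:
            raise RuntimeError("histogram too narrow for a two-parameter fit")
        popt, _ = curve_fit(_gaussian_pdf, n_vals, p,
                            p0=[sample_mean, max(np.sqrt(sample_var), 0.5)],
                            maxfev=10000)
        mean, sd = float(popt[0]), float(abs(popt[1]))
    except RuntimeError:       # degenerate histogram (e.g. empty pattern)
        mean, sd = sample_mean, float(np.sqrt(sample_var))
    return OPDResult(n=n_vals, p=p, mean=mean, sd=sd,
                     sample_mean=sample_mean, sample_var=sample_var,
                     window_radius=window_radius, n_frames=len(frames))


def pdmt(frames) -> PDMTResult:
    """Pairwise centre distances between microtubules, per frame.

    ``frames`` may be a ``ParticleState``, an (n, 2) array of MT positions,
    or a sequence of either. Distances are Euclidean (the statistic is used
    in the disk domain).
    """
    if isinstance(frames, (ParticleState, np.ndarray)):
        frames = [frames]
    dists = []
    for f in frames:
        pts = f.mt_pos if isinstance(f, ParticleState) else np.asarray(f, float)
        if len(pts) < 2:
            raise ValueError("pdmt needs at least two microtubules")
        dists.append(pdist(pts))
    return PDMTResult(distances=dists,
                      mean_per_frame=np.array([d.mean() for d in dists]))


def pdmt_series(record) -> tuple[np.ndarray, np.ndarray]:
    """(t, mean PDMT) series from a TrajectoryRecord's summary series."""
    t = np.asarray(record.series["t"], dtype=float)
    m = np.asarray(record.series["pdmt_mean"], dtype=float)
    return t, m
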