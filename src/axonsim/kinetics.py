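"""Discrete stochastic events: neurofilament bind/unbind/depart/replace and
organelle arrival, transit, engagement and departure.

All events are Bernoulli-thinned at the kinetics step ``h``: an event of rate
``k`` fires with probability ``k·h`` per step (the rates involved are at most
2 /s, so at h = 1/50 s every probability is ≤ 0.04 and the thinning error is
O(h²)). Competing transitions of a bound neurofilament (unbind vs depart) are
resolved with a single uniform draw against cumulative probabilities so that
at most one fires per step.

Every function consumes randomness from the caller's ``numpy.random.Generator``
in a fixed order, which makes whole trajectories bitwise reproducible for a
given seed.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .state import BondSet, OrganelleInstance, ParticleState

__all__ = [
    "nf_binding_step",
    "nf_replace_departed",
    "organelle_arrival_step",
    "organelle_advance",
    "organelle_binding_step",
    "remove_departed_organelles",
]

MAX_PLACEMENT_ATTEMPTS = 100



def _placement_ok(state: ParticleState, point: np.ndarray, radius: float) -> bool:
    """True if a new disk at ``point`` overlaps nothing and is inside the
    domain."""
    if not state.domain.contains(point, radius).all():
        return False
    pos = state.packed_positions()
    if len(pos) == 0:
        return True
    rad = state.packed_radii()
    disp = state.domain.displacement(point[None, :], pos)
    gaps = np.hypot(disp[:, 0], disp[:, 1]) - rad - radius
    return bool(np.all(gaps > 0.0))


def _sample_around_mt(state: ParticleState, mt_idx: int, radius: float,
                      gap: float, rng: np.random.Generator,
                      full_fit_radius: float | None = None) -> np.ndarray | None:
    """One rejection-sampling attempt: a point at surface distance ``gap``
    from microtubule ``mt_idx``, at a uniform angle. ``full_fit_radius``
    additionally requires that a disk of that radius centred at the point
    stays clear of the membrane (used for arriving organelles, which will
    grow to full size on the spot)."""
    theta = rng.uniform(0.0, 2.0 * np.pi)
    offset = (gap + state.mt_radius + radius) * np.array(
        [np.cos(theta), np.sin(theta)])
    point = state.domain.wrap(state.mt_pos[mt_idx] + offset)
    if full_fit_radius is not None and not state.domain.periodic:
        if not state.domain.contains(point, full_fit_radius).all():
            return None
    if _placement_ok(state, point, radius):
        return point
    return None


# ----------------------------------------------------------------------
# Mechanism 1: slow axonal transport of neurofilaments
# ----------------------------------------------------------------------

def nf_binding_step(state: ParticleState, bonds: BondSet, params: ModelParams,
                    h: float, rng: np.random.Generator) -> list[int]:
    """One kinetics step of NF↔MT engagement.

    Unbound neurofilaments with at least one microtubule within the capture
    radius bind with probability ``k_on_N·h`` to a uniformly chosen candidate.
    Bound neurofilaments either unbind (``k_off_N·h``) or are marked as
    *departure candidates* (``k_out_N·h``); departure is only completed by
    :func:`nf_replace_departed`, which may cancel it if no entry site exists.

    Returns the list of departure-candidate NF indices. ``bonds`` is updated
    in place.
    """
    n_nf = state.n_nf
    if n_nf == 0:
        return []
    u = rng.random(n_nf)  # one variate per NF per step, bound or not
    p_on = params.k_on_N * h
    p_off = params.k_off_N * h
    p_out = params.k_out_N * h

    unbound = bonds.nf_bond < 0
    binders = np.flatnonzero(unbound & (u < p_on))
    if len(binders) and state.n_mt:
        # candidate search only for the (few) filaments whose clock fired
        gaps = state.surface_distances_to_mts(state.nf_pos[binders],
                                              state.nf_radius)
        for row, i in enumerate(binders):
            cand = np.flatnonzero(gaps[row] <= params.R_b)
            if len(cand):
                bonds.nf_bond[i] = cand[rng.integers(len(cand))]

    bound = ~unbound
    bonds.nf_bond[bound & (u < p_off)] = -1
    departures = np.flatnonzero(bound & (u >= p_off) & (u < p_off + p_out))
    return [int(i) for i in departures]


def nf_replace_departed(state: ParticleState, bonds: BondSet,
                        params: ModelParams, rng: np.random.Generator,
                        departures: list[int]) -> int:
    """Complete NF departures by re-entering each departing filament next to
    a microtubule, conserving the total NF count.

    The entrant is placed at surface distance ``R_b`` from an *eligible*
    microtubule — one already within ``R_b`` of another neurofilament, so
    that filaments cannot materialise inside an NF-free region — at a
    rejection-sampled angle that overlaps nothing and stays in the domain.
    If no eligible microtubule or no free site is found within a bounded
    number of attempts, the departure is cancelled and the filament simply
    stays where it was (still bound). The entrant starts unbound.

    Returns the number of completed departures.
    """
    done = 0
    for i in departures:
        if state.n_mt == 0:
            break
        # eligibility from the *other* neurofilaments
        gaps = state.surface_distances_to_mts(state.nf_pos, state.nf_radius)
        mask = np.ones(state.n_nf, dtype=bool)
        mask[i] = False
        eligible = np.flatnonzero(np.any(gaps[mask] <= params.R_b, axis=0))
        if len(eligible) == 0:
            continue
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            mt = eligible[rng.integers(len(eligible))]
            point = _sample_around_mt(state, mt, state.nf_radius, params.R_b, rng)
            if point is not None:
                state.nf_pos[i] = point
                bonds.nf_bond[i] = -1
                done += 1
                break
    return done


# ----------------------------------------------------------------------
# Mechanism 2: fast axonal transport of organelles
# ----------------------------------------------------------------------

def organelle_arrival_step(state: ParticleState, bonds: BondSet,
                           params: ModelParams, h: float,
                           rng: np.random.Generator, t: float = 0.0) -> bool:
    """With probability ``k_in_O·h``, a new organelle enters the plane.

    It appears with zero cross-sectional radius (axial position ``z = −a``)
    at surface distance ``R_b`` from a uniformly chosen microtubule — its
    transport track — to which it is immediately bonded. Candidate sites
    must keep the organelle, at its full grown radius, one repulsion range
    ``L_r`` clear of the rigid membrane: a track closer to the membrane
    cannot physically carry a cargo of that size through the cross-section,
    and admitting one would wedge incompressible particles between the
    growing cargo and the immovable wall. With no microtubule in the domain,
    or no admissible collision-free site, the arrival is dropped.
    """
    if rng.random() >= params.k_in_O * h:
        return False
    if state.n_mt == 0:
        return False
    fit = params.org_b + params.L_r
    for _ in range(MAX_PLACEMENT_ATTEMPTS):
        mt = int(rng.integers(state.n_mt))
        point = _sample_around_mt(state, mt, 0.0, params.R_b, rng,
                                  full_fit_radius=fit)
        if point is not None:
            state.organelles.append(OrganelleInstance(
                center=point, z=-params.org_a, a=params.org_a, b=params.org_b,
                entry_time=t))
            k = bonds.add_organelle()
            bonds.org_bonds[k].add(mt)
            return True
    return False


def organelle_advance(state: ParticleState, bonds: BondSet,
                      params: ModelParams, h: float) -> None:
    """Deterministic axial advance ``z += s_O·h`` of every organelle, with
    removal (and bond cleanup) once the trailing tip clears the plane."""
    for o in state.organelles:
        o.z += params.s_O_nm * h
    remove_departed_organelles(state, bonds)


def remove_departed_organelles(state: ParticleState, bonds: BondSet) -> int:
    """Drop organelles with ``z >= a``; returns how many were removed."""
    removed = 0
    for k in reversed(range(state.n_org)):
        if state.organelles[k].z >= state.organelles[k].a:
            del state.organelles[k]
            bonds.remove_organelle(k)
            removed += 1
    return removed


def organelle_binding_step(state: ParticleState, bonds: BondSet,
                           params: ModelParams, h: float,
                           rng: np.random.Generator) -> None:
    """One kinetics step of organelle↔MT engagement.

    Existing bonds break independently with probability ``k_off_O·h`` and
    each (organelle, in-range unbonded MT) pair forms a bond with probability
    ``k_on_O·h``; both transitions are evaluated against the engagement state
    at the start of the step, so a pair cannot unbind and rebind within one
    step. The ``m_max`` cap is honoured by uniform subsampling when more
    pairs fire than slots remain.
    """
    if state.n_mt == 0:
        return
    p_on = params.k_on_O * h
    p_off = params.k_off_O * h
    for k, org in enumerate(state.organelles):
        bound = sorted(bonds.org_bonds[k])
        gaps = state.surface_distances_to_mts(org.center, org.radius)[0]
        cand = [m for m in np.flatnonzero(gaps <= params.R_b)
                if m not in bonds.org_bonds[k]]
        if bound:
            drops = np.asarray(bound)[rng.random(len(bound)) < p_off]
            bonds.org_bonds[k].difference_update(drops.tolist())
        if not cand:
            continue
        fired = [m for m in cand if rng.random() < p_on]
        if params.m_max is not None:
            slots = params.m_max - len(bonds.org_bonds[k])
            if slots <= 0:
                continue
            if len(fired) > slots:
                fired = list(rng.choice(np.asarray(fired), size=slots,
                                        replace=False))
        bonds.org_bonds[k].update(int(m) for m in fired)
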