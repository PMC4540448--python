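"""Numba inner loops for force evaluation and Euler–Maruyama stepping.

These kernels operate on packed arrays (microtubules first, then
neurofilaments, then organelles; see ``ParticleState.packed_positions``).
Correctness is defined by the independent pure-Python oracle in
``axonsim.testing``; the kernels are an optimization of the same force laws.

Force laws (all central, evaluated on the surface gap d):
  repulsion   -ε'(L_r/d − 1) ê   for 0 < d ≤ L_r, else 0; diverges at contact
  motor spring  κ d ê            attractive for 0 ≤ d ≤ R_b, else 0
  boundary    -ε(L_r/d_B − 1) ê_out  for the disk membrane, d_B = R0 − |x| − r
with ε' = ε scaled ×2 per pair member that is an organelle currently pushing
into the plane (z < 0), the hydrodynamic-flow heuristic.

``em_block`` accelerates the pairwise sum with a Verlet pair list (pairs
within the interaction range plus a skin), rebuilt whenever any particle's
accumulated displacement — including the growth of organelle radii — could
invalidate it. The skin bound guarantees that a pair absent from the list
has a strictly positive gap, so contact detection is exact.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# status codes returned by the kernels
OK = 0
CONTACT = 1          # proposed configuration had overlapping surfaces
BAD_INPUT = 2        # incoming configuration already overlapped

#: Verlet-list skin, nm. Half of it bounds the per-particle displacement
#: (plus organelle radius growth) allowed before a rebuild.
SKIN = 80.0


@njit(cache=False)
def compute_forces(pos, radius, factor, nf_bond, org_po, org_pm,
                   n_mt, n_nf, eps, L_r, kappa_N, kappa_O, R_b,
                   periodic, box_side, R0, out):  # pragma: no cover - numba
    """Fill ``out`` with total forces (pN) by direct O(N²) summation;
    return OK or CONTACT.

    ``factor[i]`` is the per-particle ε multiplier (2 for incoming
    organelles, else 1); a pair uses eps·factor[i]·factor[j].
    ``org_po``/``org_pm`` list organelle-bond endpoints as *global* particle
    index and MT index respectively.
    """
    n = pos.shape[0]
    for i in range(n):
        out[i, 0] = 0.0
        out[i, 1] = 0.0

    # pairwise repulsion, all species pairs
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        ri = radius[i]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            if periodic:
                dx -= box_side * math.floor(dx / box_side + 0.5)
                dy -= box_side * math.floor(dy / box_side + 0.5)
            cut = L_r + ri + radius[j]
            r2 = dx * dx + dy * dy
            if r2 >= cut * cut:
                continue
            r = math.sqrt(r2)
            d = r - ri - radius[j]
            if d <= 0.0:
                return CONTACT
            mag = eps * factor[i] * factor[j] * (L_r / d - 1.0)
            fx = mag * dx / r
            fy = mag * dy / r
            out[i, 0] -= fx
            out[i, 1] -= fy
            out[j, 0] += fx
            out[j, 1] += fy

    st = _add_springs_and_boundary(pos, radius, nf_bond, org_po, org_pm,
                                   n_mt, n_nf, eps, L_r, kappa_N, kappa_O,
                                   R_b, periodic, box_side, R0, out)
    return st


@njit(cache=False)
def _add_springs_and_boundary(pos, radius, nf_bond, org_po, org_pm,
                              n_mt, n_nf, eps, L_r, kappa_N, kappa_O, R_b,
                              periodic, box_side, R0,
                              out):  # pragma: no cover - numba
    # NF-MT motor springs
    for jn in range(n_nf):
        m = nf_bond[jn]
        if m < 0:
            continue
        j = n_mt + jn
        dx = pos[j, 0] - pos[m, 0]
        dy = pos[j, 1] - pos[m, 1]
        if periodic:
            dx -= box_side * math.floor(dx / box_side + 0.5)
            dy -= box_side * math.floor(dy / box_side + 0.5)
        r = math.sqrt(dx * dx + dy * dy)
        if r <= 0.0:
            continue
        d = r - radius[m] - radius[j]
        if d <= 0.0 or d > R_b:
            continue
        mag = kappa_N * d
        fx = mag * dx / r
        fy = mag * dy / r
        out[m, 0] += fx     # MT pulled toward NF
        out[m, 1] += fy
        out[j, 0] -= fx
        out[j, 1] -= fy

    # organelle-MT motor springs
    for b in range(org_po.shape[0]):
        i = org_po[b]
        m = org_pm[b]
        dx = pos[i, 0] - pos[m, 0]
        dy = pos[i, 1] - pos[m, 1]
        if periodic:
            dx -= box_side * math.floor(dx / box_side + 0.5)
            dy -= box_side * math.floor(dy / box_side + 0.5)
        r = math.sqrt(dx * dx + dy * dy)
        if r <= 0.0:
            continue
        d = r - radius[m] - radius[i]
        if d <= 0.0 or d > R_b:
            continue
        mag = kappa_O * d
        fx = mag * dx / r
        fy = mag * dy / r
        out[m, 0] += fx
        out[m, 1] += fy
        out[i, 0] -= fx
        out[i, 1] -= fy

    # membrane repulsion (disk only)
    if not periodic:
        for i in range(pos.shape[0]):
            rc = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            d = R0 - rc - radius[i]
            if d <= 0.0:
                return CONTACT
            if d >= L_r or rc <= 0.0:
                continue
            mag = eps * (L_r / d - 1.0)
            out[i, 0] -= mag * pos[i, 0] / rc
            out[i, 1] -= mag * pos[i, 1] / rc
    return OK


@njit(cache=False)
def _build_pair_list(pos, radius, grow, L_r, skin, periodic,
                     box_side):  # pragma: no cover - numba
    """Pairs within L_r + r_i + r_j + grow_i + grow_j + skin of each other.
    ``grow`` is the maximum possible radius increase of each particle over
    the lifetime of the list (nonzero only for entering organelles)."""
    n = pos.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if periodic:
                dx -= box_side * math.floor(dx / box_side + 0.5)
                dy -= box_side * math.floor(dy / box_side + 0.5)
            cut = L_r + radius[i] + radius[j] + grow[i] + grow[j] + skin
            if dx * dx + dy * dy < cut * cut:
                count += 1
    pi = np.empty(count, dtype=np.int32)
    pj = np.empty(count, dtype=np.int32)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if periodic:
                dx -= box_side * math.floor(dx / box_side + 0.5)
                dy -= box_side * math.floor(dy / box_side + 0.5)
            cut = L_r + radius[i] + radius[j] + grow[i] + grow[j] + skin
            if dx * dx + dy * dy < cut * cut:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


@njit(cache=False)
def _forces_from_list(pos, radius, factor, pi, pj, nf_bond, org_po, org_pm,
                      n_mt, n_nf, eps, L_r, kappa_N, kappa_O, R_b,
                      periodic, box_side, R0, out):  # pragma: no cover
    n = pos.shape[0]
    for i in range(n):
        out[i, 0] = 0.0
        out[i, 1] = 0.0
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        if periodic:
            dx -= box_side * math.floor(dx / box_side + 0.5)
            dy -= box_side * math.floor(dy / box_side + 0.5)
        cut = L_r + radius[i] + radius[j]
        r2 = dx * dx + dy * dy
        if r2 >= cut * cut:
            continue
        r = math.sqrt(r2)
        d = r - radius[i] - radius[j]
        if d <= 0.0:
            return CONTACT
        mag = eps * factor[i] * factor[j] * (L_r / d - 1.0)
        fx = mag * dx / r
        fy = mag * dy / r
        out[i, 0] -= fx
        out[i, 1] -= fy
        out[j, 0] += fx
        out[j, 1] += fy
    return _add_springs_and_boundary(pos, radius, nf_bond, org_po, org_pm,
                                     n_mt, n_nf, eps, L_r, kappa_N, kappa_O,
                                     R_b, periodic, box_side, R0, out)


@njit(cache=False)
def em_block(pos, radius, factor, inv_mu, noise_amp,
             nf_bond, org_po, org_pm, n_mt, n_nf,
             org_z, org_a, org_b, s_O,
             eps, L_r, kappa_N, kappa_O, R_b,
             periodic, box_side, R0,
             normals, h, pi, pj, cum, use_cache):  # pragma: no cover
    """Advance ``nsub = normals.shape[0]`` Euler–Maruyama substeps of size h.

    Each substep proposes ``x' = x + F/μ h + √(2Dh) ξ``, deterministically
    advances organelle axial positions, then validates the proposal by
    evaluating forces there; an overlapping proposal is rejected and the
    kernel returns (CONTACT, substeps_completed) with the state left at the
    start of the failed substep. Committed state: pos, radius, factor, org_z
    are updated in place.

    ``pi, pj, cum`` carry the Verlet pair list and the per-particle
    displacement since it was built; with ``use_cache`` the provided list is
    reused (the caller guarantees positions are unchanged since it was
    returned and that no organelle is growing), otherwise it is rebuilt.

    Returns (status, substeps_completed, pi, pj, cum).
    """
    n = pos.shape[0]
    nsub = normals.shape[0]
    n_org = org_z.shape[0]
    org0 = n_mt + n_nf
    sqrt_h = math.sqrt(h)

    # maximum radius growth over the whole block (entering organelles only)
    grow = np.zeros(n)
    for k in range(n_org):
        if org_z[k] < 0.0:
            grow[org0 + k] = (2.0 * org_b[k] / org_a[k]) * s_O * h * nsub

    if not use_cache:
        pi, pj = _build_pair_list(pos, radius, grow, L_r, SKIN, periodic,
                                  box_side)
        cum = np.zeros(n)   # displacement since the list was built

    F = np.zeros((n, 2))
    st = _forces_from_list(pos, radius, factor, pi, pj, nf_bond, org_po,
                           org_pm, n_mt, n_nf, eps, L_r, kappa_N, kappa_O,
                           R_b, periodic, box_side, R0, F)
    if st != OK:
        return BAD_INPUT, 0, pi, pj, cum

    newpos = np.empty_like(pos)
    F2 = np.zeros((n, 2))
    half_skin = 0.5 * SKIN
    for s in range(nsub):
        rebuild = False
        for i in range(n):
            ddx = F[i, 0] * inv_mu[i] * h + noise_amp[i] * sqrt_h * normals[s, i, 0]
            ddy = F[i, 1] * inv_mu[i] * h + noise_amp[i] * sqrt_h * normals[s, i, 1]
            newpos[i, 0] = pos[i, 0] + ddx
            newpos[i, 1] = pos[i, 1] + ddy
            if periodic:
                newpos[i, 0] -= box_side * math.floor(newpos[i, 0] / box_side)
                newpos[i, 1] -= box_side * math.floor(newpos[i, 1] / box_side)
            cum[i] += math.sqrt(ddx * ddx + ddy * ddy)
            if cum[i] > half_skin:
                rebuild = True

        # deterministic axial advance of organelles; radius follows z
        for k in range(n_org):
            idx = org0 + k
            z = org_z[k] + s_O * h
            org_z[k] = z
            if z >= org_a[k] or z <= -org_a[k]:
                radius[idx] = 0.0
            else:
                radius[idx] = org_b[k] * (1.0 - (z / org_a[k]) ** 2)
            factor[idx] = 2.0 if z < 0.0 else 1.0

        if rebuild:
            # list rebuilt at the proposed positions: a superset of every
            # interacting pair there, so contact detection stays exact
            pi, pj = _build_pair_list(newpos, radius, grow, L_r, SKIN,
                                      periodic, box_side)
            for i in range(n):
                cum[i] = 0.0

        st = _forces_from_list(newpos, radius, factor, pi, pj, nf_bond,
                               org_po, org_pm, n_mt, n_nf, eps, L_r,
                               kappa_N, kappa_O, R_b, periodic, box_side,
                               R0, F2)
        if st != OK:
            # reject: roll back the organelle advance, keep pos unchanged
            for k in range(n_org):
                idx = org0 + k
                z = org_z[k] - s_O * h
                org_z[k] = z
                if z >= org_a[k] or z <= -org_a[k]:
                    radius[idx] = 0.0
                else:
                    radius[idx] = org_b[k] * (1.0 - (z / org_a[k]) ** 2)
                factor[idx] = 2.0 if z < 0.0 else 1.0
            return CONTACT, s, pi, pj, cum

        for i in range(n):
            pos[i, 0] = newpos[i, 0]
            pos[i, 1] = newpos[i, 1]
        tmp = F
        F = F2
        F2 = tmp
    return OK, nsub, pi, pj, cum
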