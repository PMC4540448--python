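"""Euler–Maruyama integration of the overdamped Langevin system, interleaved
with the discrete cargo kinetics.

Time is organised in *ticks* of length ``h_slow`` (1/50 s by default). At the
start of each tick the due schedule events are applied and the kinetics
events fire with per-tick probabilities ``rate·h_slow``. The tick is then
integrated mechanically: in a single Euler–Maruyama step of ``h_slow`` when no
organelle is present, or in substeps of ``h_fast`` (1/1600 s) while one is —
the pushing of a growing organelle makes the equations stiff. A proposed
substep that produces overlapping surfaces is rejected and retried at half
the step, recursively, down to ``h_fast/64``; persistent contact aborts the
run with a diagnostic snapshot.

A strict mode (``kinetics_mode="step"``) instead evaluates the kinetics
before every mechanical substep with probabilities ``rate·h``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kernels, kinetics, stats
from .forces import ContactError
from .params import EventSchedule, ModelParams
from .state import BondSet, ParticleState
from .trajectory import Snapshot, TrajectoryRecord

__all__ = ["run", "em_step", "SimClock", "ContactError"]

logger = logging.getLogger("axonsim")

#: factor by which the fast step may be halved before a contact aborts the
#: run. While an organelle grows through a crowded region, microtubules are
#: pushed ahead of it at surface gaps of order 1 nm (their drag limits how
#: fast they can yield), and the low-drag organelle's explicit-Euler kick at
#: such gaps overshoots unless the local step is orders of magnitude below
#: h_fast; the halving ladder therefore needs a deep floor.
MIN_H_FACTOR = 65536
#: fresh-noise attempts for a contacting substep at the smallest step size
MAX_FLOOR_RETRIES = 20


@dataclass
class SimClock:
    """Simulation time, current step size and step counter. The step size is
    ``h_fast`` whenever at least one organelle is present, else ``h_slow``."""

    t: float = 0.0
    h_current: float = 0.0
    n_steps: int = 0


class _Packed:
    """Packed-array view of a (state, bonds) pair for the numba kernels."""

    def __init__(self, state: ParticleState, bonds: BondSet,
                 params: ModelParams):
        self.state = state
        self.bonds = bonds
        self.params = params
        n = state.n_total
        nm, nn, no = state.n_mt, state.n_nf, state.n_org
        self.n, self.n_mt, self.n_nf = n, nm, nn
        self.pos = state.packed_positions()
        self.radius = state.packed_radii()
        self.factor = np.ones(n)
        inv_mu_by_kind = np.array([1.0 / params.drag(k) for k in range(3)])
        amp_by_kind = np.array([np.sqrt(2.0 * params.diffusion(k))
                                for k in range(3)])
        kindcodes = state.packed_kinds()
        self.inv_mu = inv_mu_by_kind[kindcodes]
        self.noise_amp = amp_by_kind[kindcodes]
        self.org_z = np.array([o.z for o in state.organelles])
        self.org_a = np.array([o.a for o in state.organelles])
        self.org_b = np.array([o.b for o in state.organelles])
        for k, o in enumerate(state.organelles):
            if o.incoming:
                self.factor[nm + nn + k] = 2.0
        po, pm = bonds.org_pairs()
        self.org_po = po + nm + nn
        self.org_pm = pm
        dom = state.domain
        self.periodic = dom.periodic
        self.box_side = dom.side if dom.periodic else 0.0
        self.R0 = 0.0 if dom.periodic else dom.radius
        # Verlet pair-list cache (pi, pj, cum); reusable across consecutive
        # organelle-free ticks while positions evolve only through _block
        self.pair_cache: tuple | None = None

    def adopt_cache(self, other: "_Packed | None") -> None:
        """Take over a predecessor's pair list. Only valid when nothing
        outside the kernels moved or resized particles in between and no
        organelle is present (their radii change within a block)."""
        if other is not None and other.pair_cache is not None \
                and self.n == other.n and not self.state.organelles:
            self.pair_cache = other.pair_cache

    def _block(self, h: float, normals: np.ndarray) -> tuple[int, int]:
        p = self.params
        if self.pair_cache is None:
            pi = np.empty(0, dtype=np.int32)
            pj = np.empty(0, dtype=np.int32)
            cum = np.empty(0)
            use_cache = False
        else:
            pi, pj, cum = self.pair_cache
            use_cache = True
        status, done, pi, pj, cum = kernels.em_block(
            self.pos, self.radius, self.factor, self.inv_mu, self.noise_amp,
            self.bonds.nf_bond, self.org_po, self.org_pm, self.n_mt, self.n_nf,
            self.org_z, self.org_a, self.org_b, p.s_O_nm,
            p.eps_r, p.L_r, p.kappa_N, p.kappa_O, p.R_b,
            self.periodic, self.box_side, self.R0,
            normals, h, pi, pj, cum, use_cache)
        if self.state.organelles or status != kernels.OK:
            # growth allowances are per-block, and a rejected proposal may
            # have rebuilt the list at positions that were never committed:
            # in either case the list cannot be carried over
            self.pair_cache = None
        else:
            self.pair_cache = (pi, pj, cum)
        return status, done

    def advance(self, h: float, nsub: int, rng: np.random.Generator,
                min_h: float) -> int:
        """Advance ``nsub`` substeps of size ``h``, halving locally on
        contact. Returns the number of committed elementary substeps."""
        normals = rng.standard_normal((nsub, self.n, 2))
        status, done = self._block(h, normals)
        if status == kernels.OK:
            return nsub
        if status == kernels.BAD_INPUT:
            raise ContactError("force evaluation on an overlapping "
                               "configuration; state is corrupt")
        # contact while proposing substep `done`: resolve it at h/2, then
        # finish the remaining substeps at h
        n_done = done
        if h / 2.0 < min_h:
            # at the smallest step the thermal kick per substep can exceed a
            # tightly squeezed gap; redraw the noise a bounded number of
            # times before declaring the contact unresolvable
            for _ in range(MAX_FLOOR_RETRIES):
                status, _ = self._block(h, rng.standard_normal((1, self.n, 2)))
                if status == kernels.OK:
                    break
            else:
                raise ContactError(
                    f"persistent surface contact at time step h={h:g}s; "
                    f"step underflow below {min_h:g}s")
            n_done += 1
        else:
            n_done += self.advance(h / 2.0, 2, rng, min_h)
        remaining = nsub - done - 1
        if remaining > 0:
            n_done += self.advance(h, remaining, rng, min_h)
        return n_done

    def writeback(self) -> None:
        st = self.state
        nm, nn = self.n_mt, self.n_nf
        st.mt_pos[:] = self.pos[:nm]
        st.nf_pos[:] = self.pos[nm:nm + nn]
        for k, o in enumerate(st.organelles):
            o.center[:] = self.pos[nm + nn + k]
            o.z = float(self.org_z[k])


def em_step(state: ParticleState, bonds: BondSet, params: ModelParams,
            h: float, rng: np.random.Generator,
            normals: np.ndarray | None = None) -> None:
    """One Euler–Maruyama step ``x ← x + (F/μ)h + √(2Dh)ξ`` for every
    particle, in place, with deterministic organelle axial advance.

    ``normals``, if given, must be shaped (n_total, 2) and replaces the
    random draws (used for deterministic checks; set to zeros to integrate
    the drift alone). Contact in the proposed configuration triggers the
    halving retry policy, except when explicit normals are supplied.
    """
    packed = _Packed(state, bonds, params)
    if normals is not None:
        status, _ = packed._block(h, normals.reshape(1, packed.n, 2))
        if status != kernels.OK:
            raise ContactError("contact in em_step with explicit normals")
    else:
        packed.advance(h, 1, rng, params.h_fast / MIN_H_FACTOR)
    packed.writeback()


def _record_series(record: TrajectoryRecord, t: float, state: ParticleState,
                   bonds: BondSet) -> None:
    mean_pdmt = (stats.pdmt(state).mean if state.n_mt >= 2 else np.nan)
    frac = bonds.n_nf_bound / state.n_nf if state.n_nf else np.nan
    record.series["t"].append(t)
    record.series["pdmt_mean"].append(mean_pdmt)
    record.series["n_org"].append(state.n_org)
    record.series["nf_bound_frac"].append(frac)
    logger.info("t=%8.1f s  n_org=%d  nf_bound=%.3f  mean_pdmt=%.1f nm",
                t, state.n_org, frac, mean_pdmt)


def run(state: ParticleState, bonds: BondSet, params: ModelParams,
        end_time: float, *, schedule: EventSchedule | None = None,
        rng: np.random.Generator | int | None = None,
        snapshot_every: float = 60.0, series_every: float = 60.0,
        kinetics_mode: str = "tick", metadata: dict | None = None,
        kinetics_enabled: bool = True) -> TrajectoryRecord:
    """Simulate the full model from ``state``/``bonds`` for ``end_time``
    seconds, mutating them in place and returning a :class:`TrajectoryRecord`.

    Per tick: due schedule events → NF kinetics (binding/unbinding/departure
    with conserving replacement) → organelle arrival → organelle engagement →
    mechanical integration → organelle departure cleanup → periodic capture
    of snapshots and summary series. Deterministic for a fixed seed.
    """
    if kinetics_mode not in ("tick", "step"):
        raise ValueError("kinetics_mode must be 'tick' or 'step'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    params = params.copy()  # schedule mutates the working copy
    min_h = params.h_fast / MIN_H_FACTOR

    record = TrajectoryRecord(metadata=dict(metadata or {}))
    record.metadata.setdefault("params", params.to_dict())
    record.metadata.setdefault("end_time", end_time)
    clock = SimClock(t=0.0, h_current=params.h_slow)

    record.snapshots.append(Snapshot(0.0, state.copy(), bonds.copy()))
    _record_series(record, 0.0, state, bonds)
    next_snap = snapshot_every
    next_series = series_every
    n_events = len(schedule) if schedule else 0
    ev_idx = 0

    def do_kinetics(h: float, t: float) -> bool:
        """Returns True if any particle was moved or added outside the
        integrator (which invalidates a cached pair list)."""
        departures = kinetics.nf_binding_step(state, bonds, params, h, rng)
        moved = False
        if departures:
            moved = kinetics.nf_replace_departed(state, bonds, params, rng,
                                                 departures) > 0
        arrived = kinetics.organelle_arrival_step(state, bonds, params, h,
                                                  rng, t)
        kinetics.organelle_binding_step(state, bonds, params, h, rng)
        return moved or arrived

    t = 0.0
    eps_t = 1e-9
    prev_packed = None
    while t < end_time - eps_t:
        dt = min(params.h_slow, end_time - t)
        while ev_idx < n_events and schedule.events[ev_idx][0] <= t + eps_t:
            _, name, value = schedule.events[ev_idx]
            setattr(params, name, value)
            logger.info("t=%.1f s: schedule sets %s=%g", t, name, value)
            prev_packed = None   # force constants may have changed
            ev_idx += 1

        if kinetics_enabled and kinetics_mode == "tick":
            if do_kinetics(dt, t):
                prev_packed = None

        packed = _Packed(state, bonds, params)
        packed.adopt_cache(prev_packed)
        if state.n_org > 0:
            nsub = max(1, round(dt / params.h_fast))
            h = dt / nsub
        else:
            nsub, h = 1, dt
        clock.h_current = params.h_fast if state.n_org > 0 else params.h_slow
        if kinetics_enabled and kinetics_mode == "step":
            for s in range(nsub):
                do_kinetics(h, t + s * h)
                packed = _Packed(state, bonds, params)
                try:
                    clock.n_steps += packed.advance(h, 1, rng, min_h)
                except ContactError as err:
                    err.snapshot = Snapshot(t, state.copy(), bonds.copy())
                    raise
                packed.writeback()
        else:
            try:
                clock.n_steps += packed.advance(h, nsub, rng, min_h)
            except ContactError as err:
                packed.writeback()
                err.snapshot = Snapshot(t, state.copy(), bonds.copy())
                raise
            packed.writeback()
        prev_packed = packed
        if kinetics.remove_departed_organelles(state, bonds):
            prev_packed = None
        t += dt
        clock.t = t

        if t + eps_t >= next_series:
            _record_series(record, t, state, bonds)
            next_series += series_every
        if t + eps_t >= next_snap:
            record.snapshots.append(Snapshot(t, state.copy(), bonds.copy()))
            next_snap += snapshot_every

    if record.snapshots[-1].t < t - eps_t:
        record.snapshots.append(Snapshot(t, state.copy(), bonds.copy()))
    record.metadata["n_steps"] = clock.n_steps
    return record
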