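"""Preset experiment protocols and the initial-condition generator.

Initial configurations are produced by seeding particles on a hexagonal
lattice (overlap-free by construction) and then "randomizing": evolving them
under excluded-volume repulsion, the membrane force and Brownian motion
only — no motor bonds, no cargo traffic — until the pattern has lost the
lattice order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import integrator, stats
from .domain import DiskDomain, Domain, PeriodicBox
from .params import EventSchedule, ModelParams, counts_from_density
from .state import BondSet, ParticleState
from .trajectory import TrajectoryRecord

__all__ = ["ScenarioSpec", "preset", "preset_names", "alt_blockage_offrate",
           "init_hexagonal_randomized", "hex_lattice", "simulate",
           "normal_axon_pdmt", "scaled_segregation_spec"]

HOUR = 3600.0

#: experimentally determined areal densities in axonal cross-sections, /μm²
MT_DENSITY = 18.0
NF_DENSITY = 115.0


def hex_lattice(domain: Domain, n: int, margin: float,
                rng: np.random.Generator,
                min_spacing: float = 0.0) -> np.ndarray:
    """``n`` sites of a hexagonal lattice inside the domain.

    The lattice spacing is chosen as large as possible while still providing
    at least ``n`` sites at distance ``margin`` from the disk membrane (or
    anywhere in the periodic cell); ``n`` sites are then drawn uniformly
    without replacement, so thinning is spatially unbiased.
    """
    if isinstance(domain, DiskDomain):
        area = np.pi * (domain.radius - margin) ** 2
    else:
        area = domain.area

    def sites(spacing: float) -> np.ndarray:
        dy = spacing * np.sqrt(3) / 2.0
        if isinstance(domain, DiskDomain):
            R = domain.radius - margin
            rows = int(np.ceil(2 * R / dy)) + 2
            out = []
            for j in range(-rows, rows + 1):
                y = j * dy
                x0 = (j % 2) * spacing / 2.0
                cols = int(np.ceil(2 * R / spacing)) + 2
                for i in range(-cols, cols + 1):
                    x = x0 + i * spacing
                    if x * x + y * y <= R * R:
                        out.append((x, y))
            return np.asarray(out)
        L = domain.side
        ny = max(1, int(L / dy))
        nx = max(1, int(L / spacing))
        out = []
        for j in range(ny):
            x0 = (j % 2) * spacing / 2.0
            for i in range(nx):
                out.append(((x0 + i * spacing) % L, j * L / ny))
        return np.asarray(out)

    # ideal hexagonal cell area s²·√3/2 = area/n; shrink until enough sites
    spacing = np.sqrt(2.0 * area / (np.sqrt(3) * n))
    if spacing < min_spacing:
        raise ValueError("requested count exceeds packing capacity")
    pts = sites(spacing)
    while len(pts) < n:
        spacing *= 0.97
        if spacing < max(min_spacing, 1e-3):
            raise ValueError("requested count exceeds packing capacity")
        pts = sites(spacing)
    idx = rng.choice(len(pts), size=n, replace=False)
    return pts[idx]


def init_hexagonal_randomized(domain: Domain, n_mt: int, n_nf: int,
                              params: ModelParams,
                              randomize_duration: float,
                              rng: np.random.Generator | int | None = None,
                              h: float | None = None,
                              pdmt_guard: bool = False) -> ParticleState:
    """Hexagonally seeded, Brownian-randomized mixed configuration.

    Microtubules and neurofilaments are assigned to lattice sites uniformly
    at random, then evolved with repulsion, membrane force and Brownian
    motion only for ``randomize_duration`` seconds (``h`` overrides the slow
    step for this phase). With ``pdmt_guard`` the randomization stops early
    once the mean pairwise MT distance changes by less than 1% over 10 s.
    A duration of zero returns the exact lattice.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = n_mt + n_nf
    r_max = max(params.r_M if n_mt else params.r_N, params.r_N)
    pts = hex_lattice(domain, n, r_max + 1.0, rng,
                      min_spacing=2.0 * r_max + 1.0)
    order = rng.permutation(n)
    state = ParticleState(pts[order[:n_mt]], pts[order[n_mt:]], domain,
                          params.r_M, params.r_N)
    if randomize_duration <= 0:
        return state
    quiet = params.copy(k_on_N=0.0, k_in_O=0.0)
    if h is not None:
        quiet = quiet.copy(h_slow=h)
    bonds = BondSet.empty_for(state)
    if pdmt_guard and n_mt >= 2:
        elapsed, chunk = 0.0, 10.0
        last = stats.pdmt(state).mean
        while elapsed < randomize_duration:
            dt = min(chunk, randomize_duration - elapsed)
            integrator.run(state, bonds, quiet, dt, rng=rng,
                           snapshot_every=np.inf, series_every=np.inf,
                           kinetics_enabled=False)
            elapsed += dt
            cur = stats.pdmt(state).mean
            if abs(cur - last) / last < 0.01:
                break
            last = cur
    else:
        integrator.run(state, bonds, quiet, randomize_duration, rng=rng,
                       snapshot_every=np.inf, series_every=np.inf,
                       kinetics_enabled=False)
    return state


# ----------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """A complete, runnable experiment protocol."""

    name: str
    domain_kind: str = "disk"          # "disk" | "periodic"
    domain_size: float = 1000.0        # R0 or box side, nm
    n_mt: int = 56
    n_nf: int = 361
    params: ModelParams = field(default_factory=ModelParams)
    schedule: EventSchedule = field(default_factory=EventSchedule)
    end_time: float = 20 * HOUR
    snapshot_every: float = 60.0
    series_every: float = 60.0
    randomize_duration: float = 60.0
    randomize_h: float | None = None
    kinetics_enabled: bool = True

    def domain(self) -> Domain:
        if self.domain_kind == "disk":
            return DiskDomain(self.domain_size)
        if self.domain_kind == "periodic":
            return PeriodicBox(self.domain_size)
        raise ValueError(f"unknown domain kind {self.domain_kind!r}")

    def replace(self, **kw) -> "ScenarioSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        d["schedule"] = [list(e) for e in self.schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        d["params"] = ModelParams.from_dict(d.get("params", {}))
        d["schedule"] = EventSchedule(
            [tuple(e) for e in d.get("schedule", [])])
        return cls(**d)


def _disk_spec(name: str, **kw) -> ScenarioSpec:
    base = dict(name=name, domain_kind="disk", domain_size=1000.0,
                n_mt=counts_from_density(MT_DENSITY, 1.0),
                n_nf=counts_from_density(NF_DENSITY, 1.0))
    base.update(kw)
    return ScenarioSpec(**base)


def _nf_only_spec(name: str, n_nf: int, eps: float) -> ScenarioSpec:
    # pure neurofilament runs in a 1 μm periodic box, integrated at 1/200 s;
    # morphometrics are read from frames between 25 s and 30 s
    return ScenarioSpec(
        name=name, domain_kind="periodic", domain_size=1000.0,
        n_mt=0, n_nf=n_nf,
        params=ModelParams(eps_r=eps, h_slow=1.0 / 200.0, k_in_O=0.0),
        end_time=30.0, snapshot_every=0.1, series_every=np.inf,
        randomize_duration=0.0)


def _blockage_schedule(k_on: float = 0.0, t_block: float = HOUR,
                       t_restore: float | None = None) -> EventSchedule:
    ev = [(t_block, "k_on_N", k_on)]
    if t_restore is not None:
        ev.append((t_restore, "k_on_N", ModelParams().k_on_N))
    return EventSchedule(ev)


def _presets() -> dict[str, ScenarioSpec]:
    reg: dict[str, ScenarioSpec] = {}
    reg["control"] = _disk_spec("control", end_time=20 * HOUR)
    reg["blockage"] = _disk_spec("blockage", schedule=_blockage_schedule(),
                                 end_time=12 * HOUR)
    reg["reversible_segregation"] = _disk_spec(
        "reversible_segregation",
        schedule=_blockage_schedule(t_restore=13 * HOUR),
        end_time=20 * HOUR)
    for f in (50, 20, 0):
        reg[f"partial_block_{f}"] = _disk_spec(
            f"partial_block_{f}",
            schedule=_blockage_schedule(k_on=ModelParams().k_on_N * f / 100.0),
            end_time=18 * HOUR)
    for m in (1, 2, 4, 8, 16):
        reg[f"mmax_{m}"] = _disk_spec(
            f"mmax_{m}", params=ModelParams(m_max=m),
            schedule=_blockage_schedule(), end_time=18 * HOUR)
    for b, fx in ((140, 1.0), (140, 1.5), (70, 1.0), (70, 2.0)):
        key = f"b{b}_flux_x{fx:g}"
        reg[key] = _disk_spec(
            key, params=ModelParams(org_b=float(b),
                                    k_in_O=0.105 * fx),
            schedule=_blockage_schedule(), end_time=18 * HOUR)
    reg["nf_only_200"] = _nf_only_spec("nf_only_200", 200, 0.5)
    reg["nf_only_400"] = _nf_only_spec("nf_only_400", 400, 0.5)
    reg["nf_only_400_eps025"] = _nf_only_spec("nf_only_400_eps025", 400, 0.25)
    return reg


def preset_names() -> list[str]:
    return sorted(_presets())


def preset(name: str) -> ScenarioSpec:
    """A fully populated protocol by name; unknown names raise KeyError."""
    reg = _presets()
    if name not in reg:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(reg)}")
    return reg[name]


def alt_blockage_offrate(factor: float) -> ScenarioSpec:
    """Alternative transport-blockage protocol: multiply the NF off-rate by
    ``factor`` at the blockage time instead of zeroing the on-rate."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    p = ModelParams()
    return _disk_spec(
        f"offrate_x{factor:g}",
        schedule=EventSchedule([(HOUR, "k_off_N", p.k_off_N * factor)]),
        end_time=12 * HOUR)


def make_initial(spec: ScenarioSpec,
                 rng: np.random.Generator | int | None = None) -> ParticleState:
    """Resolve a spec into its randomized initial configuration."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dur = spec.randomize_duration
    if spec.name.startswith("nf_only"):
        dur = 0.0   # randomization is the recorded run itself
    return init_hexagonal_randomized(
        spec.domain(), spec.n_mt, spec.n_nf, spec.params, dur, rng,
        h=spec.randomize_h, pdmt_guard=spec.n_mt >= 2)


def simulate(spec: ScenarioSpec, seed: int | None = None,
             end_time: float | None = None) -> TrajectoryRecord:
    """Initial condition plus full run for one scenario, one seed. The seed
    feeds a single PCG64 stream used for randomization, kinetics and noise,
    so the whole trajectory is reproducible."""
    rng = np.random.default_rng(seed)
    state = make_initial(spec, rng)
    bonds = BondSet.empty_for(state)
    record = integrator.run(
        state, bonds, spec.params,
        end_time if end_time is not None else spec.end_time,
        schedule=spec.schedule, rng=rng,
        snapshot_every=spec.snapshot_every, series_every=spec.series_every,
        kinetics_enabled=spec.kinetics_enabled,
        metadata={"scenario": spec.name, "seed": seed,
                  "spec": spec.to_dict()})
    return record


def normal_axon_pdmt(seeds=(0, 1, 2), settle_time: float = 1.5 * HOUR,
                     sample_time: float = 1800.0) -> dict:
    """Mean pairwise MT distance of the normal (interspersed) axon, in units
    of R_0.

    For each seed: build the randomized 56 MT + 361 NF disk configuration,
    run 1.5 simulated hours of normal transport so the pattern reaches its
    dynamic working state (organelle zippering transiently clusters
    microtubules and pulls the mean below the randomized, nearly uniform
    value; the slow fluctuations of the mean PDMT have a correlation time
    of tens of minutes, hence the long settle), then average the per-minute
    mean PDMT over ``sample_time``.
    Returns per-seed means, their grand mean, and the frame count.
    """
    spec = preset("control")
    per_seed = []
    n_frames = 0
    for s in seeds:
        rec = simulate(spec, seed=int(s),
                       end_time=settle_time + sample_time)
        t = np.asarray(rec.series["t"], dtype=float)
        m = np.asarray(rec.series["pdmt_mean"], dtype=float)
        sel = t > settle_time
        n_frames = int(sel.sum())
        per_seed.append(float(m[sel].mean()) / spec.domain_size)
    return {"per_seed": per_seed, "mean": float(np.mean(per_seed)),
            "n_frames": n_frames, "n_particles": spec.n_mt + spec.n_nf}


def scaled_segregation_spec(condition: str, R0_um: float = 0.5,
                            settle_time: float = HOUR,
                            follow_time: float = 2 * HOUR) -> ScenarioSpec:
    """Half-scale desk protocol for the segregation trend.

    Particle counts follow the measured areal densities and the organelle
    flux scales with cross-sectional area, so traffic per unit area — and
    with it the balance between neurofilament transport and organelle
    zippering — matches the full-size model; organelle size stays at the
    default. Transport runs normally for ``settle_time``; the ``blockage``
    and ``mmax1`` conditions then zero the NF binding rate (``mmax1`` also
    caps each organelle at one engagement throughout), while ``control``
    continues unperturbed.
    """
    if condition not in ("blockage", "control", "mmax1"):
        raise ValueError(f"unknown condition {condition!r}")
    p = ModelParams(k_in_O=ModelParams().k_in_O * R0_um**2,
                    m_max=1 if condition == "mmax1" else None)
    sched = (EventSchedule() if condition == "control"
             else EventSchedule([(settle_time, "k_on_N", 0.0)]))
    return ScenarioSpec(
        name=f"scaled_{condition}",
        domain_kind="disk", domain_size=R0_um * 1000.0,
        n_mt=counts_from_density(MT_DENSITY, R0_um),
        n_nf=counts_from_density(NF_DENSITY, R0_um),
        params=p, schedule=sched, end_time=settle_time + follow_time,
        snapshot_every=1e9, series_every=60.0, randomize_duration=60.0)
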