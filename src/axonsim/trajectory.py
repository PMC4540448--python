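"""Trajectory container and on-disk formats (HDF5 or a CSV directory).

A ``TrajectoryRecord`` carries enough metadata (full resolved parameter set,
seed, package version) to re-run the simulation bit-identically, a sparse
series of full configuration snapshots, and a denser per-minute series of
summary quantities (mean pairwise MT distance, organelle count, bound-NF
fraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .domain import DiskDomain, Domain, PeriodicBox
from .state import BondSet, OrganelleInstance, ParticleState

__all__ = ["Snapshot", "TrajectoryRecord"]


@dataclass
class Snapshot:
    t: float
    state: ParticleState
    bonds: BondSet


@dataclass
class TrajectoryRecord:
    metadata: dict
    snapshots: list[Snapshot] = field(default_factory=list)
    series: dict[str, list] = field(default_factory=lambda: {
        "t": [], "pdmt_mean": [], "n_org": [], "nf_bound_frac": []})

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    def series_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.series)

    # ------------------------------------------------------------------
    def save(self, path, fmt: str | None = None) -> None:
        path = Path(path)
        if fmt is None:
            fmt = "csv" if path.suffix == "" else "h5"
        if fmt == "h5":
            self.to_hdf5(path)
        elif fmt == "csv":
            self.to_csv_dir(path)
        else:
            raise ValueError(f"unknown trajectory format {fmt!r}")

    @classmethod
    def load(cls, path) -> "TrajectoryRecord":
        path = Path(path)
        if path.is_dir():
            return cls.from_csv_dir(path)
        return cls.from_hdf5(path)

    # ------------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["metadata"] = json.dumps(self.metadata, sort_keys=True)
            g = f.create_group("series")
            for k, v in self.series.items():
                g.create_dataset(k, data=np.asarray(v, dtype=float))
            snaps = f.create_group("snapshots")
            for i, s in enumerate(self.snapshots):
                gi = snaps.create_group(f"{i:06d}")
                gi.attrs["t"] = s.t
                gi.attrs.update(_domain_meta(s.state.domain))
                gi.attrs["mt_radius"] = s.state.mt_radius
                gi.attrs["nf_radius"] = s.state.nf_radius
                gi.create_dataset("mt_pos", data=s.state.mt_pos)
                gi.create_dataset("nf_pos", data=s.state.nf_pos)
                gi.create_dataset("org", data=_org_table(s.state))
                gi.create_dataset("nf_bond", data=s.bonds.nf_bond)
                po, pm = s.bonds.org_pairs()
                gi.create_dataset("org_pairs",
                                  data=np.stack([po, pm], axis=1)
                                  if len(po) else np.empty((0, 2), dtype=np.int64))

    @classmethod
    def from_hdf5(cls, path) -> "TrajectoryRecord":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["metadata"])
            series = {k: list(np.asarray(v)) for k, v in f["series"].items()}
            snapshots = []
            for key in sorted(f["snapshots"]):
                gi = f["snapshots"][key]
                state = ParticleState(
                    np.asarray(gi["mt_pos"]), np.asarray(gi["nf_pos"]),
                    _domain_from_meta(dict(gi.attrs)),
                    float(gi.attrs["mt_radius"]), float(gi.attrs["nf_radius"]),
                    _orgs_from_table(np.asarray(gi["org"])))
                bonds = BondSet(state.n_nf, state.n_org)
                bonds.nf_bond[:] = np.asarray(gi["nf_bond"])
                for o, m in np.asarray(gi["org_pairs"], dtype=np.int64):
                    bonds.org_bonds[int(o)].add(int(m))
                snapshots.append(Snapshot(float(gi.attrs["t"]), state, bonds))
        return cls(meta, snapshots, series)

    # ------------------------------------------------------------------
    def to_csv_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "metadata.json").write_text(
            json.dumps(self.metadata, sort_keys=True, indent=1))
        self.series_frame().to_csv(path / "series.csv", index=False,
                                   float_format="%.17g")
        rows, brows = [], []
        for i, s in enumerate(self.snapshots):
            dm = _domain_meta(s.state.domain)
            for j, p in enumerate(s.state.mt_pos):
                rows.append((i, s.t, "MT", j, p[0], p[1], s.state.mt_radius,
                             np.nan, np.nan, np.nan, dm["domain_kind"],
                             dm["domain_size"]))
            for j, p in enumerate(s.state.nf_pos):
                rows.append((i, s.t, "NF", j, p[0], p[1], s.state.nf_radius,
                             np.nan, np.nan, np.nan, dm["domain_kind"],
                             dm["domain_size"]))
            for j, o in enumerate(s.state.organelles):
                rows.append((i, s.t, "ORG", j, o.center[0], o.center[1],
                             o.radius, o.z, o.a, o.b, dm["domain_kind"],
                             dm["domain_size"]))
            for j, m in enumerate(s.bonds.nf_bond):
                if m >= 0:
                    brows.append((i, "NF", j, int(m)))
            po, pm = s.bonds.org_pairs()
            for o, m in zip(po, pm):
                brows.append((i, "ORG", int(o), int(m)))
        cols = ["frame", "t", "kind", "index", "x", "y", "radius",
                "z", "a", "b", "domain_kind", "domain_size"]
        pd.DataFrame(rows, columns=cols).to_csv(path / "snapshots.csv",
                                                index=False,
                                                float_format="%.17g")
        pd.DataFrame(brows, columns=["frame", "kind", "cargo", "mt"]).to_csv(
            path / "bonds.csv", index=False)

    @classmethod
    def from_csv_dir(cls, path) -> "TrajectoryRecord":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        series = pd.read_csv(path / "series.csv",
                             float_precision="round_trip").to_dict(orient="list")
        snaps_df = pd.read_csv(path / "snapshots.csv",
                               float_precision="round_trip")
        bonds_df = pd.read_csv(path / "bonds.csv")
        snapshots = []
        if len(snaps_df):
            for i, grp in snaps_df.groupby("frame"):
                mt = grp[grp.kind == "MT"].sort_values("index")
                nf = grp[grp.kind == "NF"].sort_values("index")
                og = grp[grp.kind == "ORG"].sort_values("index")
                domain = _domain_from_meta({
                    "domain_kind": grp.domain_kind.iloc[0],
                    "domain_size": grp.domain_size.iloc[0]})
                orgs = [OrganelleInstance(np.array([r.x, r.y]), r.z, r.a, r.b)
                        for r in og.itertuples()]
                mt_r = mt.radius.iloc[0] if len(mt) else 12.5
                nf_r = nf.radius.iloc[0] if len(nf) else 5.0
                state = ParticleState(mt[["x", "y"]].to_numpy(),
                                      nf[["x", "y"]].to_numpy(),
                                      domain, mt_r, nf_r, orgs)
                bonds = BondSet(state.n_nf, state.n_org)
                bsel = bonds_df[bonds_df.frame == i]
                for r in bsel[bsel.kind == "NF"].itertuples():
                    bonds.nf_bond[int(r.cargo)] = int(r.mt)
                for r in bsel[bsel.kind == "ORG"].itertuples():
                    bonds.org_bonds[int(r.cargo)].add(int(r.mt))
                snapshots.append(Snapshot(float(grp.t.iloc[0]), state, bonds))
        return cls(meta, snapshots, series)


def _org_table(state: ParticleState) -> np.ndarray:
    return np.array([[o.center[0], o.center[1], o.z, o.a, o.b, o.entry_time]
                     for o in state.organelles]).reshape(-1, 6)


def _orgs_from_table(tab: np.ndarray) -> list[OrganelleInstance]:
    return [OrganelleInstance(row[:2].copy(), row[2], row[3], row[4], row[5])
            for row in tab]


def _domain_meta(domain: Domain) -> dict:
    if domain.periodic:
        return {"domain_kind": "periodic", "domain_size": domain.side}
    return {"domain_kind": "disk", "domain_size": domain.radius}


def _domain_from_meta(meta: dict) -> Domain:
    if meta["domain_kind"] == "periodic":
        return PeriodicBox(float(meta["domain_size"]))
    return DiskDomain(float(meta["domain_size"]))
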