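import numpy as np
import pytest
from hypothesis import settings

import axonsim as ax

settings.register_profile("fixed", derandomize=True)
settings.load_profile("fixed")


@pytest.fixture
def params() -> ax.ModelParams:
    return ax.ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_disk_state(rng, n_mt=10, n_nf=35, n_org=2, R0=1000.0,
                      params=None, org_z=None):
    """Random overlap-free disk configuration for oracle comparisons."""
    p = params or ax.ModelParams()
    placed = []  # (xy, radius)
    zs = (np.asarray(org_z, dtype=float) if org_z is not None
          else rng.uniform(-p.org_a * 0.9, p.org_a * 0.9, n_org))
    radii = [p.r_M] * n_mt + [p.r_N] * n_nf + [
        max(0.0, p.org_b * (1 - (z / p.org_a) ** 2)) for z in zs]
    for r in radii:
        for _ in range(10000):
            x = rng.uniform(-R0 + r + 1, R0 - r - 1, 2)
            if np.hypot(*x) + r >= R0 - 1.0:
                continue
            if all(np.hypot(*(x - q)) - r - rq > 1.0 for q, rq in placed):
                placed.append((x, r))
                break
        else:
            raise RuntimeError("could not place particle")
    pts = np.array([q for q, _ in placed])
    orgs = [ax.OrganelleInstance(pts[n_mt + n_nf + k], zs[k], p.org_a, p.org_b)
            for k in range(n_org)]
    state = ax.ParticleState(pts[:n_mt], pts[n_mt:n_mt + n_nf],
                             ax.DiskDomain(R0), p.r_M, p.r_N, orgs)
    bonds = ax.BondSet(n_nf, n_org)
    # a few NF and organelle bonds
    for i in rng.choice(n_nf, size=min(5, n_nf), replace=False):
        bonds.nf_bond[i] = rng.integers(n_mt)
    for k in range(n_org):
        for m in rng.choice(n_mt, size=min(3, n_mt), replace=False):
            bonds.org_bonds[k].add(int(m))
    return state, bonds
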