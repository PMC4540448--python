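# axonsim

Stochastic Brownian-dynamics model of microtubule–neurofilament
organization in axonal cross-sections.

## The problem

In healthy axons, microtubules (MTs) and neurofilaments (NFs) are
interspersed across the cross-section. In many toxic neuropathies (IDPN,
2,5-hexanedione) and neurodegenerative diseases, the two polymer systems
*segregate*: microtubules and membranous organelles cluster centrally while
neurofilaments are displaced to the periphery — a reorganization that
precedes neurofilament accumulation and axonal swelling. `axonsim`
implements a particle-based model of the cross-section that explains this
segregation as an emergent consequence of selectively impairing
neurofilament transport, and provides the morphometric statistics used to
quantify it. It is intended for computational cell biologists and
biophysicists studying axonal transport and cytoskeletal organization.

## The model

MTs, NFs and transiting organelles are rigid disks in a 2D domain (a disk
of radius R₀, or a periodic box for boundary-free NF studies) obeying
overdamped Langevin dynamics,

    dx_i = (F_i / μ_k) dt + √(2 D_k) dW_i,      D_k = kT / μ_k,

integrated with the explicit Euler–Maruyama scheme. The force F_i sums

* soft excluded-volume repulsion −ε(L_r/d − 1) ê on each surface gap
  d ≤ L_r (diverging at contact; ε doubled for organelles pushing into the
  plane, a hydrodynamic heuristic),
* motor-spring attraction κ d ê between a cargo and each microtubule it is
  engaged with (gap up to the capture radius R_b), and
* the same soft repulsion from the axonal membrane.

Discrete stochastic events model axonal transport through the plane: NFs
bind/unbind MTs (k_on^N, k_off^N), bound NFs depart and are replaced next
to an NF-adjacent microtubule (k_out^N, conserving NF number); organelles
arrive on random tracks (k_in^O), cross at speed s^O with cross-sectional
radius b(1 − z²/a²), and engage up to m_max microtubules at once
(k_on^O, k_off^O) — the "zippering" that pulls microtubules together.
All parameters default to measured values (see `axonsim.ModelParams`).

Key statistics: the radial distribution function g(r), the occupancy
probability distribution p_n with its Gaussian fit, and the mean pairwise
distance between microtubules (PDMT) — the segregation order parameter.

See `docs/methods.md` for the full model description, numerical policies
and the desk-scale problem sizes used by the tests.

## Worked example

Simulate two minutes of a normal axon (56 MTs, 361 NFs, organelle traffic
in a 1 μm disk) and inspect the summary series:

```python
import axonsim as ax
from axonsim.scenarios import preset, simulate

spec = preset("control").replace(end_time=120.0, randomize_duration=30.0)
rec = simulate(spec, seed=1)
print(rec.series_frame())
```

prints

```
       t   pdmt_mean  n_org  nf_bound_frac
0    0.0  935.840330      0       0.000000
1   60.0  930.170204      0       0.022161
2  120.0  921.158199      0       0.022161
```

`pdmt_mean` is the mean pairwise MT distance in nm (≈ 0.93·R₀ for the
freshly randomized pattern; over the first 1–2 simulated hours of normal
transport it settles to its working value ≈ 0.84·R₀), `n_org` the number
of organelles currently crossing the plane, and `nf_bound_frac` the
fraction of neurofilaments engaged with a microtubule (~1–3%, the product
of the ≈13% duty ratio of in-range filaments and the fraction of filaments
within the capture radius).

The disease protocol is a preset: `preset("reversible_segregation")` blocks
NF–MT binding between t = 1 h and t = 13 h and shows segregation (mean PDMT
dropping by ~40%) followed by remixing. From the shell:

```bash
axonsim presets                                   # list protocols
axonsim -v run --preset reversible_segregation --seed 1 --out runs/
axonsim stats pdmt runs/reversible_segregation_seed1.h5
axonsim stats opd  runs/nf_only_400_seed0.h5 --t-min 25 --t-max 30
axonsim plot runs/reversible_segregation_seed1.h5 --frame -1
```

`run` writes the trajectory (HDF5 or a CSV directory), a per-minute summary
CSV, and — with `--seeds N` — the replicate mean±SD PDMT curve; `stats`
recomputes g(r), the OPD or the PDMT from stored snapshots. Runs are
bitwise reproducible for a given seed.

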