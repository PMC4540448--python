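# Methods

## The model

`axonsim` simulates the cross-sectional organization of the axonal
cytoskeleton. A fixed plane through an axon is modelled as a disk *D* of
radius R₀ (default 1 μm) containing three species of rigid disks:

* **microtubules** (MT), radius r^M = 12.5 nm — the transport tracks;
* **neurofilaments** (NF), radius r^N = 5 nm — space-filling polymers and
  cargoes of slow axonal transport;
* **membranous organelles** — cargoes of fast transport, modelled as rigid
  spindles of half-length a and maximum radius b that cross the plane at
  constant axial speed s^O. While crossing, an organelle appears in *D* as a
  disk of radius r^O(z) = b(1 − z²/a²), where z ∈ [−a, a] is the axial
  offset of its midpoint; it is removed exactly when z reaches +a.

Because microtubules and neurofilaments are long polymers aligned with the
axon, their longitudinal transport appears in the cross-section as discrete
arrival/departure events rather than in-plane motion; the axial dimension
enters only through organelle z and the cargo event schedule.

### Forces

All interactions are central forces on the surface gap
d = |xᵢ − xⱼ| − rᵢ − rⱼ:

* **Excluded volume**: soft repulsion of magnitude ε(L_r/d − 1) for
  0 < d ≤ L_r, zero beyond L_r, divergent at contact. It represents the
  entropic-brush repulsion of neurofilament sidearms and analogous
  polymer-coat effects; a single scale ε = 0.5 pN is used for every species
  pair and for the membrane (the measured value is for NF–NF; no other pair
  has a measured value, and a single scale is the minimal choice).
* **Motor springs**: a cargo engaged with a microtubule through motors is
  coupled by a zero-rest-length spring of stiffness κ (κ^N = 0.18 pN/nm for
  NF–MT, κ^O = 0.9 pN/nm for organelle–MT, the latter representing several
  motors). The spring acts for 0 ≤ d ≤ R_b (R_b = 80 nm, the motor capture
  radius) and exerts no force beyond R_b, although the engagement itself
  persists until a stochastic unbinding event.
* **Membrane**: the same soft repulsion against the rigid boundary of the
  disk, on the gap d_B = R₀ − |x| − r.
* **Hydrodynamic heuristic**: an organelle whose radius is growing (z < 0)
  pushes axoplasm ahead of itself; this is mimicked by doubling the
  repulsion prefactor of each pair that involves such an organelle (the
  factor is 2 per entering-organelle member, so the rare pair of two
  entering organelles is quadrupled — the doubling rule applied literally
  to both directed coefficients). No explicit fluid solver is used.

Overdamped Langevin dynamics govern every particle:
dxᵢ = (Fᵢ/μ_k) dt + √(2 D_k) dWᵢ, with drag coefficients μ^N = 73.5,
μ^M = 512, μ^O = 40.3 pN·s/μm and diffusion coefficients fixed by the
Einstein relation D = kT/μ at kT = 4.11×10⁻³ pN·μm (≈ 298 K), which
reproduces the measured values D_N = 5.59×10⁻⁵, D_M = 8.02×10⁻⁶,
D_O = 1.02×10⁻⁴ μm²/s to three significant figures.

### Stochastic cargo kinetics

All discrete events are Bernoulli-thinned at the kinetics step h: an event
of rate k fires with probability k·h (all rates ≤ 2 /s, so probabilities at
h = 1/50 s are ≤ 0.04; the thinning error is O(h²)).

* A free NF with at least one MT within R_b binds at rate k_on^N = 10⁻² /s
  to a uniformly chosen in-range MT; each NF engages at most one MT at a
  time (an in-range NF is bound ~13% of the time, so dual engagement would
  be a ~2% effect). A bound NF unbinds at k_off^N = 6.5×10⁻² /s or departs
  the plane at k_out^N = 0.1 /s; the two competing transitions are resolved
  with one uniform draw so at most one fires per step. Only bound (moving)
  filaments can depart.
* Departures conserve the NF count: the departing filament re-enters at
  surface distance R_b from a randomly chosen *eligible* MT — one already
  within R_b of another NF, since a filament can only enter the plane where
  filaments exist in the adjacent plane — at a rejection-sampled angle
  (≤100 attempts over MTs and angles; if no admissible site exists the
  departure is cancelled and the filament stays put). This eligibility rule
  is enforced in every scenario.
* Organelles arrive at rate k_in^O (default 0.105 /s), starting at z = −a
  with zero radius at surface distance R_b from a uniformly chosen MT, to
  which they are immediately engaged (transport requires a track). Entry
  sites must leave the organelle, at full radius b, at least one repulsion
  range L_r clear of the membrane: a rigid cross-section cannot pass a
  cargo on a membrane-hugging track, and admitting one wedges
  incompressible particles against the immovable wall (in practice this
  manifested as unresolvable contacts however small the time step). While
  present, an organelle binds additional in-range MTs at k_on^O = 2 /s and
  loses each engagement at k_off^O = 2 /s, subject to the optional cap
  m_max on simultaneous engagements ("zippering"); the cap is enforced at
  binding time by subsampling. The initial track bond is not privileged.
* Dwell time is exactly 2a/s^O (2.8 s for b = 140 nm, a/b = 10,
  s^O = 1 μm/s).

### Integration

Time advances in ticks of h_slow = 1/50 s. Each tick applies due schedule
events, fires the kinetics (with per-tick probabilities rate·h_slow), then
integrates the mechanics with the explicit Euler–Maruyama scheme — strong
order 1.0 here since the noise amplitudes are constant. With no organelle
present the tick is one mechanical step of h_slow; while any organelle is
present the tick is split into substeps of h_fast = 1/1600 s, because the
growth of an entering organelle (up to 2b·s^O/a ≈ 200 nm/s radially) makes
the repulsion terms stiff. A strict mode that fires kinetics before every
substep with probabilities rate·h_fast is available
(``kinetics_mode="step"``); at these rates the two modes differ only at
O(h²).

A proposed substep that would produce a non-positive surface gap anywhere
is rejected and re-attempted as two substeps of h/2, recursively. The floor
of this halving ladder is h_fast/65536 ≈ 10⁻⁸ s: while an organelle grows
through a crowd, microtubules yield at quasi-static gaps of order 1 nm
(drag-limited), and the low-drag organelle's explicit-Euler displacement at
such gaps exceeds the gap unless the local step is several orders of
magnitude below h_fast. At the floor, the thermal kick can exceed a
squeezed gap, so up to 20 fresh noise draws are attempted before the run
aborts with a diagnostic snapshot. Rejections are local and rare, so the
cost is negligible; an abort is an integration failure, never silently
ignored, and overlap in any accepted state is checked to be impossible
(the repulsion diverges at contact).

The pairwise force sum uses a Verlet pair list with an 80 nm skin, rebuilt
inside the kernel whenever any particle's accumulated displacement (plus
the worst-case growth of entering organelle radii, which is folded into the
list cutoff) could invalidate it; a pair absent from the list therefore
provably has a positive gap, so contact detection is exact. Correctness of
the kernel is pinned to an independently written pure-Python O(N²) oracle
(`axonsim.testing.brute_force_forces`) at machine precision.

All randomness — initial lattice thinning, kinetics, thermal noise,
placement rejection sampling — flows from a single seeded PCG64 stream in a
fixed order, so a run is bitwise reproducible from its seed and
configuration.

## Initial conditions

Particles are seeded on a hexagonal lattice (spacing chosen to fit the
requested count, sites thinned uniformly at random, species assigned to
sites uniformly at random) and then "randomized" by evolving with
repulsion, membrane force and Brownian motion only. The NF-only protocols
randomize for 25 s at h = 1/200 s in a 1 μm periodic box; the mixed disk
protocols randomize for up to 60 s with an early stop once the mean
pairwise MT distance drifts by less than 1% over 10 s.

The randomized pattern is *not* the dynamical steady state of the full
model: with transport switched on, organelle zippering transiently clusters
microtubules and NF turnover rearranges the rim, and over tens of minutes
the mean pairwise MT distance settles from the randomized value (≈0.9·R₀,
essentially the uniform-pattern value) toward the normal-axon working value
of ≈0.8·R₀. Protocols that compare normal and perturbed axons therefore
run one simulated hour of normal transport before applying a perturbation,
as in the reversible-segregation protocol (blockage at t = 1 h).

## Analysis statistics

* **PDMT** — all pairwise MT centre distances; the per-frame mean (reported
  in units of R₀) is the segregation order parameter. Centre distances are
  used: the alternative surface distance would shift the normal-axon mean
  by ~35 nm ≪ 0.8 μm.
* **RDF g(r)** — pair-distance histogram in 5 nm bins normalised by the
  expectation for a uniform pattern of the same density (exact
  minimum-image annulus normalisation in the periodic box; in the disk,
  reference particles are restricted to those ≥ r_max from the membrane so
  no edge correction is needed). For the NF-only protocols it is averaged
  over 50 frames between t = 25 s and 30 s.
* **OPD p_n** — occupancy histogram of randomly placed circular windows
  (default radius 60 nm, 2000 windows per frame; in the disk, windows are
  sampled wholly inside the membrane), with an unweighted least-squares fit
  of a Gaussian density to the normalised histogram. On uniform patterns
  the OPD is Poisson(ρπR_w²) and the fit recovers mean ≈ variance.

## Problem sizes used by the test suite and acceptance script

Long protocols are verified at sizes chosen once, as the package's own
desk-scale study conditions:

* Parameter self-consistency and force/kinetics properties run at full
  fidelity (they are cheap).
* The normal-axon geometry check runs the full 56 MT + 361 NF disk with
  organelle traffic for 2 h of simulated normal transport per seed (3
  seeds) and averages the per-minute mean PDMT over the final 30 minutes;
  the first 1.5 h are discarded as settling (the mean PDMT relaxes from the
  randomized ≈0.9·R₀ to its working value with fluctuations whose
  correlation time is tens of minutes).
* The segregation-trend check runs a half-scale domain, R₀ = 0.5 μm, with
  counts from the same areal densities (n^M = floor(18πR₀²) = 14,
  n^N = floor(115πR₀²) = 90) and organelle flux scaled with
  cross-sectional area (k_in^O = 0.105·R₀²/μm² ≈ 0.026 /s) so that traffic
  *per unit area* — and hence the balance between neurofilament transport
  and organelle zippering — matches the full-scale model; organelle size
  stays at the default b = 140 nm. Each arm (transport blocked; control;
  blocked with m_max = 1) settles for 1 h under normal transport and is
  then followed for 2 h; the trend is assessed by Spearman rank correlation
  of the 10-minute means of the PDMT (12 points, seed-averaged). Blocking
  neurofilament transport must produce a segregation-scale decline — a
  significant negative trend *and* a drop of more than 10% over the window —
  while the control and the m_max = 1 arm must not: slow percent-level
  relaxation drifts (the m_max = 1 pattern stays near the randomized level,
  well above even the normal working value, because neither zippering nor
  neurofilament turnover compacts it) are not segregation.

What the scaled conditions do *not* probe: full-scale cluster coalescence
(fewer, relatively larger organelles per domain make segregation less
gradual than in the 1 μm domain) and multi-hour completeness of
segregation or remixing, which need the full 12 h+ protocols
(`axonsim run --preset reversible_segregation`).

## Known limitations

* The 2D cross-section carries no information along the axon: longitudinal
  accumulation, swelling and gradients are out of scope by design.
* Hydrodynamics is reduced to the ε-doubling heuristic for entering
  organelles; the boundary force of the organelle itself is not doubled
  (the rule is applied only to the pair coefficients, as stated).
* Organelles are rigid; a real vesicle would deform instead of wedging
  particles against the membrane, which is approximated here by the
  entry-site admissibility rule rather than by deformation.
* Bernoulli thinning slightly distorts event statistics at O(h²); the
  stationary two-state occupancies are exact by construction (simultaneous
  update against the start-of-step state).
* The Gaussian OPD fit is an unweighted least-squares fit to the histogram;
  for very sparse histograms it falls back to the sample mean/SD.
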