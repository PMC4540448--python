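import numpy as np
import pytest

import axonsim as ax
from axonsim import kinetics

P = ax.ModelParams()
DISK = ax.DiskDomain(1000.0)


def pair_state(gap=50.0):
    """One MT and one NF at a given surface gap in a large disk."""
    sep = gap + P.r_M + P.r_N
    state = ax.ParticleState([[0.0, 0.0]], [[sep, 0.0]], DISK, P.r_M, P.r_N)
    return state, ax.BondSet(1, 0)


class TestNFBinding:
    def test_zero_on_rate_never_binds(self, rng):
        state, bonds = pair_state()
        p = P.copy(k_on_N=0.0)
        for _ in range(2000):
            kinetics.nf_binding_step(state, bonds, p, p.h_slow, rng)
        assert bonds.nf_bond[0] == -1

    def test_out_of_range_cannot_bind(self, rng):
        state, bonds = pair_state(gap=81.0)   # just beyond R_b = 80
        p = P.copy(k_on_N=1e6)  # would bind instantly if allowed
        kinetics.nf_binding_step(state, bonds, p, 1e-7, rng)
        assert bonds.nf_bond[0] == -1

    def test_empirical_rates_match_bernoulli_thinning(self, rng):
        """Per-step transition frequencies converge to rate·h (within a
        3-sigma binomial interval)."""
        h = P.h_slow
        n_trials = 40000
        state, bonds = pair_state()
        on = off = out = 0
        n_on_trials = n_off_trials = 0
        for _ in range(n_trials):
            was = bonds.nf_bond[0]
            deps = kinetics.nf_binding_step(state, bonds, P, h, rng)
            if was < 0:
                n_on_trials += 1
                on += bonds.nf_bond[0] >= 0
            else:
                n_off_trials += 1
                off += bonds.nf_bond[0] < 0
                out += len(deps)
            if deps:            # departure candidate: reset bond
                bonds.nf_bond[0] = -1
        for count, trials, rate in ((on, n_on_trials, P.k_on_N),
                                    (off, n_off_trials, P.k_off_N),
                                    (out, n_off_trials, P.k_out_N)):
            pexp = rate * h
            se = np.sqrt(pexp * (1 - pexp) * trials)
            assert abs(count - pexp * trials) < 3 * se + 1

    def test_two_state_occupancy_fraction(self, rng):
        """With departure disabled, the long-run bound fraction of an
        in-range NF approaches k_on/(k_on+k_off) = 1/7.5 ≈ 0.13."""
        p = P.copy(k_out_N=0.0)
        h = 0.5  # coarse steps are fine for occupancy accounting
        state, bonds = pair_state()
        bound = 0
        n = 120000
        for _ in range(n):
            kinetics.nf_binding_step(state, bonds, p, h, rng)
            bound += bonds.nf_bond[0] >= 0
        frac = bound / n
        expected = p.k_on_N / (p.k_on_N + p.k_off_N)
        assert frac == pytest.approx(expected, abs=0.015)


class TestNFReplacement:
    def _three_particle_state(self):
        # MT0 with an NF neighbour (eligibility) plus a distant bound NF
        state = ax.ParticleState(
            [[0.0, 0.0]], [[60.0, 0.0], [400.0, 0.0]], DISK, P.r_M, P.r_N)
        bonds = ax.BondSet(2, 0)
        bonds.nf_bond[1] = 0
        return state, bonds

    def test_count_conserved_and_entrant_at_Rb(self, rng):
        state, bonds = self._three_particle_state()
        n_before = state.n_nf
        done = kinetics.nf_replace_departed(state, bonds, P, rng, [1])
        assert done == 1
        assert state.n_nf == n_before
        assert bonds.nf_bond[1] == -1  # entrant starts unbound
        gap = ax.surface_distance(state.nf_pos[1], P.r_N,
                                  state.mt_pos[0], P.r_M, DISK)
        assert gap == pytest.approx(P.R_b)

    def test_no_eligible_mt_cancels_departure(self, rng):
        # the only other NF is far outside R_b of the MT -> no eligible MT
        state = ax.ParticleState(
            [[0.0, 0.0]], [[500.0, 0.0], [300.0, 300.0]], DISK, P.r_M, P.r_N)
        bonds = ax.BondSet(2, 0)
        bonds.nf_bond[0] = 0
        pos_before = state.nf_pos.copy()
        done = kinetics.nf_replace_departed(state, bonds, P, rng, [0])
        assert done == 0
        assert bonds.nf_bond[0] == 0      # still bound: departure cancelled
        np.testing.assert_array_equal(state.nf_pos, pos_before)

    def test_departing_nf_does_not_self_certify(self, rng):
        # departing NF is the only one near the MT: without it the MT is
        # ineligible, so the departure must be cancelled
        state = ax.ParticleState(
            [[0.0, 0.0]], [[60.0, 0.0], [600.0, 600.0]], DISK, P.r_M, P.r_N)
        bonds = ax.BondSet(2, 0)
        bonds.nf_bond[0] = 0
        assert kinetics.nf_replace_departed(state, bonds, P, rng, [0]) == 0


class TestOrganelleArrival:
    def test_poisson_mean_of_arrivals(self, rng):
        """Expected arrivals in T seconds is k_in·T (Monte-Carlo check
        within 3 standard errors); dwell time is 2a/s_O = 2.8 s for the
        default geometry."""
        p = P.copy(org_b=140.0)
        assert 2 * p.org_a / p.s_O_nm == pytest.approx(2.8)
        state = ax.ParticleState([[0.0, 0.0]], np.empty((0, 2)), DISK,
                                 P.r_M, P.r_N)
        bonds = ax.BondSet(0, 0)
        h, n_steps = P.h_slow, 50 * 1000   # 1000 s
        arrivals = 0
        for _ in range(n_steps):
            if kinetics.organelle_arrival_step(state, bonds, p, h, rng):
                arrivals += 1
                state.organelles.clear()
                bonds.org_bonds.clear()
        lam = p.k_in_O * h * n_steps
        assert abs(arrivals - lam) < 3 * np.sqrt(lam)

    def test_no_mts_no_arrival(self, rng):
        state = ax.ParticleState(np.empty((0, 2)), np.empty((0, 2)), DISK)
        bonds = ax.BondSet(0, 0)
        p = P.copy(k_in_O=1e6)
        assert not kinetics.organelle_arrival_step(state, bonds, p, 1e-7, rng)
        assert state.n_org == 0

    def test_entrant_geometry_and_track_bond(self, rng):
        state = ax.ParticleState([[0.0, 0.0]], np.empty((0, 2)), DISK,
                                 P.r_M, P.r_N)
        bonds = ax.BondSet(0, 0)
        p = P.copy(k_in_O=1e6)
        assert kinetics.organelle_arrival_step(state, bonds, p, 1.0, rng)
        o = state.organelles[0]
        assert o.z == -p.org_a and o.radius == 0.0
        assert bonds.org_bonds[0] == {0}
        # placed at R_b from the track (entrant radius 0)
        d = np.hypot(*(o.center - state.mt_pos[0])) - P.r_M
        assert d == pytest.approx(P.R_b)

    def test_full_size_must_clear_membrane(self, rng):
        # single MT close to the membrane: no admissible entry site
        state = ax.ParticleState([[930.0, 0.0]], np.empty((0, 2)), DISK,
                                 P.r_M, P.r_N)
        bonds = ax.BondSet(0, 0)
        p = P.copy(k_in_O=1e6)
        assert not kinetics.organelle_arrival_step(state, bonds, p, 1.0, rng)


class TestOrganelleTransit:
    def test_advance_and_removal(self):
        p = P
        state = ax.ParticleState([[0.0, 0.0]], np.empty((0, 2)), DISK,
                                 P.r_M, P.r_N)
        state.organelles.append(
            ax.OrganelleInstance([300.0, 0.0], -p.org_a, p.org_a, p.org_b))
        bonds = ax.BondSet(0, 1)
        bonds.org_bonds[0].add(0)
        dwell = 2 * p.org_a / p.s_O_nm
        kinetics.organelle_advance(state, bonds, p, dwell / 2)
        assert state.organelles[0].z == pytest.approx(0.0)
        assert state.organelles[0].radius == pytest.approx(p.org_b)
        kinetics.organelle_advance(state, bonds, p, dwell / 2)
        assert state.n_org == 0 and bonds.org_bonds == []

    def test_advance_is_deterministic(self):
        p = P
        zs = []
        for _ in range(2):
            state = ax.ParticleState([[0.0, 0.0]], np.empty((0, 2)), DISK)
            state.organelles.append(
                ax.OrganelleInstance([300.0, 0.0], -p.org_a, p.org_a, p.org_b))
            bonds = ax.BondSet(0, 1)
            trace = []
            for _ in range(10):
                kinetics.organelle_advance(state, bonds, p, 0.1)
                trace.append(state.organelles[0].z)
            zs.append(trace)
        assert zs[0] == zs[1]


class TestOrganelleBinding:
    def _org_among_mts(self, n_mt, rng):
        th = np.linspace(0, 2 * np.pi, n_mt, endpoint=False)
        r = 200.0
        mts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        state = ax.ParticleState(mts, np.empty((0, 2)), DISK, P.r_M, P.r_N)
        state.organelles.append(
            ax.OrganelleInstance([0.0, 0.0], 0.0, P.org_a, P.org_b))
        bonds = ax.BondSet(0, 1)
        return state, bonds

    def test_m_max_cap_never_violated(self, rng):
        state, bonds = self._org_among_mts(8, rng)
        p = P.copy(k_on_O=50.0, m_max=1)
        for _ in range(500):
            kinetics.organelle_binding_step(state, bonds, p, p.h_slow, rng)
            assert len(bonds.org_bonds[0]) <= 1

    def test_uncapped_steady_state_is_half(self, rng):
        """k_on = k_off ⇒ each in-range pair is bound half the time."""
        state, bonds = self._org_among_mts(6, rng)
        h = 0.05
        tot = n = 0
        for i in range(30000):
            kinetics.organelle_binding_step(state, bonds, P, h, rng)
            if i > 500:
                tot += len(bonds.org_bonds[0])
                n += 1
        assert tot / (n * 6) == pytest.approx(0.5, abs=0.02)

    def test_engagement_reach(self):
        # an organelle at full size can reach MTs with centres within
        # b + r_M + R_b = 232.5 nm
        assert P.org_b + P.r_M + P.R_b == pytest.approx(232.5)

    def test_bondset_empties_without_sources(self, rng):
        """With binding switched off and no organelles, the engagement graph
        monotonically empties and then never changes."""
        sep = 50.0 + P.r_M + P.r_N
        state = ax.ParticleState([[0.0, 0.0]], [[sep, 0.0]], DISK,
                                 P.r_M, P.r_N)
        bonds = ax.BondSet(1, 0)
        bonds.nf_bond[0] = 0
        p = P.copy(k_on_N=0.0, k_in_O=0.0, k_out_N=0.0)
        sizes = []
        for _ in range(3000):
            kinetics.nf_binding_step(state, bonds, p, p.h_slow, rng)
            sizes.append(bonds.n_nf_bound)
        assert sorted(sizes, reverse=True) == sizes
        assert sizes[-1] == 0
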