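import numpy as np
import pytest
from scipy.integrate import solve_ivp

import axonsim as ax
from axonsim import integrator
from axonsim.testing import bonded_pair_equilibrium_gap, make_bonded_pair

P = ax.ModelParams()


def _gap(state):
    return (np.hypot(*(state.nf_pos[0] - state.mt_pos[0]))
            - state.mt_radius - state.nf_radius)


def _pair_gap_ode(gap0, t_end):
    """Independent reference for the deterministic relaxation of a bonded
    MT-NF pair: the gap obeys d' = -(1/μ_M + 1/μ_N)(κd - ε(L_r/d - 1))."""
    mob = 1.0 / P.drag(0) + 1.0 / P.drag(1)

    def rhs(t, d):
        spring = P.kappa_N * d[0] if d[0] <= P.R_b else 0.0
        rep = P.eps_r * (P.L_r / d[0] - 1.0) if d[0] < P.L_r else 0.0
        return [-mob * (spring - rep)]

    sol = solve_ivp(rhs, (0, t_end), [gap0], rtol=1e-10, atol=1e-12)
    return sol.y[0, -1]


class TestEmStep:
    def test_pure_drift_displacement_is_exact(self):
        """With the noise zeroed, one step moves each particle exactly
        (F/μ)·h."""
        fx = make_bonded_pair(40.0)
        acc = ax.total_forces(fx.state, fx.bonds, P)
        before_mt = fx.state.mt_pos.copy()
        before_nf = fx.state.nf_pos.copy()
        h = P.h_slow
        zeros = np.zeros((fx.state.n_total, 2))
        ax.em_step(fx.state, fx.bonds, P, h, rng=None, normals=zeros)
        np.testing.assert_allclose(
            fx.state.mt_pos - before_mt, acc.mt / P.drag(0) * h, atol=1e-12)
        np.testing.assert_allclose(
            fx.state.nf_pos - before_nf, acc.nf / P.drag(1) * h, atol=1e-12)

    def test_bonded_pair_relaxes_to_equilibrium_gap(self):
        """Noise-free integration from a 60 nm gap converges monotonically to
        d* ≈ 17.0 nm and tracks an independent ODE solution."""
        fx = make_bonded_pair(60.0)
        zeros = np.zeros((2, 2))
        gaps = [_gap(fx.state)]
        h = P.h_slow
        for _ in range(3000):
            ax.em_step(fx.state, fx.bonds, P, h, rng=None, normals=zeros)
            gaps.append(_gap(fx.state))
        gaps = np.array(gaps)
        assert np.all(np.diff(gaps) <= 1e-12)
        d_star = bonded_pair_equilibrium_gap(P.kappa_N, P.eps_r, P.L_r)
        assert gaps[-1] == pytest.approx(d_star, abs=0.05)
        assert gaps[-1] == pytest.approx(_pair_gap_ode(60.0, 3000 * h),
                                         rel=1e-3)

    def test_halving_h_halves_drift_error(self):
        """First-order (Richardson) behaviour of the deterministic part on a
        stiff bonded pair."""
        t_end = 2.0
        ref = _pair_gap_ode(60.0, t_end)
        errs = []
        for h in (0.02, 0.01):
            fx = make_bonded_pair(60.0)
            zeros = np.zeros((2, 2))
            for _ in range(int(round(t_end / h))):
                ax.em_step(fx.state, fx.bonds, P, h, rng=None, normals=zeros)
            errs.append(abs(_gap(fx.state) - ref))
        ratio = errs[0] / errs[1]
        assert 1.6 < ratio < 2.4

    def test_free_diffusion_msd(self, rng):
        """Mean squared displacement of force-free particles grows as 4Dτ
        (within 3 standard errors over ≥1000 trajectories)."""
        n = 1200
        side = 2.0e6
        # spread far apart in a huge periodic box: no interactions
        grid = np.stack(np.meshgrid(np.arange(40), np.arange(30)),
                        axis=-1).reshape(-1, 2)[:n] * 5.0e4 + 1.0e4
        state = ax.ParticleState(np.empty((0, 2)), grid.astype(float),
                                 ax.PeriodicBox(side), P.r_M, P.r_N)
        bonds = ax.BondSet(n, 0)
        h, n_steps = P.h_slow, 150
        start = state.nf_pos.copy()
        for _ in range(n_steps):
            ax.em_step(state, bonds, P, h, rng)
        disp = state.nf_pos - start
        msd = np.mean(np.sum(disp**2, axis=1))
        tau = n_steps * h
        expected = 4.0 * P.diffusion(1) * tau
        se = np.std(np.sum(disp**2, axis=1)) / np.sqrt(n)
        assert abs(msd - expected) < 3 * se


def tiny_spec(**kw):
    from axonsim.scenarios import ScenarioSpec
    base = dict(name="tiny", domain_kind="disk", domain_size=500.0,
                n_mt=5, n_nf=20,
                params=ax.ModelParams(org_b=70.0, k_in_O=0.5),
                end_time=20.0, snapshot_every=5.0, series_every=5.0,
                randomize_duration=5.0)
    base.update(kw)
    return ScenarioSpec(**base)


class TestRun:
    def test_zero_duration_returns_initial_snapshot_only(self, rng):
        from axonsim.scenarios import make_initial
        spec = tiny_spec(end_time=0.0)
        state = make_initial(spec, rng)
        rec = integrator.run(state, ax.BondSet.empty_for(state), spec.params,
                             0.0, rng=rng)
        assert len(rec.snapshots) == 1
        assert rec.snapshots[0].t == 0.0

    def test_bitwise_reproducibility(self):
        """Identical seed and configuration give bitwise identical
        trajectories, including cargo arrivals and departures."""
        from axonsim.scenarios import simulate
        rec1 = simulate(tiny_spec(), seed=7)
        rec2 = simulate(tiny_spec(), seed=7)
        assert rec1.series["pdmt_mean"] == rec2.series["pdmt_mean"]
        for s1, s2 in zip(rec1.snapshots, rec2.snapshots):
            np.testing.assert_array_equal(s1.state.mt_pos, s2.state.mt_pos)
            np.testing.assert_array_equal(s1.state.nf_pos, s2.state.nf_pos)
            np.testing.assert_array_equal(s1.bonds.nf_bond, s2.bonds.nf_bond)
            assert [o.z for o in s1.state.organelles] == \
                [o.z for o in s2.state.organelles]

    def test_different_seeds_diverge(self):
        from axonsim.scenarios import simulate
        rec1 = simulate(tiny_spec(), seed=7)
        rec2 = simulate(tiny_spec(), seed=8)
        assert not np.array_equal(rec1.snapshots[-1].state.nf_pos,
                                  rec2.snapshots[-1].state.nf_pos)

    def test_step_size_policy(self, rng):
        """h = h_slow with no organelle present; h = h_fast otherwise (the
        step counter reflects the 32 substeps per tick)."""
        from axonsim.scenarios import make_initial
        spec = tiny_spec(params=ax.ModelParams(org_b=70.0, k_in_O=0.0))
        state = make_initial(spec, 3)
        rec = integrator.run(state, ax.BondSet.empty_for(state), spec.params,
                             2.0, rng=rng)
        assert rec.metadata["n_steps"] == round(2.0 / spec.params.h_slow)

        # a lone organelle crossing an otherwise empty disk forces h_fast
        state = ax.ParticleState(np.empty((0, 2)), np.empty((0, 2)),
                                 ax.DiskDomain(500.0))
        state.organelles.append(ax.OrganelleInstance(
            [0.0, 0.0], -spec.params.org_a, spec.params.org_a, 70.0))
        bonds = ax.BondSet.empty_for(state)
        rec = integrator.run(state, bonds, spec.params, 1.0, rng=rng,
                             kinetics_enabled=False)
        assert rec.metadata["n_steps"] == round(1.0 / spec.params.h_fast)

    def test_particles_stay_in_domain_and_nonoverlapping(self):
        from axonsim.scenarios import simulate
        rec = simulate(tiny_spec(), seed=3)
        final = rec.snapshots[-1]
        final.state.check_no_overlap()

    def test_nf_count_conserved(self):
        from axonsim.scenarios import simulate
        rec = simulate(tiny_spec(), seed=5)
        assert all(s.state.n_nf == rec.snapshots[0].state.n_nf
                   for s in rec.snapshots)

    def test_schedule_applies_parameter_change(self):
        """Blocking the NF on-rate mid-run stops new engagements."""
        from axonsim.scenarios import simulate
        spec = tiny_spec(
            params=ax.ModelParams(org_b=70.0, k_in_O=0.0, k_on_N=50.0,
                                  k_off_N=1e-9, k_out_N=1e-9, R_b=150.0),
            schedule=ax.EventSchedule([(10.0, "k_on_N", 0.0),
                                       (10.0, "k_off_N", 50.0)]),
            end_time=20.0, series_every=1.0)
        rec = simulate(spec, seed=2)
        frac = np.asarray(rec.series["nf_bound_frac"])
        t = np.asarray(rec.series["t"])
        # every in-range NF binds quickly and stays bound before the switch
        assert frac[(t > 5) & (t <= 10)].min() > 0.1
        # the switch zeroes the on-rate and makes unbinding instantaneous
        assert frac[t > 12].max() == 0.0
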