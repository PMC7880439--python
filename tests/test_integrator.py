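"""Brownian dynamics propagation: diffusion oracles, equipartition,
determinism, and step-size robustness."""

import numpy as np
import pytest
from scipy import stats

import cryofil as cf
from cryofil.constants import kt_at
from cryofil.environment import CoolingSchedule, ThermalProtocol, mobilities
from cryofil.integrator import BDConfig, bd_step, run, sample_equilibrium_init

ISO_295 = ThermalProtocol(CoolingSchedule(T0=295.15, rate_v=0.0, T_stop=226.1),
                          cf.PLUNGE_LAW)


def _free_particle_params(n):
    # vanishing potentials: every free monomer is an independent walker
    return cf.FilamentParams(n_monomers=n, radius=2.0, bend_stiffness_b=1e-300,
                             theta0=0.0, bond_stiffness_k=1e-300, n_fixed=1)


@pytest.fixture(scope="module")
def walkers():
    p = _free_particle_params(201)
    dt = 1e-4
    n_steps = 1000
    cfg_proto = dict(dt_policy=dt, max_steps=n_steps, record_every=0)
    disp2, dth2 = [], []
    for seed in range(50):
        st = cf.straight_state(p)
        traj = run(st, p, ISO_295, BDConfig(seed=seed, **cfg_proto))
        f = traj.final_state
        disp2.append((f.x[1:] - st.x[1:]) ** 2 + (f.y[1:] - st.y[1:]) ** 2)
        dth2.append((f.theta[1:] - st.theta[1:]) ** 2)
    t = dt * n_steps
    return np.concatenate(disp2), np.concatenate(dth2), t


class TestFreeDiffusion:
    """Einstein-relation oracles for the noise amplitudes."""

    def test_planar_msd_matches_4dt(self, walkers):
        disp2, _, t = walkers
        D = mobilities(cf.PLUNGE_LAW, 295.15, 2.0)["D_t"]
        msd = disp2.mean()
        se = disp2.std(ddof=1) / np.sqrt(disp2.size)
        assert abs(msd - 4 * D * t) < 3 * se
        assert msd == pytest.approx(4 * D * t, rel=0.05)

    def test_angular_variance_matches_2drt(self, walkers):
        _, dth2, t = walkers
        Dr = mobilities(cf.PLUNGE_LAW, 295.15, 2.0)["D_r"]
        se = dth2.std(ddof=1) / np.sqrt(dth2.size)
        assert abs(dth2.mean() - 2 * Dr * t) < 3 * se


class TestBDStep:
    def test_zero_temperature_ground_state_is_fixed_point(self, small_params, rng):
        st = cf.relaxed_state(small_params)
        new = bd_step(st, small_params, 295.15, 1e-3, 1e-5, rng, noise_scale=0.0)
        np.testing.assert_allclose(new.x, st.x, atol=1e-12)
        np.testing.assert_allclose(new.y, st.y, atol=1e-12)
        np.testing.assert_allclose(new.theta, st.theta, atol=1e-12)

    def test_unstable_step_raises(self, small_params, rng):
        st = cf.straight_state(small_params)
        st.x[-1] += 1.0
        with pytest.raises(FloatingPointError, match="time step"):
            s = st
            for _ in range(200):
                s = bd_step(s, small_params, 295.15, 1e-3, 5.0, rng)

    def test_clamped_monomers_never_move(self, small_params, rng):
        st = cf.straight_state(small_params)
        s = st
        for _ in range(50):
            s = bd_step(s, small_params, 295.15, 1e-3, 1e-5, rng)
        nf = small_params.n_fixed
        np.testing.assert_array_equal(s.x[:nf], st.x[:nf])
        np.testing.assert_array_equal(s.theta[:nf], st.theta[:nf])


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = cf.FLOPPY_PF
        cfg = BDConfig(seed=42, max_steps=20_000, record_every=5000)
        out = []
        for _ in range(2):
            traj = run(cf.straight_state(p), p, ISO_295, cfg)
            out.append(traj)
        a, b = out
        np.testing.assert_array_equal(a.final_state.x, b.final_state.x)
        np.testing.assert_array_equal(a.final_state.theta, b.final_state.theta)
        assert len(a.states) == len(b.states)
        for sa, sb in zip(a.states, b.states):
            np.testing.assert_array_equal(sa.x, sb.x)

    def test_different_seed_differs(self):
        p = cf.FLOPPY_PF
        t1 = run(cf.straight_state(p), p, ISO_295, BDConfig(seed=1, max_steps=5000))
        t2 = run(cf.straight_state(p), p, ISO_295, BDConfig(seed=2, max_steps=5000))
        assert not np.array_equal(t1.final_state.x, t2.final_state.x)

    def test_clamp_bit_identical_across_trajectory(self):
        p = cf.FLOPPY_PF
        st = cf.straight_state(p)
        traj = run(st, p, ISO_295, BDConfig(seed=9, max_steps=30_000,
                                            record_every=3000))
        for s in traj.states + [traj.final_state]:
            np.testing.assert_array_equal(s.x[:p.n_fixed], st.x[:p.n_fixed])
            np.testing.assert_array_equal(s.y[:p.n_fixed], st.y[:p.n_fixed])


def _equilibrium_samples(scheme, safety, n_reps, t_end=4.0, burn=1.0):
    """Decorrelated joint angles and squared bond extensions of a short
    floppy chain equilibrated isothermally at 295.15 K."""
    p = cf.FilamentParams(n_monomers=6, radius=2.0, bend_stiffness_b=58.0,
                          theta0=0.2, bond_stiffness_k=100.0, n_fixed=2)
    angles, bond2 = [], []
    for seed in range(n_reps):
        cfg = BDConfig(seed=seed, scheme=scheme, safety=safety,
                       max_time=t_end, record_every=8000,
                       max_recorded_states=512)
        rng = np.random.default_rng(seed)
        st = sample_equilibrium_init(p, 295.15, rng)
        traj = run(st, p, ISO_295, cfg)
        for s in traj.states:
            if s.time < burn:
                continue
            angles.extend(np.diff(s.theta)[p.n_fixed - 1:])
            plus, minus = cf.interaction_sites(s, p)
            d = plus[:-1] - minus[1:]
            bond2.extend(np.sum(d * d, axis=1)[p.n_fixed - 1:])
    return p, np.asarray(angles), np.asarray(bond2)


@pytest.fixture(scope="module")
def lm_samples():
    return _equilibrium_samples("lm", 0.1, n_reps=36)


class TestEquipartition:
    """Boltzmann statistics of the harmonic modes at the default time step."""

    def test_joint_angle_variance(self, lm_samples):
        p, angles, _ = lm_samples
        expected = kt_at(295.15) / p.bend_stiffness_b
        assert np.var(angles) == pytest.approx(expected, rel=0.05)

    def test_joint_angle_mean_is_theta0(self, lm_samples):
        p, angles, _ = lm_samples
        se = angles.std(ddof=1) / np.sqrt(angles.size)
        assert abs(angles.mean() - p.theta0) < 4 * se

    def test_bond_extension_mean_square(self, lm_samples):
        p, _, bond2 = lm_samples
        expected = 2.0 * kt_at(295.15) / p.bond_stiffness_k
        assert bond2.mean() == pytest.approx(expected, rel=0.05)

    def test_joint_angle_marginal_is_gaussian(self, lm_samples):
        p, angles, _ = lm_samples
        sigma = np.sqrt(kt_at(295.15) / p.bend_stiffness_b)
        n = min(angles.size, 10_000)
        ks = stats.kstest(angles[:n], "norm", args=(p.theta0, sigma))
        assert ks.pvalue > 0.01

    def test_euler_agrees_at_reduced_step(self):
        # Euler's O(dt) variance bias forces a smaller step for the same bands
        p, angles, bond2 = _equilibrium_samples("euler", 0.02, n_reps=16)
        assert np.var(angles) == pytest.approx(
            kt_at(295.15) / p.bend_stiffness_b, rel=0.05)
        assert bond2.mean() == pytest.approx(
            2.0 * kt_at(295.15) / p.bond_stiffness_k, rel=0.07)


class TestViscosityTimeRescaling:
    def test_noise_free_dynamics_rescale_exactly(self):
        p = cf.FLOPPY_PF
        st = cf.straight_state(p)
        st.x[-1] += 1.5  # out of equilibrium so there is deterministic drift
        law2 = cf.ViscosityLaw(eta0=2 * cf.PLUNGE_LAW.eta0, Ts=cf.PLUNGE_LAW.Ts,
                               gamma=cf.PLUNGE_LAW.gamma, label="doubled")
        proto2 = ThermalProtocol(ISO_295.schedule, law2)
        f1 = run(st, p, ISO_295, BDConfig(seed=0, dt_policy=1e-5,
                                          noise_scale=0.0, max_steps=2000)).final_state
        f2 = run(st, p, proto2, BDConfig(seed=0, dt_policy=2e-5,
                                         noise_scale=0.0, max_steps=2000)).final_state
        np.testing.assert_array_equal(f1.x, f2.x)
        np.testing.assert_array_equal(f1.theta, f2.theta)


class TestEquilibriumSampler:
    def test_mean_joint_angle(self):
        p = cf.FLOPPY_PF
        rng = np.random.default_rng(3)
        joints = []
        for _ in range(2000):
            st = sample_equilibrium_init(p, 295.15, rng)
            joints.extend(np.diff(st.theta)[p.n_fixed - 1:])
        joints = np.asarray(joints)
        se = joints.std(ddof=1) / np.sqrt(joints.size)
        assert abs(joints.mean() - p.theta0) < 3 * se

    def test_infinite_stiffness_limit_is_uniform_arc(self):
        p = cf.FLOPPY_PF.with_(bend_stiffness_b=1e14)
        rng = np.random.default_rng(0)
        st = sample_equilibrium_init(p, 295.15, rng)
        # every free joint sits at theta0 (the clamped dimer stays straight)
        np.testing.assert_allclose(np.diff(st.theta)[p.n_fixed - 1:],
                                   p.theta0, atol=1e-5)
        e = cf.total_energy(st, p)
        assert e.stretching == pytest.approx(0.0, abs=1e-12)

    def test_sampler_agrees_with_dynamics(self):
        """Persistence length from direct sampling vs BD equilibration."""
        p = cf.FilamentParams(n_monomers=8, radius=2.0, bend_stiffness_b=58.0,
                              theta0=0.0, bond_stiffness_k=100.0, n_fixed=1)
        rng = np.random.default_rng(7)
        sampled = [sample_equilibrium_init(p, 295.15, rng) for _ in range(600)]
        dyn = []
        for seed in range(64):
            st = sample_equilibrium_init(p, 295.15, rng)
            traj = run(st, p, ISO_295, BDConfig(seed=seed, max_time=3.0))
            dyn.append(traj.final_state)
        fit_s = cf.fit_persistence_length(cf.mean_cos_deflection(
            cf.TraceEnsemble.from_states(sampled, p.spacing)), 295.15)
        fit_d = cf.fit_persistence_length(cf.mean_cos_deflection(
            cf.TraceEnsemble.from_states(dyn, p.spacing)), 295.15)
        # joint confidence interval overlap (dynamics is the noisier one)
        joint = 3 * np.hypot(fit_s.P_se, fit_d.P_se)
        assert abs(fit_s.P_hat - fit_d.P_hat) < max(joint, 0.3 * fit_s.P_hat)


class TestStepSizeRobustness:
    def test_halving_dt_preserves_frozen_curvature_profile(self):
        spec = dict(species="floppy_pf", protocol="plunge_1e7",
                    n_replicates=12, init_mode="straight", base_seed=5)
        res_a = cf.freeze_experiment(cf.ExperimentSpec(**spec))
        res_b = cf.freeze_experiment(cf.ExperimentSpec(
            **spec, bd=BDConfig(safety=0.05)))
        pa, pb = res_a.profile, res_b.profile
        diff = pa.mean_curvature - pb.mean_curvature
        comb = np.hypot(pa.sem_curvature, pb.sem_curvature)
        assert np.all(np.abs(diff) < 3.5 * comb)

    def test_schedule_log_is_monotone(self):
        p = cf.FLOPPY_PF
        proto = ThermalProtocol(CoolingSchedule(295.15, 1e7, 226.1), cf.PLUNGE_LAW)
        traj = run(cf.straight_state(p), p, proto,
                   BDConfig(seed=0, record_every=50_000))
        log = traj.schedule_log
        assert np.all(np.diff(log[:, 0]) > 0)      # time strictly increasing
        assert np.all(np.diff(log[:, 1]) <= 0)     # T non-increasing
        assert np.all(np.diff(log[:, 2]) >= 0)     # eta non-decreasing
        assert traj.terminated_reason == "reached_T_stop"
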