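"""Curvature and persistence estimators against constructed-shape oracles."""

import numpy as np
import pytest

import cryofil as cf
from cryofil.analysis import (curvature_gradient, curvature_profile,
                              fit_persistence_length, mean_cos_deflection)
from cryofil.fixtures import make_fixture_traces


class TestCurvatureProfile:
    def test_straight_traces_have_zero_curvature(self):
        ens = make_fixture_traces("straight", n_points=16, n_traces=5)
        prof = curvature_profile(ens, segment_len=8.0)
        np.testing.assert_allclose(prof.mean_curvature, 0.0, atol=1e-10)

    def test_arc_has_uniform_known_curvature(self):
        # radius 28.65 nm -> 180/(pi*28.65) = 2.0 deg/nm in every bin
        ens = make_fixture_traces("arc", n_points=16, radius=28.65)
        prof = curvature_profile(ens, segment_len=8.0)
        np.testing.assert_allclose(prof.mean_curvature,
                                   np.degrees(1 / 28.65), rtol=1e-10)

    def test_linear_curvature_ramp_recovered(self):
        ens = make_fixture_traces("linear-curvature", n_points=24, spacing=4.0,
                                  kappa0=0.5, kappa_slope=0.03, n_traces=3)
        prof = curvature_profile(ens, segment_len=8.0)
        expected = 0.5 + 0.03 * prof.distance_from_tip
        np.testing.assert_allclose(prof.mean_curvature, expected, rtol=0.03)

    def test_short_traces_excluded_with_warning(self):
        long = make_fixture_traces("arc", n_points=16).traces[0]
        short = long[:4]
        ens = cf.TraceEnsemble([long, long, short], 4.0)
        with pytest.warns(UserWarning, match="excluded"):
            prof = curvature_profile(ens, segment_len=8.0)
        assert prof.n_excluded == 1

    def test_segment_length_must_span_two_spacings(self):
        ens = make_fixture_traces("arc", n_points=16)
        with pytest.raises(ValueError):
            curvature_profile(ens, segment_len=4.0)

    def test_rigid_body_invariance(self, rng):
        ens = make_fixture_traces("gaussian-chain", n_points=16, n_traces=20,
                                  sigma2=0.05, rng=rng)
        prof0 = curvature_profile(ens, 8.0)
        ang = 1.234
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = cf.TraceEnsemble([t @ R.T + [55.0, -12.0] for t in ens.traces],
                                 ens.spacing)
        prof1 = curvature_profile(moved, 8.0)
        np.testing.assert_allclose(prof1.mean_curvature, prof0.mean_curvature,
                                   rtol=1e-10)
        g0 = curvature_gradient(prof0)
        g1 = curvature_gradient(prof1)
        assert g1[0] == pytest.approx(g0[0], abs=1e-10)


class TestCurvatureGradient:
    def test_flat_profile_slope_zero_within_se(self, rng):
        ens = make_fixture_traces("arc", n_points=20, n_traces=40)
        # add small independent positional jitter so sems are non-degenerate
        jitter = cf.TraceEnsemble(
            [t + rng.normal(0, 0.01, t.shape) for t in ens.traces], ens.spacing)
        slope, se = curvature_gradient(curvature_profile(jitter, 8.0))
        assert abs(slope) < 2 * se

    def test_constructed_slope_magnitude_recovered(self):
        ens = make_fixture_traces("linear-curvature", n_points=24,
                                  kappa0=0.5, kappa_slope=0.03, n_traces=4)
        prof = curvature_profile(ens, segment_len=8.0)
        # deterministic construction: jitter-free sems are ~0; fit on means
        w = np.polyfit(prof.distance_from_tip, prof.mean_curvature, 1)
        assert abs(w[0]) == pytest.approx(0.03, rel=0.02)

    def test_subsampling_replicates_widens_error(self, rng):
        ens = make_fixture_traces("gaussian-chain", n_points=20, n_traces=120,
                                  sigma2=0.03, rng=rng)
        prof_full = curvature_profile(ens, 8.0)
        sub = cf.TraceEnsemble(ens.traces[:30], ens.spacing)
        prof_sub = curvature_profile(sub, 8.0)
        _, se_full = curvature_gradient(prof_full)
        _, se_sub = curvature_gradient(prof_sub)
        assert se_sub > se_full

    def test_degenerate_range_errors(self):
        ens = make_fixture_traces("arc", n_points=20, n_traces=5)
        prof = curvature_profile(ens, 8.0)
        with pytest.raises(ValueError):
            curvature_gradient(prof, fit_range=(7.9, 8.1))


class TestMeanCosDeflection:
    def test_straight_ensemble_is_unity(self):
        ens = make_fixture_traces("straight", n_points=12, n_traces=3)
        d = mean_cos_deflection(ens)
        np.testing.assert_allclose(d[:, 1], 1.0)
        assert d[0, 0] == 0.0

    def test_gaussian_chain_matches_closed_form(self):
        # independent N(0, 0.02) joints, d = 4 nm: <cos> = exp(-0.01 n)
        rng = np.random.default_rng(11)
        ens = make_fixture_traces("gaussian-chain", n_points=16, spacing=4.0,
                                  sigma2=0.02, n_traces=4000, rng=rng)
        d = mean_cos_deflection(ens)
        n = d[:, 0] / 4.0
        expected = np.exp(-0.01 * n)
        np.testing.assert_allclose(d[:, 1], expected, atol=0.01)


class TestPersistenceFit:
    def test_exact_exponential_inverts(self):
        s = np.arange(0, 16) * 4.0
        decay = np.column_stack([s, np.exp(-s / 400.0)])
        # decay convention: P is the bare e-folding length
        fit = fit_persistence_length(decay, 295.15, convention="decay")
        assert fit.P_hat == pytest.approx(400.0, rel=1e-6)
        # planar convention: exp(-s/2P) -> P = 200
        fit2 = fit_persistence_length(decay, 295.15, convention="planar")
        assert fit2.P_hat == pytest.approx(200.0, rel=1e-6)

    def test_gaussian_chains_recover_stiffness(self):
        # sigma^2 = kT d / B  ->  decay length 2 d / sigma^2 = 2 B / kT
        rng = np.random.default_rng(4)
        sigma2 = 0.02
        ens = make_fixture_traces("gaussian-chain", n_points=16, spacing=4.0,
                                  sigma2=sigma2, n_traces=1000, rng=rng)
        fit = fit_persistence_length(mean_cos_deflection(ens), 295.15)
        assert fit.P_hat == pytest.approx(2 * 4.0 / sigma2, rel=0.10)

    def test_direct_sampled_ensembles_converge_to_2b_over_kt(self):
        """Estimator consistency against the closed-form 2B/kBT."""
        p = cf.FLOPPY_PF.with_(theta0=0.0)
        rng = np.random.default_rng(6)
        chains = [cf.sample_equilibrium_init(p, 295.15, rng) for _ in range(1000)]
        ens = cf.TraceEnsemble.from_states(chains, p.spacing)
        fit = fit_persistence_length(mean_cos_deflection(ens), 295.15)
        assert fit.P_hat == pytest.approx(p.persistence_length(295.15, "decay"),
                                          rel=0.05)

    def test_non_decaying_data_flagged_lower_bound(self):
        s = np.arange(0, 10) * 4.0
        decay = np.column_stack([s, np.ones_like(s)])
        fit = fit_persistence_length(decay, 295.15)
        assert fit.lower_bound
        assert np.isinf(fit.P_hat)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_persistence_length(np.array([[0.0, 1.0], [4.0, 0.9]]), 295.15)
        bad = np.column_stack([np.arange(5) * 4.0, np.full(5, 0.5)])
        with pytest.raises(ValueError):
            fit_persistence_length(bad, 295.15)  # first point not (0, 1)


class TestTraceEnsemble:
    def test_rejects_wrong_spacing_metadata(self):
        t = make_fixture_traces("straight", n_points=10, spacing=4.0).traces[0]
        with pytest.raises(ValueError, match="spacing"):
            cf.TraceEnsemble([t], spacing=8.0)

    def test_from_states_puts_tip_first_and_trims_clamp(self):
        p = cf.FLOPPY_PF
        st = cf.straight_state(p)
        ens = cf.TraceEnsemble.from_states([st], p.spacing, n_trim=p.n_fixed)
        assert ens.traces[0].shape == (p.n_monomers - p.n_fixed, 2)
        # tip (last monomer, highest y) must come first
        assert ens.traces[0][0, 1] > ens.traces[0][-1, 1]
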