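"""Growth dynamics: sources, stepping, remeshing, outcome classification."""

import numpy as np
import pytest

from tipshell import (
    DimensionlessParameters,
    FixtureShape,
    NumericsConfig,
    Outcome,
    StrainRateField,
    TipSimulator,
    VelocityField,
    WallState,
    activation_rate,
    make_fixture,
    remesh,
    steady_state_residual,
    synthase_rhs,
    wall_mass_rhs,
)
from conftest import FAST_NUMERICS

P_REF = DimensionlessParameters(gamma=5.0, lam_ratio=0.2)


def fixture_state(n=61, L=6.0, a=1.5, h=1.0, rho_A=0.5, rho_I=0.5):
    return make_fixture(FixtureShape("capped_cylinder", a=a, n_grid=n,
                                     domain_len=L), with_state=True,
                        h=h, rho_A=rho_A, rho_I=rho_I)


ZERO_VEL = VelocityField(u=np.zeros(61), vn=np.zeros(61))
ZERO_SR = StrainRateField(eps_s=np.zeros(61), eps_phi=np.zeros(61))


class TestActivationRate:
    def test_no_feedback_gives_zero(self):
        sr = StrainRateField(eps_s=np.linspace(0, 1, 5),
                             eps_phi=np.linspace(1, 0, 5))
        assert np.all(activation_rate(sr, 0.0) == 0.0)

    def test_proportional_to_total_expansion(self):
        sr = StrainRateField(eps_s=np.full(3, 0.1), eps_phi=np.full(3, 0.2))
        assert np.allclose(activation_rate(sr, 2.0), 0.6)

    def test_contraction_clamped_to_zero(self):
        sr = StrainRateField(eps_s=np.full(3, -0.4), eps_phi=np.full(3, 0.1))
        assert np.all(activation_rate(sr, 2.0) == 0.0)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            activation_rate(ZERO_SR, -1.0)


class TestWallMassRhs:
    def test_pure_assembly_without_motion(self):
        st = fixture_state(rho_A=0.7)
        dh = wall_mass_rhs(st, ZERO_VEL, ZERO_SR, P_REF)
        assert np.allclose(dh, 0.7, atol=1e-12)

    def test_expansion_without_assembly_thins(self):
        st = fixture_state(rho_A=0.0, h=0.8)
        sr = StrainRateField(eps_s=np.full(61, 0.3), eps_phi=np.full(61, 0.2))
        dh = wall_mass_rhs(st, ZERO_VEL, sr, P_REF)
        assert np.allclose(dh, -0.8 * 0.5, atol=1e-12)
        assert np.all(dh < 0)


class TestSynthaseRhs:
    def test_exo_endo_fixed_point_without_activation(self):
        """With kon=koff-free transport off, rho_I relaxes to kX/kD; at the
        apex the fixed point is kX0/kD0 (scaled: 1/kD_hat)."""
        p = DimensionlessParameters(gamma=0.0, lam_ratio=0.2, kD_hat=2.0,
                                    lamD_hat=1.0)
        st = fixture_state(rho_A=0.0, rho_I=0.0)
        s = st.shape.s
        fp = np.exp(-s ** 2) / (2.0 * np.exp(-s ** 2))  # kX/kD = 1/kD_hat
        st_fp = WallState(shape=st.shape, h=st.h, rho_A=st.rho_A, rho_I=fp)
        rI_t, rA_t = synthase_rhs(st_fp, np.zeros(61), ZERO_VEL, ZERO_SR, p)
        assert np.allclose(rI_t, 0.0, atol=1e-12)
        assert np.allclose(rA_t, 0.0, atol=1e-12)
        assert fp[0] == pytest.approx(1.0 / p.kD_hat)

    def test_two_state_kinetic_balance(self):
        """rho_A/rho_I = kon/koff is stationary for the exchange terms."""
        p = DimensionlessParameters(gamma=1.0, lam_ratio=0.2, kD_hat=1.0,
                                    lamD_hat=1.0)  # kX = kD profiles
        st = fixture_state()
        rho_I = np.ones(61)  # exo/endo fixed point kX/kD = 1 for kD_hat=1
        kon = np.full(61, 2.0)
        rho_A = (kon / p.koff_hat) * rho_I
        st2 = WallState(shape=st.shape, h=st.h, rho_A=rho_A, rho_I=rho_I)
        rI_t, rA_t = synthase_rhs(st2, kon, ZERO_VEL, ZERO_SR, p)
        assert np.allclose(rA_t, 0.0, atol=1e-12)
        assert np.allclose(rI_t, 0.0, atol=1e-12)


class TestAdvance:
    def test_zero_pressure_limit_only_relaxes_inactive_pool(self):
        """P=0: no tensions, no motion; rho_I relaxes toward kX/kD."""
        p = DimensionlessParameters(gamma=1.0, lam_ratio=0.0)
        sim = TipSimulator(p, FAST_NUMERICS, constitutive=False)
        st0 = sim.initial_state()
        st0 = WallState(shape=st0.shape, h=st0.h,
                        rho_A=np.zeros(sim.n), rho_I=np.zeros(sim.n))
        st1 = sim.advance(st0, 3.0)
        assert np.allclose(st1.shape.theta, st0.shape.theta, atol=1e-9)
        assert np.allclose(st1.h, st0.h, atol=1e-9)
        assert np.allclose(st1.rho_A, 0.0, atol=1e-9)
        # rho_I moved monotonically toward the exo/endo fixed point
        fp = sim.kX / np.maximum(sim.kD, 1e-300)
        apex_expected = (1 - np.exp(-sim.kD[0] * 3.0)) * fp[0]
        assert st1.rho_I[0] == pytest.approx(apex_expected, rel=1e-5)

    def test_small_step_matches_forward_euler_to_second_order(self):
        nu = FAST_NUMERICS.with_(rtol=1e-11, atol=1e-13)
        sim = TipSimulator(P_REF, nu)
        st = sim.initial_state()
        y0 = sim.pack(st)
        m = 4 * sim.n  # field components (budget accumulators excluded)
        errs = []
        for dt in (2e-3, 1e-3):
            y_bdf = sim.pack(sim.advance(st, dt))
            y_euler = y0 + dt * sim.rhs(0.0, y0)
            errs.append(np.max(np.abs(y_bdf[:m] - y_euler[:m])))
        ratio = errs[0] / errs[1]
        assert 3.0 < ratio < 5.0  # O(dt^2) defect of the Euler tendency

    def test_step_doubling_consistency(self):
        sim = TipSimulator(P_REF, FAST_NUMERICS)
        st = sim.initial_state()
        dt = 0.5
        a = sim.advance(st, dt)
        b = sim.advance(sim.advance(st, dt / 2), dt / 2)
        scale = np.max(np.abs(sim.pack(a)))
        assert np.max(np.abs(sim.pack(a) - sim.pack(b))) < 50 * FAST_NUMERICS.rtol * scale


class TestRemesh:
    def test_identity_on_uniform_cylinder(self):
        st = make_fixture(FixtureShape("cylinder", a=2.0, n_grid=61,
                                       domain_len=6.0), with_state=True)
        st2 = remesh(st)
        assert np.allclose(st2.shape.r, st.shape.r, atol=1e-13)
        assert np.allclose(st2.shape.theta, st.shape.theta, atol=1e-13)
        assert np.allclose(st2.h, st.h, atol=1e-13)

    def test_near_identity_on_arclength_tip_state(self):
        sim = TipSimulator(P_REF, FAST_NUMERICS)
        st = sim.initial_state()
        st2 = sim.remesh(st)
        assert np.max(np.abs(st2.shape.theta - st.shape.theta)) < 1e-4
        assert np.max(np.abs(st2.h - st.h)) < 1e-4

    def test_inflated_hemisphere_matches_closed_form_resampling(self):
        """A hemisphere inflated by an exact factor, still sampled at the old
        nodes, must come back resampled to uniform arclength: theta(s) =
        s/(c*a), fields shifted to f(s/c)."""
        a, c, n = 4.0, 1.05, 121
        L = a * np.pi / 2
        s = np.linspace(0.0, L, n)
        from tipshell import ShellShape
        theta = s / a                      # angles unchanged by inflation
        r = c * a * np.sin(theta)          # radii scaled by c
        z = c * a * (np.cos(theta) - 1.0)
        ks = np.full(n, 1.0 / (c * a))
        kp = np.full(n, 1.0 / (c * a))
        h = 1.0 + 0.3 * np.cos(s)
        shape = ShellShape(s=s, r=r, theta=theta, kappa_s=ks, kappa_phi=kp, z=z)
        st = WallState(shape=shape, h=h, rho_A=np.zeros(n), rho_I=np.zeros(n))
        st2 = remesh(st, P_REF, NumericsConfig(n_grid=n, domain_len=L))
        assert np.allclose(st2.shape.theta, s / (c * a), atol=1e-9)
        assert np.allclose(st2.shape.r, c * a * np.sin(s / (c * a)), atol=1e-7)
        assert np.allclose(st2.h, 1.0 + 0.3 * np.cos(s / c), atol=2e-5)

    def test_mass_preserved_through_remesh(self):
        nu = NumericsConfig(n_grid=161, domain_len=8.0, first_chunk=0.25)
        sim = TipSimulator(P_REF, nu)
        rec = sim.run()
        st = rec.profile.state
        m0 = sim.total_wall_mass(st)
        m1 = sim.total_wall_mass(sim.remesh(st))
        assert abs(m1 - m0) / m0 < 1e-6


class TestSteadyStateResidual:
    def test_frozen_shape_residual_is_inactive_pool_rate(self):
        """With P=0 and only rho_I out of equilibrium, the residual equals
        max |d rho_I/dt|."""
        p = DimensionlessParameters(gamma=1.0, lam_ratio=0.0)
        sim = TipSimulator(p, FAST_NUMERICS, constitutive=False)
        st0 = sim.initial_state()
        st = WallState(shape=st0.shape, h=st0.h, rho_A=np.zeros(sim.n),
                       rho_I=np.zeros(sim.n))
        res = steady_state_residual(st, p, FAST_NUMERICS, constitutive=False)
        # d rho_I/dt = kX at rho_I = 0, maximal at the apex where kX = 1
        assert res == pytest.approx(1.0, rel=1e-12)

    def test_exact_exo_endo_fixed_point_is_steady(self):
        p = DimensionlessParameters(gamma=1.0, lam_ratio=0.0, lamD_hat=1.0)
        sim = TipSimulator(p, FAST_NUMERICS, constitutive=False)
        st0 = sim.initial_state()
        fp = sim.kX / sim.kD
        st = WallState(shape=st0.shape, h=st0.h, rho_A=np.zeros(sim.n),
                       rho_I=fp)
        assert steady_state_residual(st, p, FAST_NUMERICS,
                                     constitutive=False) < 1e-12


class TestOutcomes:
    def test_no_feedback_lyses_at_high_mechanical_ratio(self, run_cache):
        rec = run_cache(0.0, 1.0)
        assert rec.outcome is Outcome.LYSIS_THINNING
        assert rec.h0[-1] <= FAST_NUMERICS.h_min_frac * 1.01

    def test_no_feedback_thickens_at_low_mechanical_ratio(self, run_cache):
        rec = run_cache(0.0, 0.1)
        assert rec.outcome is Outcome.THICKENING
        assert np.max(rec.h0) >= FAST_NUMERICS.h_max_frac * 0.99

    def test_feedback_stabilizes_growth(self, stable_run):
        rec = stable_run
        assert rec.outcome is Outcome.STABLE
        assert rec.residual[-1] <= FAST_NUMERICS.steady_tol
        # residual decays overall from the initial transient
        assert rec.residual[-1] < 1e-2 * rec.residual[0]

    def test_increasing_ratio_at_fixed_feedback_flips_to_lysis(self, run_cache):
        assert run_cache(2.0, 0.2).outcome is Outcome.STABLE
        assert run_cache(2.0, 0.5).outcome is Outcome.LYSIS_THINNING

    def test_positivity_on_stable_run(self, stable_run):
        st = stable_run.profile.state
        assert np.all(st.h > 0)
        assert np.all(st.rho_A >= 0)
        assert np.all(st.rho_I >= 0)

    def test_trajectory_record_metadata(self, stable_run):
        assert stable_run.params.gamma == 5.0
        assert stable_run.error is None
        assert not stable_run.constitutive
        assert len(stable_run.t) == len(stable_run.h0)


class TestObservables:
    def test_analytic_capped_fixture_radius_exact(self):
        """On a synthetic capped-cylinder 'profile' R equals the tube radius."""
        from tipshell.dynamics import extract_observables_from_fields
        nu = NumericsConfig(n_grid=61, domain_len=6.0)
        st = make_fixture(FixtureShape("capped_cylinder", a=1.5, n_grid=61,
                                       domain_len=6.0), with_state=True)
        f = dict(r=st.shape.r, h=st.h, eps_s=np.zeros(61),
                 eps_phi=np.zeros(61), kappa_s=st.shape.kappa_s,
                 rho_A=st.rho_A, rho_I=st.rho_I, vn=np.zeros(61),
                 u=np.zeros(61))
        obs = extract_observables_from_fields(f, nu)
        assert obs.R == pytest.approx(1.5, abs=1e-12)
        assert obs.H == pytest.approx(1.0, abs=1e-12)

    def test_apex_isotropy_on_stable_profile(self, stable_run):
        f = stable_run.profile.fields
        assert f["eps_s"][0] == pytest.approx(f["eps_phi"][0], rel=1e-6)
        assert f["kappa_s"][0] == pytest.approx(f["kappa_phi"][0], rel=1e-6)

    def test_domain_doubling_leaves_radius_unchanged(self, stable_run):
        nu2 = FAST_NUMERICS.with_(domain_len=12.0, n_grid=121)
        rec2 = TipSimulator(P_REF, nu2).run()
        assert rec2.outcome is Outcome.STABLE
        R1 = stable_run.profile.observables.R
        R2 = rec2.profile.observables.R
        assert abs(R2 - R1) / R1 < 0.005

    def test_flatness_gate_raises_for_unconverged_plateau(self):
        from tipshell.dynamics import (DomainTooShortError,
                                       extract_observables_from_fields)
        nu = NumericsConfig(n_grid=61, domain_len=6.0)
        n = 61
        f = dict(r=np.linspace(1.0, 2.0, n), h=np.ones(n),
                 eps_s=np.zeros(n), eps_phi=np.zeros(n),
                 kappa_s=np.zeros(n), rho_A=np.zeros(n), rho_I=np.zeros(n),
                 vn=np.zeros(n), u=np.zeros(n))
        with pytest.raises(DomainTooShortError):
            extract_observables_from_fields(f, nu)


class TestBudgets:
    def test_budget_closure_on_steady_growth(self, stable_run):
        sim = TipSimulator(P_REF, FAST_NUMERICS)
        dm, ds = sim.budget_drift(stable_run.profile.state, 10.0)
        assert dm < 1e-5
        assert ds < 1e-5
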