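"""Time evolution of the growing shell: wall thickness, synthase densities,
surface motion, steady-state detection and outcome classification.

The moving-boundary problem is solved on a fixed uniform arclength grid in a
tip-co-moving frame: the apex is pinned at s = 0 and the grid tangential
velocity W(s) = -int_0^s kappa_s*vn ds' is chosen so that s remains arclength
at all times.  With curve normal velocity vn the shape angle evolves as

    d(theta)/dt = W*kappa_s - d(vn)/ds,

and r is recovered from theta by quadrature (dr/ds = cos(theta) holds by
construction).  Material fields are advected through the grid with relative
velocity (u - W):

    dh/dt    = -(u-W) dh/ds    - h*(eps_s+eps_phi) + rho_A
    drho_A/dt = -(u-W) drho_A/ds - rho_A*(eps_s+eps_phi) + kon*rho_I - koff*rho_A
    drho_I/dt =  koff*rho_A - kon*rho_I + kX - kD*rho_I - rho_I*(dr/dt)/r

(all scaled: lengths by lambda_X, time by 1/kX0, densities by rho_0,
thickness by H0; the scaled wall-assembly source is then exactly rho_A and
the scaled turgor pressure is 12*lam_ratio).  Inactive synthases are not
transported along the surface (membrane diffusion and advection neglected);
their geometric dilution factor is kept exactly as in the conservative form
d(rho_I*r)/dt = r*[...], which holds in this grid frame.

The activation rate implements the cell-wall-integrity mechanical feedback,

    kon = gamma * max(eps_s + eps_phi, 0),

so faster wall expansion activates more synthases.  Without feedback
(gamma = 0) activation would vanish entirely; the no-feedback variant of the
model therefore delivers synthases directly in the active state
("constitutive" mode): d(rho_A r)/dt + d(rho_A r u)/ds = r*(kX - kD*rho_A).

Trajectories are classified as STABLE (steady-state residual below
``steady_tol``), LYSIS_THINNING (apical wall thinner than ``h_min_frac``),
THICKENING (wall anywhere thicker than ``h_max_frac``) or TIMEOUT.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from ._fd import EVEN, NONE, ODD, cumint_matrix, diff_matrix
from .mechanics import (
    KinematicsError,
    MechanicsError,
    ShellShape,
    StrainRateField,
    VelocityField,
    curvatures_from_shape,
)
from .params import DimensionlessParameters, NumericsConfig

__all__ = [
    "Outcome",
    "WallState",
    "TrajectoryRecord",
    "SteadyStateProfile",
    "Observables",
    "TipSimulator",
    "GeometryError",
    "DomainTooShortError",
    "activation_rate",
    "wall_mass_rhs",
    "synthase_rhs",
    "advance",
    "remesh",
    "steady_state_residual",
    "run_to_outcome",
    "extract_observables",
    "initial_state",
]

_H_FLOOR = 1e-12  # thickness floor used only inside RHS divisions


class GeometryError(RuntimeError):
    """Shape became degenerate (self-intersection / fold-over)."""


class DomainTooShortError(RuntimeError):
    """No distal plateau within the domain; increase domain_len."""


class Outcome(str, enum.Enum):
    STABLE = "STABLE"
    LYSIS_THINNING = "LYSIS_THINNING"
    THICKENING = "THICKENING"
    TIMEOUT = "TIMEOUT"


@dataclass(frozen=True)
class WallState:
    """Full dynamical state: geometry plus wall and synthase fields."""

    shape: ShellShape
    h: np.ndarray  #: wall thickness (units of H0)
    rho_A: np.ndarray  #: active Fks1/2 surface density (units of rho_0)
    rho_I: np.ndarray  #: inactive Fks1/2 surface density (units of rho_0)
    t: float = 0.0


@dataclass(frozen=True)
class Observables:
    """Apical and far-field summary of a converged profile."""

    R: float  #: projection radius far from the apex
    H: float  #: wall thickness far from the apex
    eps0: float  #: apical expansion rate eps_s(0) = eps_phi(0)
    kappa0: float  #: apical meridional curvature
    rhoA0: float  #: apical active synthase density
    rhoI0: float  #: apical inactive synthase density
    tip_speed: float  #: projection elongation rate vn(0) + u(L)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("R", "H", "eps0", "kappa0", "rhoA0", "rhoI0", "tip_speed")}


@dataclass
class TrajectoryRecord:
    """Sampled history and final classification of one run."""

    t: np.ndarray
    h0: np.ndarray  #: apical thickness h(0, t)
    rhoA0: np.ndarray
    rhoI0: np.ndarray
    residual: np.ndarray  #: steady-state residual history
    tip_speed: np.ndarray
    outcome: Outcome
    params: DimensionlessParameters
    numerics: NumericsConfig
    constitutive: bool
    error: str | None = None
    profile: "SteadyStateProfile | None" = None
    #: wall-mass and synthase budget drift: final |int r f ds - initial -
    #: time-integrated (source - outflux)|, absolute, over the whole run
    mass_drift: float = float("nan")
    synthase_drift: float = float("nan")


@dataclass(frozen=True)
class SteadyStateProfile:
    """Converged state plus its diagnostic fields and observables."""

    state: WallState
    fields: dict  #: s, r, theta, curvatures, tensions, strain rates, ...
    observables: Observables
    residual: float
    params: DimensionlessParameters
    numerics: NumericsConfig


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

class TipSimulator:
    """Method-of-lines integrator for one parameter point.

    Pre-assembles the differentiation/quadrature operators and the frozen
    spatial profiles (viscosity, exo-/endocytosis) for the configured grid.
    The state vector is [theta, h, rho_A, rho_I, B_mass, B_syn] where the two
    trailing scalars accumulate the source-minus-outflux integrals of the
    wall-mass and synthase budgets (so budget closure can be checked against
    solver accuracy rather than sampling accuracy).
    """

    def __init__(
        self,
        p: DimensionlessParameters,
        numerics: NumericsConfig | None = None,
        constitutive: bool | None = None,
    ):
        self.p = p
        self.numerics = numerics if numerics is not None else NumericsConfig()
        self.constitutive = (p.gamma == 0.0) if constitutive is None else constitutive
        nu = self.numerics
        self.n = nu.n_grid
        self.s = nu.s
        self.ds = nu.ds
        self.De = diff_matrix(self.n, self.ds, EVEN)
        self.Do = diff_matrix(self.n, self.ds, ODD)
        self.Qe = cumint_matrix(self.n, self.ds, EVEN)
        self.Qo = cumint_matrix(self.n, self.ds, ODD)
        self.w_odd = self.Qo[-1]
        s2 = self.s ** 2
        self.mu_hat = np.exp(s2)
        self.kX = np.exp(-s2)
        self.kD = p.kD_hat * np.exp(-s2 / p.lamD_hat ** 2)
        self.Phat = p.pressure_hat

    # -- state <-> vector ------------------------------------------------
    def pack(self, state: WallState, budgets=(0.0, 0.0)) -> np.ndarray:
        return np.concatenate([
            state.shape.theta, state.h, state.rho_A, state.rho_I,
            np.asarray(budgets, float),
        ])

    def unpack(self, y: np.ndarray, t: float = 0.0) -> WallState:
        n = self.n
        th = y[:n]
        r = self.Qe @ np.cos(th)
        r[0] = 0.0
        ks, kp = curvatures_from_shape(self.s, r, th)
        shape = ShellShape(s=self.s, r=r, theta=th, kappa_s=ks, kappa_phi=kp)
        return WallState(shape=shape, h=y[n:2 * n].copy(),
                         rho_A=y[2 * n:3 * n].copy(),
                         rho_I=y[3 * n:4 * n].copy(), t=t)

    def initial_state(self) -> WallState:
        """Hemisphere-capped cylinder with uniform wall and the exo/endo
        fixed-point synthase profile (split evenly between states in
        feedback mode, all active in constitutive mode)."""
        nu, p = self.numerics, self.p
        a = nu.ic_tip_radius
        b = a * np.pi / 2.0
        if nu.ic_smooth > 0:
            kprof = (0.5 / a) * (1.0 - np.tanh((self.s - b) / nu.ic_smooth))
            th = self.Qe @ kprof
            th *= (np.pi / 2.0) / th[-1]
        else:
            th = np.minimum(self.s / a, np.pi / 2.0)
        r = self.Qe @ np.cos(th)
        r[0] = 0.0
        ks, kp = curvatures_from_shape(self.s, r, th)
        shape = ShellShape(s=self.s, r=r, theta=th, kappa_s=ks, kappa_phi=kp)
        h = np.ones(self.n)
        with np.errstate(divide="ignore"):
            fp = np.where(self.kD > 0, self.kX / np.maximum(self.kD, 1e-300), 0.0)
        fp = np.minimum(fp, 1.0 / p.kD_hat)  # guard lamD_hat < 1 blow-up
        if self.constitutive:
            rho_A, rho_I = fp, np.zeros(self.n)
        else:
            rho_A, rho_I = 0.5 * fp, 0.5 * fp
        return WallState(shape=shape, h=h, rho_A=rho_A, rho_I=rho_I, t=0.0)

    # -- core evaluation -------------------------------------------------
    def _eval(self, Y: np.ndarray) -> dict:
        """All instantaneous fields and tendencies; Y is (m,) or (m, k)."""
        single = Y.ndim == 1
        Y2 = Y[:, None] if single else Y
        n = self.n
        th = Y2[:n]
        h = Y2[n:2 * n]
        rA = Y2[2 * n:3 * n]
        rI = Y2[3 * n:4 * n]
        hs = np.maximum(h, _H_FLOOR)
        cos_th = np.cos(th)
        sin_th = np.sin(th)
        r = self.Qe @ cos_th
        r[0] = 0.0
        ks = self.Do @ th
        kp = np.empty_like(r)
        kp[1:] = sin_th[1:] / r[1:]
        kp[0] = ks[0]
        sss = self.Phat / (2.0 * kp)
        spp = (self.Phat - sss * ks) / kp
        den = 6.0 * self.mu_hat[:, None] * hs
        es = (2.0 * sss - spp) / den
        ep = (2.0 * spp - sss) / den
        ee = es + ep
        # velocity reconstruction (gauge: du/ds = 0 at the apex)
        if self.numerics.normal_strain_in_eps_s:
            g = es - (ks / kp) * ep
            integ = np.empty_like(g)
            integ[1:] = g[1:] / sin_th[1:]
            integ[0] = 0.0
            u = sin_th * (self.Qo @ integ)
        else:
            u = self.Qo @ es
        vn = np.empty_like(u)
        vn[1:] = (ep[1:] - u[1:] * cos_th[1:] / r[1:]) / kp[1:]
        vn[0] = ep[0] / kp[0]
        W = -(self.Qe @ (ks * vn))
        th_t = W * ks - self.De @ vn
        th_t[0] = 0.0
        th_t[-1] = 0.0  # distal clamp theta = pi/2
        adv = u - W
        r_t = vn * sin_th + W * cos_th
        h_t = -adv * (self.De @ h) - h * ee + rA
        if self.constitutive:
            kon = np.zeros_like(ee)
            rA_t = (-adv * (self.De @ rA) - rA * ee
                    + self.kX[:, None] - self.kD[:, None] * rA)
            rI_t = np.zeros_like(rA_t)
            syn_src = self.kX[:, None] - self.kD[:, None] * rA
        else:
            kon = self.p.gamma * np.maximum(ee, 0.0)
            rA_t = (-adv * (self.De @ rA) - rA * ee
                    + kon * rI - self.p.koff_hat * rA)
            rtr = np.empty_like(r_t)
            rtr[1:] = r_t[1:] / r[1:]
            rtr[0] = 0.0
            rI_t = (self.p.koff_hat * rA - kon * rI
                    + self.kX[:, None] - self.kD[:, None] * rI - rI * rtr)
            syn_src = self.kX[:, None] - self.kD[:, None] * rI
        # budget accumulators: d/dt int r*h = int r*rho_A - outflux, etc.
        dB_mass = self.w_odd @ (r * rA) - (r * h * adv)[-1]
        dB_syn = self.w_odd @ (r * syn_src) - (r * rA * adv)[-1]
        out = dict(theta=th, h=h, rho_A=rA, rho_I=rI, r=r, kappa_s=ks,
                   kappa_phi=kp, sigma_ss=sss, sigma_pp=spp, eps_s=es,
                   eps_phi=ep, u=u, vn=vn, W=W, kon=kon, theta_t=th_t,
                   r_t=r_t, h_t=h_t, rho_A_t=rA_t, rho_I_t=rI_t,
                   dB_mass=dB_mass, dB_syn=dB_syn)
        if single:
            out = {k: (v[..., 0] if np.ndim(v) > 0 else v) for k, v in out.items()}
        return out

    def rhs(self, t: float, Y: np.ndarray) -> np.ndarray:
        f = self._eval(Y)
        parts = [f["theta_t"], f["h_t"], f["rho_A_t"], f["rho_I_t"]]
        if Y.ndim == 1:
            return np.concatenate(parts + [np.atleast_1d(f["dB_mass"]),
                                           np.atleast_1d(f["dB_syn"])])
        return np.vstack(parts + [f["dB_mass"][None, :], f["dB_syn"][None, :]])

    # -- diagnostics -----------------------------------------------------
    def diagnostics(self, state: WallState) -> dict:
        """All fields of ``_eval`` for a WallState (1-D arrays)."""
        f = self._eval(self.pack(state))
        f["s"] = self.s
        return f

    def residual(self, state: WallState) -> float:
        return self.residual_from_fields(self.diagnostics(state))

    @staticmethod
    def residual_from_fields(f: dict) -> float:
        """Max |d/dt| over the scaled fields r, h, rho_A, rho_I."""
        return float(max(np.max(np.abs(f["r_t"])), np.max(np.abs(f["h_t"])),
                         np.max(np.abs(f["rho_A_t"])),
                         np.max(np.abs(f["rho_I_t"]))))

    def total_wall_mass(self, state: WallState) -> float:
        return float(self.w_odd @ (state.shape.r * state.h))

    def total_synthase(self, state: WallState) -> float:
        return float(self.w_odd @ (state.shape.r * (state.rho_A + state.rho_I)))

    def budget_drift(self, state: WallState, T: float) -> tuple[float, float]:
        """Relative budget drift per unit time over [t, t+T].

        Integrates the state together with the budget accumulators and
        returns (mass, synthase) closure defects |int r f ds(T) - int r f
        ds(0) - int_0^T (source - outflux) dt| / (int r f ds(0) * T).
        """
        nu = self.numerics
        y0 = self.pack(state)
        mass0 = self.total_wall_mass(state)
        syn0 = (self.w_odd @ (state.shape.r * state.rho_A)
                if self.constitutive else self.total_synthase(state))
        sol = solve_ivp(self.rhs, (state.t, state.t + T), y0, method="BDF",
                        rtol=nu.rtol, atol=nu.atol, vectorized=True)
        if not sol.success:
            raise RuntimeError(f"budget integration failed: {sol.message}")
        st = self.unpack(sol.y[:, -1])
        mass1 = self.total_wall_mass(st)
        syn1 = (self.w_odd @ (st.shape.r * st.rho_A)
                if self.constitutive else self.total_synthase(st))
        n = self.n
        return (abs(mass1 - mass0 - sol.y[4 * n, -1]) / (mass0 * T),
                abs(syn1 - syn0 - sol.y[4 * n + 1, -1]) / (syn0 * T))

    # -- stepping --------------------------------------------------------
    def advance(self, state: WallState, dt: float) -> WallState:
        """Integrate the coupled system over [t, t+dt] with stiff BDF."""
        nu = self.numerics
        y0 = self.pack(state)
        sol = solve_ivp(self.rhs, (state.t, state.t + dt), y0, method="BDF",
                        rtol=nu.rtol, atol=nu.atol, vectorized=True)
        if not sol.success:
            raise RuntimeError(f"implicit step failed: {sol.message}")
        return self.unpack(sol.y[:, -1], t=float(sol.t[-1]))

    def remesh(self, state: WallState) -> WallState:
        """Re-establish the uniform arclength grid after surface motion.

        Recomputes node arclengths from the (r, z) meridian, resamples all
        fields by monotone cubic interpolation and re-imposes the apex
        boundary values; r is rebuilt from theta by quadrature so that
        dr/ds = cos(theta) holds exactly on the new grid.
        """
        sh = state.shape
        apex = sh.has_apex
        par_r = ODD if apex else NONE
        par_z = EVEN if apex else NONE
        n, ds = sh.n, sh.ds
        zeta = sh.axial()
        dr = diff_matrix(n, ds, par_r) @ sh.r
        dz = diff_matrix(n, ds, par_z) @ zeta
        speed = np.hypot(dr, dz)
        if np.any(speed <= 0) or not np.all(np.isfinite(speed)):
            raise GeometryError("degenerate meridian")
        s_true = cumint_matrix(n, ds, EVEN if apex else NONE) @ speed
        if np.any(np.diff(s_true) <= 0):
            raise GeometryError("self-intersecting or folded meridian")
        s_new = self.s

        def resample(f):
            return PchipInterpolator(s_true, f, extrapolate=True)(s_new)

        th = resample(sh.theta)
        h = resample(state.h)
        rA = resample(state.rho_A)
        rI = resample(state.rho_I)
        if apex:
            th[0] = 0.0
            r = self.Qe @ np.cos(th)
            r[0] = 0.0
        else:
            r = resample(sh.r)
        ks, kp = curvatures_from_shape(s_new, r, th)
        shape = ShellShape(s=s_new, r=r, theta=th, kappa_s=ks, kappa_phi=kp)
        return WallState(shape=shape, h=h, rho_A=rA, rho_I=rI, t=state.t)

    # -- outcome classification -------------------------------------------
    def run(self, record_every: float | None = None) -> TrajectoryRecord:
        """Integrate from the standard initial condition to an outcome."""
        nu = self.numerics
        state = self.initial_state()
        y = self.pack(state)
        t = 0.0
        chunk = nu.first_chunk
        next_remesh = nu.remesh_every
        samples = {k: [] for k in ("t", "h0", "rhoA0", "rhoI0", "residual",
                                   "tip_speed")}
        outcome = Outcome.TIMEOUT
        error: str | None = None
        f0 = self._eval(y)
        self._sample(samples, 0.0, f0)
        n = self.n
        mass0 = self.total_wall_mass(state)
        syn0 = (self.w_odd @ (state.shape.r * state.rho_A)
                if self.constitutive else self.total_synthase(state))

        def ev_lysis(t_, y_):
            return y_[n] - nu.h_min_frac

        def ev_thick(t_, y_):
            return nu.h_max_frac - np.max(y_[n:2 * n])

        ev_lysis.terminal = True
        ev_thick.terminal = True

        while t < nu.t_max:
            t_end = min(t + chunk, nu.t_max)
            try:
                sol = solve_ivp(self.rhs, (t, t_end), y, method="BDF",
                                rtol=nu.rtol, atol=nu.atol, vectorized=True,
                                events=[ev_lysis, ev_thick])
            except (MechanicsError, GeometryError, FloatingPointError) as exc:
                error = f"{type(exc).__name__}: {exc}"
                break
            if not sol.success:
                error = str(sol.message)
                break
            y = sol.y[:, -1]
            t = float(sol.t[-1])
            if sol.status == 1:  # a terminal event fired
                fired_lysis = len(sol.t_events[0]) > 0
                f = self._eval(y)
                self._sample(samples, t, f)
                outcome = Outcome.LYSIS_THINNING if fired_lysis else Outcome.THICKENING
                break
            if not np.all(np.isfinite(y)):
                error = "non-finite state"
                break
            # clip round-off negatives; flag genuine negativity
            dens = y[2 * n:4 * n]
            if np.any(dens < -1e-6):
                error = "negative synthase density"
                break
            np.clip(dens, 0.0, None, out=dens)
            f = self._eval(y)
            res = self.residual_from_fields(f)
            self._sample(samples, t, f, res)
            if res <= nu.steady_tol:
                outcome = Outcome.STABLE
                break
            if t >= next_remesh and t < nu.t_max:
                try:
                    budgets = (y[4 * n], y[4 * n + 1])
                    y = self.pack(self.remesh(self.unpack(y, t)), budgets)
                except GeometryError as exc:
                    error = f"GeometryError: {exc}"
                    break
                next_remesh = t + nu.remesh_every
            chunk = min(2.0 * chunk, nu.max_chunk)

        st_end = self.unpack(y, t)
        mass_end = self.total_wall_mass(st_end)
        syn_end = (self.w_odd @ (st_end.shape.r * st_end.rho_A)
                   if self.constitutive else self.total_synthase(st_end))
        rec = TrajectoryRecord(
            t=np.array(samples["t"]), h0=np.array(samples["h0"]),
            rhoA0=np.array(samples["rhoA0"]), rhoI0=np.array(samples["rhoI0"]),
            residual=np.array(samples["residual"]),
            tip_speed=np.array(samples["tip_speed"]),
            outcome=outcome, params=self.p, numerics=nu,
            constitutive=self.constitutive, error=error,
            mass_drift=abs(mass_end - mass0 - y[4 * n]),
            synthase_drift=abs(syn_end - syn0 - y[4 * n + 1]))
        if outcome is Outcome.STABLE:
            st = self.unpack(y, t)
            f = self.diagnostics(st)
            f["plateau_flatness"] = plateau_flatness(f, nu)
            # lenient here; extract_observables() enforces plateau flatness
            obs = extract_observables_from_fields(f, nu, flatness_tol=np.inf)
            rec.profile = SteadyStateProfile(
                state=st, fields=f, observables=obs,
                residual=self.residual_from_fields(f), params=self.p,
                numerics=nu)
        return rec

    def _sample(self, samples: dict, t: float, f: dict,
                res: float | None = None) -> None:
        samples["t"].append(t)
        samples["h0"].append(float(f["h"][0]))
        samples["rhoA0"].append(float(f["rho_A"][0]))
        samples["rhoI0"].append(float(f["rho_I"][0]))
        samples["residual"].append(self.residual_from_fields(f)
                                   if res is None else res)
        samples["tip_speed"].append(float(f["vn"][0] + f["u"][-1]))


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def activation_rate(sr: StrainRateField, gamma: float) -> np.ndarray:
    """Mechanical-feedback activation rate kon = gamma*max(eps_s+eps_phi, 0).

    Expansion-rate sensing: synthases are only activated where the wall is
    actually expanding; locally contracting regions give kon = 0.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return gamma * np.maximum(sr.total, 0.0)


def _grid_ops(shape: ShellShape):
    par = shape.has_apex
    De = diff_matrix(shape.n, shape.ds, EVEN if par else NONE)
    Qe = cumint_matrix(shape.n, shape.ds, EVEN if par else NONE)
    return De, Qe


def _relative_advection(shape: ShellShape, vel: VelocityField) -> np.ndarray:
    """u - W: material velocity relative to the tip-pinned arclength grid."""
    _, Qe = _grid_ops(shape)
    W = -(Qe @ (shape.kappa_s * vel.vn))
    return vel.u - W


def wall_mass_rhs(state: WallState, vel: VelocityField, sr: StrainRateField,
                  p: DimensionlessParameters) -> np.ndarray:
    """Scaled thickness tendency dh/dt on the grid.

    Advective form of wall mass conservation: the material derivative is
    -h*(eps_s+eps_phi) + rho_A (geometric dilution plus assembly by active
    synthases), transported relative to the grid.
    """
    De, _ = _grid_ops(state.shape)
    adv = _relative_advection(state.shape, vel)
    return -adv * (De @ state.h) - state.h * sr.total + state.rho_A


def synthase_rhs(state: WallState, kon: np.ndarray, vel: VelocityField,
                 sr: StrainRateField, p: DimensionlessParameters
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Scaled (drho_I/dt, drho_A/dt) on the grid.

    Active synthases are wall-anchored: advected with the wall and diluted by
    the area expansion rate.  Inactive synthases exchange with the vesicle
    pool (exocytosis source kX, endocytosis sink kD) and with the active
    state, without transport along s.
    """
    sh = state.shape
    De, Qe = _grid_ops(sh)
    s = sh.s
    kX = np.exp(-s ** 2)
    kD = p.kD_hat * np.exp(-(s / p.lamD_hat) ** 2)
    adv = vel.u + (Qe @ (sh.kappa_s * vel.vn))
    rA_t = (-adv * (De @ state.rho_A) - state.rho_A * sr.total
            + kon * state.rho_I - p.koff_hat * state.rho_A)
    W = -(Qe @ (sh.kappa_s * vel.vn))
    r_t = vel.vn * np.sin(sh.theta) + W * np.cos(sh.theta)
    rtr = np.zeros_like(r_t)
    nz = sh.r > 0
    rtr[nz] = r_t[nz] / sh.r[nz]
    rI_t = (p.koff_hat * state.rho_A - kon * state.rho_I
            + kX - kD * state.rho_I - state.rho_I * rtr)
    return rI_t, rA_t


def initial_state(p: DimensionlessParameters,
                  numerics: NumericsConfig | None = None,
                  constitutive: bool | None = None) -> WallState:
    return TipSimulator(p, numerics, constitutive).initial_state()


def advance(state: WallState, dt: float, p: DimensionlessParameters,
            numerics: NumericsConfig | None = None,
            constitutive: bool | None = None) -> WallState:
    return TipSimulator(p, numerics, constitutive).advance(state, dt)


def remesh(state: WallState, p: DimensionlessParameters | None = None,
           numerics: NumericsConfig | None = None) -> WallState:
    if p is None:
        p = DimensionlessParameters(gamma=1.0, lam_ratio=1.0)
    if numerics is None:
        numerics = NumericsConfig(
            n_grid=state.shape.n,
            domain_len=float(state.shape.s[-1]))
    return TipSimulator(p, numerics).remesh(state)


def steady_state_residual(state: WallState, p: DimensionlessParameters,
                          numerics: NumericsConfig | None = None,
                          constitutive: bool | None = None) -> float:
    """Max |d/dt| of the scaled fields {r, h, rho_A, rho_I} over the grid."""
    return TipSimulator(p, numerics, constitutive).residual(state)


def run_to_outcome(p: DimensionlessParameters,
                   numerics: NumericsConfig | None = None,
                   constitutive: bool | None = None) -> TrajectoryRecord:
    """Integrate from the standard initial condition until the trajectory is
    classified; the record carries a SteadyStateProfile when STABLE."""
    return TipSimulator(p, numerics, constitutive).run()


def plateau_flatness(f: dict, numerics: NumericsConfig,
                     plateau_frac: float = 0.1) -> dict:
    """Relative spread (max-min)/mean of r and h over the distal window."""
    s = numerics.s
    win = s >= s[-1] * (1.0 - plateau_frac)
    out = {}
    for name in ("r", "h"):
        vals = f[name][win]
        out[name] = float((vals.max() - vals.min()) / vals.mean())
    return out


def extract_observables_from_fields(f: dict, numerics: NumericsConfig,
                                    plateau_frac: float = 0.1,
                                    flatness_tol: float = 0.01) -> Observables:
    s = numerics.s
    win = s >= s[-1] * (1.0 - plateau_frac)
    flat = plateau_flatness(f, numerics, plateau_frac)
    for name in ("r", "h"):
        if flat[name] > flatness_tol:
            raise DomainTooShortError(
                f"no distal plateau in {name!r} (flatness {flat[name]:.3g});"
                " increase domain_len")
    return Observables(
        R=float(f["r"][win].mean()), H=float(f["h"][win].mean()),
        eps0=float(f["eps_s"][0]), kappa0=float(f["kappa_s"][0]),
        rhoA0=float(f["rho_A"][0]), rhoI0=float(f["rho_I"][0]),
        tip_speed=float(f["vn"][0] + f["u"][-1]))


def extract_observables(profile: SteadyStateProfile,
                        plateau_frac: float = 0.1,
                        flatness_tol: float = 0.01) -> Observables:
    """Far-field radius/thickness plateaus and apical values of a STABLE run."""
    return extract_observables_from_fields(profile.fields, profile.numerics,
                                           plateau_frac, flatness_tol)
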