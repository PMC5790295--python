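"""Model parameters, nondimensionalization and prescribed spatial profiles.

The model describes the growing mating projection (shmoo) of budding yeast as
an axisymmetric thin viscous shell inflated by turgor pressure ``P`` and
assembled by membrane-localized 1,3-beta-glucan synthases (Fks1/2) delivered
by exocytosis.  Twelve physical constants govern the system; after scaling
lengths by the exocytosis decay length lambda_X, times by the apical
exocytosis rate 1/kX0, synthase densities by the vesicle delivery density
rho_0 and wall thickness by H0 = m_w*rho_0*k_p/(rho_w*kX0), exactly five
dimensionless groups remain:

    lam_ratio = lambda_X / lambda_m = P*rho_w*lambda_X / (12*mu0*m_w*rho_0*k_p)
    gamma     = Gamma                (mechanical feedback strength)
    koff_hat  = k_off / kX0
    kD_hat    = kD0 / kX0
    lamD_hat  = lambda_D / lambda_X

lambda_m is the mechanical length over which turgor-driven expansion competes
with wall assembly; lam_ratio is the key mechanical control parameter.  This
choice of scales removes every remaining constant from the scaled thickness
and synthase equations and makes the scaled turgor pressure 12*lam_ratio.

Exocytosis and endocytosis rates follow Gaussian profiles centred on the apex,
and the wall viscosity grows as the reciprocal Gaussian (the wall stiffens
away from the tip as fewer wall-loosening enzymes are delivered there):

    kX(s) = kX0 exp(-s^2/lambda_X^2)
    kD(s) = kD0 exp(-s^2/lambda_D^2)
    mu(s) = mu0 exp(+s^2/lambda_X^2)
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "PhysicalParameters",
    "DimensionlessParameters",
    "NumericsConfig",
    "nondimensionalize",
    "realize",
    "exocytosis_rate",
    "endocytosis_rate",
    "viscosity",
]


@dataclass(frozen=True)
class PhysicalParameters:
    """Dimensional constants of the shell-assembly model.

    Units are arbitrary but must be mutually consistent (e.g. SI).
    All parameters must be strictly positive except the feedback strength
    ``Gamma`` which may be zero (no mechanical feedback).
    """

    P: float  #: turgor pressure (force / area)
    rho_w: float  #: wall mass density (mass / volume)
    mu0: float  #: apical wall viscosity (pressure * time)
    m_w: float  #: mass of one 1,3-beta-glucan monomer
    rho_0: float  #: Fks1/2 surface density delivered by vesicles (1 / area)
    k_p: float  #: glucan monomer extrusion rate per active synthase (1 / time)
    lambda_X: float  #: exocytosis decay length
    lambda_D: float  #: endocytosis decay length
    kX0: float  #: apical exocytosis rate (1 / time)
    kD0: float  #: apical endocytosis rate (1 / time)
    k_off: float  #: Fks1/2 inactivation rate (1 / time)
    Gamma: float = 0.0  #: mechanical feedback strength (dimensionless)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if f.name == "Gamma":
                if v < 0:
                    raise ValueError(f"Gamma must be >= 0, got {v!r}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v!r}")

    # -- derived scales -------------------------------------------------
    @property
    def lambda_m(self) -> float:
        """Mechanical length 12*mu0*m_w*rho_0*k_p/(P*rho_w)."""
        return 12.0 * self.mu0 * self.m_w * self.rho_0 * self.k_p / (self.P * self.rho_w)

    @property
    def length_scale(self) -> float:
        return self.lambda_X

    @property
    def time_scale(self) -> float:
        return 1.0 / self.kX0

    @property
    def density_scale(self) -> float:
        return self.rho_0

    @property
    def thickness_scale(self) -> float:
        """H0 = m_w*rho_0*k_p/(rho_w*kX0), the natural wall-thickness unit."""
        return self.m_w * self.rho_0 * self.k_p / (self.rho_w * self.kX0)


@dataclass(frozen=True)
class DimensionlessParameters:
    """The five dimensionless groups controlling the scaled dynamics.

    Defaults for ``koff_hat``, ``kD_hat`` and ``lamD_hat`` are order-one
    placeholders; the qualitative regime structure is insensitive to them.
    Every emitted record carries the values actually used.
    """

    gamma: float  #: feedback strength Gamma
    lam_ratio: float  #: lambda_X / lambda_m
    koff_hat: float = 1.0  #: k_off / kX0
    kD_hat: float = 1.0  #: kD0 / kX0
    lamD_hat: float = 2.0  #: lambda_D / lambda_X

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma!r}")
        # lam_ratio = 0 is the zero-turgor limit (frozen mechanics), allowed
        if not np.isfinite(self.lam_ratio) or self.lam_ratio < 0:
            raise ValueError(f"lam_ratio must be >= 0, got {self.lam_ratio!r}")
        for name in ("koff_hat", "kD_hat", "lamD_hat"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")

    @property
    def pressure_hat(self) -> float:
        """Scaled turgor pressure: P*lambda_X/(mu0*H0*kX0) = 12*lam_ratio."""
        return 12.0 * self.lam_ratio

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def nondimensionalize(p: PhysicalParameters) -> DimensionlessParameters:
    """Reduce a physical parameter set to its five dimensionless groups."""
    return DimensionlessParameters(
        gamma=p.Gamma,
        lam_ratio=p.lambda_X / p.lambda_m,
        koff_hat=p.k_off / p.kX0,
        kD_hat=p.kD0 / p.kX0,
        lamD_hat=p.lambda_D / p.lambda_X,
    )


def realize(d: DimensionlessParameters) -> PhysicalParameters:
    """One physical realization of the groups ``d``.

    The four scale-setting constants (lambda_X, kX0, rho_0 and the thickness
    scale via rho_w = m_w = mu0 = k_p = 1) are fixed to one and the remaining
    parameters solved for; ``nondimensionalize`` of the result round-trips.
    """
    return PhysicalParameters(
        P=12.0 * d.lam_ratio,
        rho_w=1.0,
        mu0=1.0,
        m_w=1.0,
        rho_0=1.0,
        k_p=1.0,
        lambda_X=1.0,
        lambda_D=d.lamD_hat,
        kX0=1.0,
        kD0=d.kD_hat,
        k_off=d.koff_hat,
        Gamma=d.gamma,
    )


def _profile_constants(p) -> tuple[float, float, float, float, float]:
    """(kX0, lambda_X, kD0, lambda_D, mu0) for physical or dimensionless p."""
    if isinstance(p, PhysicalParameters):
        return p.kX0, p.lambda_X, p.kD0, p.lambda_D, p.mu0
    if isinstance(p, DimensionlessParameters):
        return 1.0, 1.0, p.kD_hat, p.lamD_hat, 1.0
    raise TypeError(f"expected parameter object, got {type(p).__name__}")


def exocytosis_rate(s, p):
    """Gaussian apical exocytosis rate kX(s) = kX0 exp(-s^2/lambda_X^2)."""
    kX0, lamX, *_ = _profile_constants(p)
    return kX0 * np.exp(-np.square(np.asarray(s, dtype=float) / lamX))


def endocytosis_rate(s, p):
    """Gaussian apical endocytosis rate kD(s) = kD0 exp(-s^2/lambda_D^2)."""
    _, _, kD0, lamD, _ = _profile_constants(p)
    return kD0 * np.exp(-np.square(np.asarray(s, dtype=float) / lamD))


def viscosity(s, p):
    """Wall viscosity mu(s) = mu0 exp(+s^2/lambda_X^2), minimal at the apex."""
    kX0, lamX, _, _, mu0 = _profile_constants(p)
    return mu0 * np.exp(np.square(np.asarray(s, dtype=float) / lamX))


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization, integrator and outcome-classification settings.

    Lengths are in units of lambda_X, times in units of 1/kX0, thicknesses in
    units of H0.  Defaults give converged steady profiles at desktop cost;
    coarser settings (n_grid ~ 61-81, domain_len ~ 6) are adequate for regime
    classification in parameter sweeps.
    """

    n_grid: int = 121  #: arclength nodes (>= 51)
    domain_len: float = 8.0  #: domain length L in lambda_X units (>= 6)
    steady_tol: float = 1e-3  #: steady-state residual threshold
    t_max: float = 500.0  #: maximum simulated time
    h_min_frac: float = 0.05  #: piercing threshold, fraction of H0
    h_max_frac: float = 20.0  #: runaway-thickening threshold, fraction of H0
    rtol: float = 1e-6  #: integrator relative tolerance
    atol: float = 1e-9  #: integrator absolute tolerance
    remesh_every: float = 5.0  #: time between remeshing passes
    first_chunk: float = 1.0  #: first integration chunk length
    max_chunk: float = 25.0  #: cap on (doubling) chunk lengths
    ic_tip_radius: float = 1.5  #: initial hemispherical cap radius
    ic_smooth: float = 0.3  #: mollification width of the cap/tube junction
    normal_strain_in_eps_s: bool = True  #: include vn*kappa_s in eps_s kinematics

    def __post_init__(self) -> None:
        if self.n_grid < 51:
            raise ValueError("n_grid must be >= 51")
        if self.domain_len < 6:
            raise ValueError("domain_len must be >= 6")
        if not (0 < self.h_min_frac < 1 < self.h_max_frac):
            raise ValueError("need 0 < h_min_frac < 1 < h_max_frac")
        for name in ("steady_tol", "t_max", "rtol", "atol", "remesh_every",
                     "first_chunk", "max_chunk", "ic_tip_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ic_smooth < 0:
            raise ValueError("ic_smooth must be >= 0")

    @property
    def ds(self) -> float:
        return self.domain_len / (self.n_grid - 1)

    @property
    def s(self) -> np.ndarray:
        return np.linspace(0.0, self.domain_len, self.n_grid)

    def with_(self, **kw) -> "NumericsConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
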