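"""Instantaneous mechanics of the pressurized axisymmetric viscous shell.

Given a meridian shape, a thickness profile and a viscosity profile, this
module solves the quasi-static force balance for the membrane tensions,
inverts the viscous constitutive law for the strain (expansion) rates, and
reconstructs the tangential/normal velocity fields of the wall.

Geometry convention: the meridian is parameterized by arclength ``s`` from
the apex, with local radius ``r(s)`` and ``theta(s)`` the angle between the
outward normal and the growth axis, so dr/ds = cos(theta), dz/ds =
-sin(theta) (growth axis out of the tip) and the principal curvatures are
kappa_s = d(theta)/ds (meridional) and kappa_phi = sin(theta)/r (azimuthal),
with the apex limit kappa_phi(0) = kappa_s(0).

Force balance (membrane, no bending):

    sigma_ss*kappa_s + sigma_pp*kappa_phi = P,   sigma_ss*kappa_phi = P/2

Viscous constitutive law (thin incompressible shell, surface viscosity
4*mu*h against stretching):

    sigma_ss = 4*mu*h*(eps_s + eps_phi/2),  sigma_pp = 4*mu*h*(eps_s/2 + eps_phi)

Velocity kinematics (full thin-shell relations, reducing to eps_s = du/ds,
eps_phi = u*cos(theta)/r when the surface is not moving normally):

    eps_s  = du/ds + vn*kappa_s
    eps_phi = u*cos(theta)/r + vn*kappa_phi

Strain rates determine the wall velocity only up to a rigid translation
along the growth axis (null mode u = c*sin(theta), vn = -c*cos(theta));
every quantity fed back into the dynamics is invariant under this gauge.
The reported fields fix the gauge by du/ds = 0 at the apex (for tip shapes),
the frame in which a uniformly inflating sphere has u = 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fd import NONE, ODD, cumint_matrix, diff_matrix

__all__ = [
    "ShellShape",
    "TensionField",
    "StrainRateField",
    "VelocityField",
    "MechanicsError",
    "KinematicsError",
    "curvatures_from_shape",
    "tensions_from_pressure",
    "strain_rates_from_tensions",
    "velocities_from_strain_rates",
    "sphere_expansion_oracle",
]


class MechanicsError(ValueError):
    """Shape incompatible with a pressurized convex tip."""


class KinematicsError(ValueError):
    """Strain-rate field violates apex axisymmetry."""


_APEX_TOL = 1e-8


def _has_apex(r: np.ndarray, theta: np.ndarray) -> bool:
    return abs(r[0]) < _APEX_TOL and abs(theta[0]) < _APEX_TOL


@dataclass(frozen=True)
class ShellShape:
    """Discretized axisymmetric meridian on a uniform arclength grid."""

    s: np.ndarray  #: arclength nodes, 0 (apex) .. L
    r: np.ndarray  #: local radius
    theta: np.ndarray  #: angle outward-normal vs growth axis
    kappa_s: np.ndarray  #: meridional curvature
    kappa_phi: np.ndarray  #: azimuthal curvature (apex-regularized)
    #: axial coordinate (apex at 0, tube at z < 0); if omitted it is
    #: reconstructed from theta assuming s is exact arclength
    z: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.s)

    @property
    def ds(self) -> float:
        return float(self.s[1] - self.s[0])

    @property
    def has_apex(self) -> bool:
        return _has_apex(self.r, self.theta)

    @classmethod
    def from_profile(cls, s, r, theta) -> "ShellShape":
        """Build a shape from (s, r, theta), computing curvatures numerically."""
        s = np.asarray(s, float)
        r = np.asarray(r, float)
        theta = np.asarray(theta, float)
        ks, kp = curvatures_from_shape(s, r, theta)
        return cls(s=s, r=r, theta=theta, kappa_s=ks, kappa_phi=kp)

    def axial(self) -> np.ndarray:
        """Axial coordinate, apex at z = 0, tube at z < 0."""
        if self.z is not None:
            return self.z
        Q = cumint_matrix(self.n, self.ds,
                          ODD if self.has_apex else NONE)
        return -(Q @ np.sin(self.theta))


@dataclass(frozen=True)
class TensionField:
    sigma_ss: np.ndarray  #: meridional tension (force/length)
    sigma_pp: np.ndarray  #: azimuthal tension (force/length)


@dataclass(frozen=True)
class StrainRateField:
    eps_s: np.ndarray  #: meridional expansion rate (1/time)
    eps_phi: np.ndarray  #: azimuthal expansion rate (1/time)

    @property
    def total(self) -> np.ndarray:
        """Area expansion rate eps_s + eps_phi."""
        return self.eps_s + self.eps_phi


@dataclass(frozen=True)
class VelocityField:
    u: np.ndarray  #: tangential wall velocity
    vn: np.ndarray  #: normal wall velocity


def curvatures_from_shape(s, r, theta) -> tuple[np.ndarray, np.ndarray]:
    """Principal curvatures (kappa_s, kappa_phi) from the meridian profile.

    kappa_s by 4th-order differentiation of theta (odd parity through the
    apex); kappa_phi = sin(theta)/r with the L'Hopital value kappa_s(0) at
    the apex node.
    """
    s = np.asarray(s, float)
    r = np.asarray(r, float)
    theta = np.asarray(theta, float)
    n = len(s)
    ds = float(s[1] - s[0])
    apex = _has_apex(r, theta)
    if np.any(r[1:] <= 0) or (not apex and r[0] <= 0):
        raise MechanicsError("degenerate shape: r <= 0 away from the apex")
    ks = diff_matrix(n, ds, ODD if apex else NONE) @ theta
    with np.errstate(divide="ignore", invalid="ignore"):
        kp = np.sin(theta) / r
    if apex:
        kp[0] = ks[0]
    return ks, kp


def tensions_from_pressure(shape: ShellShape, P: float) -> TensionField:
    """Membrane tensions from normal and meridional force balance.

    Algebraic: sigma_ss = P/(2*kappa_phi), sigma_pp = (P - sigma_ss*kappa_s)
    / kappa_phi; both balance identities then hold to round-off.
    """
    kp = shape.kappa_phi
    if np.any(kp <= 0):
        raise MechanicsError("kappa_phi <= 0: shape is not a pressurized tip")
    sigma_ss = P / (2.0 * kp)
    sigma_pp = (P - sigma_ss * shape.kappa_s) / kp
    return TensionField(sigma_ss=sigma_ss, sigma_pp=sigma_pp)


def strain_rates_from_tensions(t: TensionField, mu, h) -> StrainRateField:
    """Invert the viscous constitutive law for the expansion rates.

    eps_s = (2*sigma_ss - sigma_pp)/(6*mu*h), eps_phi = (2*sigma_pp -
    sigma_ss)/(6*mu*h); exact inverse of the forward map.
    """
    mu = np.asarray(mu, float)
    h = np.asarray(h, float)
    if np.any(mu <= 0):
        raise MechanicsError("viscosity must be positive")
    if np.any(h <= 0):
        raise MechanicsError("pierced wall: thickness h <= 0")
    d = 6.0 * mu * h
    return StrainRateField(
        eps_s=(2.0 * t.sigma_ss - t.sigma_pp) / d,
        eps_phi=(2.0 * t.sigma_pp - t.sigma_ss) / d,
    )


def tensions_from_strain_rates(sr: StrainRateField, mu, h) -> TensionField:
    """Forward constitutive map (used as the round-trip oracle in tests)."""
    mu = np.asarray(mu, float)
    h = np.asarray(h, float)
    f = 4.0 * mu * h
    return TensionField(
        sigma_ss=f * (sr.eps_s + 0.5 * sr.eps_phi),
        sigma_pp=f * (0.5 * sr.eps_s + sr.eps_phi),
    )


def velocities_from_strain_rates(
    shape: ShellShape,
    sr: StrainRateField,
    include_normal_strain: bool = True,
    apex_tol: float = 1e-6,
) -> VelocityField:
    """Tangential and normal wall velocities realizing the given strain rates.

    With the full kinematics the tangential velocity solves the first-order
    ODE u' - kappa_s*cot(theta)*u = eps_s - (kappa_s/kappa_phi)*eps_phi whose
    homogeneous solution is sin(theta); factoring it out reduces the solve to
    a single quadrature u = sin(theta) * int_0^s g/sin(theta) ds'.  The
    normal velocity follows algebraically from the azimuthal relation.

    With ``include_normal_strain=False`` the abbreviated kinematics
    eps_s = du/ds is used instead (sensitivity variant): u is then the
    direct integral of eps_s and vn = (r*eps_phi - u*cos(theta))/sin(theta).

    Raises ``KinematicsError`` if the shape has an apex but the strain rates
    are not isotropic there (|eps_s(0) - eps_phi(0)| above ``apex_tol``
    relative to their scale).
    """
    n, ds = shape.n, shape.ds
    th, r = shape.theta, shape.r
    ks, kp = shape.kappa_s, shape.kappa_phi
    es, ep = sr.eps_s, sr.eps_phi
    apex = shape.has_apex
    if apex:
        scale = max(abs(es[0]), abs(ep[0]), 1e-300)
        if abs(es[0] - ep[0]) > apex_tol * max(scale, 1.0):
            raise KinematicsError(
                f"apex strain rates not isotropic: eps_s(0)={es[0]!r}, "
                f"eps_phi(0)={ep[0]!r}")
    Qo = cumint_matrix(n, ds, ODD if apex else NONE)
    sin_th = np.sin(th)
    cos_th = np.cos(th)
    if include_normal_strain:
        g = es - (ks / kp) * ep
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = g / sin_th
        if apex:
            integrand[0] = 0.0  # odd integrand, apex isotropy makes g ~ s^2
        u = sin_th * (Qo @ integrand)
    else:
        u = Qo @ es
    # vn from the azimuthal relation; apex value by L'Hopital
    with np.errstate(divide="ignore", invalid="ignore"):
        vn = (ep - u * cos_th / r) / kp
    if apex:
        vn[0] = ep[0] / kp[0]
    return VelocityField(u=u, vn=vn)


def strain_rates_from_velocities(
    shape: ShellShape, vel: VelocityField, include_normal_strain: bool = True
) -> StrainRateField:
    """Forward kinematic map (reconstruction oracle for tests)."""
    n, ds = shape.n, shape.ds
    Do = diff_matrix(n, ds, ODD if shape.has_apex else NONE)
    du = Do @ vel.u
    es = du + (vel.vn * shape.kappa_s if include_normal_strain else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ep = vel.u * np.cos(shape.theta) / shape.r + vel.vn * shape.kappa_phi
    if shape.has_apex:
        ep[0] = du[0] + vel.vn[0] * shape.kappa_phi[0]
    return StrainRateField(eps_s=es, eps_phi=ep)


def sphere_expansion_oracle(P: float, a: float, mu: float, h: float) -> float:
    """Closed-form isotropic expansion rate of a uniform pressurized sphere.

    Chaining force balance (sigma = P*a/2) and the constitutive inversion
    (eps = sigma/(6*mu*h)) gives eps = P*a/(12*mu*h).
    """
    if min(P, a, mu, h) <= 0:
        raise ValueError("all oracle inputs must be > 0")
    return P * a / (12.0 * mu * h)
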