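# Methods

## Model

The growing mating projection (shmoo) of *Saccharomyces cerevisiae* is
modelled as an axisymmetric thin shell: the cell wall, inflated by turgor
pressure `P` and behaving on growth timescales as an inhomogeneous viscous
fluid.  The meridian is parameterized by arclength `s` from the apex, with
radius `r(s,t)`, normal angle `theta(s,t)` (so `dr/ds = cos(theta)`) and
principal curvatures `kappa_s = d(theta)/ds`, `kappa_phi = sin(theta)/r`.

**Mechanics (quasi-static).** Membrane force balance

    sigma_ss*kappa_s + sigma_pp*kappa_phi = P,   sigma_ss*kappa_phi = P/2,

is solved algebraically for the tensions at every instant; no bending
stiffness or elasticity is included.  The viscous constitutive law

    sigma_ss = 4*mu*h*(eps_s + eps_phi/2),  sigma_pp = 4*mu*h*(eps_s/2 + eps_phi)

is inverted exactly for the strain (expansion) rates, with the wall
viscosity prescribed as `mu(s) = mu0*exp(s^2/lambda_X^2)`: softest at the
apex where wall-loosening enzymes are delivered by exocytosis, stiffening
so strongly away from it that distal wall is effectively frozen — which is
also why the computational domain can simply be truncated instead of
capping the viscosity.

**Assembly.** Wall material (1,3-beta-glucan) is extruded by active Fks1/2
synthases; mass conservation gives, in material form,

    Dh/Dt = -h*(eps_s + eps_phi) + (m_w*k_p/rho_w)*rho_A.

Inactive synthases are delivered by exocytosis (`kX(s) =
kX0*exp(-s^2/lambda_X^2)`), removed by endocytosis (`kD(s) =
kD0*exp(-s^2/lambda_D^2)`), activated at rate `kon` and inactivated at
`koff`.  Active synthases extrude glucan into the wall and are thereby
anchored to it: they advect with the wall and are diluted by area growth.
Inactive synthases are membrane-bound but effectively immobile (protein
diffusion on the yeast plasma membrane is slow compared with the ~1/kX0
recycling time), so their equation carries no transport term along `s`;
their geometric `r`-dilution factor is kept exactly as in the conservative
form `d(rho_I*r)/dt = r*[...]`, which holds identically in the tip-pinned
grid frame used here.

**Mechanical feedback (cell wall integrity pathway).** Wall stress sensors
(Wsc1, Mid2) relay the local mechanical state to Rho1, which activates
Fks1/2.  The sensed quantity is taken to be the wall expansion rate:

    kon = Gamma * max(eps_s + eps_phi, 0).

The clamp at zero is a modelling choice the equations do not state: a rate
cannot be negative, and synthase activation should not occur where the wall
is not expanding.  (In practice stable profiles have `eps_s + eps_phi > 0`
everywhere, so the clamp is inert there.)

**No-feedback variant.** With `Gamma = 0` the two-state scheme would have
no activation path at all and every run would trivially thin.  The
meaningful no-feedback model delivers synthases directly in the active
state ("constitutive" mode):

    d(rho_A*r)/dt + d(rho_A*r*u)/ds = r*(kX*rho_0 - kD*rho_A),

which the simulator switches to automatically when `Gamma = 0`.  This is
the variant whose instability — progressive apical thinning and piercing at
large `lambda_X/lambda_m`, unbounded thickening at small — motivates the
feedback.

## Nondimensionalization

Scales: length `lambda_X`, time `1/kX0`, synthase density `rho_0`, and wall
thickness `H0 = m_w*rho_0*k_p/(rho_w*kX0)`.  This is the unique choice
(given the first three) that strips all constants from the scaled thickness
and synthase equations; the scaled assembly source is exactly `rho_A` and
the scaled turgor pressure is `12*lam_ratio`.  Five groups remain:

| group | meaning | default |
|---|---|---|
| `lam_ratio = lambda_X/lambda_m = P*rho_w*lambda_X/(12*mu0*m_w*rho_0*k_p)` | turgor-driven expansion vs assembly capacity | control parameter |
| `gamma` | feedback strength | control parameter |
| `koff_hat = koff/kX0` | inactivation vs exocytosis rate | 1.0 |
| `kD_hat = kD0/kX0` | endocytosis vs exocytosis rate | 1.0 |
| `lamD_hat = lambda_D/lambda_X` | endocytosis vs exocytosis reach | 2.0 |

The last three are order-one placeholders (the literature constrains them
only loosely); every emitted record carries the values actually used, and
the qualitative regime structure — never-stable at `gamma = 0`, a critical
`gamma*` increasing with `lam_ratio`, radius set by `lambda_X` — does not
depend on them.  Quantitative positions of the stability boundary do: see
"Choice of reference points" below.

## Numerical scheme

Method of lines on a uniform arclength grid `s in [0, L]`, tip-co-moving:
the apex is pinned at `s = 0` and the grid tangential velocity
`W(s) = -int_0^s kappa_s*vn ds'` keeps `s` exact arclength, so steady tip
growth is a true fixed point of the discrete system and the paper grid
never stretches.  Per right-hand-side evaluation:

1. `r` from `theta` by quadrature (so `dr/ds = cos(theta)` holds by
   construction), curvatures by 4th-order differences;
2. tensions algebraically from force balance; strain rates from the exact
   constitutive inversion;
3. tangential velocity by quadrature: the ODE
   `u' - kappa_s*cot(theta)*u = eps_s - (kappa_s/kappa_phi)*eps_phi` has
   homogeneous solution `sin(theta)` (a rigid axial translation), so
   `u = sin(theta) * int g/sin(theta)`; the translation gauge is fixed by
   `du/ds = 0` at the apex, the frame in which a uniformly inflating
   sphere moves purely radially.  All quantities re-entering the dynamics
   (shape motion, relative advection `u - W`, dilution) are
   gauge-invariant;
4. `vn` algebraically from the azimuthal kinematic relation;
5. tendencies of `theta, h, rho_A, rho_I` as above, advection with the
   relative velocity `u - W`.

Spatial operators are 4th order: 5-point central stencils in the interior,
parity-reflected stencils at the apex (every field is even or odd in `s`,
which enforces the zero-derivative apex conditions exactly), one-sided
stencils at the distal boundary (outflow).  Cumulative integrals use a
composite 4th-order rule with the same parity treatment.  Apex limits
(`kappa_phi -> kappa_s`, `u/r -> 0`, `vn -> eps_phi/kappa_phi`) are imposed
by L'Hopital values.  Time integration is implicit BDF (`scipy.integrate
.solve_ivp`) with a vectorized right-hand side for cheap finite-difference
Jacobians; tolerances default to `rtol = 1e-6`, `atol = 1e-9`.

Two auxiliary scalar states integrate the source-minus-outflux terms of the
wall-mass and synthase budgets alongside the fields, so conservation
closure is measured against solver accuracy rather than output-sampling
accuracy.  Measured on the converged travelling wave (n_grid = 121) both
budgets close to a few times 1e-7 relative per unit time; the initial
transient, which flushes the arbitrary starting profile through the domain,
accumulates a larger (still < 1e-4 relative) defect that reflects the
roughness of the initial data, not the scheme.

**Kinematic variant.** The abbreviated strain-rate relation
`eps_s = du/ds` (without the `vn*kappa_s` term) is selectable via
`NumericsConfig(normal_strain_in_eps_s=False)` for sensitivity checks; it
cannot represent the inflation of a sphere and is not the default.

**Remeshing.** Because `W` preserves arclength exactly in the continuum,
remeshing is a drift correction: node arclengths are recomputed from the
`(r, z)` meridian, fields are resampled by monotone cubic (PCHIP)
interpolation, and apex values are re-imposed; `r` is rebuilt from `theta`
by quadrature.  Wall mass is preserved to interpolation accuracy (relative
error ~1e-6 at n_grid = 121 on converged profiles).  Default cadence: every
5 time units.

**Initial condition.** Hemispherical cap of radius `1.5*lambda_X` on a
cylinder, uniform scaled thickness 1, synthase densities set to the local
exo/endocytosis fixed-point profile `kX(s)/kD(s)` (split equally between
active and inactive in feedback mode; all active in constitutive mode).
The curvature jump at the cap-tube junction is mollified over `0.3
lambda_X` so the 4th-order stencils see smooth data.  Spatially uniform
starting densities are deliberately avoided: inactive synthases are not
transported, so any distal surplus would persist indefinitely as a frozen
relic.

**Outcome classification.** A run ends STABLE when the largest scaled time
derivative of `{r, h, rho_A, rho_I}` falls below `steady_tol = 1e-3`;
LYSIS_THINNING when the apical thickness falls below `0.05*H0` (piercing);
THICKENING when the thickness anywhere exceeds `20*H0`; TIMEOUT at
`t_max = 500/kX0`.  The thresholds are classification conventions, not
model physics; at `gamma >~ 20` steady thicknesses approach `20*H0` and the
THICKENING label becomes threshold-dependent.  `t_max = 500` reflects the
observed convergence time of stable runs, roughly `7.5*gamma/lam_ratio`
(the apical expansion rate, which sets the relaxation rate, scales like
`1.2*lam_ratio/gamma`).  Integration proceeds in geometrically growing
chunks with piercing/thickening as terminal solver events; solver or
geometry failures are recorded as TIMEOUT with the error message attached.

## Phase exploration

`sweep` classifies a (gamma, lam_ratio) grid by full simulation, caching by
parameter set so grids are order-independent and resumable.
`critical_gamma` bisects the lysis/stable boundary at fixed `lam_ratio`;
near-critical runs can exhaust `t_max` without classifying (critical
slowing down) and are counted as not-yet-stable, so the returned `gamma*`
bounds the feedback strength that guarantees steady growth within `t_max`.
`radius_scaling_table` varies the physical `lambda_X` (with all other
physical constants fixed, so `lam_ratio` co-varies) and `Gamma`, reporting
the dimensional radius `R = R_hat*lambda_X`, its pooled least-squares fit
against `lambda_X` and its spread across `Gamma` at fixed `lambda_X`.

## Choice of reference points and problem sizes

Under the placeholder kinetics the stable band sits at `lam_ratio ~
0.05-0.4` with `gamma*` rising from ~0.15 to ~4 across it; at
`(gamma = 10, lam_ratio = 1)` the apical assembly demand exceeds the
sustainable active-synthase density (which is capped by delivery and the
`sqrt(gamma*koff_hat*kD_hat)`-limited activation balance) and the wall
pierces during the initial transient.  The representative stable point used
throughout the documentation and checks is therefore `(gamma = 5,
lam_ratio = 0.2)`; the trend grid is `gamma in {2.5, 4, 6} x lam_ratio in
{0.12, 0.16, 0.2}`, and the size-control table uses `lambda_X in {0.7,
0.9, 1.1, 1.3}` (about `lam_ratio` 0.14-0.26) with `gamma in {3, 5, 8}`.

Classification and phase work use `n_grid = 61`, `domain_len = 6`;
profile-fidelity and conservation checks use `n_grid = 121`,
`domain_len = 8`.  Observables converge well before that: between the two
settings `R` changes by < 1e-3 relative and the apical expansion rate by
< 1e-3 relative.

## What the checks do and do not show

The analytic fixtures (sphere, cylinder, capped cylinder) validate the
discrete operators against closed forms; the simulated phase diagram
reproduces the qualitative regime structure (no stability without
feedback; both failure modes; monotone boundary; radius set by the
exocytosis scale, weakly dependent on feedback — a few percent across a
decade of `gamma`).  None of this calibrates the model to measured yeast
parameters: turgor, viscosity and the kinetic ratios are not fitted, the
placeholder kinetics shift the quantitative position of the boundary, and
real shmoos involve regulation (osmotic control, polarisome dynamics, the
transcriptional branch of the integrity pathway) deliberately outside the
model.  Within the model, one caveat is worth noting: at very weak feedback
(e.g. `gamma = 0.2`) the active-synthase *fraction* can peak slightly off
apex even though expansion rate, total density and activity all still peak
at the apex at ordinary feedback strengths.

## Known limitations

- Purely viscous wall: no elastic or elastoplastic constitutive options,
  no bending resistance.
- No linear-stability eigenanalysis; instability is established by time
  integration, so "unstable" means "classified within `t_max`".
- The inactive-synthase equation is implemented literally (no surface
  transport); whether membrane flow should advect `rho_I` is an open
  modelling question, flagged for sensitivity analysis.
- Observables `R` and `H` are read from the distal plateau (last 10% of
  the domain, flatness < 1% enforced by `extract_observables`); very
  slowly growing runs can satisfy the steady-state criterion while the
  thickness plateau is marginally unflushed, in which case a longer domain
  or duration is required.
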